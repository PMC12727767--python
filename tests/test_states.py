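import numpy as np
import pandas as pd
import pytest

from loomsync.states import (
    FREEZE,
    HIGH,
    NORMAL,
    ThresholdSpec,
    classify_interval,
    classify_trial,
    derive_thresholds,
    label_frames,
)
from loomsync.trajectory_io import VelocityMatrix


def oracle_classify(labels, th: ThresholdSpec) -> str:
    """Independent frame-counting oracle (plain Python, no shared helpers)."""
    labels = list(labels)
    if th.freeze_duration == "total":
        freeze = sum(1 for l in labels if l == FREEZE)
    else:
        freeze = best = 0
        for l in labels:
            freeze = freeze + 1 if l == FREEZE else 0
            best = max(best, freeze)
        freeze = best
    high = sum(1 for l in labels if l == HIGH)
    satisfied = {
        "HS": high >= round(th.hs_min_s * th.fps),
        "FS": freeze >= round(th.fs_min_s * th.fps),
        "NS": True,
    }
    for s in th.precedence:
        if satisfied[s]:
            return s


class TestFrameLabels:
    @pytest.mark.parametrize(
        "speed, expected",
        [(0.1, FREEZE), (0.2, NORMAL), (0.19999, FREEZE), (5.99, NORMAL), (6.0, HIGH)],
    )
    def test_threshold_boundaries(self, speed, expected):
        assert label_frames(np.array([speed]))[0] == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            label_frames(np.array([-0.1]))


class TestIntervalClassification:
    def test_full_freezing_is_fs(self):
        assert classify_interval(np.full(50, FREEZE)).value == "FS"

    def test_all_normal_is_ns(self):
        st = classify_interval(np.full(50, NORMAL))
        assert st.value == "NS" and st.freeze_s == 0.0

    def test_single_high_frame_is_hs(self):
        frames = np.full(50, NORMAL)
        frames[30] = HIGH
        st = classify_interval(frames)
        assert st.value == "HS" and st.high_frames == 1

    def test_intermediate_freezing_is_ns(self):
        # 5 s of freezing: below the 8 s FS rule, above the 2 s NS rule
        frames = np.array([FREEZE] * 25 + [NORMAL] * 25)
        assert classify_interval(frames).value == "NS"

    def test_hs_precedence_over_fs(self):
        frames = np.array([FREEZE] * 45 + [NORMAL] * 4 + [HIGH])
        assert classify_interval(frames).value == "HS"
        th = ThresholdSpec(precedence=("FS", "HS", "NS"))
        assert classify_interval(frames, th).value == "FS"

    def test_total_vs_consecutive_duration(self):
        frames = np.array([FREEZE] * 20 + [NORMAL] * 10 + [FREEZE] * 20)
        assert classify_interval(frames).value == "FS"  # total 8 s
        th = ThresholdSpec(freeze_duration="consecutive")
        assert classify_interval(frames, th).value == "NS"  # longest run 4 s

    def test_wrong_frame_count_rejected(self):
        with pytest.raises(ValueError, match="50 frames"):
            classify_interval(np.full(49, NORMAL))

    @pytest.mark.parametrize("mode", ["total", "consecutive"])
    def test_agrees_with_counting_oracle(self, mode, rng):
        th = ThresholdSpec(freeze_duration=mode)
        for _ in range(2000):
            frames = rng.integers(0, 3, 50).astype(np.int8)
            assert classify_interval(frames, th).value == oracle_classify(frames, th)

    def test_monotone_in_evidence(self, rng):
        """Adding a high frame never removes HS; adding freeze never turns FS to NS."""
        for _ in range(300):
            frames = rng.integers(0, 3, 50).astype(np.int8)
            before = classify_interval(frames).value
            plus_high = frames.copy()
            plus_high[int(rng.integers(50))] = HIGH
            assert classify_interval(plus_high).value == "HS"
            plus_freeze = frames.copy()
            plus_freeze[frames == NORMAL] = FREEZE
            after = classify_interval(plus_freeze).value
            if before == "FS":
                assert after in ("FS", "HS")


class TestTrialClassification:
    def test_uniform_freezing(self):
        assert classify_trial(np.full(150, 0.05)) == ("FS", "FS", "FS")

    def test_reactive_pattern(self):
        speeds = np.concatenate([np.full(50, 1.0), np.full(50, 7.0), np.full(50, 0.01)])
        assert classify_trial(speeds) == ("NS", "HS", "FS")

    def test_sustained_normal(self):
        assert classify_trial(np.full(150, 1.0)) == ("NS", "NS", "NS")


def _vm_from_rows(rows: np.ndarray) -> VelocityMatrix:
    idx = pd.MultiIndex.from_tuples(
        [(0, t, i) for t in range(rows.shape[0] // 6 + 1) for i in range(6)][: rows.shape[0]],
        names=["group", "trial", "individual"],
    )
    data = pd.DataFrame(rows, index=idx, columns=range(150))
    return VelocityMatrix(data=data, conditions=pd.Series("x", index=idx))


class TestDeriveThresholds:
    def test_bimodal_point_masses_trough_between(self, rng):
        rows = np.empty((12, 150))
        rows[:] = 1.0 + rng.normal(0, 0.01, (12, 150))
        rows[:6, 100:] = 0.01 + rng.normal(0, 0.002, (6, 50)).clip(-0.005, 0.005)
        th = derive_thresholds(_vm_from_rows(np.abs(rows)))
        assert 0.01 < th.v_freeze < 1.0
        assert not th.fallback

    def test_unimodal_falls_back_with_warning(self, rng):
        rows = np.abs(1.0 + rng.normal(0, 0.05, (12, 150)))
        with pytest.warns(UserWarning, match="fallback"):
            th = derive_thresholds(_vm_from_rows(rows))
        assert (th.v_freeze, th.v_high) == (0.2, 6.0)
        assert th.fallback

    def test_default_simulation_recovers_canonical_thresholds(self, small_vm):
        """The generator's speed mixture puts the KDE trough near 0.2 cm/s and
        the pre-LS/burst overlap boundary near 6 cm/s by construction."""
        th = derive_thresholds(small_vm)
        assert not th.fallback
        assert 0.1 <= th.v_freeze <= 0.3
        assert 5.0 <= th.v_high <= 7.0

    def test_matches_brute_force_kde_grid_minimisation(self, small_vm):
        from scipy.stats import gaussian_kde

        th = derive_thresholds(small_vm, bw_method=0.05, grid_size=2048)
        post = small_vm.interval("after").ravel()
        grid = np.linspace(0, post.max(), 2048)
        dens = gaussian_kde(post, bw_method=0.05)(grid)
        # brute force: minimum density on the grid strictly between the modes
        peaks = [
            i for i in range(1, len(grid) - 1)
            if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
        ]
        top2 = sorted(sorted(peaks, key=lambda i: dens[i])[-2:])
        lo, hi = top2
        brute = grid[lo + int(np.argmin(dens[lo : hi + 1]))]
        assert th.v_freeze == pytest.approx(brute, abs=1e-9)
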