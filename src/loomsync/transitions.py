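"""Markov transition matrices, 27-pattern enumeration, and enrichment tests.

A trial's response is the ordered state triple (before, during, after LS)
drawn from {FS, NS, HS}^3, giving 27 possible transition patterns.  Each
one-step transition matrix counts transitions between states and normalises
each row.  Pattern enrichment is a one-sided (upper-tail) exact binomial
test of each pattern's count against the uniform null p0 = 1/27, with
Benjamini-Hochberg FDR correction across all 27 patterns (zero-count
patterns stay in the family with p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

STATES = ("FS", "NS", "HS")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
STATE_LETTER = {"FS": "F", "NS": "N", "HS": "H"}
N_PATTERNS = 27
STEPS = ("before_during", "during_after")


@dataclass(frozen=True)
class PatternCode:
    """One of the 27 (before, during, after) state sequences.

    Index encoding: FS=0, NS=1, HS=2 and index = 9*before + 3*during + after.
    """

    triple: tuple[str, str, str]
    index: int

    @classmethod
    def from_triple(cls, triple) -> "PatternCode":
        b, d, a = triple
        idx = 9 * STATE_INDEX[b] + 3 * STATE_INDEX[d] + STATE_INDEX[a]
        return cls(triple=(b, d, a), index=idx)

    @classmethod
    def from_index(cls, index: int) -> "PatternCode":
        if not 0 <= index < N_PATTERNS:
            raise ValueError(f"pattern index out of range: {index}")
        b, rem = divmod(index, 9)
        d, a = divmod(rem, 3)
        return cls(triple=(STATES[b], STATES[d], STATES[a]), index=index)

    @property
    def label(self) -> str:
        return "→".join(STATE_LETTER[s] for s in self.triple)


def enumerate_patterns() -> list[PatternCode]:
    """All 27 pattern codes in index order (a bijection with 0..26)."""
    return [PatternCode.from_index(i) for i in range(N_PATTERNS)]


def _as_triples(obj) -> list[tuple[str, str, str]]:
    if isinstance(obj, pd.DataFrame):
        return list(map(tuple, obj[["before", "during", "after"]].to_numpy()))
    return [tuple(t) for t in obj]


@dataclass
class TransitionMatrix:
    """One-step 3x3 transition counts and row-normalised probabilities.

    State order is fixed as (FS, NS, HS).  Rows with zero counts are left
    all-zero in ``probs`` and listed in ``zero_rows`` rather than divided.
    """

    counts: np.ndarray
    probs: np.ndarray
    zero_rows: list[str]
    step: str


def count_transitions(triples, step: str = "before_during") -> TransitionMatrix:
    """Count one-step transitions over all triples and row-normalise."""
    if step not in STEPS:
        raise ValueError(f"step must be one of {STEPS}, got {step!r}")
    triples = _as_triples(triples)
    if not triples:
        raise ValueError("no state triples given")
    src, dst = (0, 1) if step == "before_during" else (1, 2)
    counts = np.zeros((3, 3), dtype=int)
    for t in triples:
        counts[STATE_INDEX[t[src]], STATE_INDEX[t[dst]]] += 1
    probs = np.zeros((3, 3))
    zero_rows = []
    for r in range(3):
        tot = counts[r].sum()
        if tot:
            probs[r] = counts[r] / tot
        else:
            zero_rows.append(STATES[r])
    return TransitionMatrix(counts=counts, probs=probs, zero_rows=zero_rows, step=step)


def interval_state_counts(triples) -> dict[str, np.ndarray]:
    """Occupancy of each state (FS, NS, HS order) in each of the three intervals."""
    triples = _as_triples(triples)
    out = {}
    for k, name in enumerate(("before", "during", "after")):
        c = np.zeros(3, dtype=int)
        for t in triples:
            c[STATE_INDEX[t[k]]] += 1
        out[name] = c
    return out


def pattern_frequencies(triples) -> pd.DataFrame:
    """Count each of the 27 patterns; zero-count patterns are retained."""
    triples = _as_triples(triples)
    if not triples:
        raise ValueError("no state triples given")
    counts = np.zeros(N_PATTERNS, dtype=int)
    for t in triples:
        counts[PatternCode.from_triple(t).index] += 1
    pats = enumerate_patterns()
    return pd.DataFrame(
        {
            "index": [p.index for p in pats],
            "pattern": [p.label for p in pats],
            "count": counts,
            "freq": counts / counts.sum(),
        }
    )


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def binomial_enrichment(
    table: pd.DataFrame, n: int | None = None, p0: float = 1.0 / N_PATTERNS
) -> pd.DataFrame:
    """One-sided exact binomial enrichment of each pattern against p0.

    p = P(X >= k) for X ~ Binomial(n, p0); q by Benjamini-Hochberg over the
    full 27-pattern family; stars mark q < 0.05 / 0.01 / 0.001.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    counts = table["count"].to_numpy()
    if n is None:
        n = int(counts.sum())
    if np.any(counts > n):
        raise ValueError("a pattern count exceeds the number of trials n")
    p = binom.sf(counts - 1, n, p0)  # upper tail including k
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = table.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["stars"] = [_stars(v) for v in q]
    return out


def export_dot(
    m_bd: TransitionMatrix,
    m_da: TransitionMatrix,
    state_counts: dict[str, np.ndarray],
) -> str:
    """State-transition diagram as DOT text.

    Nine nodes (three states x three intervals) sized by state occupancy;
    edges carry the transition probability (two decimals) as label and a
    pen width proportional to the transition count.  Only observed
    (count > 0) transitions get edges.
    """
    intervals = ("before", "during", "after")
    colors = {"FS": "gray", "NS": "lightblue", "HS": "red"}
    totals = {iv: max(int(state_counts[iv].sum()), 1) for iv in intervals}
    max_count = max(int(m.counts.max()) for m in (m_bd, m_da)) or 1
    lines = [
        "digraph transitions {",
        "  rankdir=LR;",
        '  node [shape=circle, style=filled, fixedsize=true];',
    ]
    for iv in intervals:
        for s in STATES:
            n = int(state_counts[iv][STATE_INDEX[s]])
            width = 0.4 + 1.6 * n / totals[iv]
            lines.append(
                f'  "{iv}_{s}" [label="{s}\\n{n}", width={width:.2f}, '
                f'fillcolor={colors[s]}];'
            )
    for m, (src_iv, dst_iv) in ((m_bd, ("before", "during")), (m_da, ("during", "after"))):
        for r, s_from in enumerate(STATES):
            for c, s_to in enumerate(STATES):
                cnt = int(m.counts[r, c])
                if cnt == 0:
                    continue
                pen = 0.5 + 5.0 * cnt / max_count
                lines.append(
                    f'  "{src_iv}_{s_from}" -> "{dst_iv}_{s_to}" '
                    f'[label="{m.probs[r, c]:.2f}", penwidth={pen:.2f}];'
                )
    lines.append("}")
    return "\n".join(lines) + "\n"
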