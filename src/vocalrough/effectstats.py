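"""Nonparametric effect sizes and tests shared by all analyses.

Cliff's delta d = (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y) with the
conventional magnitude bins (negligible / small / medium / large at 0.147,
0.33, 0.474); two-sided Wilcoxon signed-rank for paired and Mann-Whitney
rank-sum for unpaired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

NEGLIGIBLE = "negligible"
SMALL = "small"
MEDIUM = "medium"
LARGE = "large"

# boundary values fall into the lower bin (strict upper inequalities)
_BIN_EDGES = ((0.147, NEGLIGIBLE), (0.33, SMALL), (0.474, MEDIUM))


@dataclass
class EffectSizeReport:
    d: float
    bin: str
    test: str | None = None
    p: float | None = None


def effect_bin(d: float) -> str:
    a = abs(d)
    for edge, label in _BIN_EDGES:
        if a <= edge:
            return label
    return LARGE


def cliffs_delta(x, y) -> EffectSizeReport:
    """Cliff's delta via the rank/U statistic (tie-aware, O(n log n)).

    Equivalent to full pairwise enumeration: the Mann-Whitney U counts each
    pair with x > y as 1 and ties as 1/2, so d = 2U/(n_x n_y) - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    d = 2.0 * u / (x.size * y.size) - 1.0
    # clamp fp residue
    d = float(np.clip(d, -1.0, 1.0))
    return EffectSizeReport(d, effect_bin(d))


def cliffs_delta_bruteforce(x, y) -> float:
    """Full pairwise enumeration — the independent check for small samples."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((np.sign(x - y)).mean())


def cliffs_delta_matrix(a: np.ndarray, b: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Cell-wise Cliff's delta between two stacks of equally shaped maps.

    ``a`` has shape (n_a, ...), ``b`` (n_b, ...); the delta is computed
    independently per trailing cell, chunked to bound memory.
    """
    na, nb = a.shape[0], b.shape[0]
    cells = int(np.prod(a.shape[1:]))
    af = a.reshape(na, cells)
    bf = b.reshape(nb, cells)
    out = np.empty(cells)
    for lo in range(0, cells, chunk):
        hi = min(lo + chunk, cells)
        diff = np.sign(af[:, None, lo:hi] - bf[None, :, lo:hi])
        out[lo:hi] = diff.mean(axis=(0, 1))
    return out.reshape(a.shape[1:])


def paired_and_unpaired_tests(x, y, paired: bool) -> float:
    """Two-sided nonparametric p-value.

    Paired: Wilcoxon signed-rank (exact for n <= 25 without zeros/ties,
    normal approximation otherwise — the library's own switch point).
    Unpaired: Mann-Whitney rank-sum.  All-zero paired differences leave the
    signed-rank undefined; ``nan`` is returned and flagged to the caller by
    that value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        diffs = x - y
        if np.all(diffs == 0):
            return float("nan")
        return float(stats.wilcoxon(x, y).pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def compare_groups(x, y, paired: bool = False) -> EffectSizeReport:
    """Effect size plus the matching nonparametric test in one report."""
    rep = cliffs_delta(x, y)
    rep.test = "signrank" if paired else "ranksum"
    rep.p = paired_and_unpaired_tests(x, y, paired)
    return rep
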