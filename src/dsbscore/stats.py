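"""Small statistical primitives: exact Wilcoxon signed-rank and the
normality-gated two-group comparison used for pathway-score contrasts."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank", "GroupComparison", "compare_scores"]

EXACT_N_MAX = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after zero differences are dropped
    method: str  # "exact" or "approx"
    direction: int  # sign of the median/mean paired difference


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped (Wilcoxon's original treatment). For
    ``n <= 12`` remaining pairs the null distribution of W+ is obtained by
    full enumeration of all 2^n sign assignments on the tie-averaged ranks of
    |d|, so the p-value is exact even with tied magnitudes; larger n uses the
    normal approximation with tie correction.

    The two-sided p-value is ``P(|W' - mu| >= |W - mu|)`` with
    ``mu = n(n+1)/4``, the center of the null distribution.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.ndim != 1:
        raise ValueError("paired samples must be 1-D")
    d = d[d != 0]
    n = d.size
    direction = int(np.sign(d.sum())) if n else 0
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "exact", 0)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_N_MAX:
        # all 2^n sign assignments, vectorized: rows = assignments
        signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= np.abs(w_pos - mu) - 1e-12))
        return WilcoxonResult(w_pos, min(p, 1.0), n, "exact", direction)
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return WilcoxonResult(w_pos, float(res.pvalue), n, "approx", direction)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two-group score comparison with a normality gate."""

    labels: tuple[str, str]
    test: str  # "t-test" or rank-based fallback name
    gate_p: tuple[float, float]  # Shapiro–Wilk p per group
    gate_passed: bool
    statistic: float
    p_value: float
    means: tuple[float, float]
    n: tuple[int, int]
    paired: bool

    def to_dict(self) -> dict:
        return asdict(self)


def compare_scores(groups, paired: bool = False, alpha_gate: float = 0.05) -> GroupComparison:
    """Compare two score vectors, gating the t-test on Shapiro–Wilk normality.

    ``groups`` is ``[(label, values), (label, values)]``. Zero-score exclusion
    is applied upstream; each group needs at least 3 observations. If both
    groups pass the Shapiro–Wilk gate at ``alpha_gate`` a t-test is used
    (Welch if unpaired, paired otherwise); otherwise the rank-based fallback
    (Mann–Whitney rank-sum, or Wilcoxon signed-rank when paired).
    """
    if len(groups) != 2:
        raise ValueError("compare_scores expects exactly two groups")
    (la, xa), (lb, xb) = groups
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs n >= 3 observations")
    if paired and xa.size != xb.size:
        raise ValueError("paired comparison requires equal group sizes")

    def _shapiro_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 0.0  # degenerate constant vector: treat as non-normal
        return float(sps.shapiro(v).pvalue)

    ga, gb = _shapiro_p(xa), _shapiro_p(xb)
    gate = ga > alpha_gate and gb > alpha_gate
    if np.array_equal(xa, xb):
        stat, p, test = 0.0, 1.0, "t-test" if gate else ("wilcoxon-signed-rank" if paired else "rank-sum")
    elif gate:
        if paired:
            stat, p = sps.ttest_rel(xa, xb)
        else:
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        stat, p, test = float(stat), float(p), "t-test"
    elif paired:
        r = wilcoxon_signed_rank(xa, xb)
        stat, p, test = r.statistic, r.p_value, "wilcoxon-signed-rank"
    else:
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        stat, p, test = float(stat), float(p), "rank-sum"
    return GroupComparison(
        labels=(str(la), str(lb)), test=test, gate_p=(ga, gb), gate_passed=gate,
        statistic=stat, p_value=p, means=(float(xa.mean()), float(xb.mean())),
        n=(int(xa.size), int(xb.size)), paired=paired,
    )
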