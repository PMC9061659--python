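"""Agreement statistics: Bland-Altman, proportional bias, rank tests.

The rank statistics are implemented from their definitions (midranks for
ties, normal approximation with continuity correction for larger samples,
exact enumeration otherwise) rather than delegated, so that the test suite
can check them against an independent reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from perisim.geometry import TestGrid

__all__ = [
    "AgreementSummary",
    "PointwiseMap",
    "bland_altman",
    "proportional_bias",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "pointwise_bias_map",
]

_LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias, limits of agreement and proportional-bias test."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    prop_slope: float | None = None
    prop_t: float | None = None
    prop_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
            "prop_slope": self.prop_slope,
            "prop_t": self.prop_t,
            "prop_p": self.prop_p,
        }


@dataclass(frozen=True)
class PointwiseMap:
    """Per-location bias (and SD) of paired differences across subjects."""

    grid: TestGrid
    bias: np.ndarray
    sd: np.ndarray
    n: int
    convention: str = "difference = first - second"

    def to_rows(self) -> list[tuple[int, int, float, float]]:
        return [
            (p.x, p.y, float(self.bias[i]), float(self.sd[i]))
            for i, p in enumerate(self.grid.points)
        ]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return x, y


def bland_altman(x, y, with_regression: bool = True) -> AgreementSummary:
    """Agreement of paired measurements; differences are x - y."""
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise ValueError("at least 2 pairs are required")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    summary = dict(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - _LOA_MULTIPLIER * sd,
        loa_high=bias + _LOA_MULTIPLIER * sd,
        n=n,
    )
    if with_regression and n >= 3:
        slope, t, p = proportional_bias(x, y)
        summary.update(prop_slope=slope, prop_t=t, prop_p=p)
    return AgreementSummary(**summary)


def proportional_bias(x, y) -> tuple[float, float, float]:
    """OLS of the difference on the pair mean; t-test for slope != 0."""
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("at least 3 pairs are required")
    d = x - y
    m = (x + y) / 2.0
    mc = m - m.mean()
    sxx = float(np.sum(mc**2))
    if sxx == 0:
        raise ValueError("pair means have zero variance")
    slope = float(np.sum(mc * d) / sxx)
    intercept = float(d.mean() - slope * m.mean())
    resid = d - (intercept + slope * m)
    dof = n - 2
    s2 = float(np.sum(resid**2)) / dof
    se = (s2 / sxx) ** 0.5
    if se == 0:
        t = 0.0 if slope == 0 else float("inf") * np.sign(slope)
    else:
        t = slope / se
    p = float(2.0 * _st.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
    return slope, float(t), p


def _midranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sa = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value."""
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("at least 3 pairs are required")
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("rho is undefined for constant input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * _st.t.sf(abs(t), n - 2))
    return rho, p


def _wilcoxon_exact_cdf(ranks: np.ndarray, t_obs: float) -> tuple[float, float]:
    """P(T+ <= t_obs) and P(T+ >= t_obs) by dynamic programming.

    Valid for integer ranks (no ties).
    """
    total = int(np.sum(ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    t_int = int(round(t_obs))
    return float(counts[: t_int + 1].sum()), float(counts[t_int:].sum())


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties get midranks.  Exact p for n <= 25
    with untied ranks, otherwise the normal approximation with tie and
    continuity corrections.  The statistic is the smaller of the positive
    and negative rank sums.
    """
    x, y = _paired(x, y)
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero; no signal to test")
    r = _midranks(np.abs(d))
    t_plus = float(np.sum(r[d > 0]))
    t_minus = float(np.sum(r[d < 0]))
    stat = min(t_plus, t_minus)
    has_ties = np.unique(np.abs(d)).size != n
    if n <= 25 and not has_ties:
        lo, hi = _wilcoxon_exact_cdf(r, t_plus)
        p = min(1.0, 2.0 * min(lo, hi))
        return stat, p
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        raise ValueError("degenerate variance in the signed-rank test")
    z = (stat - mu + 0.5) / np.sqrt(var)  # continuity correction toward 0
    p = min(1.0, 2.0 * float(_st.norm.cdf(z)))
    return stat, p


def pointwise_bias_map(fields_a, fields_b, grid: TestGrid) -> PointwiseMap:
    """Per-location Bland-Altman bias across subjects.

    ``fields_a`` and ``fields_b`` are (n_subjects, n_locations) arrays in the
    same subject order; the map reports mean and SD of a - b per location.
    """
    a = np.asarray(fields_a, dtype=float)
    b = np.asarray(fields_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("field sets must have identical shapes")
    if a.shape[1] != len(grid):
        raise ValueError("field width does not match the grid")
    d = a - b
    return PointwiseMap(
        grid=grid,
        bias=np.mean(d, axis=0),
        sd=np.std(d, axis=0, ddof=1) if d.shape[0] > 1 else np.zeros(d.shape[1]),
        n=a.shape[0],
    )
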