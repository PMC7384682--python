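"""Two-sample tests, p-value aggregation, confidence bands, similarity measures.

First-level comparisons of per-cluster feature distributions use the
two-sample Kolmogorov–Smirnov test (asymptotic) and the Wilcoxon
rank-sum test (exact for small samples, normal approximation with tie
correction otherwise).  The two p-values at each cluster dimension are
fused with a weighted t-norm AND operator from fuzzy logic,

    p_and = 1 - sqrt(w (1-pv)^2 + (1-w) (1-pw)^2),

which is idempotent (p AND p = p) and lets the weight w favour one test.

Second-level (global) comparisons use empirical two-sided rank p-values
of one sample's mean feature against the other sample's bootstrap
distribution, plus normal and bootstrap-percentile confidence bands.

Two scalar similarity measures in [0, 1] summarise an aggregated p-value
curve against a significance level alpha: sim_M from the curve's mean,
and sim_L from the overlap between the critical strip [0, alpha] and the
area under the band's lower bound.  Below 0.45 the samples are read as
dissimilar, above 0.55 as similar, in between as marginal.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "ks_2sample",
    "wx_2sample",
    "tnorm_and",
    "multivariate_ks",
    "empirical_pvalue",
    "confidence_band",
    "sim_M",
    "sim_L",
    "verdict",
]

MARGINAL_LO = 0.45
MARGINAL_HI = 0.55


def _check_nonempty(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    return x, y


def ks_2sample(x, y) -> float:
    """Two-sided asymptotic two-sample KS p-value.

    p = Q_KS(sqrt(n1 n2 / (n1 + n2)) * D) with Q_KS the Kolmogorov
    survival function.  The asymptotic form is reasonably accurate once
    n1*n2/(n1+n2) >= 4.
    """
    x, y = _check_nonempty(x, y)
    D = sps.ks_2samp(x, y, method="asymp").statistic
    en = np.sqrt(len(x) * len(y) / (len(x) + len(y)))
    return float(np.clip(special.kolmogorov(en * D), 0.0, 1.0))


def wx_2sample(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when n1 + n2 <= 20 and there are no ties;
    otherwise the normal approximation with tie correction (no
    continuity correction, so identical samples give p = 1).
    """
    x, y = _check_nonempty(x, y)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance (all values tied): statistic at its null mean
        return 1.0
    return min(p, 1.0)


def tnorm_and(pv, pw, w: float = 0.55):
    """Weighted t-norm AND aggregation of two p-values (vectorised)."""
    pv = np.asarray(pv, dtype=float)
    pw = np.asarray(pw, dtype=float)
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight w must be in [0, 1]")
    out = 1.0 - np.sqrt(w * (1.0 - pv) ** 2 + (1.0 - w) * (1.0 - pw) ** 2)
    out = np.clip(out, 0.0, 1.0)
    # nan propagates (missing cells stay missing)
    out = np.where(np.isnan(pv) | np.isnan(pw), np.nan, out)
    return float(out) if out.ndim == 0 else out


def _peacock_d(a: np.ndarray, b: np.ndarray) -> float:
    """Sup over the 4 quadrant orientations at every data point of |F1 - F2|."""
    origins = np.vstack([a, b])
    d = 0.0
    for ox, oy in origins:
        for sx in (True, False):
            for sy in (True, False):
                fa = np.mean(((a[:, 0] <= ox) if sx else (a[:, 0] >= ox)) & ((a[:, 1] <= oy) if sy else (a[:, 1] >= oy)))
                fb = np.mean(((b[:, 0] <= ox) if sx else (b[:, 0] >= ox)) & ((b[:, 1] <= oy) if sy else (b[:, 1] >= oy)))
                d = max(d, abs(fa - fb))
    return d


def multivariate_ks(xy1, xy2) -> tuple[float, float]:
    """Peacock-style two-sample 2D KS test; returns (D, approximate p).

    D is the supremum of ECDF differences over the four quadrant
    orientations anchored at every data point of either sample.  The
    p-value uses the standard 2D asymptotic approximation (Kolmogorov
    survival function with an effective sample size shrunk by the
    samples' coordinate correlation) and is approximate by construction.
    """
    a = np.asarray(xy1, dtype=float)
    b = np.asarray(xy2, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) arrays")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    # vectorised quadrant scan over all origins
    origins = np.vstack([a, b])
    D = 0.0
    for le_x in (True, False):
        for le_y in (True, False):
            ax = a[:, 0][None, :] <= origins[:, 0][:, None] if le_x else a[:, 0][None, :] >= origins[:, 0][:, None]
            ay = a[:, 1][None, :] <= origins[:, 1][:, None] if le_y else a[:, 1][None, :] >= origins[:, 1][:, None]
            bx = b[:, 0][None, :] <= origins[:, 0][:, None] if le_x else b[:, 0][None, :] >= origins[:, 0][:, None]
            by = b[:, 1][None, :] <= origins[:, 1][:, None] if le_y else b[:, 1][None, :] >= origins[:, 1][:, None]
            fa = (ax & ay).mean(axis=1)
            fb = (bx & by).mean(axis=1)
            D = max(D, float(np.abs(fa - fb).max()))

    n_eff = len(a) * len(b) / (len(a) + len(b))
    rs = []
    for s in (a, b):
        if len(s) > 1 and s[:, 0].std() > 0 and s[:, 1].std() > 0:
            rs.append(np.corrcoef(s[:, 0], s[:, 1])[0, 1] ** 2)
        else:
            rs.append(0.0)
    r2 = float(np.mean(rs))
    sqn = np.sqrt(n_eff)
    denom = 1.0 + np.sqrt(max(1.0 - r2, 0.0)) * (0.25 - 0.75 / sqn)
    p = float(np.clip(special.kolmogorov(sqn * D / denom), 0.0, 1.0))
    return D, p


def empirical_pvalue(x: float, ref) -> float:
    """Two-sided empirical rank p-value of x against a reference sample.

    With b = #{ref <= x} and a = #{ref >= x},
    p = min(1, 2 * min(a+1, b+1) / (M+1)); the +1 convention avoids
    exact-zero p-values from finite bootstrap samples.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    ref = ref[np.isfinite(ref)]
    M = len(ref)
    if M < 1:
        raise ValueError("reference sample must contain at least one value")
    b = int(np.sum(ref <= x))
    a = int(np.sum(ref >= x))
    return min(1.0, 2.0 * min(a + 1, b + 1) / (M + 1))


def confidence_band(row, method: str = "bpci", alpha: float = 0.05) -> tuple[float, float]:
    """Confidence interval for one bootstrap row of p-values.

    ``normal``: mean +/- z_{1-alpha/2} * std, clipped to [0, 1]
    (z = 1.96 at alpha = 0.05).  ``bpci``: the alpha and 1-alpha
    empirical percentiles of the sorted row (outward-rounding rule, so
    the band endpoints are always observed values).
    """
    row = np.asarray(row, dtype=float).ravel()
    row = row[np.isfinite(row)]
    if len(row) < 2:
        raise ValueError("confidence band needs at least 2 values")
    if method == "normal":
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        m, s = row.mean(), row.std(ddof=0)
        return float(np.clip(m - z * s, 0.0, 1.0)), float(np.clip(m + z * s, 0.0, 1.0))
    if method == "bpci":
        lo = np.quantile(row, alpha, method="lower")
        hi = np.quantile(row, 1.0 - alpha, method="higher")
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def sim_M(p_curve, alpha: float = 0.05) -> float:
    """Mean-p similarity: m/(2a) below alpha, 1 - a/(2m) above; 0.5 at m = alpha."""
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    p = np.asarray(p_curve, dtype=float).ravel()
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("p-curve is empty")
    m = float(p.mean())
    if m < alpha:
        return m / (2.0 * alpha)
    return 1.0 - alpha / (2.0 * m)


def sim_L(lower_band, alpha: float, grid) -> float:
    """Band similarity: 1 - intersec(p)/cr.

    cr = alpha * (size_max - size_min) is the area of the critical strip.
    intersec integrates max(0, alpha - max(0, lb(d))) over the full
    dimension interval (trapezoidal over the grid, with the first band
    value extended back to size_min so the integration interval matches
    cr exactly).
    """
    lb = np.asarray(lower_band, dtype=float).ravel()
    dims = grid.dims
    if len(lb) != len(dims):
        raise ValueError("lower band must be defined on the grid")
    integrand = np.maximum(0.0, alpha - np.maximum(0.0, lb))
    xs = np.concatenate([[grid.size_min], dims])
    ys = np.concatenate([[integrand[0]], integrand])
    ok = np.isfinite(ys)
    intersec = float(np.trapezoid(ys[ok], xs[ok]))
    cr = alpha * grid.d_interval
    return float(np.clip(1.0 - intersec / cr, 0.0, 1.0))


def verdict(sim: float) -> str:
    """Map a similarity value to similar / marginal / dissimilar."""
    if sim >= MARGINAL_HI:
        return "similar"
    if sim <= MARGINAL_LO:
        return "dissimilar"
    return "marginal"
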