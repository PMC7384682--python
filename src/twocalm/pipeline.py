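"""The two-sample comparison pipeline and its report types.

Workflow: (optional DBSCAN outlier filter) -> equalize or paired
bootstrap -> per-resample cluster-feature sweep and Ripley curves ->
first-level KS/Wilcoxon p-value matrices and t-norm aggregation ->
second-level mean-cross tests on averaged features and Ripley values ->
confidence bands -> sim_M / sim_L similarity values and verdicts.

Matrix layout follows the bootstrap convention: rows are cluster
dimensions (L of them), columns are resample pairs (M of them).

    KD / KC   KS-test p-values on density / curvature distributions
    WD / WC   Wilcoxon rank-sum p-values on density / curvature
    DM / CM   average relative density / average curvature per resample
    KR / HR   Ripley K / H values per resample

The overall verdict is governed by the combined first-level curve's
sim_M; Ripley-based similarities are reported as auxiliary features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .features import DimensionGrid, feature_sweep, make_grid
from .localizations import LocalizationCloud
from .preprocess import DBSCANParams, filter_outliers
from .resampling import BootstrapPlan, bootstrap_pairs, equalize
from .ripley import ripley_k
from .stats import (
    confidence_band,
    empirical_pvalue,
    ks_2sample,
    sim_L,
    sim_M,
    tnorm_and,
    verdict,
    wx_2sample,
)

__all__ = [
    "CompareConfig",
    "PValueMatrices",
    "AggregatedCurve",
    "SimilarityResult",
    "ComparisonReport",
    "level1_sweep",
    "mean_cross",
    "cross_test",
    "compare_samples",
]

DIRECT_PATH_MAX_POINTS = 50_000  # below this, a direct equalized comparison is sensible


@dataclass
class CompareConfig:
    """Resolved parameters of one comparison run (fully serialisable)."""

    size_min: float = 10.0
    step: float = 10.0
    size_max: float | str = "auto"
    volume_mode: str = "bullet"
    resamples: int = 100  # M
    points_per_resample: int = 8000  # N
    alpha: float = 0.05
    weight: float = 0.55  # t-norm AND weight
    seed: int = 0
    ci_method: str = "bpci"
    edge_correction: str = "translation"
    equalize_only: bool = False
    filter_rho: Optional[float] = None  # nm; enables DBSCAN outlier filtering
    filter_min_points: int = 3
    cross_k: int = 5  # columns pooled per draw in the cross test
    cross_draws: int = 10

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PValueMatrices:
    """L x M first-level p-values and per-resample feature/Ripley values."""

    dims: np.ndarray
    KD: np.ndarray
    WD: np.ndarray
    KC: np.ndarray
    WC: np.ndarray
    DM1: np.ndarray
    DM2: np.ndarray
    CM1: np.ndarray
    CM2: np.ndarray
    KR1: np.ndarray
    KR2: np.ndarray
    HR1: np.ndarray
    HR2: np.ndarray

    @property
    def L(self) -> int:
        return self.KD.shape[0]

    @property
    def M(self) -> int:
        return self.KD.shape[1]


@dataclass
class AggregatedCurve:
    """A per-dimension aggregated p-value curve with optional confidence band."""

    dims: np.ndarray
    p: np.ndarray
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None
    ci_method: Optional[str] = None


@dataclass
class SimilarityResult:
    sim_M: float
    sim_L: Optional[float]
    alpha: float
    verdict: str


@dataclass
class ComparisonReport:
    """Everything one comparison run produced."""

    config: CompareConfig
    grid: DimensionGrid
    matrices: PValueMatrices
    pd_curve: AggregatedCurve  # level-1 density
    pc_curve: AggregatedCurve  # level-1 curvature
    combined_curve: AggregatedCurve  # t-norm AND of pd and pc
    cell_combined: np.ndarray  # L x M per-cell aggregated p (band source)
    mean_cross_curves: Optional[dict]  # name -> L-vector (p5..p10 + HR)
    similarity: dict  # name -> SimilarityResult
    overall: SimilarityResult
    n_input: tuple
    exclusions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "schema_version": 1,
            "config": self.config.to_dict(),
            "dims": arr(self.grid.dims),
            "n_input": list(self.n_input),
            "matrices": {
                k: arr(getattr(self.matrices, k))
                for k in ("KD", "WD", "KC", "WC", "DM1", "DM2", "CM1", "CM2", "KR1", "KR2", "HR1", "HR2")
            },
            "curves": {
                name: {"p": arr(c.p), "ci_lo": arr(c.ci_lo), "ci_hi": arr(c.ci_hi), "ci_method": c.ci_method}
                for name, c in (("pd", self.pd_curve), ("pc", self.pc_curve), ("combined", self.combined_curve))
            },
            "cell_combined": arr(self.cell_combined),
            "mean_cross": None
            if self.mean_cross_curves is None
            else {k: arr(v) for k, v in self.mean_cross_curves.items()},
            "similarity": {
                k: {"sim_M": s.sim_M, "sim_L": s.sim_L, "alpha": s.alpha, "verdict": s.verdict}
                for k, s in self.similarity.items()
            },
            "overall": {
                "sim_M": self.overall.sim_M,
                "sim_L": self.overall.sim_L,
                "alpha": self.overall.alpha,
                "verdict": self.overall.verdict,
            },
            "exclusions": self.exclusions,
        }


def _cell_test(x: np.ndarray, y: np.ndarray, test) -> float:
    """One matrix cell; missing (nan) when either distribution is empty."""
    if len(x) == 0 or len(y) == 0:
        return np.nan
    return test(x, y)


def level1_sweep(features1: list, features2: list, w: float = 0.55):
    """First-level matrices and aggregated curves from per-resample feature sets.

    ``features1[k][i]`` is the :class:`ClusterFeatureSet` of resample k of
    sample 1 at dimension i.  Returns (KD, WD, KC, WC, pd, pc, combined)
    where the curves aggregate row means of the KS and Wilcoxon matrices
    with the weighted t-norm AND.
    """
    M = len(features1)
    if M == 0 or len(features2) != M:
        raise ValueError("need the same positive number of resamples per sample")
    L = len(features1[0])
    KD = np.full((L, M), np.nan)
    WD = np.full((L, M), np.nan)
    KC = np.full((L, M), np.nan)
    WC = np.full((L, M), np.nan)
    for k in range(M):
        for i in range(L):
            f1, f2 = features1[k][i], features2[k][i]
            KD[i, k] = _cell_test(f1.densities, f2.densities, ks_2sample)
            WD[i, k] = _cell_test(f1.densities, f2.densities, wx_2sample)
            KC[i, k] = _cell_test(f1.curvatures, f2.curvatures, ks_2sample)
            WC[i, k] = _cell_test(f1.curvatures, f2.curvatures, wx_2sample)
    pd_curve = tnorm_and(_row_means(KD), _row_means(WD), w)
    pc_curve = tnorm_and(_row_means(KC), _row_means(WC), w)
    combined = tnorm_and(pd_curve, pc_curve, 0.5)
    return KD, WD, KC, WC, pd_curve, pc_curve, combined


def _row_means(mat: np.ndarray) -> np.ndarray:
    """Row means ignoring missing cells; nan for all-missing rows."""
    ok = np.isfinite(mat)
    counts = ok.sum(axis=1)
    sums = np.where(ok, mat, 0.0).sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def mean_cross(A1: np.ndarray, A2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Directional mean-cross p-value curves.

    Per dimension d: p5(d) tests mean(A1[d,:]) against the bootstrap
    distribution A2[d,:], p6(d) the reverse direction.
    """
    if A1.shape != A2.shape:
        raise ValueError("matrices must have matching shapes")
    L = A1.shape[0]
    p5 = np.full(L, np.nan)
    p6 = np.full(L, np.nan)
    for i in range(L):
        r1 = A1[i][np.isfinite(A1[i])]
        r2 = A2[i][np.isfinite(A2[i])]
        if len(r1) and len(r2):
            p5[i] = empirical_pvalue(float(r1.mean()), r2)
            p6[i] = empirical_pvalue(float(r2.mean()), r1)
    return p5, p6


def cross_test(A1: np.ndarray, A2: np.ndarray, k: int, seed: int = 0, n_draws: int = 10) -> np.ndarray:
    """Cross-hypothesis curve: KS of k pooled random columns of A1 vs all of A2.

    Averaged over ``n_draws`` random draws; reproducible given the seed.
    """
    if k > A1.shape[1]:
        raise ValueError("k must not exceed the number of resamples")
    rng = np.random.default_rng(seed)
    L = A1.shape[0]
    out = np.full(L, np.nan)
    for i in range(L):
        r2 = A2[i][np.isfinite(A2[i])]
        if len(r2) == 0:
            continue
        ps = []
        for _ in range(n_draws):
            cols = rng.choice(A1.shape[1], size=k, replace=False)
            pooled = A1[i, cols]
            pooled = pooled[np.isfinite(pooled)]
            if len(pooled):
                ps.append(ks_2sample(pooled, r2))
        if ps:
            out[i] = float(np.mean(ps))
    return out


def _band_curves(matrix: np.ndarray, method: str, alpha: float):
    """Row-wise confidence band of an L x M p-value matrix."""
    L = matrix.shape[0]
    lo = np.full(L, np.nan)
    hi = np.full(L, np.nan)
    for i in range(L):
        row = matrix[i][np.isfinite(matrix[i])]
        if len(row) >= 2:
            lo[i], hi[i] = confidence_band(row, method=method, alpha=alpha)
    return lo, hi


def compare_samples(
    cloud1: LocalizationCloud, cloud2: LocalizationCloud, config: CompareConfig | None = None
) -> ComparisonReport:
    """Run the full two-sample comparison and return its report."""
    cfg = config or CompareConfig()
    n_input = (len(cloud1), len(cloud2))

    if cfg.filter_rho is not None:
        params = DBSCANParams(rho=cfg.filter_rho, min_points=cfg.filter_min_points)
        cloud1 = filter_outliers(cloud1, params)
        cloud2 = filter_outliers(cloud2, params)

    grid = make_grid(
        [cloud1.bounding_box, cloud2.bounding_box],
        size_min=cfg.size_min,
        step=cfg.step,
        size_max=cfg.size_max,
    )

    if cfg.equalize_only:
        if max(n_input) > DIRECT_PATH_MAX_POINTS:
            import warnings

            warnings.warn(
                f"direct (equalize-only) comparison of {max(n_input)} points; "
                f"bootstrap resampling is recommended above {DIRECT_PATH_MAX_POINTS}"
            )
        c1, c2 = equalize(cloud1, cloud2, seed=cfg.seed)
        pairs = [(c1, c2)]
    else:
        plan = BootstrapPlan(M=cfg.resamples, N=cfg.points_per_resample, seed=cfg.seed)
        pairs = list(bootstrap_pairs(cloud1, cloud2, plan))
    M = len(pairs)
    L = grid.L

    features1, features2 = [], []
    KR1 = np.full((L, M), np.nan)
    KR2 = np.full((L, M), np.nan)
    HR1 = np.full((L, M), np.nan)
    HR2 = np.full((L, M), np.nan)
    DM1 = np.full((L, M), np.nan)
    DM2 = np.full((L, M), np.nan)
    CM1 = np.full((L, M), np.nan)
    CM2 = np.full((L, M), np.nan)
    excl = {"density": 0, "curvature": 0}
    for k, (b1, b2) in enumerate(pairs):
        f1 = feature_sweep(b1, grid, volume_mode=cfg.volume_mode)
        f2 = feature_sweep(b2, grid, volume_mode=cfg.volume_mode)
        features1.append(f1)
        features2.append(f2)
        DM1[:, k] = [f.av_density for f in f1]
        DM2[:, k] = [f.av_density for f in f2]
        CM1[:, k] = [f.av_curv for f in f1]
        CM2[:, k] = [f.av_curv for f in f2]
        excl["density"] += sum(f.n_excluded_density for f in f1 + f2)
        excl["curvature"] += sum(f.n_excluded_curvature for f in f1 + f2)
        r1 = ripley_k(b1, grid, edge_correction=cfg.edge_correction)
        r2 = ripley_k(b2, grid, edge_correction=cfg.edge_correction)
        KR1[:, k], HR1[:, k] = r1.K, r1.H
        KR2[:, k], HR2[:, k] = r2.K, r2.H

    KD, WD, KC, WC, pd_p, pc_p, comb_p = level1_sweep(features1, features2, w=cfg.weight)
    matrices = PValueMatrices(
        dims=grid.dims, KD=KD, WD=WD, KC=KC, WC=WC,
        DM1=DM1, DM2=DM2, CM1=CM1, CM2=CM2, KR1=KR1, KR2=KR2, HR1=HR1, HR2=HR2,
    )

    # per-cell aggregated p: band source for sim_L
    cell_combined = tnorm_and(tnorm_and(KD, WD, cfg.weight), tnorm_and(KC, WC, cfg.weight), 0.5)

    with_ci = M >= 2
    if with_ci:
        lo, hi = _band_curves(cell_combined, cfg.ci_method, cfg.alpha)
        pd_lo, pd_hi = _band_curves(tnorm_and(KD, WD, cfg.weight), cfg.ci_method, cfg.alpha)
        pc_lo, pc_hi = _band_curves(tnorm_and(KC, WC, cfg.weight), cfg.ci_method, cfg.alpha)
    else:
        lo = hi = pd_lo = pd_hi = pc_lo = pc_hi = None

    pd_curve = AggregatedCurve(grid.dims, pd_p, pd_lo, pd_hi, cfg.ci_method if with_ci else None)
    pc_curve = AggregatedCurve(grid.dims, pc_p, pc_lo, pc_hi, cfg.ci_method if with_ci else None)
    combined_curve = AggregatedCurve(grid.dims, comb_p, lo, hi, cfg.ci_method if with_ci else None)

    if with_ci:
        p5, p6 = mean_cross(DM1, DM2)
        p7, p8 = mean_cross(CM1, CM2)
        p9, p10 = mean_cross(KR1, KR2)
        ph1, ph2 = mean_cross(HR1, HR2)
        mc = {"p5": p5, "p6": p6, "p7": p7, "p8": p8, "p9": p9, "p10": p10, "hr1": ph1, "hr2": ph2}
    else:
        mc = None

    alpha = cfg.alpha
    similarity = {
        "density": SimilarityResult(sim_M(pd_p, alpha), sim_L(pd_lo, alpha, grid) if with_ci else None, alpha, ""),
        "curvature": SimilarityResult(sim_M(pc_p, alpha), sim_L(pc_lo, alpha, grid) if with_ci else None, alpha, ""),
        "combined": SimilarityResult(sim_M(comb_p, alpha), sim_L(lo, alpha, grid) if with_ci else None, alpha, ""),
    }
    if mc is not None:
        ripley_curve = np.nanmean(np.vstack([mc["p9"], mc["p10"]]), axis=0)
        if np.isfinite(ripley_curve).any():
            similarity["ripley"] = SimilarityResult(sim_M(ripley_curve, alpha), None, alpha, "")
    for s in similarity.values():
        s.verdict = verdict(s.sim_M)

    overall = similarity["combined"]
    return ComparisonReport(
        config=cfg,
        grid=grid,
        matrices=matrices,
        pd_curve=pd_curve,
        pc_curve=pc_curve,
        combined_curve=combined_curve,
        cell_combined=cell_combined,
        mean_cross_curves=mc,
        similarity=similarity,
        overall=overall,
        n_input=n_input,
        exclusions=excl,
    )
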