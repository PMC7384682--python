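"""Equalization and paired bootstrap resampling of two point clouds.

Two samples rarely contain the same number of localisations.  For direct
comparison the larger one is subsampled without replacement down to the
smaller (equalization).  The default route instead draws M pairs of
bootstrap resamples — N points i.i.d. with replacement from each sample,
the same N for both members of a pair — and every downstream statistic
is computed once per pair, giving the empirical distributions that feed
the second-level analysis and the confidence bands.

Seeding: a single root seed spawns one child seed per resample through
``numpy.random.SeedSequence``, so any individual resample can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localizations import LocalizationCloud

__all__ = ["BootstrapPlan", "BootstrapPairSeries", "equalize", "bootstrap_pairs"]


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling plan: M resamples of N points each, rooted at ``seed``."""

    M: int = 100
    N: int = 8000
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    def validate(self, n1: int, n2: int) -> None:
        if self.with_replacement and self.N >= min(n1, n2):
            raise ValueError(
                f"bootstrap size N={self.N} must be < min(N1, N2) = {min(n1, n2)}"
            )


@dataclass
class BootstrapPairSeries:
    """M ordered pairs (bs1(k), bs2(k)) of equally sized resampled clouds."""

    pairs: list

    @property
    def M(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def equalize(
    cloud1: LocalizationCloud, cloud2: LocalizationCloud, seed: int = 0
) -> tuple[LocalizationCloud, LocalizationCloud]:
    """Subsample the larger cloud (uniform, without replacement) to the smaller's size."""
    n1, n2 = len(cloud1), len(cloud2)
    if n1 == n2:
        return cloud1, cloud2
    rng = np.random.default_rng(seed)
    n = min(n1, n2)
    if n1 > n2:
        idx = np.sort(rng.choice(n1, size=n, replace=False))
        return cloud1.subset(idx), cloud2
    idx = np.sort(rng.choice(n2, size=n, replace=False))
    return cloud1, cloud2.subset(idx)


def bootstrap_pairs(
    cloud1: LocalizationCloud, cloud2: LocalizationCloud, plan: BootstrapPlan
) -> BootstrapPairSeries:
    """Draw M independent pairs of N-point with-replacement resamples."""
    plan.validate(len(cloud1), len(cloud2))
    children = np.random.SeedSequence(plan.seed).spawn(plan.M)
    pairs = []
    for ss in children:
        rng = np.random.default_rng(ss)
        if plan.with_replacement:
            i1 = rng.integers(0, len(cloud1), size=plan.N)
            i2 = rng.integers(0, len(cloud2), size=plan.N)
        else:
            i1 = rng.choice(len(cloud1), size=plan.N, replace=False)
            i2 = rng.choice(len(cloud2), size=plan.N, replace=False)
        pairs.append((cloud1.subset(i1), cloud2.subset(i2)))
    return BootstrapPairSeries(pairs=pairs)
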