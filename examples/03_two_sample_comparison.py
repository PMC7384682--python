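"""Full two-sample comparison: bootstrap, cluster features, verdict.

Compares a CSR cloud against a clustered (Thomas) cloud of equal size.
The pipeline bootstraps both, sweeps cluster dimensions, runs KS and
Wilcoxon tests on the per-cluster density/curvature distributions,
aggregates the p-values with the weighted t-norm AND, and converts the
aggregated curve into the similarity score sim_M (0 = clearly
different, 1 = indistinguishable; 0.45-0.55 is the marginal band).
"""

import numpy as np

from twocalm import CompareConfig, compare_samples
from twocalm.synthetic import SyntheticSpec, generate

c1 = generate(SyntheticSpec(kind="csr", n_points=6000, box=(1500, 1500, 1500), seed=11))
c2 = generate(
    SyntheticSpec(kind="thomas", n_points=6000, box=(1500, 1500, 1500), seed=12,
                  params={"n_parents": 60, "sigma": 30.0})
)

cfg = CompareConfig(size_min=40, step=40, size_max=480, resamples=20,
                    points_per_resample=2000, seed=3)
report = compare_samples(c1, c2, cfg)

print("d [nm]   p_density   p_curvature   combined")
for d, pd_, pc_, pb in zip(report.grid.dims, report.pd_curve.p, report.pc_curve.p,
                           report.combined_curve.p):
    print(f"{d:6.0f}   {pd_:9.4f}   {pc_:11.4f}   {pb:8.4f}")
for name, s in report.similarity.items():
    sl = f", sim_L = {s.sim_L:.3f}" if s.sim_L is not None else ""
    print(f"{name:10s}: sim_M = {s.sim_M:.3f}{sl}  -> {s.verdict}")
# Aggregated p-values collapse to ~0 at small cluster dimensions, where the
# 30 nm clusters make densities and curvatures differ most; sim_M far below
# 0.45 yields the 'dissimilar' verdict.
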