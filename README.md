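# twocalm

Two-sample comparative analysis of 3D localisation-microscopy point clouds.

Single-molecule localisation microscopy (dSTORM and relatives) renders a
biological sample as a cloud of 10⁴–10⁵ fitted emitter positions in
nanometre coordinates.  A recurring question is whether two such clouds —
two proteins, two treatment conditions, two replicates — exhibit the *same*
spatial organisation.  `twocalm` answers it with a bootstrap-resampled,
multi-scale statistical comparison plus an optional neural-network
classifier, for biophysicists and imaging scientists who want a
quantitative similarity verdict rather than a visual impression.

## Method

For each pair of bootstrap resamples (M pairs of N points each, drawn with
replacement), a single complete-linkage dendrogram per cloud is cut at a
sweep of cluster dimensions *d = size_min + i·Δ*; complete linkage
guarantees every cluster's diameter ≤ *d*.  Each cluster contributes

* **relative density** — (n_k/V_k) / (N/V), with V_k from a *bullet*
  (sum of per-point half-nearest-neighbour spheres), convex-hull or
  bounding-box estimator;
* **curvature (surface variation)** — τ = λ₁/(λ₁+λ₂+λ₃) of the scatter
  matrix eigenvalues, 0 for flat/linear clusters up to 1/3 for isotropic
  ones;

and each resample contributes 3D Ripley statistics
K(d) = (V/N²)·Σ_k Σ_{l≠k} e_k(d)·1[dist(k,l) ≤ d] and
H(d) = (3K/4π)^{1/3} − d (translation edge correction; H > 0 ⇒ clustering).

**First level:** per (d, resample), two-sample Kolmogorov–Smirnov and
Wilcoxon rank-sum tests compare the density and curvature distributions,
giving L×M p-value matrices KD/WD/KC/WC.  Per dimension, row means are
fused with the weighted t-norm AND, p = 1 − √(w(1−pv)² + (1−w)(1−pw)²).
**Second level:** directional empirical p-values compare each sample's mean
average-density, average-curvature and Ripley-K against the other sample's
bootstrap distribution; normal and bootstrap-percentile (BPCI) bands are
attached.  An aggregated p-curve maps to similarity scores

* sim_M = mean(p)/2α if mean(p) < α else 1 − α/(2·mean(p)),
* sim_L = 1 − intersec(p)/cr, the overlap of the band's lower bound with
  the critical strip [0, α],

with verdicts dissimilar (≤ 0.45) / marginal / similar (≥ 0.55).  An
11-20-2 tanh/softmax MLP trained on (d, p1…p10) feature vectors provides a
posterior probability of similarity as an independent read-out.

## Worked example

```python
from twocalm import CompareConfig, compare_samples
from twocalm.synthetic import SyntheticSpec, generate

c1 = generate(SyntheticSpec(kind="csr", n_points=6000, box=(1500, 1500, 1500), seed=11))
c2 = generate(SyntheticSpec(kind="thomas", n_points=6000, box=(1500, 1500, 1500),
                            seed=12, params={"n_parents": 60, "sigma": 30.0}))
report = compare_samples(c1, c2, CompareConfig(size_min=40, step=40, size_max=480,
                                               resamples=20, points_per_resample=2000, seed=3))
for name, s in report.similarity.items():
    print(name, round(s.sim_M, 3), s.verdict)
```

prints (random cloud vs 30 nm-clustered cloud at equal density):

```
density 0.0 dissimilar
curvature 0.367 dissimilar
combined 0.173 dissimilar
ripley 0.769 similar
```

The aggregated first-level p-values collapse to ~0 at small cluster
dimensions where the 30 nm clusters dominate, so sim_M lands far below the
0.45 dissimilarity threshold.  (The auxiliary Ripley score is floored by
the empirical-p convention 2/(M+1) at M=20; with the default M=100 it is
discriminative as well.)  The `examples/` scripts walk through simulation,
Ripley analysis, the full comparison, MLP training and mesh export; the
`twocalm` CLI (`simulate`, `filter`, `roi`, `ripley`, `compare`, `train`,
`classify`, `viz`) wraps the same functions for shell use.

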