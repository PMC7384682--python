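"""Detect clustering scale with Ripley K/H and recover the aggregation radius.

A Thomas cloud with 40 nm offspring spread is analysed over a 20-400 nm
sweep.  H(d) > 0 flags clustering at scale d; the maximising d ("radius
of maximal aggregation") estimates the dominant cluster size and is the
recommended DBSCAN radius for extracting the primary clusters.
"""

import numpy as np

from twocalm import h_argmax, ripley_k
from twocalm.features import DimensionGrid
from twocalm.synthetic import SyntheticSpec, generate

cloud = generate(
    SyntheticSpec(kind="thomas", n_points=4000, box=(1500, 1500, 1500), seed=7,
                  params={"n_parents": 50, "sigma": 40.0})
)
grid = DimensionGrid(size_min=10, step=10, L=39)  # dims 20..400 nm
curves = ripley_k(cloud, grid, edge_correction="translation")
d_star, flag = h_argmax(curves)

print("d [nm]   H(d) [nm]")
for d, h in zip(curves.dims[::4], curves.H[::4]):
    print(f"{d:6.0f}   {h:+8.1f}")
print(f"\nradius of maximal aggregation: {d_star} nm ({flag})")
# H rises well above 0 around ~100 nm: points cluster at roughly 2-3x the
# 40 nm offspring sigma, as expected for Gaussian clusters (the radius
# containing most of a cluster's mass is a small multiple of sigma).
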