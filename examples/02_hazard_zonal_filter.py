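"""Rescale a hazard grid, aggregate it to tract means, apply the moderate filter.

A 6x6 classed hazard grid (classes 0-5) is rescaled to [0, 1], averaged over a
2x2 tract tessellation by cell-center membership, and filtered to the tracts
with at least moderate fire potential.
"""

import numpy as np
from shapely.geometry import box

import fire_equity as fe

rng = np.random.default_rng(1)
classes = rng.integers(0, 6, size=(6, 6)).astype(float)
raster = fe.HazardRaster(classes, np.zeros_like(classes, dtype=bool))
rescaled = fe.rescale_hazard(raster, in_min=0, in_max=5)

tracts = [
    ("NW", box(0, 3, 3, 6)), ("NE", box(3, 3, 6, 6)),
    ("SW", box(0, 0, 3, 3)), ("SE", box(3, 0, 6, 3)),
]
zm = fe.zonal_mean(rescaled, tracts)
print(zm.to_string(index=False))
print()
print("whp is the mean rescaled hazard over the 9 cells in each tract.")

kept = fe.filter_at_least_moderate(zm, threshold=0.4)
print(f"tracts at or above the moderate threshold 0.4: {list(kept['tract_id'])}")
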