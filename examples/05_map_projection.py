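"""Distortion-corrected measurement on a cartographic sphere map.

An equirectangular map of a spherical embryo stretches areas near the
poles.  The metric field (s_u, s_v) corrects every measurement back to the
curved surface: the whole map integrates to 4*pi*R^2 and a polar cap above
30 degrees latitude covers exactly a quarter of the surface.
"""

import math

import numpy as np

from epifluid import corrected_measures, sphere_equirect_metric, tissue_area_series
from epifluid.cartography import masked_area

R = 250.0  # sphere radius, um
shape = (192, 384)
metric = sphere_equirect_metric(R, shape)

full = np.ones(shape, bool)
print(f"full map corrected area : {masked_area(full, metric):12.0f} um^2")
print(f"4*pi*R^2                : {4 * math.pi * R**2:12.0f} um^2")

cap = np.zeros(shape, bool)
cap[: shape[0] // 3] = True  # latitude > 30 deg
print(f"cap>30deg fraction      : {masked_area(cap, metric) / (4 * math.pi * R**2):.4f} (closed form 0.25)")

# the same map square shrinks on the surface away from the equator
square = np.array([[0, 0], [6, 0], [6, 6], [0, 6]], float)
a_eq, _ = corrected_measures(square + [192, 94], metric)
a_60, _ = corrected_measures(square + [192, 30], metric)
print(f"map-identical square, equator vs 60deg: {a_eq:.0f} vs {a_60:.0f} um^2 (ratio {a_eq / a_60:.2f}, cos ratio 2)")

# an expanding cap = spreading tissue; normalized to the first frame
masks = []
for top in (shape[0] // 3, shape[0] // 2, 2 * shape[0] // 3, shape[0]):
    m = np.zeros(shape, bool)
    m[:top] = True
    masks.append(m)
series = tissue_area_series(masks, metric, reference_frame=0)
print()
print(series.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("Coverage rises to 1.0 as the spreading cap envelops the sphere.")
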