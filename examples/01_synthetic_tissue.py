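"""Generate synthetic epithelia and show how relaxation sets the shape index.

Voronoi tissues of seeded random points; Lloyd relaxation drives the
packing toward hexagonal order, lowering the mean shape index p = P/sqrt(A)
toward the regular-hexagon value 3.722.  Unrelaxed tessellations mimic the
irregular packing of a fluidized region.
"""

from epifluid import SyntheticTissueParams, extract_polygons, generate_tissue, metrics_table

for iters in (0, 3, 10, 25):
    params = SyntheticTissueParams(
        n_cells=150, domain_size=(240, 240), lloyd_iterations=iters, rng_seed=42
    )
    tissue = generate_tissue(params)
    cells = metrics_table(extract_polygons(tissue))
    print(
        f"lloyd_iterations={iters:2d}: {len(cells):3d} interior cells, "
        f"mean p = {cells.p.mean():.3f}, mean area = {cells.A_um2.mean():.0f} um^2"
    )

print()
print("Mean p falls monotonically with relaxation: disordered packings sit")
print("well above the hexagonal floor of 3.722, relaxed ones approach it.")
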