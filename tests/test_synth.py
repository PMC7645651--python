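"""Generator invariants: determinism, partition, knobs, planted truth."""

import dataclasses

import numpy as np
import pytest

from epifluid.rasters import extract_polygons
from epifluid.shape import cell_elongation, metrics_table
from epifluid.synth import (
    RecoilSimParams,
    SyntheticTissueParams,
    generate_recoil_trace,
    generate_tissue,
    generate_window_series,
)


def small_params(**kw):
    base = dict(n_cells=40, domain_size=(120, 120), rng_seed=5)
    base.update(kw)
    return SyntheticTissueParams(**base)


def test_same_seed_is_bit_identical():
    a = generate_tissue(small_params()).values
    b = generate_tissue(small_params()).values
    assert np.array_equal(a, b)


def test_different_seed_differs():
    a = generate_tissue(small_params()).values
    b = generate_tissue(small_params(rng_seed=6)).values
    assert not np.array_equal(a, b)


def test_partition_no_window():
    """Without a window, every pixel belongs to exactly one cell."""
    r = generate_tissue(small_params())
    assert (r.values > 0).all()


def test_partition_with_window():
    """With a window, background is exactly the window disk."""
    p = small_params(window_center=(60, 60), window_radius_schedule=[20])
    r = generate_tissue(p)
    ys, xs = np.mgrid[0 : r.values.shape[0], 0 : r.values.shape[1]]
    disk = np.hypot(xs + 0.5 - 60, ys + 0.5 - 60) <= 20
    assert (r.values[disk] == 0).all()
    assert (r.values[~disk] > 0).all()


def test_three_cells_no_window():
    r = generate_tissue(SyntheticTissueParams(n_cells=3, domain_size=(40, 40), rng_seed=1))
    assert r.n_cells == 3


def test_lloyd_relaxation_decreases_mean_shape_index():
    ps = []
    for iters in (0, 20):
        r = generate_tissue(small_params(n_cells=80, domain_size=(200, 200), lloyd_iterations=iters, rng_seed=9))
        t = metrics_table(extract_polygons(r))
        ps.append(t.p.mean())
    assert ps[1] < ps[0]


def test_stretch_field_elongates_cells():
    k = 2.0
    stretch = np.array([[k, 0.0], [0.0, 1.0]])
    iso = generate_tissue(small_params(n_cells=60, domain_size=(200, 200), lloyd_iterations=4))
    ani = generate_tissue(
        small_params(n_cells=60, domain_size=(200, 200), lloyd_iterations=4, stretch_field=stretch)
    )
    def mean_elong(r):
        return np.mean([cell_elongation(p)[0] for p in extract_polygons(r) if not p.touches_border])
    assert mean_elong(ani) > mean_elong(iso) + 0.2


def test_isotropic_tissue_has_no_coherent_orientation():
    """Identity stretch: the mean elongation *tensor* over cells ≈ 0."""
    r = generate_tissue(small_params(n_cells=120, domain_size=(260, 260), lloyd_iterations=2, rng_seed=11))
    mags, thetas = [], []
    for p in extract_polygons(r):
        if p.touches_border:
            continue
        m, th = cell_elongation(p)
        mags.append(m)
        thetas.append(th)
    mags, thetas = np.asarray(mags), np.asarray(thetas)
    tensor_mean = np.hypot(
        np.mean(mags * np.cos(2 * thetas)), np.mean(mags * np.sin(2 * thetas))
    )
    assert tensor_mean < 3.0 * np.mean(mags) / np.sqrt(len(mags))


def test_window_larger_than_domain_rejected():
    with pytest.raises(ValueError, match="window"):
        small_params(window_center=(60, 60), window_radius_schedule=[80])


def test_schedule_must_be_monotone():
    with pytest.raises(ValueError, match="monotone"):
        small_params(window_center=(60, 60), window_radius_schedule=[10, 12])


def test_series_labels_are_tracked(closure):
    """Persistent ids: later frames only reveal pixels, never rename cells."""
    frames = closure["frames"]
    first = set(int(l) for l in frames[0].labels)
    for fr in frames[1:]:
        assert set(int(l) for l in fr.labels) <= first | set(int(l) for l in frames[-1].labels)
    # static tessellation outside the window: frame 0 cells persist
    assert first <= set(int(l) for l in frames[-1].labels)


def test_series_constant_radius_is_static():
    p = small_params(window_center=(60, 60), window_radius_schedule=[18, 18, 18])
    frames = generate_window_series(p)
    for fr in frames[1:]:
        assert np.array_equal(fr.values, frames[0].values)


def test_final_radius_zero_closes_window(closure):
    last = closure["frames"][-1].values
    assert (last > 0).all()


def test_planted_event_missing_cell_errors():
    p = small_params(
        window_center=(60, 60),
        window_radius_schedule=[18, 15, 12],
        planted_t1_events=[(0, (900, 901, 902, 903))],
    )
    with pytest.raises(ValueError, match="900"):
        generate_window_series(p)


def test_planted_eviction_requires_rim_cell(random_tissue):
    p = small_params(
        window_center=(60, 60),
        window_radius_schedule=[18, 15, 12],
        planted_evictions=[(0, 999)],
    )
    with pytest.raises(ValueError, match="999"):
        generate_window_series(p)


# --- recoil traces ---------------------------------------------------------


def test_recoil_trace_noiseless_shape():
    tr = generate_recoil_trace(RecoilSimParams(D=2.0, alpha=0.5, dt=0.5, duration=10.0))
    sep = tr.separation()
    t = sep.time_s.to_numpy()
    assert np.allclose(sep.d_um, 2.0 * np.sqrt(t))
    assert t[0] == pytest.approx(0.5) and len(t) == 20


def test_recoil_alpha_zero_is_constant():
    tr = generate_recoil_trace(RecoilSimParams(D=3.0, alpha=0.0, dt=1.0, duration=5.0))
    assert np.allclose(tr.separation().d_um, 3.0)


def test_recoil_edges_split_symmetrically():
    tr = generate_recoil_trace(RecoilSimParams(D=2.0, alpha=0.5, dt=0.5, duration=4.0))
    assert np.allclose(tr.samples.edge1_pos_um, -tr.samples.edge2_pos_um)


def test_recoil_param_validation():
    with pytest.raises(ValueError):
        RecoilSimParams(D=2.0, alpha=1.5)
    with pytest.raises(ValueError):
        RecoilSimParams(D=-1.0, alpha=0.5)
    with pytest.raises(ValueError):
        RecoilSimParams(D=1.0, alpha=0.5, dt=2.0, duration=1.0)


def test_recoil_trace_deterministic():
    a = generate_recoil_trace(RecoilSimParams(D=2, alpha=0.5, noise_sd=0.2, rng_seed=4))
    b = generate_recoil_trace(RecoilSimParams(D=2, alpha=0.5, noise_sd=0.2, rng_seed=4))
    assert a.samples.equals(b.samples)
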