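import dataclasses
import logging

import numpy as np
import pytest

from epifluid.synth import (
    SyntheticTissueParams,
    fluid_band_tissue,
    generate_tissue,
    generate_window_series,
    hexagonal_tissue,
    suggest_evictions,
    suggest_t1_quartets,
)

logging.getLogger("epifluid").setLevel(logging.ERROR)

WINDOW_CENTER = (110.0, 110.0)
RADII = [34, 30, 26, 22, 18, 14, 10, 6, 3, 0]


@pytest.fixture(scope="session")
def hex_raster():
    """Regular hexagonal tissue (side ≈ 10.4 px, spacing 18 px)."""
    return hexagonal_tissue((220, 220), spacing_px=18.0)


@pytest.fixture(scope="session")
def random_tissue():
    """Mildly relaxed random tissue, no window."""
    return generate_tissue(
        SyntheticTissueParams(n_cells=120, domain_size=(200, 200), lloyd_iterations=3, rng_seed=7)
    )


@pytest.fixture(scope="session")
def band_tissue():
    """Two-region tissue: relaxed bulk + planted wiggly (fluid) central band."""
    raster, in_band = fluid_band_tissue(rng_seed=3)
    return raster, in_band


@pytest.fixture(scope="session")
def closure():
    """Closure series with 3 planted T1s and 2 planted evictions (+ truth)."""
    base_params = SyntheticTissueParams(
        n_cells=140,
        domain_size=(220, 220),
        lloyd_iterations=3,
        window_center=WINDOW_CENTER,
        window_radius_schedule=RADII,
        rng_seed=2,
    )
    plain = generate_window_series(base_params)
    rng = np.random.default_rng(1002)
    quartets = suggest_t1_quartets(plain[0], 3, rng)
    t1_events = list(zip([1, 3, 5], quartets))
    evictions = suggest_evictions(plain, WINDOW_CENTER, [1, 2], rng)
    params = dataclasses.replace(
        base_params, planted_t1_events=t1_events, planted_evictions=evictions
    )
    frames, truth = generate_window_series(params, return_truth=True)
    return {
        "frames": frames,
        "truth": truth,
        "t1_events": t1_events,
        "evictions": evictions,
        "window_center": WINDOW_CENTER,
    }
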