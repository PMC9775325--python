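import warnings

import numpy as np
import pytest

from sentinelgaze.distfit import DEFAULT_SEED, FAMILIES, SamplerConfig, fit_hier_model
from sentinelgaze.eventio import Event, ObservationMeta, derive_looks
from sentinelgaze.synthgen import SimConfig, simulate_population

# One synthetic study reused across modules: 30 focal observations under the
# default (lognormal) generator, ~4500 looks — the scale of a full field season.
STUDY_SEED = 11


@pytest.fixture(scope="session")
def study30():
    events, meta, truth = simulate_population(SimConfig(n_observations=30, seed=STUDY_SEED))
    looks = [lk for m in meta for lk in derive_looks(events[m.obs_id])]
    return events, meta, looks, truth


@pytest.fixture(scope="session")
def family_fits(study30):
    """Hierarchical fits of all four families on the shared study."""
    _, meta, looks, _ = study30
    seeds = np.random.SeedSequence(DEFAULT_SEED).generate_state(len(FAMILIES)) % (2**31)
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fam, s in zip(FAMILIES, seeds):
            fits[fam] = fit_hier_model(looks, meta, fam, SamplerConfig(seed=int(s)))
    return fits


@pytest.fixture()
def tiny_events():
    """Minimal well-formed observation: two looks with preceding head moves."""
    return [
        Event("obs1", "head_move", 0.0, 0.1),
        Event("obs1", "look", 0.1, 1.1, 1),
        Event("obs1", "head_move", 1.1, 1.2),
        Event("obs1", "look", 1.2, 1.7, 2),
    ]


@pytest.fixture()
def tiny_meta():
    return ObservationMeta(
        obs_id="obs1", group_id="G1", individual_id="G1-AM",
        status="adult_male", group_size=4, duration=1.7,
    )
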