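import numpy as np
import pytest

import periomap as pm
from periomap import synth


@pytest.fixture(scope="session")
def left_sheet():
    spec = pm.default_sheet_spec("left")
    mesh, parc = pm.make_surface(spec)
    return spec, mesh, parc


@pytest.fixture(scope="session")
def truth(left_sheet):
    _spec, mesh, parc = left_sheet
    return pm.make_ground_truth(mesh, parc)


@pytest.fixture(scope="session")
def noiseless_statmaps(left_sheet, truth):
    """Noiseless 60-volume rate experiment fitted with the sparse GLM."""
    spec, mesh, _parc = left_sheet
    sched = synth.make_schedule(60, synth.RATE_CONDITIONS, seed=1)
    series = synth.simulate_sparse_experiment(
        truth, mesh, sched, noise=synth.NoiseParams(sd=0.0), grid=spec.grid
    )
    stat = pm.fit_glm(series, pm.build_design(sched))
    return stat


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
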