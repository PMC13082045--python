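import numpy as np
import pytest

from exorun import skeleton as sk
from exorun import synth
from exorun import tracking as tr
from exorun.contact import ExotendonSpec

# Coarse study conditions used by solver-level tests: small mesh so the
# nonlinear program stays tractable on one CPU.
COARSE_MESH = 8
COARSE_MAXITER = 400


@pytest.fixture(scope="session")
def model():
    return sk.scale_model(sk.build_default_model(), sk.ScaleSpec(1.78, 73.0))


@pytest.fixture(scope="session")
def reference(model):
    return synth.generate_reference_gait(4.0, 0.70, seed=0, model=model)


@pytest.fixture(scope="session")
def natural_solution(model, reference):
    """Converged coarse-mesh natural-running solution (solved once)."""
    cfg = tr.OcpConfig(mesh_intervals=COARSE_MESH, maxiter=COARSE_MAXITER)
    return tr.solve_tracking(model, reference, None, cfg)


@pytest.fixture(scope="session")
def medium_solution(model, reference):
    """Converged coarse-mesh solution with the medium-original exotendon."""
    cfg = tr.OcpConfig(mesh_intervals=COARSE_MESH, maxiter=COARSE_MAXITER)
    exo = ExotendonSpec.from_percent(120.0, 25.0, name="medium-original")
    return tr.solve_tracking(model, reference, exo, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
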