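"""Shared fixtures: scaled-down simulation runs reused across test modules.

The session-scoped runs use the package's documented default study
conditions (vessel cell 0.65 um, dt 1e-4 s; tumor cell = fenestra/4) except
where a fixture docstring says it is a deliberately miniaturised domain.
"""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tumorperf import geometry as tg
from tumorperf import pipeline as tp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_cfl_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="advective CFL")
        yield


@pytest.fixture(scope="session")
def default_cfg() -> tp.ExperimentConfig:
    return tp.ExperimentConfig()


@pytest.fixture(scope="session")
def vessel_result(default_cfg):
    """Full-length (0.30 s) three-phase vessel run at the default coarse grid."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="advective CFL")
        return tp.run_vessel_stage(default_cfg)


@pytest.fixture(scope="session")
def tumor3_result(vessel_result, default_cfg):
    """Model-3 tumor run to 0.30 s driven by the probed vessel series."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="advective CFL")
        return tp.run_tumor_stage(3, vessel_result.probe, default_cfg)


@pytest.fixture(scope="session")
def constant_probe():
    """Synthetic steady probe (0.3 mm/s into the fenestra) for tumor tests."""
    return tp.ProbeSeries(np.array([0.0, 1.0]), np.array([3000.0, 3000.0]),
                          np.array([0.0, 0.0]), np.array([-3e-4, -3e-4]))


@pytest.fixture(scope="session")
def mini_tumor_runs(constant_probe):
    """All three fenestra models on a miniaturised 3x3 um tumor domain.

    One shared cell size (0.025 um) resolves even the 0.1 um fenestra, so
    the three models are directly comparable; the short horizon keeps the
    fronts inside the domain.
    """
    circles = tg.place_fibers(3.0, 3.0, 0.27, rng_seed=1,
                              r_min=0.25, r_max=0.45, min_gap=0.12,
                              exclusions=((1.5, 3.0, 0.55),))
    cfg = tp.ExperimentConfig(
        tumor_width=3.0, tumor_height=3.0, fiber_circles=tuple(circles),
        tumor_cell_size=0.025, end_time=0.01, snapshot_times=(0.005, 0.01))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="advective CFL")
        return cfg, {m: tp.run_tumor_stage(m, constant_probe, cfg)
                     for m in (1, 2, 3)}
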