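"""Shared fixtures.

The expensive 40-specimen end-to-end fit (the packaged default population)
is computed once per session and shared by the correspondence and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mc3ssm import synthetic_data as sd
from mc3ssm import mesh_core as mc
from mc3ssm import correspondence as corr


@pytest.fixture(scope="session")
def base_mesh():
    return sd.make_base_shape()


@pytest.fixture(scope="session")
def small_population():
    """Eight specimens with clouds; no fitting."""
    spec = sd.SyntheticSpec(n_specimens=8, seed=7)
    base, modes, pop = sd.sample_population(spec, return_base=True)
    rng = np.random.default_rng(11)
    clouds = [
        sd.export_point_cloud(base, p, spec.cloud_density, spec.point_noise_sd, rng)
        for p in pop
    ]
    return spec, base, modes, pop, clouds


@pytest.fixture(scope="session")
def default_population_fit():
    """Host + fine fits and the full correspondence loop on the packaged
    default 40-specimen population (the study-scale configuration)."""
    spec = sd.SyntheticSpec()
    base, modes, pop = sd.sample_population(spec, return_base=True)
    rng = np.random.default_rng(2024)
    clouds = [
        sd.export_point_cloud(base, p, spec.cloud_density, spec.point_noise_sd, rng)
        for p in pop
    ]
    hosts = [mc.host_mesh_fit(base, c) for c in clouds]
    fits = [mc.fine_fit(h, c) for h, c in zip(hosts, clouds)]
    result = corr.correspondence_loop(base, clouds, fits)
    return {
        "spec": spec,
        "base": base,
        "modes": modes,
        "population": pop,
        "clouds": clouds,
        "host_rms": np.array([h.rms for h in hosts]),
        "fine_rms": np.array([f.rms for f in fits]),
        "result": result,
    }
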