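"""Shared fixtures: small random problems and the one expensive shared
optimization (the 15N universal-90x design run from 10 seeds)."""

from __future__ import annotations

import numpy as np
import pytest

import pulseforge as pf


@pytest.fixture(scope="session")
def n15_spec() -> pf.PulseSpec:
    return pf.fixture_specs()["n15_u90x"]


@pytest.fixture(scope="session")
def n15_multiseed(n15_spec):
    """The 15N universal 90x problem optimized to convergence from 10 seeds.

    Shared across the optimizer, simulation and acceptance tests because it
    is by far the most expensive computation in the suite.
    """
    return [pf.optimize(n15_spec, pf.OptimizerOptions(seed=s)) for s in range(1, 11)]


@pytest.fixture(scope="session")
def n15_result(n15_multiseed):
    return n15_multiseed[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_su2(rng: np.random.Generator) -> pf.SU2Propagator:
    """A Haar-ish random SU(2) element from a normalized complex pair."""
    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    return pf.SU2Propagator(complex(v[0], v[1]), complex(v[2], v[3]))


def random_element(rng: np.random.Generator) -> pf.RFElementParams:
    return pf.RFElementParams(
        phase=rng.uniform(0, 2 * np.pi),
        rf_amplitude=rng.uniform(0, 30e3),
        offset=rng.uniform(-30e3, 30e3),
        duration=rng.uniform(0.2e-6, 10e-6),
    )


def small_mixed_spec() -> pf.PulseSpec:
    """A tiny spec exercising all four restraints and the 3-point ensemble."""
    return pf.PulseSpec(
        nucleus="13C",
        larmor_mhz=150.9,
        carrier_ppm=58.0,
        peak_amplitude_khz=17.6,
        duration_us=32.0,
        n_elements=16,
        bands=(
            pf.Band(40, 78, 4, pf.UniversalRotation(axis=(0.0, 1.0, 0.0), angle=90.0)),
            pf.Band(158, 198, 3, pf.StateToState("z", "-z")),
            pf.Band(8, 40, 3, pf.XYcite()),
            pf.Band(100, 120, 2, pf.Suppression()),
        ),
    )
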