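"""Shared fixtures: one acceptance-scale bare-probe simulation per session.

The probe phase space is the costliest input; it is generated once (about
two minutes) and shared by the spectrum, applicator, dose and acceptance
tests.  All simulations are seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from minikv import ElectronSourceSpec, generate_phase_space

PROBE_SEED = 20260901
PROBE_HISTORIES = 1_100_000  # yields >= 2e5 surface-scored photons


@pytest.fixture(scope="session")
def probe_sim():
    """(PhaseSpaceFile, Spectrum) for the full-scale bare-probe run."""
    spec = ElectronSourceSpec()
    phsp, spectrum = generate_phase_space(
        spec, n_histories=PROBE_HISTORIES, seed=PROBE_SEED
    )
    assert len(phsp) >= 200_000
    return phsp, spectrum


@pytest.fixture(scope="session")
def probe_phsp(probe_sim):
    return probe_sim[0]


@pytest.fixture(scope="session")
def probe_spectrum(probe_sim):
    return probe_sim[1]


@pytest.fixture(scope="session")
def small_probe_sim():
    """A fast, smaller probe run for unit-scale checks."""
    spec = ElectronSourceSpec()
    return generate_phase_space(spec, n_histories=30_000, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
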