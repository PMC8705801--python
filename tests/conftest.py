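import numpy as np
import pytest

from rsikit.pipeline import analyze_cohort
from rsikit.signal_io import Phase, PhaseProtocol
from rsikit.synthetic import (
    SubjectSpec,
    rho_varying_spec,
    shift_varying_spec,
    simulate_cohort,
    simulate_subject,
)

_ROLES = ("baseline", "stressor", "recovery", "stressor", "recovery")


def five_phase_protocol(phase_s: float) -> PhaseProtocol:
    return PhaseProtocol(
        tuple(
            Phase(f"phase{k + 1}", phase_s * k, phase_s * (k + 1), _ROLES[k])
            for k in range(5)
        )
    )


@pytest.fixture(scope="session")
def small_protocol() -> PhaseProtocol:
    """Five 10-s phases, used with fs=32 for fast end-to-end tests."""
    return five_phase_protocol(10.0)


@pytest.fixture(scope="session")
def small_recording(small_protocol):
    spec = SubjectSpec("demo", recovery_fraction=0.9, spike_rate=0.001, seed=7)
    return simulate_subject(spec, small_protocol, fs=32.0)


@pytest.fixture(scope="session")
def rho_cohort():
    """20 full-scale subjects with recovery fraction ~ U[0, 1]."""
    return simulate_cohort(20, master_seed=11, spec_generator=rho_varying_spec)


@pytest.fixture(scope="session")
def rho_cohort_results(rho_cohort):
    """All four methods on the rho-varying cohort (shared across criteria)."""
    recordings, truth = rho_cohort
    distances, indices = analyze_cohort(recordings)
    return distances, indices, truth


@pytest.fixture(scope="session")
def shift_cohort_results():
    """Linear-PCA run on a cohort with 3x-varying stress shifts."""
    recordings, truth = simulate_cohort(
        20, master_seed=13, spec_generator=shift_varying_spec
    )
    distances, indices = analyze_cohort(recordings, methods=("edpca",))
    return distances, indices, truth
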