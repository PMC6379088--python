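import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from somnokit.records import Hypnogram, ProtocolMeta
from somnokit.synth import SyntheticStudyConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default 4-day synthetic study (SD at ZT0-6 of day 3)."""
    return generate_bundle(SyntheticStudyConfig(seed=3))


@pytest.fixture(scope="session")
def baseline_bundle():
    """A 2-day undisturbed recording with temperature and LMA."""
    cfg = SyntheticStudyConfig(seed=11, protocol=ProtocolMeta(n_days=2, sd_day=None))
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def spectra_bundle():
    """A 1-day undisturbed recording including per-epoch spectra."""
    cfg = SyntheticStudyConfig(seed=7, protocol=ProtocolMeta(n_days=1, sd_day=None))
    return generate_bundle(cfg, with_spectra=True)


def make_hypnogram(states, epoch_s=4.0, protocol=None, tdw=None, artefact=None):
    """Small hand-built hypnogram helper; pads defaults."""
    states = np.asarray(list(states), dtype="U1")
    if artefact is None:
        artefact = np.zeros(len(states), bool)
    if protocol is None:
        hours = len(states) * epoch_s / 3600.0
        protocol = ProtocolMeta(n_days=max(1, int(np.ceil(hours / 24.0))), sd_day=None)
    return Hypnogram(
        states=states, artefact=artefact, tdw=tdw, epoch_s=epoch_s, protocol=protocol
    )
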