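import pytest
from hypothesis import HealthCheck, settings

from cushionbench import BModel, ThresholdConfig, TrialRecord, default_layout

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def layout():
    return default_layout()


@pytest.fixture
def config():
    return ThresholdConfig()


def build_trial(
    surface_value=50.0,
    internal_value=70.0,
    cushion_id="c",
    model=BModel.ELLIPTICAL,
    load=50.0,
    trial_index=1,
    surface_overrides=None,
):
    """A uniform trial record with optional per-channel surface overrides."""
    layout = default_layout()
    surface = {c: float(surface_value) for c in layout.surface_ids}
    if surface_overrides:
        surface.update({k: float(v) for k, v in surface_overrides.items()})
    internal = {c: float(internal_value) for c in layout.internal_ids}
    return TrialRecord(
        cushion_id=cushion_id,
        model=model,
        load=load,
        trial_index=trial_index,
        surface=surface,
        internal=internal,
    )


@pytest.fixture
def make_trial():
    return build_trial
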