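import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def reference_points():
    """The built-in measured occupancy table as (concentrations, percentages)."""
    from dropstat import OCCUPANCY_REFERENCE

    return list(OCCUPANCY_REFERENCE), list(OCCUPANCY_REFERENCE.values())
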