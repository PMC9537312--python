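import pytest

from glenocard.card_design import CardSpec, build_card


@pytest.fixture(scope="session")
def standard_card():
    """The 50 mm, 5-strips-per-quadrant card (40 cells of 2.5 % each)."""
    return build_card(CardSpec(radius_mm=25.0, strips_per_quadrant=5))
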