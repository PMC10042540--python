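import numpy as np
import pytest

from covnuc import BindingScheme, koff_from_kd


@pytest.fixture()
def table1_scheme() -> BindingScheme:
    """Binding scheme with the published GDP-reporter and pda-analogue rates."""
    return BindingScheme(
        kon_reporter=4.22,
        koff_reporter=koff_from_kd(2.5, 4.22),
        kon_competitor=3.34,
        koff_competitor=koff_from_kd(8.6, 3.34),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
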