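import pytest

from ctckinetics import ExchangeParams


@pytest.fixture(scope="session")
def sclc_params() -> ExchangeParams:
    """Exchange parameters of the worked SCLC experiment: ~7,000 cells
    transferred and ~500 returned over 4 h at 60 uL/min."""
    return ExchangeParams(r_gen=406.25, t_half_s=93.3, V=1.75, Q=60.0)
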