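import pytest

from varipept.quant import GroupDesign
from varipept.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One default synthetic study shared across the session."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(SimulationConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def design_10v8():
    return GroupDesign(
        {f"case_{i + 1:02d}": "case" for i in range(10)}
        | {f"control_{i + 1:02d}": "control" for i in range(8)}
    )
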