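import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import btarecruit as br

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def fiber():
    """Default cylinder model: radius 15 nm, calibrated axial rise."""
    return br.FiberModel()


@pytest.fixture
def composition_25pct():
    """The 25% receptor-density assembly: 0.5 uM BTA-DNA + 1.5 uM BTA-3OH."""
    return br.AssemblyComposition(conc_btadna=0.5e-6, conc_bta3oh=1.5e-6)


@pytest.fixture
def enzyme():
    """1 nM enzyme on 20 nM recruiter with the default handle duplex K_d."""
    return br.RecruitedSpecies("enzyme", recruiter_total=20e-9, protein_total=1e-9)


@pytest.fixture
def inhibitor():
    """10 nM inhibitor on 200 nM recruiter (titration condition)."""
    return br.RecruitedSpecies(
        "inhibitor", recruiter_total=200e-9, protein_total=10e-9
    )


@pytest.fixture
def inhibition_model():
    return br.InhibitionModel()


@pytest.fixture
def titration_grid():
    """Inhibitor grid spanning 0 and 0.5-100 nM, as in the titration assay."""
    return np.concatenate([[0.0], np.geomspace(0.5e-9, 100e-9, 11)])
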