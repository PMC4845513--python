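import pytest

from phytoflux.scenarios import ConstraintSet
from phytoflux.synthetic_models import (
    ToySpec,
    make_futile_cycle_model,
    make_toy,
)

# canonical toy study conditions: uptake <= 10, energy yield 3,
# maintenance drain fixed at 2, biomass 0.5 substrate + 1 energy
TOY1_SPEC = ToySpec()
TOY2_SPEC = ToySpec(n_pathways=2)


@pytest.fixture
def toy1():
    return make_toy(TOY1_SPEC, model_id="toy1")


@pytest.fixture
def toy2():
    return make_toy(TOY2_SPEC, model_id="toy2")


@pytest.fixture
def futile():
    return make_futile_cycle_model(ToySpec())


@pytest.fixture
def toy_constraints():
    return ConstraintSet(carbon_uptake=("EX_G", 10.0), ngam=("NGAM", 2.0))
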