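import numpy as np
import pytest

from flavorqtl.encoding import build_rin_design, encode_parental_dosage
from flavorqtl.simulate import CrossPlan, make_founders, simulate_population


@pytest.fixture(scope="session")
def founders6():
    """Four founders on 6 chromosomes x 12 markers (small but genome-like)."""
    return make_founders(12, [50_000_000] * 6, seed=101)


@pytest.fixture(scope="session")
def f2_pop(founders6):
    """Full half diallel, 50 F2 per cross, origin-tracked."""
    plan = CrossPlan(crosses=founders6.half_diallel(), generation="F2", n_per_cross=50)
    return simulate_population(founders6, plan, 2.0, seed=202)


@pytest.fixture(scope="session")
def encoded(f2_pop):
    return encode_parental_dosage(f2_pop)


@pytest.fixture(scope="session")
def rin_design(f2_pop):
    return build_rin_design(f2_pop)
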