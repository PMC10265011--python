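import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from inequifit.games import BeliefConfig, build_schedule
from inequifit.preferences import CompiledSchedule
from inequifit.simulate import (
    SimulationConfig,
    sample_genotypes,
    sample_preferences,
    simulate_choices,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beliefs():
    return BeliefConfig()


@pytest.fixture(scope="session")
def schedule(beliefs):
    return build_schedule(beliefs)


@pytest.fixture(scope="session")
def compiled(schedule):
    return CompiledSchedule(schedule)


@pytest.fixture(scope="session")
def published_genotype_table():
    """Synthetic genotype table whose marginal counts equal the published
    distribution (n = 420): OXTR 171/196/53, RS3 117/203/100 with 154
    carriers of the 334 bp allele, OPRM1 114/201/105."""
    import pandas as pd

    oxtr = ["AA"] * 171 + ["AG"] * 196 + ["GG"] * 53
    oprm1 = ["AA"] * 114 + ["AG"] * 201 + ["GG"] * 105
    rs3 = ["SS"] * 117 + ["SL"] * 203 + ["LL"] * 100
    a1, a2 = [], []
    carriers_left = 154
    for g in rs3:
        if g == "SS":
            a1.append(320), a2.append(324)
        elif g == "SL":
            long_allele = 334 if carriers_left > 0 else 340
            carriers_left -= 1 if long_allele == 334 else 0
            a1.append(322), a2.append(long_allele)
        else:
            long_allele = 334 if carriers_left > 0 else 336
            carriers_left -= 1 if long_allele == 334 else 0
            a1.append(long_allele), a2.append(340)
    assert carriers_left == 0
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(1, 421)],
            "oxtr": oxtr,
            "avpr1a_allele1_bp": a1,
            "avpr1a_allele2_bp": a2,
            "oprm1": oprm1,
            "age": [30 + (i % 30) for i in range(420)],
            "sex": ["female" if i % 2 else "male" for i in range(420)],
        }
    )


@pytest.fixture(scope="session")
def small_study(schedule):
    """12 softmax agents with fixed inverse temperature, full schedule."""
    rng = np.random.default_rng(2024)
    cfg = SimulationConfig(n_participants=12, seed=2024)
    genotypes = sample_genotypes(cfg, rng)
    truth = sample_preferences(genotypes, cfg, rng)
    truth["true_lambda"] = 5.0
    behaviour = simulate_choices(truth, schedule, rng)
    return {"genotypes": genotypes, "truth": truth, "behaviour": behaviour}
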