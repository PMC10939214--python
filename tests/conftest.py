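import numpy as np
import pandas as pd
import pytest

from arenasim.ecopath import solve_mass_balance
from arenasim.model import DietMatrix, EcopathModel, Fleet, FunctionalGroup
from arenasim.synth import SyntheticScenario, generate_foodweb, generate_reference_data


def make_model(groups, diet, fleets=None, **kw):
    names = [g.name for g in groups]
    dc = pd.DataFrame(0.0, index=names, columns=names)
    for (prey, pred), frac in diet.items():
        dc.at[prey, pred] = frac
    return EcopathModel(groups=groups, diet=DietMatrix(dc),
                        fleets=fleets or [], **kw)


@pytest.fixture
def two_group_model():
    """Prey producer (B=10, P/B=2) supporting one predator (B=1, Q/B=5)."""
    return make_model(
        [FunctionalGroup("prey", role="producer", B=10, PB=2),
         FunctionalGroup("pred", B=1, PB=0.5, QB=5, EE=0.0)],
        {("prey", "pred"): 1.0})


@pytest.fixture
def chain3_model():
    """Producer -> zooplankton -> fish chain with a fast producer."""
    return make_model(
        [FunctionalGroup("phyto", role="producer", B=30, PB=100),
         FunctionalGroup("zoop", B=5, PB=20, QB=60),
         FunctionalGroup("fish", B=0.5, PB=1.5, QB=8)],
        {("phyto", "zoop"): 1.0, ("zoop", "fish"): 1.0},
        base_year=1979)


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def small_web(small_scenario):
    model = generate_foodweb(small_scenario)
    solution = solve_mass_balance(model)
    return model, solution


@pytest.fixture(scope="session")
def small_refdata(small_scenario, small_web):
    model, _ = small_web
    return generate_reference_data(small_scenario, model)


def random_web(rng: np.random.Generator, n: int) -> EcopathModel:
    """A random acyclic web: group 0 is a producer, each consumer eats
    lower-numbered groups; the top consumer has unknown B (EE given and a
    catch), one mid consumer has unknown Q/B, everything else solves EE."""
    groups = [FunctionalGroup("g0", role="producer",
                              B=float(rng.uniform(20, 60)),
                              PB=float(rng.uniform(30, 80)))]
    diet = {}
    for i in range(1, n):
        b = float(rng.uniform(0.5, 5) * 10 ** (-i / 3))
        pb = float(rng.uniform(0.5, 3))
        qb = pb / float(rng.uniform(0.1, 0.3))
        groups.append(FunctionalGroup(f"g{i}", B=b, PB=pb, QB=qb))
        prey = rng.choice(i, size=min(i, 2), replace=False)
        w = rng.dirichlet(np.ones(len(prey)))
        for p, frac in zip(prey, w):
            diet[(f"g{p}", f"g{i}")] = float(frac)
    qb_unknown = f"g{max(1, n // 2)}"
    top = f"g{n - 1}"
    fleets = []
    for g in groups:
        if g.name == qb_unknown and g.name != top:
            g.GE = g.PB / g.QB  # Q/B supplied only through growth efficiency
            g.QB = None
        elif g.name == top:
            g.EE = 0.5
            fleets.append(Fleet("f", {top: 0.3 * g.B * g.PB}))
            g.B = None
    return make_model(groups, diet, fleets)
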