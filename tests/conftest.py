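import numpy as np
import pytest

import bnrisk as b


@pytest.fixture(scope="session")
def dictionary():
    return b.build_variable_dictionary()


@pytest.fixture(scope="session")
def fixture():
    """The packaged cohort-emulating generator fixture (with missingness)."""
    return b.gbcs_fixture()


@pytest.fixture(scope="session")
def complete_fixture(fixture):
    return fixture.without_missingness()


@pytest.fixture(scope="session")
def cohort_4k(complete_fixture):
    """A complete-data cohort of 4,000 rows for fast model tests."""
    return b.sample_cohort(complete_fixture, n=4000, seed=101)


@pytest.fixture(scope="session")
def fitted_model(fixture):
    """Parameters fitted on one full-size fixture sample, known structure."""
    cohort = b.sample_cohort(fixture, seed=11)
    return b.fit_parameters(fixture.dag, cohort, 1.0), cohort


def random_model(rng, n_nodes, max_card=2, p_arc=0.35):
    """A random discrete network with Dirichlet CPTs (test oracle input)."""
    names = [f"x{i}" for i in range(n_nodes)]
    arcs = [(names[i], names[j]) for i in range(n_nodes)
            for j in range(i + 1, n_nodes) if rng.random() < p_arc]
    dag = b.Dag(names, arcs)
    cards = {nm: int(rng.integers(2, max_card + 1)) for nm in names}
    cats = {nm: tuple(f"c{k}" for k in range(cards[nm])) for nm in names}
    cpts = {}
    for nm in names:
        parents = dag.parents(nm)
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        table = rng.dirichlet(np.ones(cards[nm]), size=q)
        cpts[nm] = b.Cpt(nm, parents, cats[nm],
                         tuple(cats[p] for p in parents),
                         table, np.zeros_like(table))
    return b.BayesianNetworkModel(dag, cpts)
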