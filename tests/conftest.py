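import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import pepflux as pf
from pepflux.profiles import ALPHABET, AMINO_ACIDS, LOCI, FrequencyMatrix


def uniform_matrix(peptidase_id="uniform", p1_residue=None):
    """Columns uniform over the 20 residues; optionally one-hot at P1."""
    f = np.zeros((len(ALPHABET), len(LOCI)))
    f[: len(AMINO_ACIDS), :] = 1.0 / len(AMINO_ACIDS)
    if p1_residue is not None:
        j = LOCI.index("P1")
        f[:, j] = 0.0
        f[ALPHABET.index(p1_residue), j] = 1.0
    return FrequencyMatrix(peptidase_id, f)


def linear_balance_solve(graph, z):
    """Independent oracle: dense linear solve of the stationary balance system.

    One equation per node: (degradation + cleavage outflow rate) * x_v
    minus the inflow from cleavage of longer peptides equals creation.
    """
    order = sorted(graph.nodes)
    idx = {s: i for i, s in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for s in order:
        b[idx[s]] = z.creation.get(s, 0.0)
        a[idx[s], idx[s]] += z.degradation.get(s, 0.0)
    for e in graph.events:
        flux = e.rho * z.activities[e.peptidase_id]
        a[idx[e.substrate], idx[e.substrate]] += flux
        a[idx[e.prefix], idx[e.substrate]] -= flux
        a[idx[e.suffix], idx[e.substrate]] -= flux
    x = np.linalg.solve(a, b)
    return dict(zip(order, x))


@pytest.fixture
def toy_graph():
    """Single event AGAV -> AG + AV."""
    g = pf.CleavageGraph()
    g.add_event(pf.EventNode("AGAV", "AG", "AV", "pep", 1.0))
    g.nodes["AGAV"].is_precursor = True
    return g


@pytest.fixture
def toy_params():
    return pf.ModelParameters({"AGAV": 10.0}, {"AG": 2.0, "AV": 5.0}, {"pep": 1.0})


@pytest.fixture
def chain_graph():
    """Two chained events: AGAGAV -> AG + AGAV, then AGAV -> AG + AV.

    Smallest graph satisfying the well-posedness condition m >= n
    (m = 4 nodes, n = |S| + |L| + |P| = 1 + 2 + 1 = 4).
    """
    g = pf.CleavageGraph()
    g.add_event(pf.EventNode("AGAGAV", "AG", "AGAV", "p", 1.0))
    g.add_event(pf.EventNode("AGAV", "AG", "AV", "p", 0.5))
    g.nodes["AGAGAV"].is_precursor = True
    return g


@pytest.fixture
def chain_params():
    return pf.ModelParameters({"AGAGAV": 10.0}, {"AG": 2.0, "AV": 5.0}, {"p": 1.0})


@pytest.fixture(scope="session")
def benchmark():
    return pf.make_benchmark(pf.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def truth_profile(benchmark):
    profile, _ = pf.normalize_activities(benchmark.truth.z_true)
    return profile
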