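import numpy as np
import pytest

import fetoconn as fc


def random_connectome(rng, d=8, density=0.6, connected=True):
    """Random symmetric non-negative connectome for oracle tests."""
    while True:
        w = np.zeros((d, d))
        iu = np.triu_indices(d, k=1)
        mask = rng.random(iu[0].size) < density
        vals = rng.uniform(0.2, 3.0, size=iu[0].size) * mask
        w[iu] = vals
        w = w + w.T
        c = fc.Connectome(w, [f"n{i}" for i in range(d)])
        if not connected:
            return c
        from fetoconn.metrics import _components

        if _components(c.weights)[0] == 1:
            return c


@pytest.fixture(scope="session")
def default_study():
    """Desk-scale synthetic study shared across tests (package defaults)."""
    return fc.default_study()


@pytest.fixture(scope="session")
def fitted_templates(default_study):
    """Aggregation-fitted templates for the shared study (default config)."""
    from fetoconn.io import node_distances
    from fetoconn.templates import fit_templates

    field, cohort, truth = default_study
    D = node_distances(cohort.node_table)
    return fit_templates(cohort, list(range(22, 38)), D)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
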