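import numpy as np
import pytest

import stcar
from stcar.mcmc import MCMCConfig


@pytest.fixture(scope="session")
def lattice34():
    return stcar.make_lattice_graph(3, 4)


@pytest.fixture(scope="session")
def default_panel(lattice34):
    panel, truth = stcar.simulate_panel(lattice34, 4, stcar.SimulationParams(seed=42))
    return panel, truth


@pytest.fixture(scope="session")
def fitted(default_panel, lattice34):
    """A short but converged fit of the default synthetic panel, shared across tests."""
    panel, _ = default_panel
    return stcar.run_chains(
        panel, lattice34,
        config=MCMCConfig(n_chains=3, n_iterations=4000, n_burnin=1000, thin=5, seed=7))


@pytest.fixture()
def tiny_panel():
    return stcar.ArealPanel(
        area_ids=["A", "B"], years=[2010, 2011],
        counts=np.array([[10.0, 12.0], [30.0, 28.0]]),
        populations=np.array([[2000.0, 2000.0], [3000.0, 3000.0]]),
        thi=np.array([[30.0, 32.0], [40.0, 41.0]]),
        ebf=np.array([55.0, 65.0]))


@pytest.fixture()
def pair_graph():
    return stcar.AdjacencyGraph(labels=["A", "B"],
                                weights=np.array([[0.0, 1.0], [1.0, 0.0]]))


def make_samples(scalars, n_areas=2, n_years=2, rr=None, u=None, v=None, delta=None,
                 variant="full"):
    """Hand-build a PosteriorSamples object from (chains, kept) scalar arrays."""
    some = next(iter(scalars.values()))
    c, k = np.asarray(some).shape
    full = {nm: np.asarray(scalars.get(nm, np.ones((c, k)))) for nm in
            ("alpha", "beta_thi", "beta_ebf", "gamma",
             "sigma2_u", "sigma2_v", "sigma2_delta")}
    for nm, val in scalars.items():
        full[nm] = np.asarray(val)
    zeros = np.zeros((c, k, n_areas))
    return stcar.PosteriorSamples(
        area_ids=[f"A{i}" for i in range(n_areas)],
        years=list(range(2010, 2010 + n_years)), variant=variant,
        scalars=full,
        u=zeros if u is None else u, v=zeros if v is None else v,
        delta=zeros if delta is None else delta,
        rr=rr, acceptance=[],
        config=MCMCConfig(n_iterations=max(k, 2), n_burnin=0, thin=1),
        prior=stcar.PriorSpec())
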