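import numpy as np
import pytest

from tandemer.fixtures import (
    RandomNetworkParams,
    methionine_fluxes,
    methionine_network,
    methionine_tracers,
    random_fluxes,
    random_network,
    random_tracers,
    toy_network,
)


@pytest.fixture(scope="session")
def toy():
    """(network, fluxes, tracers, targets) of the worked-example toy model."""
    return toy_network()


@pytest.fixture(scope="session")
def methionine():
    """(network, fluxes, tracers, targets) of the methionine model."""
    network, targets = methionine_network()
    return network, methionine_fluxes(network), methionine_tracers(network), targets


def make_random_case(seed: int, **param_overrides):
    """A random (network, fluxes, tracers, targets) tuple for property tests.

    Targets are random fragment pairs of up to three internal metabolites.
    """
    params = RandomNetworkParams(seed=seed, **param_overrides)
    network = random_network(params)
    fluxes = random_fluxes(network, seed=seed + 1)
    tracers = random_tracers(network, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    internal = [
        m for m in network.metabolites.values() if not m.is_media and m.n_atoms > 0
    ]
    targets = []
    from tandemer.iso_core import MFP

    for met in rng.choice(internal, size=min(3, len(internal)), replace=False):
        n = met.n_atoms
        k_parent = int(rng.integers(1, n + 1))
        parent = sorted(rng.choice(np.arange(1, n + 1), size=k_parent, replace=False))
        k_prod = int(rng.integers(0, k_parent + 1))
        product = sorted(rng.choice(parent, size=k_prod, replace=False))
        mfp = MFP(met.id, parent, product)
        if mfp not in targets:
            targets.append(mfp)
    return network, fluxes, tracers, targets


def direct_fragment_mid(dist_values, n_atoms: int, atoms) -> np.ndarray:
    """Independent mass-isotopomer binning over a fragment, via strings."""
    mid = np.zeros(len(atoms) + 1)
    for idx, frac in enumerate(dist_values):
        pattern = format(idx, f"0{n_atoms}b")
        count = sum(1 for a in atoms if pattern[a - 1] == "1")
        mid[count] += frac
    return mid
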