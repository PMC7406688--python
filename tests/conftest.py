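from fractions import Fraction

import numpy as np
import pytest

from kcone.network import MetabolicNetwork, Metabolite, Reaction, stoichiometric_matrix
from kcone.synth import toy_network


@pytest.fixture
def chain_model():
    """Linear pathway X_ext -> A -> B -> Y_ext with k = (1, 2, 4)."""
    return toy_network("chain")


@pytest.fixture
def chain_network(chain_model):
    return chain_model.network


@pytest.fixture
def chain_S(chain_network):
    return stoichiometric_matrix(chain_network)


def random_network(rng: np.random.Generator, max_mets: int = 6, max_steps: int = 8):
    """Random small irreversible network with integer stoichiometry."""
    n_met = int(rng.integers(2, max_mets + 1))
    n_rxn = int(rng.integers(2, max_steps + 1))
    S = rng.integers(-2, 3, size=(n_met, n_rxn))
    for j in range(n_rxn):
        if not S[:, j].any():
            S[int(rng.integers(0, n_met)), j] = 1
    mets = tuple(Metabolite(f"m{i}") for i in range(n_met))
    rxns = tuple(
        Reaction(
            id=f"r{j}",
            stoich={f"m{i}": Fraction(int(S[i, j])) for i in range(n_met) if S[i, j]},
        )
        for j in range(n_rxn)
    )
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


def random_concentrations(rng: np.random.Generator, network) -> dict:
    """Random positive rational concentrations for every internal metabolite."""
    return {
        m: Fraction(int(rng.integers(1, 20)), int(rng.integers(1, 10)))
        for m in network.internal_ids
    }
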