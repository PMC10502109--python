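import numpy as np
import pytest

from decrem import MetabolicModel, SynthNetworkSpec, SynthOmicsSpec, make_network, make_omics


def toy_cycle_model(reversible_first: bool = False) -> MetabolicModel:
    """Closed 3-cycle A -> B -> C -> A, optionally with R1 reversible."""
    S = np.array(
        [
            [-1.0, 0.0, 1.0],
            [1.0, -1.0, 0.0],
            [0.0, 1.0, -1.0],
        ]
    )
    lb = np.array([-10.0 if reversible_first else 0.0, 0.0, 0.0])
    return MetabolicModel(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=["R1", "R2", "R3"],
        S=S,
        lb=lb,
        ub=np.full(3, 10.0),
        c=np.zeros(3),
    )


def chain_model() -> MetabolicModel:
    """Linear chain: uptake -> A -> B -> C -> secretion (acyclic)."""
    S = np.array(
        [
            [1.0, -1.0, 0.0, 0.0],
            [0.0, 1.0, -1.0, 0.0],
            [0.0, 0.0, 1.0, -1.0],
        ]
    )
    c = np.array([0.0, 0.0, 0.0, 1.0])
    return MetabolicModel(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=["EX_in", "R1", "R2", "EX_out"],
        S=S,
        lb=np.zeros(4),
        ub=np.full(4, 10.0),
        c=c,
    )


def fed_cycle_model(uptake: float = 5.0) -> MetabolicModel:
    """Uptake-limited cycle: EX_in -> A, cycle A->B->C->A, drain C -> out."""
    S = np.array(
        [
            [1.0, -1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, -1.0, -1.0],
        ]
    )
    c = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    return MetabolicModel(
        metabolite_ids=["A", "B", "C"],
        reaction_ids=["EX_in", "R1", "R2", "R3", "EX_out"],
        S=S,
        lb=np.zeros(5),
        ub=np.array([uptake, 1000.0, 1000.0, 1000.0, 1000.0]),
        c=c,
    )


@pytest.fixture
def two_cycle_network():
    return make_network(
        SynthNetworkSpec(n_cycles=2, n_chain_reactions=4, n_bridge_reactions=2, seed=3)
    )


@pytest.fixture
def omics_panel():
    return make_omics(SynthOmicsSpec(seed=5))
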