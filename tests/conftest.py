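"""Shared fixtures: a small reference bundle, planted truth, and one
simulated sample, generated fresh (deterministically) at test time."""

import pytest

from aluedit import (
    SimParams,
    make_reference,
    plant_truth,
    simulate_sample,
)


@pytest.fixture(scope="session")
def toy_ref():
    return make_reference(n_genes=5, alu_per_gene=2, alu_len=300, seed=11)


@pytest.fixture(scope="session")
def toy_truth(toy_ref):
    return plant_truth(
        toy_ref,
        n_edit_sites=60,
        freq_by_condition={"control": 0.25, "kd": 0.10},
        n_snps=20,
        donor_scalars={"d1": 1.0, "d2": 0.9},
        seed=12,
    )


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(depth=30.0, read_len=100, error_rate=0.001, seed=13)


@pytest.fixture(scope="session")
def toy_sample(toy_ref, toy_truth, sim_params):
    return simulate_sample(toy_ref, toy_truth, "control", "d1", sim_params)
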