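"""Shared fixtures: one small simulated experiment reused across modules."""

from __future__ import annotations

import pytest

from l1ripseq import simulate


def small_config(seed: int = 11, **overrides) -> simulate.SimulationConfig:
    base = dict(
        seed=seed,
        n_l1_loci=12,
        divergence_rate=0.02,
        class_proportions=(0.5, 0.25, 0.25),
        host_categories={
            "mRNA": 15,
            "histone": 4,
            "MT": 3,
            "rRNA": 2,
            "lncRNA": 5,
            "circRNA_host": 3,
        },
        n_reads_input=4000,
        n_reads_ip=4000,
        # mechanism-test mix: keep every compartment populated at 4k reads
        l1_fraction_input=0.05,
        expression_multiplier={"rRNA": 40.0, "MT": 2.0, "histone": 5.0, "circRNA": 0.5},
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)


@pytest.fixture(scope="session")
def cfg():
    return small_config()


@pytest.fixture(scope="session")
def experiment(cfg):
    """(genome, truth, reads, hits) for the shared small experiment."""
    return simulate.simulate_all(cfg)


@pytest.fixture(scope="session")
def genome(experiment):
    return experiment[0]


@pytest.fixture(scope="session")
def truth(experiment):
    return experiment[1]


@pytest.fixture(scope="session")
def reads(experiment):
    return experiment[2]


@pytest.fixture(scope="session")
def hits(experiment):
    return experiment[3]
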