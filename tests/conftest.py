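import numpy as np
import pytest

from triepistasis.data_model import DHPopulation, LinkageMap, MarkerMatrix, TraitVector
from triepistasis.simulate import (
    ChromosomeSpec,
    EffectSpec,
    SimulationConfig,
    make_full_factorial,
)


@pytest.fixture
def factorial3() -> DHPopulation:
    return make_full_factorial(3)


@pytest.fixture
def tiny_pop() -> DHPopulation:
    """3 lines x 2 markers hand-written population with one trait."""
    linkage = LinkageMap((("m1", "1H", 0.0), ("m2", "1H", 12.5)))
    genotypes = MarkerMatrix(("L1", "L2", "L3"), np.array([[1, -1], [-1, 1], [1, 1]], float))
    trait = TraitVector("GY", "ID91", np.array([4.2, 3.1, 5.0]), lines=("L1", "L2", "L3"))
    return DHPopulation(map=linkage, genotypes=genotypes, traits=[trait])


def anchor_config(
    seed: int,
    delta: float = 0.8,
    sigma_e: float = 1.0,
    missing_rate: float = 0.0,
    n_lines: int = 150,
) -> SimulationConfig:
    """Study-shaped population: 3 chromosomes x 20 markers at 10 cM, three
    additive anchors of 1.0 mid-chromosome, optionally one triple effect."""
    effects = [
        EffectSpec(("chr1_m010",), 1.0),
        EffectSpec(("chr2_m010",), 1.0),
        EffectSpec(("chr3_m010",), 1.0),
    ]
    if delta:
        effects.append(EffectSpec(("chr1_m010", "chr2_m010", "chr3_m010"), delta))
    return SimulationConfig(
        n_lines=n_lines,
        chromosomes=[ChromosomeSpec(f"chr{i + 1}", 20, 10.0) for i in range(3)],
        effects=effects,
        mu=0.0,
        sigma_e=sigma_e,
        missing_rate=missing_rate,
        seed=seed,
    )
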