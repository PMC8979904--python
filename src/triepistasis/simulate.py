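"""Synthetic DH populations with known genetic architecture.

Genotypes are simulated per chromosome as a two-state Markov chain over
{-1, +1}: the first marker is +-1 with probability 1/2 each (balanced 1:1
segregation), and each subsequent marker flips relative to its neighbour
with the Haldane recombination fraction of the inter-marker distance.
Chromosomes are independent and there is no crossover interference,
matching the model assumed by the flanking imputation.

Traits follow the marker-product model
``y = mu + sum beta_l x_l + sum gamma x x' + sum delta x x' x'' + e`` with
i.i.d. Gaussian noise.  Missing-genotype masking is applied after trait
generation so the injected effects stay well defined.

Presets mimic the two barley DH panels commonly used for this kind of
study: ``sxm_like`` (150 lines, 223 markers on 7 chromosomes, mean spacing
5.66 cM) and ``hxt_like`` (145 lines, 127 markers, mean spacing 10.62 cM).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .data_model import DHPopulation, LinkageMap, MarkerMatrix, TraitVector
from .errors import ConfigurationError
from .preprocess import haldane_r

__all__ = [
    "ChromosomeSpec",
    "EffectSpec",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_trait",
    "mask_missing",
    "simulate_population",
    "make_full_factorial",
    "sxm_like",
    "hxt_like",
    "load_config",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: either regular spacing or explicit positions."""

    name: str
    n_markers: int = 0
    spacing_cm: float = 10.0
    positions: tuple[float, ...] | None = None

    def marker_positions(self) -> tuple[float, ...]:
        if self.positions is not None:
            return tuple(float(p) for p in self.positions)
        if self.n_markers < 1:
            raise ConfigurationError(f"chromosome {self.name}: needs >= 1 marker")
        return tuple(i * self.spacing_cm for i in range(self.n_markers))


@dataclass(frozen=True)
class EffectSpec:
    """A genetic effect: 1 marker (additive), 2 (aa) or 3 (aaa) with a value."""

    marker_ids: tuple[str, ...]
    value: float

    @property
    def order(self) -> int:
        return len(self.marker_ids)


@dataclass
class SimulationConfig:
    n_lines: int = 150
    chromosomes: list[ChromosomeSpec] = field(default_factory=list)
    effects: list[EffectSpec] = field(default_factory=list)
    mu: float = 0.0
    sigma_e: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    trait_id: str = "sim"
    environment_id: str = "E1"

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ConfigurationError(f"need >= 2 lines, got {self.n_lines}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.sigma_e < 0.0:
            raise ConfigurationError(f"sigma_e must be >= 0, got {self.sigma_e}")


def _build_map(chromosomes: Sequence[ChromosomeSpec]) -> LinkageMap:
    markers = []
    for chrom in chromosomes:
        for i, pos in enumerate(chrom.marker_positions()):
            markers.append((f"{chrom.name}_m{i + 1:03d}", chrom.name, pos))
    if not markers:
        raise ConfigurationError("simulation needs at least one chromosome with markers")
    return LinkageMap(tuple(markers))


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> DHPopulation:
    """Simulate the genotype matrix and map (no traits, no masking)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    linkage = _build_map(cfg.chromosomes)
    n = cfg.n_lines
    width = len(str(n))
    lines = tuple(f"DH{i + 1:0{width}d}" for i in range(n))
    cols: list[np.ndarray] = []
    for chrom in cfg.chromosomes:
        pos = np.asarray(chrom.marker_positions())
        first = rng.choice((-1.0, 1.0), size=n)
        chrom_cols = [first]
        for k in range(1, pos.size):
            r = haldane_r(pos[k] - pos[k - 1])
            flip = rng.random(n) < r
            chrom_cols.append(np.where(flip, -chrom_cols[-1], chrom_cols[-1]))
        cols.extend(chrom_cols)
    return DHPopulation(map=linkage, genotypes=MarkerMatrix(lines, np.column_stack(cols)))


def simulate_trait(
    pop: DHPopulation,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TraitVector:
    """Generate one trait from the configured architecture plus noise.

    Genotypes must be complete (simulate the trait before masking)."""
    if pop.genotypes.has_missing:
        raise ConfigurationError("simulate the trait before masking missing genotypes")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    y = np.full(pop.n_lines, float(cfg.mu))
    for eff in cfg.effects:
        if eff.order not in (1, 2, 3):
            raise ConfigurationError(f"effect order must be 1-3: {eff.marker_ids}")
        col = np.ones(pop.n_lines)
        for mid in eff.marker_ids:
            col = col * pop.marker_column(mid)  # raises if the marker is unknown
        y += eff.value * col
    if cfg.sigma_e > 0:
        y += rng.normal(0.0, cfg.sigma_e, size=pop.n_lines)
    return TraitVector(cfg.trait_id, cfg.environment_id, y, lines=pop.genotypes.lines)


def mask_missing(
    pop: DHPopulation, rate: float, rng: np.random.Generator
) -> DHPopulation:
    """Mask genotype entries missing uniformly at random at the given rate."""
    if rate <= 0:
        return pop
    values = pop.genotypes.values.copy()
    mask = rng.random(values.shape) < rate
    values[mask] = np.nan
    return pop.with_genotypes(values)


def simulate_population(cfg: SimulationConfig) -> DHPopulation:
    """Full generator: genotypes -> trait -> missing-data masking.

    Deterministic given the config (all randomness flows from cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_genotypes(cfg, rng)
    trait = simulate_trait(pop, cfg, rng)
    pop.traits.append(trait)
    return mask_missing(pop, cfg.missing_rate, rng)


def make_full_factorial(k: int) -> DHPopulation:
    """All 2^k +-1 combinations of k unlinked markers (one per
    pseudo-chromosome); the orthogonal fixture for exact-fit checks."""
    if not 2 <= k <= 4:
        raise ConfigurationError(f"full factorial supports k in 2..4, got {k}")
    rows = list(itertools.product((-1.0, 1.0), repeat=k))
    lines = tuple(f"F{i + 1:02d}" for i in range(len(rows)))
    markers = tuple((f"C{j + 1}_m001", f"C{j + 1}", 0.0) for j in range(k))
    return DHPopulation(
        map=LinkageMap(markers),
        genotypes=MarkerMatrix(lines, np.array(rows)),
    )


# ---------------------------------------------------------------------------
# presets and config files


def _preset(
    n_lines: int,
    n_chrom: int,
    markers_per_chrom: list[int],
    spacing: float,
    seed: int,
    missing_rate: float,
) -> SimulationConfig:
    chroms = [
        ChromosomeSpec(f"chr{c + 1}", markers_per_chrom[c], spacing) for c in range(n_chrom)
    ]
    cfg = SimulationConfig(
        n_lines=n_lines,
        chromosomes=chroms,
        mu=50.0,
        sigma_e=1.0,
        missing_rate=missing_rate,
        seed=seed,
    )
    # a handful of additive anchors plus one pairwise and one triple effect,
    # placed mid-chromosome on the first three chromosomes
    mids = [f"chr{c + 1}_m{markers_per_chrom[c] // 2:03d}" for c in range(3)]
    cfg.effects = [
        EffectSpec((mids[0],), 1.0),
        EffectSpec((mids[1],), 0.8),
        EffectSpec((mids[2],), 0.6),
        EffectSpec((mids[0], mids[1]), 0.4),
        EffectSpec((mids[0], mids[1], mids[2]), 0.5),
    ]
    return cfg


def sxm_like(seed: int = 0, missing_rate: float = 0.02) -> SimulationConfig:
    """150 lines, 223 markers on 7 chromosomes, ~5.66 cM mean spacing."""
    per_chrom = [32, 32, 32, 32, 32, 32, 31]
    return _preset(150, 7, per_chrom, 5.66, seed, missing_rate)


def hxt_like(seed: int = 0, missing_rate: float = 0.02) -> SimulationConfig:
    """145 lines, 127 markers on 7 chromosomes, ~10.62 cM mean spacing."""
    per_chrom = [19, 18, 18, 18, 18, 18, 18]
    return _preset(145, 7, per_chrom, 10.62, seed, missing_rate)


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file.

    Schema::

        n_lines: 150
        mu: 50.0
        sigma_e: 1.0
        missing_rate: 0.02
        seed: 7
        chromosomes:
          - {name: chr1, n_markers: 20, spacing_cm: 10}
          - {name: chr2, positions: [0, 5, 12.5]}
        effects:
          - {markers: [chr1_m010], value: 1.0}
          - {markers: [chr1_m010, chr2_m001, chr2_m002], value: 0.8}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    chroms = [
        ChromosomeSpec(
            name=str(c["name"]),
            n_markers=int(c.get("n_markers", 0)),
            spacing_cm=float(c.get("spacing_cm", 10.0)),
            positions=tuple(c["positions"]) if "positions" in c else None,
        )
        for c in raw.get("chromosomes", [])
    ]
    effects = [
        EffectSpec(tuple(str(m) for m in e["markers"]), float(e["value"]))
        for e in raw.get("effects", [])
    ]
    return SimulationConfig(
        n_lines=int(raw.get("n_lines", 150)),
        chromosomes=chroms,
        effects=effects,
        mu=float(raw.get("mu", 0.0)),
        sigma_e=float(raw.get("sigma_e", 1.0)),
        missing_rate=float(raw.get("missing_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
        trait_id=str(raw.get("trait_id", "sim")),
        environment_id=str(raw.get("environment_id", "E1")),
    )
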