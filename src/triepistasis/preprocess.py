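"""Trait transformation, normality screening, flanking-marker imputation
and the 1:1 segregation pre-test.

Genetic model behind the imputation: along a chromosome a DH line's
genotype is a two-state Markov chain over {-1, +1} (no crossover
interference); the transition ("flip") probability between two markers at
distance d cM is the Haldane recombination fraction
``r = (1 - exp(-2d/100)) / 2``.  With balanced 1:1 segregation the chain
is symmetric, so the correlation between markers at distance d is
``1 - 2r`` and the conditional mean of a missing genotype given observed
flanks has the closed form used in :func:`impute_flanking`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DHPopulation, LinkageMap, MarkerMatrix, TraitVector
from .errors import DegenerateInputError, DomainError, TriepistasisError

__all__ = [
    "arcsin_sqrt_transform",
    "check_normality",
    "haldane_r",
    "impute_flanking",
    "segregation_chi2",
    "SegregationTestResult",
    "segregation_report_frame",
]


def arcsin_sqrt_transform(x, lines=None) -> np.ndarray:
    """Angular transform arcsin(sqrt(x/100)) for percentage traits.

    Maps [0, 100] monotonically onto [0, pi/2] (radians); the standard
    variance-stabilising transform for percentage data.
    """
    arr = np.asarray(x, dtype=float)
    bad = ~((arr >= 0.0) & (arr <= 100.0))
    if bad.any():
        idx = int(np.flatnonzero(bad.ravel())[0])
        name = lines[idx] if lines is not None else f"index {idx}"
        raise DomainError(
            f"arcsin-sqrt transform needs values in [0, 100]; "
            f"got {arr.ravel()[idx]} at {name}"
        )
    return np.arcsin(np.sqrt(arr / 100.0))


def transform_trait(t: TraitVector) -> TraitVector:
    """Return a copy of the trait with the angular transform applied."""
    y = arcsin_sqrt_transform(t.y, lines=t.lines)
    return TraitVector(t.trait_id, t.environment_id, y, "arcsin_sqrt", t.lines)


def check_normality(y) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value for a trait vector.

    Advisory only — the pipeline reports the result but never blocks on it.
    """
    arr = np.asarray(getattr(y, "y", y), dtype=float).ravel()
    if arr.size < 8:
        raise DomainError(f"normality check needs n >= 8, got {arr.size}")
    if np.ptp(arr) == 0.0:
        raise DegenerateInputError("normality check on a constant vector")
    stat, p = stats.shapiro(arr)
    return float(stat), float(p)


def haldane_r(d) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, in [0, 0.5).
    """
    arr = np.asarray(d, dtype=float)
    if (arr < 0).any():
        raise DomainError(f"map distance must be >= 0 cM, got {arr.min()}")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    return float(r) if np.isscalar(d) or arr.ndim == 0 else r


def _conditional_mean(a: float, t_left: float, b: float, t_right: float) -> float:
    # E[x | left=a, right=b] for the symmetric +-1 Markov chain with
    # flank correlations t = 1 - 2r
    return (a * t_left + b * t_right) / (1.0 + a * b * t_left * t_right)


def impute_flanking(
    g: MarkerMatrix,
    linkage: LinkageMap,
    round_to_calls: bool = False,
) -> MarkerMatrix:
    """Replace missing genotypes by their conditional mean given the
    nearest observed flanking markers on the same chromosome.

    With both flanks observed the conditional mean follows the two-sided
    Markov-chain formula; with a single informative flank it is
    ``flank * (1 - 2 r)``; with no observed marker on the chromosome the
    balanced-segregation prior gives 0.  Observed entries are never touched,
    so the operation is idempotent.  ``round_to_calls`` snaps imputed values
    to the nearer of -1/+1 (0 rounds to +1) for strict two-level coding.
    """
    values = g.values.copy()
    positions = np.array([m[2] for m in linkage.markers])
    by_chrom = linkage.chromosome_indices()

    for i in range(values.shape[0]):
        row = values[i]
        for cols in by_chrom.values():
            cols_arr = np.asarray(cols)
            obs_mask = np.isfinite(row[cols_arr])
            miss = cols_arr[~obs_mask]
            if miss.size == 0:
                continue
            obs = cols_arr[obs_mask]
            for j in miss:
                left = obs[obs < j]
                right = obs[obs > j]
                if left.size and right.size:
                    jl, jr = left[-1], right[0]
                    tl = 1.0 - 2.0 * haldane_r(positions[j] - positions[jl])
                    tr = 1.0 - 2.0 * haldane_r(positions[jr] - positions[j])
                    row[j] = _conditional_mean(row[jl], tl, row[jr], tr)
                elif left.size:
                    jl = left[-1]
                    row[j] = row[jl] * (1.0 - 2.0 * haldane_r(positions[j] - positions[jl]))
                elif right.size:
                    jr = right[0]
                    row[j] = row[jr] * (1.0 - 2.0 * haldane_r(positions[jr] - positions[j]))
                else:
                    row[j] = 0.0
    if round_to_calls:
        values = np.where(values >= 0.0, 1.0, -1.0)
    return MarkerMatrix(g.lines, values)


@dataclass(frozen=True)
class SegregationTestResult:
    """Goodness-of-fit of one marker's +1/-1 counts against 1:1."""

    marker_id: str
    chromosome: str
    n_plus: int
    n_minus: int
    chi2: float
    p_value: float

    def distorted(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def segregation_chi2(
    g: MarkerMatrix, linkage: LinkageMap | None = None
) -> list[SegregationTestResult]:
    """Chi-square test of each marker's segregation against the expected
    1:1 ratio of a DH population.

    chi2 = (n_plus - n_minus)^2 / (n_plus + n_minus), 1 df.  Imputed
    (fractional) entries are ignored; only hard -1/+1 calls are counted.
    """
    results = []
    ids = linkage.marker_ids if linkage is not None else [f"col{j}" for j in range(g.n_markers)]
    chroms = (
        [m[1] for m in linkage.markers] if linkage is not None else ["?"] * g.n_markers
    )
    for j in range(g.n_markers):
        col = g.values[:, j]
        n_plus = int((col == 1.0).sum())
        n_minus = int((col == -1.0).sum())
        total = n_plus + n_minus
        if total == 0:
            raise TriepistasisError(
                f"segregation test: marker {ids[j]!r} has no observed -1/+1 calls"
            )
        chi2 = (n_plus - n_minus) ** 2 / total
        p = float(stats.chi2.sf(chi2, df=1))
        results.append(SegregationTestResult(ids[j], chroms[j], n_plus, n_minus, chi2, p))
    return results


def segregation_report_frame(
    results: list[SegregationTestResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Tabular segregation report (TSV-ready)."""
    return pd.DataFrame(
        {
            "marker": [r.marker_id for r in results],
            "chromosome": [r.chromosome for r in results],
            "n_plus": [r.n_plus for r in results],
            "n_minus": [r.n_minus for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p_value for r in results],
            "distorted": [r.distorted(alpha) for r in results],
        }
    )


def preprocess_population(
    pop: DHPopulation,
    transform_traits: set[str] | frozenset[str] = frozenset(),
    exclude_distorted: bool = False,
    segregation_alpha: float = 0.05,
) -> tuple[DHPopulation, list[SegregationTestResult]]:
    """Standard preprocessing: segregation report on the raw calls, optional
    exclusion of distorted markers, flanking imputation, optional angular
    transform of the named traits."""
    seg = segregation_chi2(pop.genotypes, pop.map)
    linkage, values = pop.map, pop.genotypes.values
    if exclude_distorted:
        keep = [j for j, r in enumerate(seg) if not r.distorted(segregation_alpha)]
        linkage = LinkageMap(tuple(pop.map.markers[j] for j in keep))
        values = values[:, keep]
    genotypes = impute_flanking(MarkerMatrix(pop.genotypes.lines, values), linkage)
    traits = [
        transform_trait(t) if t.trait_id in transform_traits else t for t in pop.traits
    ]
    return DHPopulation(map=linkage, genotypes=genotypes, traits=traits), seg
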