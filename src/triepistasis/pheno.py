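"""Phenotypic estimation of the total three-way (aaa) epistatic effect.

The estimator needs no marker data.  Two groups of "extreme" lines are
picked from the tails of the empirical trait distribution — ideally lines
carrying only trait-decreasing (min group) or only trait-increasing
(max group) alleles — and the total additive x additive x additive effect
is estimated as

    aaa_p = (L_max_mean + L_min_mean) / 2 - L_mean,

where L_mean is the mean over all lines.  A Wright-type effective-factor
count K = round((L_max_mean - L_min_mean)^2 / (8 s_y^2)) accompanies the
estimate; the exact formula used for that count in the classical
literature is not uniquely standardised, so the estimator is pluggable.

Note on the symmetric form: under a pure +-1 product model, odd-order
contributions of loci fixed at opposite extremes cancel in
(L_max_mean + L_min_mean)/2; the formula is nevertheless implemented
exactly as stated — see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data_model import TraitVector
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "ExtremeGroups",
    "PhenotypicEstimate",
    "select_extreme_groups",
    "estimate_aaa_phenotypic",
    "count_effective_factors",
]


@dataclass(frozen=True)
class ExtremeGroups:
    """Disjoint sets of minimal- and maximal-expression lines."""

    min_line_ids: tuple[str, ...]
    max_line_ids: tuple[str, ...]
    mean_min: float
    mean_max: float


@dataclass(frozen=True)
class PhenotypicEstimate:
    aaa_p: float
    mean_all: float
    groups: ExtremeGroups
    n_effective_factors: int


def _lines_of(y: TraitVector, lines: Sequence[str] | None) -> tuple[str, ...]:
    if lines is not None:
        return tuple(str(s) for s in lines)
    if y.lines is not None:
        return y.lines
    width = len(str(y.n))
    return tuple(f"L{i:0{width}d}" for i in range(y.n))


def select_extreme_groups(
    y: TraitVector, fraction: float = 0.05, lines: Sequence[str] | None = None
) -> ExtremeGroups:
    """Pick the ceil(fraction * n) smallest and largest lines.

    Ties at a group boundary are broken by line id (lexicographic), so the
    selection is reproducible regardless of input order.  Groups must be
    disjoint; a fraction above 0.5 (or one that makes the tails meet)
    raises a configuration error.
    """
    ids = _lines_of(y, lines)
    n = y.n
    if n < 4:
        raise ConfigurationError(f"extreme-group selection needs n >= 4, got {n}")
    if not 0.0 < fraction <= 0.5:
        raise ConfigurationError(f"extreme fraction must be in (0, 0.5], got {fraction}")
    if np.ptp(y.y) == 0.0:
        raise DegenerateInputError(
            f"trait {y.label}: constant values, extremes undefined"
        )
    size = math.ceil(fraction * n)
    if 2 * size > n:
        raise ConfigurationError(
            f"extreme groups of {size} lines each overlap for n={n} "
            f"(fraction {fraction})"
        )
    order = sorted(range(n), key=lambda i: (y.y[i], ids[i]))
    lo = [order[k] for k in range(size)]
    hi = [order[n - size + k] for k in range(size)]
    return ExtremeGroups(
        min_line_ids=tuple(ids[i] for i in lo),
        max_line_ids=tuple(ids[i] for i in hi),
        mean_min=float(np.mean(y.y[lo])),
        mean_max=float(np.mean(y.y[hi])),
    )


def count_effective_factors(
    y: TraitVector,
    groups: ExtremeGroups,
    estimator: Callable[[float, float, float], float] | None = None,
) -> int:
    """Effective-factor (gene number) count from the extreme-group range.

    Default is the Wright-type stand-in K = (range)^2 / (8 s_y^2) with
    range = mean_max - mean_min and s_y^2 the sample variance; rounded and
    clamped at 0.  Pass ``estimator(mean_max, mean_min, s2) -> float`` to
    substitute another formula.
    """
    s2 = float(np.var(y.y, ddof=1))
    if s2 == 0.0:
        raise DegenerateInputError(f"trait {y.label}: zero variance, factor count undefined")
    if estimator is None:
        k = (groups.mean_max - groups.mean_min) ** 2 / (8.0 * s2)
    else:
        k = estimator(groups.mean_max, groups.mean_min, s2)
    return max(0, round(k))


def estimate_aaa_phenotypic(
    y: TraitVector,
    groups: ExtremeGroups | None = None,
    fraction: float = 0.05,
    lines: Sequence[str] | None = None,
) -> PhenotypicEstimate:
    """Total aaa effect from the phenotype: (mean_max + mean_min)/2 - mean_all.

    If ``groups`` is omitted they are selected with ``fraction``.
    Location-invariant and scale-equivariant by construction.
    """
    if groups is None:
        groups = select_extreme_groups(y, fraction=fraction, lines=lines)
    mean_all = float(np.mean(y.y))
    aaa_p = 0.5 * (groups.mean_max + groups.mean_min) - mean_all
    try:
        k = count_effective_factors(y, groups)
    except DegenerateInputError:
        k = 0
    return PhenotypicEstimate(aaa_p=aaa_p, mean_all=mean_all, groups=groups, n_effective_factors=k)
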