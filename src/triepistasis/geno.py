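"""Marker-regression (genotypic) estimation of the total aaa effect.

The trait is modelled on p selected markers as

    y = 1*mu + X*beta + Z*gamma + W*delta + e,

where X holds the selected -1/+1 marker columns, Z all pairwise products
(additive x additive effects ``aa``), W all three-way products
(additive x additive x additive effects ``aaa``) and e is i.i.d. noise.
Because epistatic terms are assumed to involve only loci with significant
additive action, products are formed among the selected markers only.

Marker selection is staged, each stage a bidirectional stepwise search
minimising AIC:

1. per chromosome over that chromosome's additive terms,
2. over the pooled stage-1 survivors (additive terms only) — giving the
   p markers of the model,
3. from the full additive model, over the pairwise and triple product
   candidates (additive terms are kept throughout).

The fitted model yields the total three-way effect as the sum of all
retained triple-term coefficients; each triple is tested at a
Bonferroni-corrected level (see :func:`total_aaa_genotypic`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_model import DHPopulation, TraitVector
from .errors import ConfigurationError, RankError, TriepistasisError

__all__ = [
    "TermDescriptor",
    "ModelDesign",
    "FitResult",
    "GenotypicEstimate",
    "ContrastEstimate",
    "StepwiseTrace",
    "stage1_chromosome_select",
    "stage2_combined_select",
    "build_design",
    "stage3_interaction_select",
    "significant_additive_markers",
    "ols",
    "fit_ols",
    "total_aaa_genotypic",
    "contrast_aaa",
    "estimate_aaa_genotypic",
]

_EPS = 1e-10


@dataclass(frozen=True, order=True)
class TermDescriptor:
    """A model term: one marker (additive), a pair (aa) or a triple (aaa).

    ``marker_ids`` are kept in canonical map order so that (A,B,C) and
    (C,A,B) denote the same term.
    """

    order: int
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3) or len(self.marker_ids) != self.order:
            raise ConfigurationError(f"bad term: order {self.order}, ids {self.marker_ids}")
        if len(set(self.marker_ids)) != self.order:
            raise ConfigurationError(f"term markers must be distinct: {self.marker_ids}")

    @property
    def name(self) -> str:
        return {1: "a", 2: "aa", 3: "aaa"}[self.order] + "(" + ",".join(self.marker_ids) + ")"


def term(marker_ids: Iterable[str], pop: DHPopulation) -> TermDescriptor:
    """Build a TermDescriptor with ids sorted into map order."""
    ids = tuple(sorted(set(marker_ids), key=pop.map.index_of))
    return TermDescriptor(order=len(ids), marker_ids=ids)


def _term_column(t: TermDescriptor, pop: DHPopulation) -> np.ndarray:
    col = np.ones(pop.n_lines)
    for mid in t.marker_ids:
        col = col * pop.marker_column(mid)
    return col


@dataclass
class ModelDesign:
    """Design matrix of the marker-regression model: intercept + terms."""

    selected_markers: tuple[str, ...]
    terms: tuple[TermDescriptor, ...]
    matrix: np.ndarray  # n x (1 + len(terms)); first column is the intercept

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 1 + len(self.terms):
            raise TriepistasisError("design matrix width does not match term list")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def terms_of_order(self, order: int) -> list[TermDescriptor]:
        return [t for t in self.terms if t.order == order]


def build_design(
    pop: DHPopulation,
    selected_markers: Sequence[str],
    include_pairwise: bool = True,
    include_triple: bool = True,
    product_markers: Sequence[str] | None = None,
) -> ModelDesign:
    """Design on the selected markers: X plus pairwise and triple product
    columns, terms in canonical map order.

    Epistatic terms are assumed to involve only loci with significant
    additive action; ``product_markers`` (default: all selected markers)
    names the subset among which the C(.,2) pairwise and C(.,3) triple
    products are formed.
    """
    markers = tuple(sorted(set(selected_markers), key=pop.map.index_of))
    prod = (
        markers
        if product_markers is None
        else tuple(sorted(set(product_markers), key=pop.map.index_of))
    )
    if not set(prod) <= set(markers):
        raise ConfigurationError("product_markers must be a subset of selected_markers")
    terms: list[TermDescriptor] = [TermDescriptor(1, (m,)) for m in markers]
    if include_pairwise:
        terms += [TermDescriptor(2, pair) for pair in itertools.combinations(prod, 2)]
    if include_triple:
        terms += [TermDescriptor(3, tri) for tri in itertools.combinations(prod, 3)]
    cols = [np.ones(pop.n_lines)] + [_term_column(t, pop) for t in terms]
    return ModelDesign(markers, tuple(terms), np.column_stack(cols))


# ---------------------------------------------------------------------------
# OLS


@dataclass
class FitResult:
    """OLS fit of y = G alpha + e with per-term inference.

    ``terms[0]`` is None (intercept); arrays are aligned with ``terms``.
    Aliased columns are dropped deterministically (first kept in canonical
    order) and listed in ``dropped_terms`` with ``rank_ok = False``.
    """

    terms: tuple[TermDescriptor | None, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residual_variance: float
    rss: float
    aic: float
    df_resid: int
    rank_ok: bool
    dropped_terms: tuple[TermDescriptor, ...] = ()

    def coefficient(self, t: TermDescriptor | None) -> float:
        return float(self.estimates[self.terms.index(t)])

    def triples(self) -> list[tuple[TermDescriptor, float, float]]:
        """(term, estimate, p_value) for every fitted aaa term."""
        return [
            (t, float(self.estimates[i]), float(self.p_values[i]))
            for i, t in enumerate(self.terms)
            if t is not None and t.order == 3
        ]

    def n_interaction_terms(self) -> int:
        return sum(1 for t in self.terms if t is not None and t.order >= 2)


def _aic_from_rss(rss: float, n: int, k: int) -> float:
    """AIC = n log(RSS/n) + 2(k+1), dropping the n log(2 pi) + n constant.

    k counts the regression coefficients; +1 for the error variance.  The
    constant cancels in every within-dataset comparison the package makes.
    """
    return n * math.log(max(rss, 1e-300) / n) + 2.0 * (k + 1)


def _independent_columns(G: np.ndarray, tol_scale: float = 1e-9) -> list[int]:
    """Greedy left-to-right choice of a linearly independent column subset."""
    n = G.shape[0]
    kept: list[int] = []
    Q = np.empty((n, 0))
    for j in range(G.shape[1]):
        c = G[:, j]
        norm = np.linalg.norm(c)
        if norm == 0.0:
            continue
        r = c - Q @ (Q.T @ c)
        if np.linalg.norm(r) > tol_scale * max(norm, 1.0):
            kept.append(j)
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
    return kept


def ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, list[int]]:
    """Least-squares core: (coef, se, rss, df_resid, kept_columns).

    Solves the normal equations via QR; aliased columns are dropped
    first-kept-wins and get coef = se = nan in the returned arrays.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = G.shape
    kept = _independent_columns(G)
    if n <= 0 or len(kept) > n:
        raise RankError(f"cannot fit {len(kept)} columns to {n} observations")
    Gk = G[:, kept]
    coef_k, _, _, _ = np.linalg.lstsq(Gk, y, rcond=None)
    resid = y - Gk @ coef_k
    rss = float(resid @ resid)
    df = n - len(kept)
    coef = np.full(k, np.nan)
    se = np.full(k, np.nan)
    coef[kept] = coef_k
    if df > 0:
        sigma2 = rss / df
        xtx_inv = np.linalg.inv(Gk.T @ Gk)
        se[kept] = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    return coef, se, rss, df, kept


def fit_ols(design: ModelDesign, y: TraitVector | np.ndarray) -> FitResult:
    """Fit the marker-regression model by ordinary least squares.

    Inference uses the t distribution on the residual degrees of freedom;
    with zero residual df (saturated model) standard errors and p-values
    are nan — estimates remain exact.
    """
    yv = np.asarray(getattr(y, "y", y), dtype=float).ravel()
    G = design.matrix
    n = G.shape[0]
    if yv.size != n:
        raise TriepistasisError(f"y has {yv.size} values for a {n}-row design")
    if G.shape[1] > n:
        raise RankError(f"design has {G.shape[1]} columns for only {n} observations")
    coef, se, rss, df, kept = ols(G, yv)
    dropped = tuple(
        design.terms[j - 1] for j in range(G.shape[1]) if j not in kept and j >= 1
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coef / se
    if df > 0:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    else:
        pvals = np.full_like(tstat, np.nan)
    keep_mask = np.array([j in set(kept) for j in range(G.shape[1])])
    terms_all: list[TermDescriptor | None] = [None, *design.terms]
    fitted_terms = tuple(t for t, keep in zip(terms_all, keep_mask) if keep)
    return FitResult(
        terms=fitted_terms,
        estimates=coef[keep_mask],
        standard_errors=se[keep_mask],
        t_statistics=np.asarray(tstat)[keep_mask],
        p_values=np.asarray(pvals)[keep_mask],
        residual_variance=rss / df if df > 0 else float("nan"),
        rss=rss,
        aic=_aic_from_rss(rss, n, len(kept)),
        df_resid=df,
        rank_ok=len(dropped) == 0,
        dropped_terms=dropped,
    )


# ---------------------------------------------------------------------------
# stepwise AIC engine


@dataclass
class StepwiseTrace:
    """Audit trail of a stepwise search: one entry per accepted move."""

    moves: list[tuple[str, TermDescriptor, float, float]] = field(default_factory=list)

    def record(self, action: str, t: TermDescriptor, before: float, after: float) -> None:
        self.moves.append((action, t, before, after))


def _rss_of(cols: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coefs, _, _, _ = np.linalg.lstsq(cols, y, rcond=None)
    resid = y - cols @ coefs
    rank = np.linalg.matrix_rank(cols) if cols.shape[1] > 1 else 1
    return float(resid @ resid), int(rank)


def _stepwise(
    y: np.ndarray,
    base: np.ndarray,
    candidates: dict[TermDescriptor, np.ndarray],
    start: Sequence[TermDescriptor] = (),
    max_columns: int | None = None,
    trace: StepwiseTrace | None = None,
) -> list[TermDescriptor]:
    """Bidirectional stepwise AIC minimisation.

    ``base`` columns (intercept and any protected terms) are always in the
    model; ``candidates`` may be added or, once in, removed.  Each iteration
    scores every single-term addition (vectorised through the current
    orthonormal basis) and every single-term deletion, and applies the best
    strictly-improving move.  Additions respect ``max_columns`` (total
    fitted columns including base).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    current: list[TermDescriptor] = [t for t in start if t in candidates]
    cand_keys = list(candidates)
    C = (
        np.column_stack([candidates[t] for t in cand_keys])
        if cand_keys
        else np.empty((n, 0))
    )

    def model_matrix(terms: Sequence[TermDescriptor]) -> np.ndarray:
        if not terms:
            return base
        return np.column_stack([base, *[candidates[t] for t in terms]])

    G = model_matrix(current)
    rss, rank = _rss_of(G, y)
    aic = _aic_from_rss(rss, n, rank)

    while True:
        best: tuple[float, str, TermDescriptor] | None = None

        # additions: RSS drop of adding one column c is (r'c_perp)^2/||c_perp||^2
        free = [t for t in cand_keys if t not in current]
        if free and (max_columns is None or G.shape[1] + 1 <= max_columns):
            Q, _ = np.linalg.qr(G)
            coefs, _, _, _ = np.linalg.lstsq(G, y, rcond=None)
            r = y - G @ coefs
            idx = [cand_keys.index(t) for t in free]
            Cf = C[:, idx]
            C_perp = Cf - Q @ (Q.T @ Cf)
            den = np.einsum("ij,ij->j", C_perp, C_perp)
            num = (r @ C_perp) ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                rss_new = rss - np.where(den > _EPS * n, num / den, 0.0)
            for t, rn, d in zip(free, rss_new, den):
                if d <= _EPS * n:
                    continue  # aliased with the current model
                cand_aic = _aic_from_rss(max(rn, 0.0), n, rank + 1)
                if cand_aic < aic - _EPS and (best is None or cand_aic < best[0]):
                    best = (cand_aic, "add", t)

        # deletions
        for t in current:
            rest = [u for u in current if u is not t]
            rss_d, rank_d = _rss_of(model_matrix(rest), y)
            cand_aic = _aic_from_rss(rss_d, n, rank_d)
            if cand_aic < aic - _EPS and (best is None or cand_aic < best[0]):
                best = (cand_aic, "drop", t)

        if best is None:
            return current
        new_aic, action, t = best
        if trace is not None:
            trace.record(action, t, aic, new_aic)
        if action == "add":
            current.append(t)
        else:
            current.remove(t)
        G = model_matrix(current)
        rss, rank = _rss_of(G, y)
        aic = new_aic


# ---------------------------------------------------------------------------
# staged selection


def _require_complete(pop: DHPopulation) -> None:
    if pop.genotypes.has_missing:
        raise TriepistasisError("marker selection needs imputed (complete) genotypes")


def _additive_candidates(
    pop: DHPopulation, marker_ids: Iterable[str]
) -> dict[TermDescriptor, np.ndarray]:
    cands = {}
    for mid in marker_ids:
        col = pop.marker_column(mid)
        if np.ptp(col) == 0.0:
            continue  # zero-variance marker carries no signal
        cands[TermDescriptor(1, (mid,))] = col
    return cands


def stage1_chromosome_select(
    pop: DHPopulation, y: TraitVector, trace: StepwiseTrace | None = None
) -> dict[str, list[str]]:
    """Stage 1: per-chromosome bidirectional stepwise AIC over additive terms,
    from the intercept-only model.  Returns surviving marker ids per
    chromosome (possibly empty)."""
    _require_complete(pop)
    base = np.ones((pop.n_lines, 1))
    survivors: dict[str, list[str]] = {}
    for chrom, cols in pop.map.chromosome_indices().items():
        ids = [pop.map.marker_ids[j] for j in cols]
        cands = _additive_candidates(pop, ids)
        chosen = _stepwise(y.y, base, cands, trace=trace)
        survivors[chrom] = sorted(
            (t.marker_ids[0] for t in chosen), key=pop.map.index_of
        )
    return survivors


def stage2_combined_select(
    pop: DHPopulation,
    y: TraitVector,
    stage1_survivors: dict[str, list[str]],
    trace: StepwiseTrace | None = None,
) -> list[str]:
    """Stage 2: pooled bidirectional stepwise AIC over all stage-1 survivors,
    additive terms only; the result defines the p markers of the model."""
    _require_complete(pop)
    pool = [m for chrom in stage1_survivors.values() for m in chrom]
    if not pool:
        return []
    base = np.ones((pop.n_lines, 1))
    cands = _additive_candidates(pop, pool)
    chosen = _stepwise(y.y, base, cands, trace=trace)
    return sorted((t.marker_ids[0] for t in chosen), key=pop.map.index_of)


def stage3_interaction_select(
    design: ModelDesign,
    y: TraitVector | np.ndarray,
    max_params: int | None = None,
    trace: StepwiseTrace | None = None,
) -> tuple[ModelDesign, int]:
    """Stage 3: the final feature selection on the model with the epistatic
    terms included — the same bidirectional from-intercept stepwise AIC
    search as the earlier stages, now over the additive terms of the
    selected markers together with the pairwise and triple product
    candidates.  Returns the pruned design and the number of interaction
    candidates scored (the Bonferroni family size under the default
    correction scope).

    Letting the additive terms compete alongside the products (rather than
    freezing them) matters statistically: markers admitted in stage 2
    partly on a chance correlation with an epistatic signal lose their
    apparent effect once the product term is in the model, and the search
    then discards them instead of letting them drain the interaction
    coefficient.

    With no interaction candidates (fewer than two product markers) the
    design is returned unchanged — the additive selection is already final.
    ``max_params`` caps the total number of fitted parameters (default
    n - 10, preserving residual degrees of freedom)."""
    yv = np.asarray(getattr(y, "y", y), dtype=float).ravel()
    n = design.n
    p = len(design.selected_markers)
    if max_params is None:
        max_params = max(n - 10, p + 2)
    if max_params < p + 1:
        raise ConfigurationError(
            f"max_params={max_params} cannot hold the additive model (p={p})"
        )
    inter = [t for t in design.terms if t.order >= 2]
    if not inter:
        return design, 0
    col_of = {t: design.matrix[:, 1 + i] for i, t in enumerate(design.terms)}
    base = np.ones((n, 1))
    chosen = _stepwise(yv, base, dict(col_of), max_columns=max_params, trace=trace)
    kept = [t for t in design.terms if t in chosen]
    cols = [np.ones(n)] + [col_of[t] for t in kept]
    pruned = ModelDesign(design.selected_markers, tuple(kept), np.column_stack(cols))
    return pruned, len(inter)


# ---------------------------------------------------------------------------
# total aaa and the analytical contrast


@dataclass
class GenotypicEstimate:
    """Total aaa effect from the fitted marker regression.

    ``aaa_g`` is the sum of all retained triple-term coefficients; a triple
    is flagged significant when its p-value clears alpha / m_tests.
    ``ns_flag`` is set when no triple is significant (reported "NS")."""

    aaa_g: float
    per_triple: list[tuple[TermDescriptor, float, float, bool]]
    n_markers_included: int
    n_significant_aaa: int
    ns_flag: bool
    alpha: float
    m_tests: int


def total_aaa_genotypic(
    fit: FitResult,
    alpha: float = 0.05,
    m_tests: int | None = None,
    n_markers_included: int | None = None,
) -> GenotypicEstimate:
    """Sum the fitted triple (aaa) coefficients and apply the Bonferroni
    correction at per-test level alpha / m_tests.

    ``m_tests`` defaults to the number of interaction (pairwise + triple)
    terms in the fitted model; the selection pipeline passes the number of
    candidates it scored instead, which accounts for the stepwise search
    (see docs/methods.md).  nan p-values (saturated fits) never count as
    significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    triples = fit.triples()
    if m_tests is None:
        m_tests = fit.n_interaction_terms()
    m_eff = max(m_tests, 1)
    per_triple = [
        (t, est, p, bool(np.isfinite(p) and p < alpha / m_eff)) for t, est, p in triples
    ]
    n_sig = sum(1 for *_, sig in per_triple if sig)
    if n_markers_included is None:
        n_markers_included = len({m for t, *_ in per_triple for m in t.marker_ids}) or sum(
            1 for t in fit.terms if t is not None and t.order == 1
        )
    return GenotypicEstimate(
        aaa_g=float(sum(est for _, est, _, _ in per_triple)),
        per_triple=per_triple,
        n_markers_included=n_markers_included,
        n_significant_aaa=n_sig,
        ns_flag=n_sig == 0,
        alpha=alpha,
        m_tests=m_tests,
    )


@dataclass
class ContrastEstimate:
    """Balanced-design group-mean contrast for a set of marker triples.

    Under unlinked markers with exact 1:1 segregation the marker-regression
    total can be written per triple from the means of the lines carrying
    all three markers +1 (y_plus) and all three -1 (y_minus).  The
    symmetric form (y_plus + y_minus)/2 - y_all is reported as stated;
    the half-difference (y_plus - y_minus)/2 is available as a diagnostic.
    """

    per_triple: list[tuple[TermDescriptor, float, float]]  # (term, symmetric, difference)
    total_symmetric: float
    total_difference: float


def contrast_aaa(
    pop: DHPopulation,
    y: TraitVector | np.ndarray,
    triples: Sequence[TermDescriptor],
    tol: float = 1e-9,
) -> ContrastEstimate:
    """Evaluate the group-mean contrast for each triple.

    Lines enter the (+) group when all three markers are +1 and the (-)
    group when all three are -1 (within ``tol``; imputed fractional calls
    belong to neither group).  An empty group is an error naming the triple.
    """
    yv = np.asarray(getattr(y, "y", y), dtype=float).ravel()
    y_all = float(np.mean(yv))
    rows: list[tuple[TermDescriptor, float, float]] = []
    for t in triples:
        if t.order != 3:
            raise ConfigurationError(f"contrast needs triples, got {t.name}")
        cols = np.column_stack([pop.marker_column(m) for m in t.marker_ids])
        plus = np.all(np.abs(cols - 1.0) <= tol, axis=1)
        minus = np.all(np.abs(cols + 1.0) <= tol, axis=1)
        if not plus.any() or not minus.any():
            raise TriepistasisError(
                f"contrast for {t.name}: no line with all three markers "
                f"{'+1' if not plus.any() else '-1'}"
            )
        y_plus = float(np.mean(yv[plus]))
        y_minus = float(np.mean(yv[minus]))
        rows.append(
            (t, 0.5 * (y_plus + y_minus) - y_all, 0.5 * (y_plus - y_minus))
        )
    return ContrastEstimate(
        per_triple=rows,
        total_symmetric=float(sum(s for _, s, _ in rows)),
        total_difference=float(sum(d for _, _, d in rows)),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class GenotypicRun:
    """Everything produced by one genotypic analysis of one trait."""

    estimate: GenotypicEstimate
    fit: FitResult
    design: ModelDesign
    selected_markers: list[str]
    stage1_survivors: dict[str, list[str]]
    trace: StepwiseTrace


def significant_additive_markers(
    pop: DHPopulation, y: TraitVector, selected: Sequence[str], alpha: float = 0.05
) -> list[str]:
    """Markers whose additive coefficient is significant in the joint
    additive model on the selected markers, Bonferroni-corrected over the
    p markers tested (per-test level alpha / p).

    Epistatic terms are assumed to involve only such loci; correcting the
    screen keeps AIC-admitted noise markers (whose partial effects are
    null) from inflating the interaction candidate pool."""
    if not selected:
        return []
    additive = build_design(pop, selected, include_pairwise=False, include_triple=False)
    fit = fit_ols(additive, y)
    level = alpha / max(len(selected), 1)
    sig = [
        t.marker_ids[0]
        for i, t in enumerate(fit.terms)
        if t is not None and np.isfinite(fit.p_values[i]) and fit.p_values[i] < level
    ]
    return sorted(sig, key=pop.map.index_of)


def estimate_aaa_genotypic(
    pop: DHPopulation,
    y: TraitVector,
    alpha: float = 0.05,
    max_params: int | None = None,
    bonferroni_scope: str = "candidates",
    additive_alpha: float | None = 0.05,
) -> GenotypicRun:
    """Run the full three-stage pipeline on one (imputed) trait.

    ``bonferroni_scope`` chooses the correction family: ``"candidates"``
    (default) divides alpha by the number of interaction terms scored in
    stage 3, accounting for the stepwise search; ``"model"`` divides by the
    interaction terms in the final model only.

    ``additive_alpha`` is the significance level of the additive screen
    restricting the product-term pool (pairwise/triple terms are formed
    only among markers with significant additive effects in the stage-2
    model); ``None`` disables the screen and forms products among all
    selected markers.
    """
    if bonferroni_scope not in ("candidates", "model"):
        raise ConfigurationError(f"unknown bonferroni_scope {bonferroni_scope!r}")
    trace = StepwiseTrace()
    s1 = stage1_chromosome_select(pop, y, trace=trace)
    selected = stage2_combined_select(pop, y, s1, trace=trace)
    if additive_alpha is None:
        prod = list(selected)
    else:
        prod = significant_additive_markers(pop, y, selected, alpha=additive_alpha)
    design = build_design(pop, selected, product_markers=prod)
    pruned, n_scored = stage3_interaction_select(design, y, max_params=max_params, trace=trace)
    fit = fit_ols(pruned, y)
    m = n_scored if bonferroni_scope == "candidates" else None
    estimate = total_aaa_genotypic(
        fit, alpha=alpha, m_tests=m, n_markers_included=len(selected)
    )
    return GenotypicRun(
        estimate=estimate,
        fit=fit,
        design=pruned,
        selected_markers=list(selected),
        stage1_survivors=s1,
        trace=trace,
    )
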