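"""Batch comparison of the phenotypic and genotypic total-aaa estimators.

Each trait x environment set is analysed independently: preprocessing
(optional angular transform, flanking imputation, segregation report),
then the extreme-group phenotypic estimate and the three-stage
marker-regression genotypic estimate, paired into a
:class:`ComparisonRecord` with the relative ratio (aaa_g / aaa_p) * 100.
A failure in one trait is captured on its record and never aborts the
batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import DHPopulation
from .errors import ConfigurationError, TriepistasisError
from .geno import GenotypicRun, estimate_aaa_genotypic
from .pheno import PhenotypicEstimate, estimate_aaa_phenotypic
from .preprocess import preprocess_population, segregation_report_frame

__all__ = ["CompareConfig", "ComparisonRecord", "run_comparison", "summarize", "export_tables"]

log = logging.getLogger("triepistasis")


@dataclass
class CompareConfig:
    extreme_fraction: float = 0.05
    alpha: float = 0.05
    transform_traits: frozenset[str] = frozenset()
    exclude_distorted: bool = False
    segregation_alpha: float = 0.05
    max_params: int | None = None
    bonferroni_scope: str = "candidates"
    additive_alpha: float | None = 0.05
    report_difference_contrast: bool = False


@dataclass
class ComparisonRecord:
    """Paired phenotypic/genotypic totals for one trait x environment."""

    trait_id: str
    environment_id: str
    aaa_p: float | None = None
    aaa_g: float | None = None
    ratio_percent: float | None = None
    ns_flag: bool = False
    n_effective_factors: int | None = None
    n_markers_included: int | None = None
    n_significant_aaa: int | None = None
    error: str | None = None
    phenotypic: PhenotypicEstimate | None = None
    genotypic: GenotypicRun | None = None

    @property
    def label(self) -> str:
        return f"{self.trait_id}:{self.environment_id}"


def run_comparison(
    pop: DHPopulation,
    config: CompareConfig | None = None,
    segregation_out: list | None = None,
) -> list[ComparisonRecord]:
    """Analyse every trait of the population independently.

    If ``segregation_out`` is a list, the segregation report DataFrame is
    appended to it (for export alongside the result tables).
    """
    config = config or CompareConfig()
    if not pop.traits:
        raise ConfigurationError("population has no traits to analyse")
    clean, seg = preprocess_population(
        pop,
        transform_traits=set(config.transform_traits),
        exclude_distorted=config.exclude_distorted,
        segregation_alpha=config.segregation_alpha,
    )
    records: list[ComparisonRecord] = []
    for t in clean.traits:
        rec = ComparisonRecord(t.trait_id, t.environment_id)
        try:
            ph = estimate_aaa_phenotypic(t, fraction=config.extreme_fraction)
            rec.phenotypic = ph
            rec.aaa_p = ph.aaa_p
            rec.n_effective_factors = ph.n_effective_factors
            run = estimate_aaa_genotypic(
                clean,
                t,
                alpha=config.alpha,
                max_params=config.max_params,
                bonferroni_scope=config.bonferroni_scope,
                additive_alpha=config.additive_alpha,
            )
            rec.genotypic = run
            rec.aaa_g = run.estimate.aaa_g
            rec.ns_flag = run.estimate.ns_flag
            rec.n_markers_included = run.estimate.n_markers_included
            rec.n_significant_aaa = run.estimate.n_significant_aaa
            if rec.aaa_p != 0.0 and not rec.ns_flag:
                rec.ratio_percent = rec.aaa_g / rec.aaa_p * 100.0
            log.info(
                "%s: aaa_p=%.4g aaa_g=%s (markers=%s, significant aaa=%s)",
                rec.label,
                rec.aaa_p,
                "NS" if rec.ns_flag else f"{rec.aaa_g:.4g}",
                rec.n_markers_included,
                rec.n_significant_aaa,
            )
        except TriepistasisError as exc:
            rec.error = f"{type(exc).__name__}: {exc}"
            log.warning("%s: analysis failed (%s)", rec.label, rec.error)
        records.append(rec)
    if segregation_out is not None:
        segregation_out.append(segregation_report_frame(seg, alpha=config.segregation_alpha))
    return records


def _quartiles(values: list[float]) -> dict[str, float]:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(min(values)),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "max": float(max(values)),
        "n": len(values),
    }


def summarize(records: list[ComparisonRecord]) -> dict:
    """Batch summary: how often the genotypic total is the smaller one,
    significance counts, and per-trait ratio quartiles (box-plot data)."""
    if not records:
        raise ConfigurationError("no records to summarize")
    ok = [r for r in records if r.error is None]
    defined = [r for r in ok if r.ratio_percent is not None]
    n_def = len(defined)
    smaller_mag = sum(1 for r in defined if abs(r.aaa_g) < abs(r.aaa_p))
    smaller_signed = sum(1 for r in defined if r.aaa_g < r.aaa_p)
    ratios_by_trait: dict[str, list[float]] = {}
    for r in defined:
        ratios_by_trait.setdefault(r.trait_id, []).append(r.ratio_percent)
    all_ratios = [r.ratio_percent for r in defined]
    return {
        "n_records": len(records),
        "n_failed": len(records) - len(ok),
        "n_defined_pairs": n_def,
        "n_significant": sum(1 for r in ok if r.n_significant_aaa),
        "frac_genotypic_smaller_magnitude": smaller_mag / n_def if n_def else None,
        "frac_genotypic_smaller_signed": smaller_signed / n_def if n_def else None,
        "ratio_percent_overall": _quartiles(all_ratios) if all_ratios else None,
        "ratio_percent_by_trait": {
            trait: _quartiles(vals) for trait, vals in sorted(ratios_by_trait.items())
        },
        "ratio_percent_extremes": (
            {"min": float(min(all_ratios)), "max": float(max(all_ratios))}
            if all_ratios
            else None
        ),
    }


def _fmt(v, nd=6):
    if v is None:
        return "-"
    return f"{v:.{nd}g}"


def export_tables(
    records: list[ComparisonRecord],
    summary: dict,
    out_dir: str | Path,
    metadata: dict | None = None,
    segregation_report: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the phenotypic, genotypic and ratio tables plus run metadata.

    Genotypic totals of records without a significant triple are printed as
    the literal ``NS``; the included-markers / significant-aaa pair is kept
    in the classical ``(x | y)`` annotation.  Output is deterministic: same
    records, same bytes.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise TriepistasisError(f"cannot create output directory {out}: {exc}") from None

    pheno_rows, geno_rows, ratio_rows = [], [], []
    for r in records:
        base = {"trait": r.trait_id, "environment": r.environment_id}
        if r.error is not None:
            pheno_rows.append({**base, "aaa_p": "ERROR", "error": r.error})
            geno_rows.append({**base, "aaa_g": "ERROR", "error": r.error})
            continue
        ph = r.phenotypic
        pheno_rows.append(
            {
                **base,
                "aaa_p": _fmt(r.aaa_p),
                "mean_min": _fmt(ph.groups.mean_min),
                "mean_max": _fmt(ph.groups.mean_max),
                "mean_all": _fmt(ph.mean_all),
                "group_size": len(ph.groups.min_line_ids),
                "n_effective_factors": r.n_effective_factors,
                "error": "",
            }
        )
        geno_rows.append(
            {
                **base,
                "aaa_g": "NS" if r.ns_flag else _fmt(r.aaa_g),
                "annotation": f"({r.n_markers_included} | {r.n_significant_aaa})",
                "error": "",
            }
        )
        ratio_rows.append(
            {
                **base,
                "aaa_p": _fmt(r.aaa_p),
                "aaa_g": "NS" if r.ns_flag else _fmt(r.aaa_g),
                "ratio_percent": _fmt(r.ratio_percent),
            }
        )

    paths = {
        "phenotypic": out / "phenotypic_estimates.tsv",
        "genotypic": out / "genotypic_estimates.tsv",
        "ratios": out / "ratio_percent.tsv",
        "metadata": out / "run_metadata.json",
    }
    pd.DataFrame(pheno_rows).to_csv(paths["phenotypic"], sep="\t", index=False)
    pd.DataFrame(geno_rows).to_csv(paths["genotypic"], sep="\t", index=False)
    pd.DataFrame(ratio_rows).to_csv(paths["ratios"], sep="\t", index=False)
    if segregation_report is not None:
        paths["segregation"] = out / "segregation_report.tsv"
        segregation_report.to_csv(paths["segregation"], sep="\t", index=False)

    detail_rows = []
    for r in records:
        if r.genotypic is None:
            continue
        for t, est, p, sig in r.genotypic.estimate.per_triple:
            detail_rows.append(
                {
                    "trait": r.trait_id,
                    "environment": r.environment_id,
                    "markers": ",".join(t.marker_ids),
                    "estimate": _fmt(est, 9),
                    "p_value": _fmt(p, 6),
                    "significant": sig,
                }
            )
    paths["triples"] = out / "aaa_triples.tsv"
    pd.DataFrame(
        detail_rows,
        columns=["trait", "environment", "markers", "estimate", "p_value", "significant"],
    ).to_csv(paths["triples"], sep="\t", index=False)

    meta = {"package_version": __version__, "summary": summary}
    if metadata:
        meta["run"] = metadata
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths
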