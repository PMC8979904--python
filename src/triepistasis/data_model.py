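"""Core data containers and table I/O for DH marker–map–phenotype data.

A doubled-haploid (DH) population is represented by three aligned pieces:

* a :class:`LinkageMap` — ordered markers with chromosome and cM position,
* a :class:`MarkerMatrix` — lines x markers genotype array coded -1/+1
  (``nan`` for missing; fractional values in [-1, 1] after imputation),
* a collection of :class:`TraitVector` — one phenotype vector per
  trait x environment combination, aligned to the marker-matrix lines.

On disk the three tables are plain TSV/CSV with header rows; the delimiter
is inferred from the file extension (``.tsv`` tab, anything else comma).
Phenotype columns are named ``trait`` or ``trait:environment``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, CodingError, ParseError, TriepistasisError

__all__ = [
    "LinkageMap",
    "MarkerMatrix",
    "TraitVector",
    "DHPopulation",
    "read_population",
    "write_population",
    "validate_coding",
]

#: strings accepted as missing genotype codes in input files
MISSING_CODES = {"", "na", "nan", ".", "-"}


def _delim(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() == ".tsv" else ","


@dataclass(frozen=True)
class LinkageMap:
    """Ordered linkage map: (marker_id, chromosome, position in cM)."""

    markers: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate marker ids in map: {dup}")
        for _, chrom, pos in self.markers:
            if not math.isfinite(pos) or pos < 0:
                raise ParseError(f"map position must be finite and >= 0 on {chrom}, got {pos}")
        last: dict[str, float] = {}
        for mid, chrom, pos in self.markers:
            if chrom in last and pos < last[chrom]:
                raise ParseError(
                    f"map positions decrease within chromosome {chrom} at marker {mid}"
                )
            last[chrom] = pos

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.markers)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for _, chrom, _ in self.markers:
            seen.setdefault(chrom)
        return tuple(seen)

    def index_of(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise AlignmentError(f"marker {marker_id!r} not on the map") from None

    def chromosome_of(self, marker_id: str) -> str:
        return self.markers[self.index_of(marker_id)][1]

    def position_of(self, marker_id: str) -> float:
        return self.markers[self.index_of(marker_id)][2]

    def chromosome_indices(self) -> dict[str, list[int]]:
        """Column indices grouped per chromosome, in map order."""
        out: dict[str, list[int]] = {}
        for j, (_, chrom, _) in enumerate(self.markers):
            out.setdefault(chrom, []).append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.markers, columns=["marker", "chromosome", "position_cM"])


@dataclass
class MarkerMatrix:
    """n lines x q markers genotype array; nan marks missing."""

    lines: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lines = tuple(str(s) for s in self.lines)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CodingError("genotype values must be a 2-D array")
        n, q = self.values.shape
        if n != len(self.lines):
            raise AlignmentError(
                f"{len(self.lines)} line ids but {n} genotype rows"
            )
        if n < 2 or q < 1:
            raise TriepistasisError(f"need >= 2 lines and >= 1 marker, got {n} x {q}")
        if len(set(self.lines)) != n:
            raise AlignmentError("duplicate line ids in genotype table")
        bad = np.isfinite(self.values) & (np.abs(self.values) > 1 + 1e-12)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise CodingError(
                f"genotype value {self.values[i, j]} outside [-1, 1] "
                f"(line {self.lines[i]!r}, marker column {j})"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def require_integer_coding(self, marker_ids: Sequence[str] | None = None) -> None:
        """Reject entries other than -1/+1/missing (pre-imputation contract)."""
        obs = self.values[np.isfinite(self.values)]
        if obs.size and not np.all(np.isin(obs, (-1.0, 1.0))):
            bad = np.isfinite(self.values) & ~np.isin(self.values, (-1.0, 1.0))
            i, j = map(int, np.argwhere(bad)[0])
            name = marker_ids[j] if marker_ids is not None else f"column {j}"
            raise CodingError(
                f"genotype value {self.values[i, j]} is not -1/+1 "
                f"(line {self.lines[i]!r}, marker {name})"
            )


@dataclass
class TraitVector:
    """Phenotypic means of one trait in one environment, aligned to lines."""

    trait_id: str
    environment_id: str
    y: np.ndarray
    transform_applied: str = "none"
    lines: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise TriepistasisError(
                f"trait {self.label}: non-finite phenotype values present"
            )
        if self.lines is not None:
            self.lines = tuple(str(s) for s in self.lines)
            if len(self.lines) != self.y.size:
                raise AlignmentError(f"trait {self.label}: line ids do not match values")

    @property
    def label(self) -> str:
        return f"{self.trait_id}:{self.environment_id}"

    @property
    def n(self) -> int:
        return int(self.y.size)


@dataclass
class DHPopulation:
    """A linkage map, genotype matrix and trait vectors sharing one line set."""

    map: LinkageMap
    genotypes: MarkerMatrix
    traits: list[TraitVector] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotypes.n_markers != len(self.map.markers):
            raise AlignmentError(
                f"{self.genotypes.n_markers} genotype columns vs "
                f"{len(self.map.markers)} map markers"
            )
        for t in self.traits:
            if t.n != self.genotypes.n_lines:
                raise AlignmentError(
                    f"trait {t.label} has {t.n} values for {self.genotypes.n_lines} lines"
                )

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_lines

    @property
    def n_markers(self) -> int:
        return self.genotypes.n_markers

    def marker_column(self, marker_id: str) -> np.ndarray:
        return self.genotypes.values[:, self.map.index_of(marker_id)]

    def with_genotypes(self, values: np.ndarray) -> "DHPopulation":
        return DHPopulation(
            map=self.map,
            genotypes=MarkerMatrix(self.genotypes.lines, values),
            traits=list(self.traits),
        )


def _parse_genotype_cell(raw: object, path: Path, line_id: str, marker: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip()
    if text.lower() in MISSING_CODES:
        return math.nan
    try:
        val = float(text)
    except ValueError:
        raise CodingError(
            f"{path}: genotype value {text!r} (line {line_id!r}, marker {marker!r}) "
            "is not -1, 1 or a missing code"
        ) from None
    # fractional values in (-1, 1) are accepted so imputed tables round-trip
    if abs(val) > 1.0:
        raise CodingError(
            f"{path}: genotype value {text!r} (line {line_id!r}, marker {marker!r}) "
            "is outside [-1, 1] and not a missing code"
        )
    return val


def _read_table(path: Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=_delim(path), dtype=str, **kw)
    except FileNotFoundError:
        raise ParseError(f"{path}: file not found") from None
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise ParseError(f"{path}: could not parse table ({exc})") from None


def _split_trait_column(name: str) -> tuple[str, str]:
    if ":" in name:
        trait, env = name.split(":", 1)
        return trait, env
    return name, "-"


def read_population(
    genotype_path: str | Path,
    map_path: str | Path,
    phenotype_path: str | Path | None = None,
) -> DHPopulation:
    """Read and cross-validate the genotype, map and phenotype tables.

    The genotype table is a line x marker matrix whose header row holds
    marker ids (first column: line id).  The map table has columns
    ``marker``, ``chromosome``, ``position_cM``.  The phenotype table has a
    line-id column plus one column per trait x environment, named
    ``trait:environment``.  Phenotype rows are aligned to genotype rows by
    line id; the genotype file's row order is canonical.
    """
    genotype_path, map_path = Path(genotype_path), Path(map_path)

    map_df = _read_table(map_path)
    required = {"marker", "chromosome", "position_cM"}
    if not required.issubset(map_df.columns):
        raise ParseError(
            f"{map_path}: map needs columns {sorted(required)}, got {list(map_df.columns)}"
        )
    try:
        positions = map_df["position_cM"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{map_path}: non-numeric position_cM ({exc})") from None
    linkage = LinkageMap(
        tuple(zip(map_df["marker"].astype(str), map_df["chromosome"].astype(str), positions))
    )

    geno_df = _read_table(genotype_path)
    if geno_df.shape[1] < 2:
        raise ParseError(f"{genotype_path}: expected a line-id column plus marker columns")
    line_col = geno_df.columns[0]
    marker_ids = [str(c) for c in geno_df.columns[1:]]
    unknown = [m for m in marker_ids if m not in linkage.marker_ids]
    if unknown:
        raise AlignmentError(
            f"{genotype_path}: markers absent from the map: {unknown[:10]}"
        )
    if list(marker_ids) != list(linkage.marker_ids):
        # reorder genotype columns to map order; markers on the map but not
        # genotyped are an alignment error
        missing = [m for m in linkage.marker_ids if m not in marker_ids]
        if missing:
            raise AlignmentError(
                f"{genotype_path}: map markers missing from genotypes: {missing[:10]}"
            )
        geno_df = geno_df[[line_col, *linkage.marker_ids]]
        marker_ids = list(linkage.marker_ids)

    lines = tuple(geno_df[line_col].astype(str))
    values = np.empty((len(lines), len(marker_ids)))
    for j, marker in enumerate(marker_ids):
        col = geno_df.iloc[:, j + 1]
        for i, raw in enumerate(col):
            values[i, j] = _parse_genotype_cell(raw, genotype_path, lines[i], marker)
    genotypes = MarkerMatrix(lines, values)

    traits: list[TraitVector] = []
    if phenotype_path is not None:
        phenotype_path = Path(phenotype_path)
        pheno_df = _read_table(phenotype_path)
        if pheno_df.shape[1] < 1:
            raise ParseError(f"{phenotype_path}: empty phenotype table")
        pid = pheno_df.columns[0]
        pheno_lines = list(pheno_df[pid].astype(str))
        extra = sorted(set(pheno_lines) - set(lines))
        lacking = sorted(set(lines) - set(pheno_lines))
        if extra or lacking:
            raise AlignmentError(
                f"{phenotype_path}: line ids disagree with genotypes "
                f"(unknown: {extra[:10]}, missing: {lacking[:10]})"
            )
        pheno_df = pheno_df.set_index(pid).loc[list(lines)]
        for col in pheno_df.columns:
            trait, env = _split_trait_column(str(col))
            try:
                y = pheno_df[col].astype(float).to_numpy()
            except ValueError as exc:
                raise ParseError(
                    f"{phenotype_path}: non-numeric phenotype in column {col!r} ({exc})"
                ) from None
            traits.append(TraitVector(trait, env, y, lines=lines))

    return DHPopulation(map=linkage, genotypes=genotypes, traits=traits)


def write_population(pop: DHPopulation, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables in the formats accepted by :func:`read_population`.

    Integer-coded genotypes round-trip exactly; imputed fractional values are
    serialized at full (repr) precision.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise TriepistasisError(f"cannot create output directory {out}: {exc}") from None

    paths = {
        "genotypes": out / "genotypes.tsv",
        "map": out / "map.tsv",
        "phenotypes": out / "phenotypes.csv",
    }

    pop.map.to_frame().to_csv(paths["map"], sep="\t", index=False)

    def fmt(v: float) -> str:
        v = float(v)
        if math.isnan(v):
            return "NA"
        if v == int(v):
            return str(int(v))
        return repr(v)

    geno = pd.DataFrame(
        [[fmt(v) for v in row] for row in pop.genotypes.values],
        columns=list(pop.map.marker_ids),
    )
    geno.insert(0, "line", list(pop.genotypes.lines))
    geno.to_csv(paths["genotypes"], sep="\t", index=False)

    pheno = pd.DataFrame({"line": list(pop.genotypes.lines)})
    for t in pop.traits:
        pheno[t.label if t.environment_id != "-" else t.trait_id] = [repr(float(v)) for v in t.y]
    pheno.to_csv(paths["phenotypes"], sep=",", index=False)
    return paths


def validate_coding(g: MarkerMatrix, marker_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-marker counts of +1/-1/missing with a zero-variance flag.

    Purely a reporting operation; never raises on odd data.
    """
    v = g.values
    n_plus = (v == 1.0).sum(axis=0)
    n_minus = (v == -1.0).sum(axis=0)
    n_missing = np.isnan(v).sum(axis=0)
    with np.errstate(invalid="ignore"):
        zero_var = np.array(
            [np.unique(col[np.isfinite(col)]).size <= 1 for col in v.T]
        )
    ids = list(marker_ids) if marker_ids is not None else [f"col{j}" for j in range(v.shape[1])]
    return pd.DataFrame(
        {
            "marker": ids,
            "n_plus": n_plus.astype(int),
            "n_minus": n_minus.astype(int),
            "n_missing": n_missing.astype(int),
            "zero_variance": zero_var,
        }
    )
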