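"""Readers, writers and validated containers for every table the pipeline touches.

Native dialect is tab-separated UTF-8 with a header row; lines starting with
``#`` are ignored on read and used for provenance on write.  Readers never
silently drop rows — every rejection raises with the offending location.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import GENOTYPE_LEVELS, GROUP_ORDER, TREATMENT_LEVELS

logger = logging.getLogger(__name__)

ID_COL = "protein_id"
SYMBOL_COL = "gene_symbol"
COUNT_COLUMNS = (ID_COL, SYMBOL_COL, *GROUP_ORDER)


class SchemaError(ValueError):
    """A table violates its declared schema (missing/duplicate/ill-typed field)."""


@dataclass
class SpectralCountTable:
    """Protein x four-group spectral-count matrix.

    ``data`` columns: ``protein_id`` (unique), ``gene_symbol``, and the four
    group columns in canonical order.  Counts are non-negative; zeros are
    permitted (they exercise the normalization floor downstream).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"count table missing columns: {missing}")
        self.data = df = df.loc[:, list(COUNT_COLUMNS)].reset_index(drop=True)
        dup = df[ID_COL][df[ID_COL].duplicated()]
        if len(dup):
            raise SchemaError(
                f"duplicate protein identifiers: {sorted(set(dup.astype(str)))}"
            )
        counts = df[list(GROUP_ORDER)].to_numpy()
        if not np.issubdtype(counts.dtype, np.number):
            raise SchemaError("non-numeric count values present")
        if not np.isfinite(counts).all():
            bad = df[ID_COL][~np.isfinite(counts).all(axis=1)].tolist()
            raise SchemaError(f"non-finite counts for proteins: {bad}")
        if (counts < 0).any():
            bad = df[ID_COL][(counts < 0).any(axis=1)].tolist()
            raise SchemaError(f"negative counts for proteins: {bad}")

    @property
    def n_proteins(self) -> int:
        return len(self.data)

    @property
    def protein_ids(self) -> pd.Series:
        return self.data[ID_COL]

    @property
    def gene_symbols(self) -> pd.Series:
        return self.data[SYMBOL_COL]

    def counts(self) -> np.ndarray:
        """Return the n x 4 count matrix in canonical group order."""
        return self.data[list(GROUP_ORDER)].to_numpy(dtype=float)

    def subset(self, mask_or_ids) -> "SpectralCountTable":
        """Row subset preserving input order."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            np.asarray(mask_or_ids).dtype == bool
        ):
            sub = self.data[np.asarray(mask_or_ids)]
        else:
            keep = set(mask_or_ids)
            sub = self.data[self.data[ID_COL].isin(keep)]
        return SpectralCountTable(sub.reset_index(drop=True))


@dataclass
class AnnotationMap:
    """Flat term -> gene-symbol sets (no ontology graph propagation).

    Gene matching is case-insensitive (Vil1 vs VIL1); symbols are stored as
    given but compared lowercased.
    """

    terms: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not term:
                raise SchemaError("empty term name in annotation map")
            if not genes:
                raise SchemaError(f"term {term!r} annotates no genes")
            if any((not isinstance(g, str)) or (not g) for g in genes):
                raise SchemaError(f"term {term!r} contains an empty gene symbol")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def genes(self, term: str) -> frozenset:
        if term not in self.terms:
            raise KeyError(f"unknown annotation term: {term!r}")
        return self.terms[term]

    def genes_lower(self, term: str) -> frozenset:
        return frozenset(g.lower() for g in self.genes(term))


def _read_tsv(path, sep: str = "\t") -> pd.DataFrame:
    # keep_default_na=False: the category/label value "null" is data, not NA
    df = pd.read_csv(
        path, sep=sep, comment="#", dtype=str, keep_default_na=False, na_values=[""]
    )
    if df.empty and df.columns.empty:
        raise SchemaError(f"empty file: {path}")
    return df


def read_count_table(
    path,
    sep: str = "\t",
    column_map: dict[str, str] | None = None,
) -> SpectralCountTable:
    """Read a spectral-count TSV into a validated :class:`SpectralCountTable`.

    Parameters
    ----------
    column_map
        Optional mapping from canonical column names (``protein_id``,
        ``gene_symbol``, ``ctrl_vehicle``, ...) to the file's header names,
        so any export layout of a four-group count table can be adapted
        without code changes.
    """
    raw = _read_tsv(path, sep=sep)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in rename if src not in raw.columns]
        if missing:
            raise SchemaError(f"column_map names absent from {path}: {missing}")
        raw = raw.rename(columns=rename)
    missing = [c for c in COUNT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; header was {list(raw.columns)}"
        )
    df = raw.loc[:, list(COUNT_COLUMNS)].copy()
    for col in GROUP_ORDER:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            lineno = bad.index[0] + 2  # +1 header, +1 zero-based
            raise SchemaError(
                f"{path}: non-numeric count in column {col!r} near line {lineno}"
            ) from exc
    table = SpectralCountTable(df)
    logger.info("read %d proteins from %s", table.n_proteins, path)
    return table


def write_count_table(table: SpectralCountTable, path, comments: list[str] | None = None) -> None:
    _write_with_comments(table.data, path, comments)


def read_annotation(path, sep: str = "\t") -> AnnotationMap:
    """Read a two-column term<TAB>gene file, aggregating genes into sets."""
    df = _read_tsv(path, sep=sep)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: annotation file needs two columns (term, gene)")
    term_col, gene_col = df.columns[:2]
    if df.empty:
        raise SchemaError(f"{path}: annotation file has no rows")
    terms: dict[str, set] = {}
    for term, gene in zip(df[term_col], df[gene_col]):
        terms.setdefault(str(term), set()).add(str(gene))
    return AnnotationMap({t: frozenset(g) for t, g in terms.items()})


def write_annotation(annotation: AnnotationMap, path, comments: list[str] | None = None) -> None:
    rows = [
        {"term": term, "gene": gene}
        for term in sorted(annotation.terms)
        for gene in sorted(annotation.terms[term])
    ]
    _write_with_comments(pd.DataFrame(rows, columns=["term", "gene"]), path, comments)


@dataclass
class MeasurementTable:
    """Per-mouse measurements in the 2x2 design (genotype x treatment)."""

    data: pd.DataFrame
    unit: str = ""

    REQUIRED = ("mouse_id", "genotype", "treatment", "value")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"measurement table missing columns: {missing}")
        bad_geno = set(df["genotype"]) - set(GENOTYPE_LEVELS)
        if bad_geno:
            raise SchemaError(f"unknown genotype levels: {sorted(bad_geno)}")
        bad_trt = set(df["treatment"]) - set(TREATMENT_LEVELS)
        if bad_trt:
            raise SchemaError(f"unknown treatment levels: {sorted(bad_trt)}")
        values = pd.to_numeric(df["value"])
        if not np.isfinite(values).all():
            raise SchemaError("non-finite measurement values")
        self.data = df.assign(value=values).reset_index(drop=True)


def read_measurements(path, sep: str = "\t", unit: str = "") -> MeasurementTable:
    return MeasurementTable(_read_tsv(path, sep=sep), unit=unit)


def write_measurements(table: MeasurementTable, path, comments: list[str] | None = None) -> None:
    _write_with_comments(table.data, path, comments)


@dataclass
class CtTable:
    """qPCR cycle-threshold table: sample, group, target CT, reference CT."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"CT table missing columns: {missing}")
        for col in ("ct_target", "ct_reference"):
            vals = pd.to_numeric(df[col])
            if not np.isfinite(vals).all():
                bad = df["sample_id"][~np.isfinite(vals)].tolist()
                raise SchemaError(f"non-finite {col} for samples: {bad}")
            if ((vals < 10) | (vals > 40)).any():
                warnings.warn(
                    f"{col} outside the typical 10-40 cycle range", stacklevel=2
                )
            df = df.assign(**{col: vals})
        self.data = df.reset_index(drop=True)


def read_ct_table(path, sep: str = "\t") -> CtTable:
    return CtTable(_read_tsv(path, sep=sep))


def write_ct_table(table: CtTable, path, comments: list[str] | None = None) -> None:
    _write_with_comments(table.data, path, comments)


def write_results(results: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write a classification-result table (one row per protein)."""
    _write_with_comments(results, path, comments)


def write_enrichment(results: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    """Write an enrichment-result table (one row per term)."""
    _write_with_comments(results, path, comments)


def _write_with_comments(df: pd.DataFrame, path, comments: list[str] | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
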