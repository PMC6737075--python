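"""Hypergeometric term enrichment with Benjamini-Hochberg control.

Replaces an external ontology-enrichment web service with a transparent,
in-repo one-sided hypergeometric test.  The universe is the identified
proteome (every gene in the input count table), not the whole genome, and
annotation sets are intersected with the universe before testing.  Terms
with zero query overlap are untestable and excluded from both the output
and the multiple-testing family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AnnotationMap, SpectralCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment evidence on the identified-proteome universe."""

    term: str
    universe_size: int  # N
    term_size: int      # K (after intersection with the universe)
    query_size: int     # n
    overlap: int        # k
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.term_size, self.query_size):
            raise ValueError("overlap outside [0, min(K, n)]")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(
    query_genes,
    annotation: AnnotationMap,
    universe_genes,
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of every overlapping term.

    Gene matching is case-insensitive.  Results are sorted by adjusted p
    ascending, ties broken by term name.  ``adjust=False`` reports the raw p
    in the adjusted column (strict emulation of an uncorrected analysis).
    """
    universe = {g.lower() for g in universe_genes}
    if not universe:
        raise ValueError("empty universe")
    query = {g.lower() for g in query_genes}
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes absent from the universe: {stray}")

    N, n = len(universe), len(query)
    rows = []
    for term in sorted(annotation.terms):
        term_genes = annotation.genes_lower(term) & universe
        K = len(term_genes)
        k = len(term_genes & query)
        if k == 0:
            continue  # untestable: excluded from output and the BH family
        rows.append((term, N, K, n, k, hypergeom_upper_tail(N, K, n, k)))

    if not rows:
        return []
    raw_p = np.array([r[5] for r in rows])
    adj = bh_adjust(raw_p) if adjust else raw_p.copy()
    results = [
        EnrichmentResult(term, N, K, n, k, p, float(q))
        for (term, N, K, n, k, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term", "universe_size", "term_size", "query_size", "overlap", "p_value", "adjusted_p"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results], columns=cols)


def select_term_proteins(
    term: str,
    annotation: AnnotationMap,
    table: SpectralCountTable,
) -> SpectralCountTable:
    """Restrict a count table to proteins annotated to ``term`` (order kept)."""
    term_genes = annotation.genes_lower(term)  # raises KeyError on unknown term
    mask = table.gene_symbols.str.lower().isin(term_genes).to_numpy()
    if not mask.any():
        warnings.warn(f"term {term!r} covers no gene in the table", stacklevel=2)
    sub = SpectralCountTable(table.data[mask].reset_index(drop=True))
    logger.info("term %s selected %d of %d proteins", term, sub.n_proteins, table.n_proteins)
    return sub
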