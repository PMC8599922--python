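"""Padlock SNP-capture allelotyping.

Input is a long-format table of per-SNP allelic read counts (129 and cast
alleles) across samples. The pipeline zeroes under-detected counts,
requires detection in a configured sample set, aggregates counts per gene,
drops known escapees, and scores each gene with a pseudocounted log
allelic ratio:

    score = log_b((count_129 + pc) / (count_cast + pc))

with pseudocount ``pc`` = 10 and base 10 by default. Positive scores mean
129-allele bias (monoallelic 129 expression); zero means balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of the long-format SNP count table
SNP_COLUMNS = ("snp_id", "gene", "sample", "count_129", "count_cast")


def _check_matrix(matrix: pd.DataFrame) -> None:
    missing = [c for c in SNP_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"SNP count matrix missing columns: {missing}")
    for col in ("count_129", "count_cast"):
        if (matrix[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    genes_per_snp = matrix.groupby("snp_id")["gene"].nunique()
    multi = genes_per_snp[genes_per_snp > 1]
    if len(multi):
        raise ValueError(f"SNPs mapped to more than one gene: {list(multi.index[:5])}")


def filter_undetected(
    matrix: pd.DataFrame, min_reads: int = 10, per_allele: bool = True
) -> pd.DataFrame:
    """Zero out under-detected counts.

    A count below ``min_reads`` is considered undetected and set to 0
    (a count equal to ``min_reads`` is kept). By default the rule applies
    to each allele count separately; with ``per_allele=False`` it applies
    to the per-SNP total, zeroing both alleles together.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    _check_matrix(matrix)
    out = matrix.copy()
    if per_allele:
        for col in ("count_129", "count_cast"):
            out.loc[out[col] < min_reads, col] = 0
    else:
        low = (out["count_129"] + out["count_cast"]) < min_reads
        out.loc[low, ["count_129", "count_cast"]] = 0
    return out


def require_complete(matrix: pd.DataFrame, required_samples: Sequence[str]) -> pd.DataFrame:
    """Keep only SNPs detected (nonzero total) in every required sample.

    The matrix is expected to have passed :func:`filter_undetected`
    already; detection means a nonzero post-filter 129+cast total. A SNP
    with no row at all for a required sample counts as undetected.
    """
    _check_matrix(matrix)
    present = set(matrix["sample"].unique())
    unknown = [s for s in required_samples if s not in present]
    if unknown:
        raise ValueError(f"required samples absent from matrix: {unknown}")
    sub = matrix[matrix["sample"].isin(required_samples)]
    totals = (
        sub.assign(total=sub["count_129"] + sub["count_cast"])
        .pivot_table(index="snp_id", columns="sample", values="total", aggfunc="sum")
        .reindex(columns=list(required_samples))
    )
    ok = totals.notna().all(axis=1) & (totals > 0).all(axis=1)
    keep = set(totals.index[ok])
    return matrix[matrix["snp_id"].isin(keep)].copy()


def allelotype_score(
    count_129: float, count_cast: float, pseudocount: float = 10, log_base: float = 10
) -> float:
    """Pseudocounted log allelic ratio of a (129, cast) count pair."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log((count_129 + pseudocount) / (count_cast + pseudocount), log_base)


@dataclass(frozen=True)
class AllelotypeResult:
    """Gene x sample score matrix plus the aggregated counts behind it."""

    scores: pd.DataFrame  # genes x samples, ordered
    totals: pd.DataFrame  # long: gene, sample, total_129, total_cast, score
    pseudocount: float
    log_base: float


def gene_allelotype(
    matrix: pd.DataFrame,
    pseudocount: float = 10,
    log_base: float = 10,
    escapees: Iterable[str] = (),
    gene_positions: Mapping[str, tuple] | None = None,
) -> AllelotypeResult:
    """Aggregate SNP counts per gene and score the allelic ratio.

    Counts of all surviving SNPs of a gene are summed per sample before
    scoring. Genes on the escapee list are removed. ``gene_positions``
    maps gene -> (chrom, start) and fixes chromosomal row order; genes
    without a position sort last, alphabetically.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    _check_matrix(matrix)
    esc = set(escapees)
    removed = sorted(set(matrix["gene"].unique()) & esc)
    if removed:
        logger.info("removed %d escapee genes: %s", len(removed), removed)
    kept = matrix[~matrix["gene"].isin(esc)]
    totals = (
        kept.groupby(["gene", "sample"], as_index=False)[["count_129", "count_cast"]]
        .sum()
        .rename(columns={"count_129": "total_129", "count_cast": "total_cast"})
    )
    totals["score"] = [
        allelotype_score(r.total_129, r.total_cast, pseudocount, log_base)
        for r in totals.itertuples()
    ]
    wide = totals.pivot(index="gene", columns="sample", values="score")

    def sort_key(gene: str):
        if gene_positions and gene in gene_positions:
            chrom, start = gene_positions[gene]
            return (0, str(chrom), int(start), gene)
        return (1, "", 0, gene)

    wide = wide.reindex(sorted(wide.index, key=sort_key))
    return AllelotypeResult(scores=wide, totals=totals, pseudocount=pseudocount, log_base=log_base)
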