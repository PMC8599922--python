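"""ATAC insertion-site binning and chromatin-compaction scoring.

Each aligned read marks one transposon insertion site. The "cut count" of
a 1-Mb bin is the number of distinct insertion sites falling in it
(half-open, BED-style 0-based coordinates). Counts are depth-normalized
by the total number of uniquely aligned reads outside chrX, and the
compaction score of a bin is the regularized ratio

    (normalized uninduced + pc) / (normalized induced + pc)

so that loss of accessibility upon induction yields scores above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class InsertionSiteSet:
    """Insertion sites (chrom, 0-based position) with a depth-normalization total."""

    sites: pd.DataFrame  # columns chrom, pos
    total_autosomal_reads: int
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.total_autosomal_reads <= 0:
            raise ValueError("total_autosomal_reads must be > 0")
        missing = [c for c in ("chrom", "pos") if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")


@dataclass
class BinProfile:
    """Per-bin cut counts on a fixed grid covering every chromosome."""

    bins: pd.DataFrame  # columns chrom, bin_start, cut_count, normalized_cut_count
    bin_size: int = DEFAULT_BIN_SIZE

    def same_grid(self, other: "BinProfile") -> bool:
        if self.bin_size != other.bin_size or len(self.bins) != len(other.bins):
            return False
        a = self.bins[["chrom", "bin_start"]].reset_index(drop=True)
        b = other.bins[["chrom", "bin_start"]].reset_index(drop=True)
        return a.equals(b)


def normalization_factor(sample: InsertionSiteSet, reference_total: int) -> float:
    """Depth-normalization factor ``reference_total / total_autosomal_reads``."""
    if reference_total <= 0:
        raise ValueError("reference_total must be > 0")
    return reference_total / sample.total_autosomal_reads


def bin_cut_counts(
    sites: InsertionSiteSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    reference_total: int | None = None,
    distinct_sites: bool = True,
) -> BinProfile:
    """Count insertion sites per half-open bin of ``bin_size`` bp.

    A position at an exact bin boundary belongs to the bin starting there.
    ``distinct_sites`` counts each (chrom, position) once regardless of
    read multiplicity; set it False to count reads instead.
    ``reference_total`` defaults to the sample's own autosomal total
    (normalized == raw counts).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
    df = sites.sites
    for rec in df.itertuples():
        if rec.chrom not in chrom_sizes:
            raise ValueError(f"site on unknown chromosome: {rec.chrom}:{rec.pos}")
        if not (0 <= rec.pos < chrom_sizes[rec.chrom]):
            raise ValueError(
                f"site beyond chromosome length: {rec.chrom}:{rec.pos} "
                f"(size {chrom_sizes[rec.chrom]})"
            )
    if distinct_sites:
        df = df.drop_duplicates(subset=["chrom", "pos"])
    rows: List[Tuple[str, int, int]] = []
    counts = {
        (chrom, int(b)): n
        for (chrom, b), n in df.groupby(
            [df["chrom"], (df["pos"] // bin_size) * bin_size]
        ).size().items()
    }
    for chrom in chrom_sizes:
        for start in range(0, chrom_sizes[chrom], bin_size):
            rows.append((chrom, start, counts.get((chrom, start), 0)))
    out = pd.DataFrame(rows, columns=["chrom", "bin_start", "cut_count"])
    factor = 1.0 if reference_total is None else normalization_factor(sites, reference_total)
    out["normalized_cut_count"] = out["cut_count"] * factor
    return BinProfile(bins=out, bin_size=bin_size)


def compaction_score(
    uninduced: BinProfile, induced: BinProfile, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-bin compaction score, uninduced over induced.

    Both profiles must share the bin grid. Empty bins in both samples
    score exactly 1 by the pseudocount regularization.
    """
    if not uninduced.same_grid(induced):
        raise ValueError("bin grids differ between uninduced and induced profiles")
    out = uninduced.bins[["chrom", "bin_start"]].copy()
    u = uninduced.bins["normalized_cut_count"].to_numpy(float)
    i = induced.bins["normalized_cut_count"].to_numpy(float)
    out["uninduced"] = u
    out["induced"] = i
    out["compaction_score"] = (u + pseudocount) / (i + pseudocount)
    return out


def categorize_bins(
    profile: BinProfile,
    transcribed_regions: Sequence[Tuple[str, int, int]],
    cutoff: float = 0.5,
) -> pd.Series:
    """Label bins intergenic / transcribed / mixed by overlap fraction.

    ``transcribed_regions`` are half-open (chrom, start, end) intervals.
    A bin is "transcribed" when its overlap fraction is >= cutoff
    (inclusive), "intergenic" when <= 1 - cutoff, otherwise "mixed"
    (possible only when cutoff > 0.5).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in transcribed_regions:
        if end < start:
            raise ValueError(f"interval end before start: {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    # merge so overlapping inputs are not double counted
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        by_chrom[chrom] = merged
    labels = []
    size = profile.bin_size
    for rec in profile.bins.itertuples():
        b0, b1 = rec.bin_start, rec.bin_start + size
        ov = 0
        for s, e in by_chrom.get(rec.chrom, ()):
            if s >= b1:
                break
            ov += max(0, min(e, b1) - max(s, b0))
        frac = ov / size
        if frac >= cutoff:
            labels.append("transcribed")
        elif frac <= 1 - cutoff:
            labels.append("intergenic")
        else:
            labels.append("mixed")
    return pd.Series(labels, index=profile.bins.index, name="category")
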