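"""Mutational-profiling reactivity from chemical probing reads.

Chemical adducts on a probed RNA are read out as reverse-transcription
mutations; the per-position mutation rate is events/depth after trimming
``primer_length`` aligned positions from the read ends. Reactivity uses a
single vehicle control:

    reactivity = rate(treated) - rate(control)

with no denominator normalization. Cross-sample analyses run on
"profiled" positions, those covered by strictly more than a depth cutoff
in every sample; a position is called positive when its rate strictly
exceeds a rate threshold (default 0.1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set

import numpy as np
import pysam
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_PRIMER_LENGTH = 30
DEFAULT_MIN_DEPTH = 5000
DEFAULT_PROFILED_DEPTH = 10000
DEFAULT_POSITIVE_THRESHOLD = 0.001

# CIGAR op codes (pysam)
_CMATCH, _CINS, _CDEL = 0, 1, 2
_CREF_SKIP, _CSOFT, _CHARD = 3, 4, 5
_CEQUAL, _CDIFF = 7, 8


@dataclass
class PositionProfile:
    """Per-position depth and mutation-event counts for one sample.

    Positions are 1-based along the transcript; arrays have length
    ``transcript_length`` with index ``i`` holding position ``i + 1``.
    """

    depth: np.ndarray
    mutation_events: np.ndarray
    sample_label: str = ""
    condition: str = ""
    min_depth: int = DEFAULT_MIN_DEPTH

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.mutation_events = np.asarray(self.mutation_events, dtype=np.int64)
        if self.depth.shape != self.mutation_events.shape:
            raise ValueError("depth and mutation_events length mismatch")
        if (self.mutation_events > self.depth).any():
            raise ValueError("mutation_events exceed depth")
        if (self.depth < 0).any() or (self.mutation_events < 0).any():
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.depth) + 1)

    @property
    def mutation_rate(self) -> np.ndarray:
        """events/depth; NaN where depth is zero or below ``min_depth``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = self.mutation_events / self.depth
        rate[self.depth < max(1, self.min_depth)] = np.nan
        return rate

    @property
    def low_depth_mask(self) -> np.ndarray:
        return self.depth < self.min_depth


@dataclass
class ReactivityProfile:
    """Positionwise treated-minus-control rate difference."""

    reactivity: np.ndarray
    profiled_mask: np.ndarray
    sample_label: str = ""


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # components x positions
    sample_labels: List[str] = field(default_factory=list)


def _aligned_events(read: pysam.AlignedSegment) -> tuple[List[int], Set[int]]:
    """Reference positions covered by the alignment, and event positions.

    An event is a mismatch (X), a deleted reference base (D, one event per
    deleted position) or an insertion (I, assigned to the preceding
    aligned reference position). M ops carry no mismatch information in a
    minimal record and are treated as matches.
    """
    covered: List[int] = []
    events: Set[int] = set()
    ref = read.reference_start  # 0-based
    saw_m = False
    for op, length in read.cigartuples or ():
        if op in (_CEQUAL, _CMATCH):
            covered.extend(range(ref, ref + length))
            ref += length
            saw_m = saw_m or op == _CMATCH
        elif op == _CDIFF:
            covered.extend(range(ref, ref + length))
            events.update(range(ref, ref + length))
            ref += length
        elif op == _CDEL:
            covered.extend(range(ref, ref + length))
            events.update(range(ref, ref + length))
            ref += length
        elif op == _CINS:
            if covered:
                events.add(covered[-1])
        elif op == _CREF_SKIP:
            ref += length
        elif op in (_CSOFT, _CHARD):
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if saw_m:
        logger.warning("read %s uses M ops; treated as matches", read.query_name)
    return covered, events


def count_mutations(
    reads: str | Iterable[pysam.AlignedSegment],
    transcript_length: int,
    primer_length: int = DEFAULT_PRIMER_LENGTH,
    trim_both_ends: bool = True,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample_label: str = "",
    condition: str = "",
) -> PositionProfile:
    """Build a :class:`PositionProfile` from aligned reads (SAM path or records).

    The first and last ``primer_length`` aligned positions of each read
    are excluded from both depth and events (only the last — the RT
    primer end — when ``trim_both_ends`` is off). Events collapse to at
    most one per reference position per read.
    """
    if isinstance(reads, str):
        with pysam.AlignmentFile(reads, "r", check_sq=False) as fh:
            return count_mutations(
                list(fh), transcript_length, primer_length, trim_both_ends,
                min_depth, sample_label, condition,
            )
    depth = np.zeros(transcript_length, dtype=np.int64)
    events = np.zeros(transcript_length, dtype=np.int64)
    n_ok = n_bad = 0
    for read in reads:
        if read.is_unmapped or not read.cigartuples:
            n_bad += 1
            logger.warning("skipping unusable record %s", read.query_name)
            continue
        try:
            covered, ev = _aligned_events(read)
        except ValueError as exc:
            n_bad += 1
            logger.warning("skipping record %s: %s", read.query_name, exc)
            continue
        if trim_both_ends:
            kept = covered[primer_length : len(covered) - primer_length]
        else:
            kept = covered[: len(covered) - primer_length] if primer_length else covered
        kept = [p for p in kept if 0 <= p < transcript_length]
        if not kept:
            n_bad += 1
            continue
        n_ok += 1
        kept_set = set(kept)
        depth[np.asarray(kept)] += 1
        hit = [p for p in ev if p in kept_set]
        if hit:
            events[np.asarray(hit)] += 1
    if n_ok == 0:
        raise ValueError("no usable alignment records")
    return PositionProfile(
        depth=depth,
        mutation_events=events,
        sample_label=sample_label,
        condition=condition,
        min_depth=min_depth,
    )


def merge_amplicons(
    amplicons: Sequence[tuple[PositionProfile, int]],
    transcript_length: int,
    sample_label: str = "",
    condition: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> PositionProfile:
    """Merge per-amplicon profiles onto transcript coordinates.

    Each entry is (profile, offset) with ``offset`` the 0-based transcript
    coordinate of the amplicon's first position. Overlapping positions are
    resolved by summing depth and events.
    """
    depth = np.zeros(transcript_length, dtype=np.int64)
    events = np.zeros(transcript_length, dtype=np.int64)
    for prof, offset in amplicons:
        if offset < 0 or offset + len(prof) > transcript_length:
            raise ValueError(
                f"amplicon of length {len(prof)} at offset {offset} exceeds transcript"
            )
        depth[offset : offset + len(prof)] += prof.depth
        events[offset : offset + len(prof)] += prof.mutation_events
    return PositionProfile(
        depth=depth, mutation_events=events,
        sample_label=sample_label, condition=condition, min_depth=min_depth,
    )


def reactivity(treated: PositionProfile, control: PositionProfile) -> ReactivityProfile:
    """One-control reactivity: treated rate minus control rate, positionwise."""
    if len(treated) != len(control):
        raise ValueError(
            f"profile length mismatch: {len(treated)} vs {len(control)}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rt = treated.mutation_events / treated.depth
        rc = control.mutation_events / control.depth
    mask = (treated.depth > 0) & (control.depth > 0)
    out = np.where(mask, rt - rc, np.nan)
    return ReactivityProfile(
        reactivity=out, profiled_mask=mask, sample_label=treated.sample_label
    )


def profiled_positions(
    profiles: Sequence[PositionProfile], min_reads: int = DEFAULT_PROFILED_DEPTH
) -> np.ndarray:
    """1-based positions with depth strictly above ``min_reads`` in every profile."""
    if not profiles:
        raise ValueError("at least one profile required")
    length = len(profiles[0])
    ok = np.ones(length, dtype=bool)
    for p in profiles:
        if len(p) != length:
            raise ValueError("profile length mismatch")
        ok &= p.depth > min_reads
    return np.flatnonzero(ok) + 1


def positive_calls(
    profile: PositionProfile,
    threshold: float = DEFAULT_POSITIVE_THRESHOLD,
    restrict_to: np.ndarray | None = None,
) -> np.ndarray:
    """1-based positions whose mutation rate strictly exceeds ``threshold``.

    Rates at low-depth positions are undefined (NaN) and never positive.
    ``restrict_to`` limits calls to a 1-based position subset (e.g. the
    profiled set).
    """
    rate = profile.mutation_rate
    with np.errstate(invalid="ignore"):
        pos = np.flatnonzero(rate > threshold) + 1
    if restrict_to is not None:
        pos = np.intersect1d(pos, np.asarray(restrict_to))
    return pos


def pca_profiles(
    reactivities: Sequence[ReactivityProfile],
    restrict_to: np.ndarray,
    n_components: int | None = None,
) -> PcaResult:
    """Mean-centered PCA of reactivity profiles over a shared position set.

    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """
    if len(reactivities) < 2:
        raise ValueError("PCA requires at least 2 samples")
    restrict = np.asarray(restrict_to, dtype=int)
    if restrict.size == 0:
        raise ValueError("restriction position set is empty")
    idx = restrict - 1
    mat = np.vstack([r.reactivity[idx] for r in reactivities])
    if np.isnan(mat).any():
        raise ValueError("reactivity undefined at some restricted positions")
    if n_components is None:
        n_components = min(len(reactivities), restrict.size)
    pca = PCA(n_components=n_components)
    with np.errstate(invalid="ignore"):  # zero-variance input
        scores = pca.fit_transform(mat)
    comps = pca.components_
    total_var = float(np.sum(np.var(mat, axis=0, ddof=1))) if mat.shape[0] > 1 else 0.0
    if total_var > 0:
        ratios = pca.explained_variance_ratio_.copy()
    else:
        ratios = np.zeros(comps.shape[0])
        scores = np.zeros_like(scores)
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    return PcaResult(
        scores=scores,
        explained_variance_ratio=ratios,
        components=comps,
        sample_labels=[r.sample_label for r in reactivities],
    )
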