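"""Affinity-MS candidate selection by per-sample score ranking.

Proteins are ranked by mass-spec protein score (sum of peptide ion scores)
within each pull-down sample. For proteins present in both the tagged
pull-down ("flag") and the empty control, the ranking gain is

    gain = rank_in_empty - rank_in_flag

so a large positive gain marks proteins specifically enriched in the tagged
sample. The candidate set is the union of flag-only proteins and shared
proteins whose gain meets an inclusive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set


@dataclass(frozen=True)
class ProteinScoreTable:
    """Per-sample mapping of protein ID to a non-negative MS protein score."""

    scores: Mapping[str, float]
    sample_label: str = ""

    def __post_init__(self) -> None:
        for pid, s in self.scores.items():
            if s < 0:
                raise ValueError(f"protein {pid!r} has negative score {s}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RankingRecord:
    protein: str
    rank_flag: int
    rank_empty: int

    @property
    def gain(self) -> int:
        return self.rank_empty - self.rank_flag


@dataclass(frozen=True)
class CandidateSet:
    unique_to_flag: Set[str]
    gain_selected: Set[str]
    threshold: int

    @property
    def candidates(self) -> Set[str]:
        return self.unique_to_flag | self.gain_selected

    def __len__(self) -> int:
        return len(self.unique_to_flag) + len(self.gain_selected)


def rank_by_score(table: ProteinScoreTable, min_score: float | None = None) -> Dict[str, int]:
    """Ordinal ranks, 1 = highest score; ties broken by protein ID.

    ``min_score`` optionally drops proteins below a score floor before
    ranking (off by default).
    """
    items = list(table.scores.items())
    if min_score is not None:
        items = [(p, s) for p, s in items if s >= min_score]
    if not items:
        raise ValueError("cannot rank an empty score table")
    items.sort(key=lambda ps: (-ps[1], ps[0]))
    return {p: i + 1 for i, (p, _) in enumerate(items)}


def ranking_gains(
    flag: ProteinScoreTable, empty: ProteinScoreTable, min_score: float | None = None
) -> List[RankingRecord]:
    """Ranking gain for every protein present in both tables.

    Ranks are computed within each full table (not within the shared
    subset). Disjoint tables give an empty list.
    """
    shared = set(flag.scores) & set(empty.scores)
    if not shared:
        return []
    rf = rank_by_score(flag, min_score)
    re_ = rank_by_score(empty, min_score)
    recs = [
        RankingRecord(p, rank_flag=rf[p], rank_empty=re_[p])
        for p in sorted(shared)
        if p in rf and p in re_
    ]
    return recs


def select_candidates(
    flag: ProteinScoreTable,
    empty: ProteinScoreTable,
    gain_threshold: int,
    min_score: float | None = None,
) -> CandidateSet:
    """Flag-only proteins plus shared proteins with gain >= threshold."""
    unique = set(flag.scores) - set(empty.scores)
    gains = ranking_gains(flag, empty, min_score)
    selected = {r.protein for r in gains if r.gain >= gain_threshold}
    return CandidateSet(unique_to_flag=unique, gain_selected=selected, threshold=gain_threshold)
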