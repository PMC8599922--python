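"""Readers and writers for the plain-text formats shared by all stages.

Conventions: TSV with a header row for tabular data, BED-style 0-based
half-open genomic coordinates, 1-based transcript positions, JSON for
truth sidecars and provenance. All readers validate the schema and cite
the offending line on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .atac import InsertionSiteSet
from .interactome import CandidateSet, ProteinScoreTable, RankingRecord
from .shape import PositionProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnSpec:
    """One column of a TSV schema: name, converter, optional row check."""

    name: str
    convert: Callable = str
    check: Callable | None = None  # value -> error message or None


def read_table(
    path: str | Path,
    schema: Sequence[ColumnSpec],
    key_columns: Sequence[str] = (),
) -> List[Dict]:
    """Schema-validated TSV reading with line-precise errors.

    The first line must be a header naming at least the schema columns.
    ``key_columns`` enforces uniqueness of the named column combination.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        logger.warning("%s: empty file", path)
        return []
    header = lines[0].rstrip("\n").split("\t")
    col_idx = {}
    for spec in schema:
        if spec.name not in header:
            raise ValueError(f"{path}: missing column {spec.name!r} in header")
        col_idx[spec.name] = header.index(spec.name)
    records: List[Dict] = []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        rec: Dict = {}
        for spec in schema:
            i = col_idx[spec.name]
            if i >= len(fields):
                raise ValueError(f"{path}:{ln}: missing value for column {spec.name!r}")
            raw = fields[i]
            try:
                val = spec.convert(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{ln}: column {spec.name!r}: cannot parse {raw!r}"
                ) from exc
            if spec.check is not None:
                msg = spec.check(val)
                if msg:
                    raise ValueError(f"{path}:{ln}: column {spec.name!r}: {msg}")
            rec[spec.name] = val
        if key_columns:
            key = tuple(rec[c] for c in key_columns)
            if key in seen:
                raise ValueError(f"{path}:{ln}: duplicate key {key}")
            seen.add(key)
        records.append(rec)
    return records


def _nonneg(v):
    return "negative count" if v < 0 else None


# -- interactome ------------------------------------------------------------

def read_score_table(path: str | Path, sample_label: str = "") -> ProteinScoreTable:
    recs = read_table(
        path,
        [ColumnSpec("protein_id"), ColumnSpec("score", float, _nonneg)],
        key_columns=("protein_id",),
    )
    return ProteinScoreTable(
        scores={r["protein_id"]: r["score"] for r in recs},
        sample_label=sample_label or Path(path).stem,
    )


def write_score_table(table: ProteinScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tscore\n")
        for pid in sorted(table.scores):
            fh.write(f"{pid}\t{table.scores[pid]:.6g}\n")


def write_ranking_records(records: Sequence[RankingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\trank_flag\trank_empty\tgain\n")
        for r in sorted(records, key=lambda r: (-r.gain, r.protein)):
            fh.write(f"{r.protein}\t{r.rank_flag}\t{r.rank_empty}\t{r.gain}\n")


def write_candidates(cands: CandidateSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\treason\n")
        for pid in sorted(cands.unique_to_flag):
            fh.write(f"{pid}\tunique\n")
        for pid in sorted(cands.gain_selected):
            fh.write(f"{pid}\tgain\n")


# -- allelotype -------------------------------------------------------------

def read_snp_counts(path: str | Path) -> pd.DataFrame:
    recs = read_table(
        path,
        [
            ColumnSpec("snp_id"), ColumnSpec("gene"), ColumnSpec("sample"),
            ColumnSpec("count_129", int, _nonneg),
            ColumnSpec("count_cast", int, _nonneg),
        ],
        key_columns=("snp_id", "sample"),
    )
    return pd.DataFrame.from_records(
        recs, columns=["snp_id", "gene", "sample", "count_129", "count_cast"]
    )


def write_snp_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> List[str]:
    """One gene per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gene_positions(path: str | Path) -> Dict[str, Tuple[str, int]]:
    recs = read_table(
        path,
        [ColumnSpec("gene"), ColumnSpec("chrom"), ColumnSpec("start", int)],
        key_columns=("gene",),
    )
    return {r["gene"]: (r["chrom"], r["start"]) for r in recs}


def write_score_matrix(scores: pd.DataFrame, path: str | Path, metadata: Dict | None = None) -> None:
    """Gene x sample score matrix, heatmap-ready; metadata as # header lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        scores.to_csv(fh, sep="\t", float_format="%.6g")


# -- atac -------------------------------------------------------------------

def read_sites_bed(
    path: str | Path, total_autosomal_reads: int, sample_label: str = ""
) -> InsertionSiteSet:
    """BED3 of insertion sites; the interval start is the insertion position."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
        if start < 0 or end < start:
            raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
        rows.append((fields[0], start))
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    return InsertionSiteSet(
        sites=sites, total_autosomal_reads=total_autosomal_reads,
        sample_label=sample_label or Path(path).stem,
    )


def write_sites_bed(sites: InsertionSiteSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in sites.sites.itertuples():
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\n")


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
        try:
            size = int(fields[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer size {fields[1]!r}") from exc
        if fields[0] in out:
            raise ValueError(f"{path}:{ln}: duplicate chromosome {fields[0]!r}")
        out[fields[0]] = size
    return out


def read_intervals_bed(path: str | Path) -> List[Tuple[str, int, int]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
        out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# -- shape ------------------------------------------------------------------

def read_position_profile(
    path: str | Path, sample_label: str = "", condition: str = "", min_depth: int = 5000
) -> PositionProfile:
    """Per-position TSV ``position depth events`` (1-based, dense or sparse)."""
    recs = read_table(
        path,
        [
            ColumnSpec("position", int, lambda v: "position must be >= 1" if v < 1 else None),
            ColumnSpec("depth", int, _nonneg),
            ColumnSpec("events", int, _nonneg),
        ],
        key_columns=("position",),
    )
    if not recs:
        raise ValueError(f"{path}: empty position profile")
    length = max(r["position"] for r in recs)
    depth = np.zeros(length, dtype=np.int64)
    events = np.zeros(length, dtype=np.int64)
    for r in recs:
        depth[r["position"] - 1] = r["depth"]
        events[r["position"] - 1] = r["events"]
    return PositionProfile(
        depth=depth, mutation_events=events,
        sample_label=sample_label or Path(path).stem,
        condition=condition, min_depth=min_depth,
    )


def write_position_profile(profile: PositionProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tdepth\tevents\n")
        for i in range(len(profile)):
            fh.write(f"{i + 1}\t{profile.depth[i]}\t{profile.mutation_events[i]}\n")


# -- decay ------------------------------------------------------------------

def read_decay_table(path: str | Path) -> List[Dict]:
    """TSV ``time_h target_cq reference_cq replicate`` or ``time_h level replicate``."""
    header = Path(path).read_text().splitlines()[0].split("\t") if Path(path).read_text() else []
    if "level" in header:
        return read_table(
            path,
            [
                ColumnSpec("time_h", float),
                ColumnSpec("level", float, lambda v: "level must be > 0" if v <= 0 else None),
                ColumnSpec("replicate"),
            ],
        )
    return read_table(
        path,
        [
            ColumnSpec("time_h", float),
            ColumnSpec("target_cq", float),
            ColumnSpec("reference_cq", float),
            ColumnSpec("replicate"),
        ],
    )


# -- provenance -------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(
    path: str | Path,
    stage: str,
    parameters: Mapping,
    inputs: Mapping[str, str | Path] | None = None,
) -> None:
    from . import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "parameters": {k: _as_jsonable(v) for k, v in parameters.items()},
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _as_jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple, np.ndarray)):
        return [_as_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {str(k): _as_jsonable(x) for k, x in v.items()}
    if isinstance(v, Path):
        return str(v)
    return v
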