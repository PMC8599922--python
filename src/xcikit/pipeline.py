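"""Stage runners: wire file inputs through the analysis modules to disk.

Every runner writes its result tables plus a provenance JSON (parameters,
package version, input digests) next to them, is deterministic given a
seed, and removes partial outputs if it fails midway.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import allelotype as at
from . import atac as ac
from . import interactome as ia
from . import io as xio
from . import kinetics as kn
from . import shape as sh
from . import synthetic as syn

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "interactome", "allelotype", "atac", "shape", "decay")


@dataclass
class RunConfig:
    """One stage invocation: stage name, its parameters, seed, log level."""

    stage: str
    params: Dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")


def run_stage(config: RunConfig) -> List[Path]:
    """Dispatch a stage run; returns the list of files written.

    Unknown parameter keys are rejected up front; on failure all files
    written so far are removed and the error propagates.
    """
    logging.basicConfig(level=config.log_level)
    runner = {
        "simulate": run_simulate,
        "interactome": run_interactome,
        "allelotype": run_allelotype,
        "atac": run_atac,
        "shape": run_shape,
        "decay": run_decay,
    }[config.stage]
    import inspect

    allowed = set(inspect.signature(runner).parameters)
    unknown = set(config.params) - allowed
    if unknown:
        raise ValueError(f"unknown parameters for stage {config.stage}: {sorted(unknown)}")
    params = dict(config.params)
    if "seed" in allowed and "seed" not in params:
        params["seed"] = config.seed
    written: List[Path] = []
    try:
        written = runner(**params)
    except Exception:
        for p in written:
            Path(p).unlink(missing_ok=True)
        raise
    return written


def _check_exists(*paths) -> None:
    for p in paths:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")


def run_interactome(
    flag: str,
    empty: str,
    out_prefix: str,
    gain_threshold: int = 11,
    min_score: float | None = None,
) -> List[Path]:
    _check_exists(flag, empty)
    flag_t = xio.read_score_table(flag, "flag")
    empty_t = xio.read_score_table(empty, "empty")
    gains = ia.ranking_gains(flag_t, empty_t, min_score)
    cands = ia.select_candidates(flag_t, empty_t, gain_threshold, min_score)
    out = Path(out_prefix)
    paths = [Path(f"{out}.rankings.tsv"), Path(f"{out}.candidates.tsv"),
             Path(f"{out}.provenance.json")]
    xio.write_ranking_records(gains, paths[0])
    xio.write_candidates(cands, paths[1])
    xio.write_provenance(
        paths[2], "interactome",
        {"gain_threshold": gain_threshold, "min_score": min_score},
        {"flag": flag, "empty": empty},
    )
    return paths


def run_allelotype(
    counts: str,
    out_prefix: str,
    escapees: str | None = None,
    gene_positions: str | None = None,
    required_samples: Sequence[str] | None = None,
    min_reads: int = 10,
    per_allele: bool = True,
    pseudocount: float = 10,
    log_base: float = 10,
) -> List[Path]:
    _check_exists(counts, escapees, gene_positions)
    matrix = xio.read_snp_counts(counts)
    esc = xio.read_gene_list(escapees) if escapees else []
    pos = xio.read_gene_positions(gene_positions) if gene_positions else None
    filtered = at.filter_undetected(matrix, min_reads=min_reads, per_allele=per_allele)
    samples = list(required_samples) if required_samples else sorted(matrix["sample"].unique())
    complete = at.require_complete(filtered, samples)
    result = at.gene_allelotype(
        complete, pseudocount=pseudocount, log_base=log_base,
        escapees=esc, gene_positions=pos,
    )
    out = Path(out_prefix)
    paths = [Path(f"{out}.allelotype.tsv"), Path(f"{out}.provenance.json")]
    xio.write_score_matrix(
        result.scores, paths[0],
        metadata={"log_base": log_base, "pseudocount": pseudocount,
                  "min_reads": min_reads, "per_allele": per_allele,
                  "required_samples": ",".join(samples)},
    )
    xio.write_provenance(
        paths[1], "allelotype",
        {"min_reads": min_reads, "per_allele": per_allele, "pseudocount": pseudocount,
         "log_base": log_base, "required_samples": samples, "escapees_removed": sorted(esc)},
        {"counts": counts, **({"escapees": escapees} if escapees else {}),
         **({"gene_positions": gene_positions} if gene_positions else {})},
    )
    return paths


def run_atac(
    uninduced: str,
    induced: str,
    chrom_sizes: str,
    out_prefix: str,
    uninduced_total: int,
    induced_total: int,
    bin_size: int = ac.DEFAULT_BIN_SIZE,
    pseudocount: float = 1.0,
    transcribed: str | None = None,
    category_cutoff: float = 0.5,
    distinct_sites: bool = True,
) -> List[Path]:
    _check_exists(uninduced, induced, chrom_sizes, transcribed)
    sizes = xio.read_chrom_sizes(chrom_sizes)
    u = xio.read_sites_bed(uninduced, uninduced_total, "uninduced")
    i = xio.read_sites_bed(induced, induced_total, "induced")
    reference = uninduced_total  # normalize both samples to the uninduced depth
    up = ac.bin_cut_counts(u, sizes, bin_size, reference, distinct_sites)
    ip = ac.bin_cut_counts(i, sizes, bin_size, reference, distinct_sites)
    table = ac.compaction_score(up, ip, pseudocount)
    if transcribed:
        table["category"] = ac.categorize_bins(
            up, xio.read_intervals_bed(transcribed), category_cutoff
        )
    else:
        table["category"] = "unannotated"
    table.insert(2, "cut_count_uninduced", up.bins["cut_count"])
    table.insert(3, "cut_count_induced", ip.bins["cut_count"])
    out = Path(out_prefix)
    paths = [Path(f"{out}.compaction.tsv"), Path(f"{out}.provenance.json")]
    table.to_csv(paths[0], sep="\t", index=False, float_format="%.6g")
    xio.write_provenance(
        paths[1], "atac",
        {"bin_size": bin_size, "pseudocount": pseudocount,
         "uninduced_total": uninduced_total, "induced_total": induced_total,
         "category_cutoff": category_cutoff, "distinct_sites": distinct_sites},
        {"uninduced": uninduced, "induced": induced, "chrom_sizes": chrom_sizes,
         **({"transcribed": transcribed} if transcribed else {})},
    )
    return paths


def _load_shape_sample(entry: Dict, transcript_length: int, min_depth: int) -> sh.PositionProfile:
    fmt = entry.get("format", "tsv")
    label = entry.get("label", Path(entry["path"]).stem)
    condition = entry.get("condition", "")
    offset = int(entry.get("offset", 0))
    if fmt == "tsv":
        prof = xio.read_position_profile(entry["path"], label, condition, min_depth)
    elif fmt == "sam":
        prof = sh.count_mutations(
            entry["path"], transcript_length=int(entry.get("aligned_length", transcript_length)),
            primer_length=int(entry.get("primer_length", sh.DEFAULT_PRIMER_LENGTH)),
            trim_both_ends=bool(entry.get("trim_both_ends", True)),
            min_depth=min_depth, sample_label=label, condition=condition,
        )
    else:
        raise ValueError(f"unknown sample format {fmt!r}")
    if offset or len(prof) != transcript_length:
        prof = sh.merge_amplicons(
            [(prof, offset)] if len(prof) + offset <= transcript_length
            else [(sh.PositionProfile(prof.depth[: transcript_length - offset],
                                      prof.mutation_events[: transcript_length - offset]),
                   offset)],
            transcript_length, label, condition, min_depth,
        )
    return prof


def run_shape(
    samples: str,
    out_prefix: str,
    min_depth: int = sh.DEFAULT_MIN_DEPTH,
    profiled_depth: int = sh.DEFAULT_PROFILED_DEPTH,
    threshold: float = sh.DEFAULT_POSITIVE_THRESHOLD,
) -> List[Path]:
    """Run reactivity, profiled/positive calls and PCA from a sample config.

    ``samples`` is a JSON file: ``{"transcript_length": L, "samples":
    [{"label", "condition": "treated_*|control_*", "path", "format":
    "tsv"|"sam", "offset": 0}, ...]}``.
    """
    _check_exists(samples)
    cfg = json.loads(Path(samples).read_text())
    length = int(cfg["transcript_length"])
    profiles = [_load_shape_sample(e, length, min_depth) for e in cfg["samples"]]
    treated = [p for p in profiles if p.condition.startswith("treated")]
    controls = [p for p in profiles if p.condition.startswith("control")]
    if not treated or not controls:
        raise ValueError("need at least one treated and one control sample")
    control = controls[0] if len(controls) == 1 else sh.merge_amplicons(
        [(c, 0) for c in controls], length, "control_pooled", "control", min_depth
    )
    profiled = sh.profiled_positions(profiles, profiled_depth)
    out = Path(out_prefix)
    paths: List[Path] = []

    reacts = []
    for t in treated:
        r = sh.reactivity(t, control)
        reacts.append(r)
        p = Path(f"{out}.reactivity.{t.sample_label}.tsv")
        with open(p, "w") as fh:
            fh.write("position\treactivity\n")
            for pos in profiled:
                fh.write(f"{pos}\t{r.reactivity[pos - 1]:.8g}\n")
        paths.append(p)

    p = Path(f"{out}.profiled_positions.txt")
    Path(p).write_text("".join(f"{pos}\n" for pos in profiled))
    paths.append(p)

    p = Path(f"{out}.positive_calls.tsv")
    with open(p, "w") as fh:
        fh.write("sample\tposition\trate\n")
        for prof in profiles:
            rate = prof.mutation_rate
            for pos in sh.positive_calls(prof, threshold, restrict_to=profiled):
                fh.write(f"{prof.sample_label}\t{pos}\t{rate[pos - 1]:.8g}\n")
    paths.append(p)

    if len(reacts) >= 2 and profiled.size:
        pca = sh.pca_profiles(reacts, profiled)
        p = Path(f"{out}.pca.tsv")
        with open(p, "w") as fh:
            ncomp = pca.scores.shape[1]
            fh.write("sample\t" + "\t".join(f"PC{i + 1}" for i in range(ncomp)) + "\n")
            fh.write("explained_variance_ratio\t"
                     + "\t".join(f"{v:.6g}" for v in pca.explained_variance_ratio) + "\n")
            for lab, row in zip(pca.sample_labels, pca.scores):
                fh.write(lab + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
        paths.append(p)

    p = Path(f"{out}.provenance.json")
    xio.write_provenance(
        p, "shape",
        {"min_depth": min_depth, "profiled_depth": profiled_depth, "threshold": threshold,
         "transcript_length": length},
        {"samples": samples},
    )
    paths.append(p)
    return paths


def _fit_report(fit: kn.DecayFit | None) -> Dict | None:
    if fit is None:
        return None
    return {
        "n0": fit.n0, "k": fit.k,
        "half_life": fit.half_life if math.isfinite(fit.half_life) else None,
        "r_squared": fit.r_squared, "no_decay": fit.no_decay,
        "n_points": int(len(fit.points_used)),
    }


def run_decay(
    input: str,
    out: str,
    exclude_t0: bool = False,
    two_phase: bool = False,
    breakpoint: float = 1.0,
    method: str = "log-linear",
    efficiency: float = 2.0,
) -> List[Path]:
    _check_exists(input)
    recs = xio.read_decay_table(input)
    if not recs:
        raise ValueError(f"{input}: no data rows")
    by_rep: Dict[str, List[Dict]] = {}
    for r in recs:
        by_rep.setdefault(r["replicate"], []).append(r)
    report: Dict = {"replicates": {}, "parameters": {
        "exclude_t0": exclude_t0, "two_phase": two_phase, "breakpoint": breakpoint,
        "method": method, "r_squared_scale": "log",
    }}
    all_series = []
    for rep, rows in sorted(by_rep.items()):
        rows.sort(key=lambda r: r["time_h"])
        t = [r["time_h"] for r in rows]
        if "level" in rows[0]:
            levels = np.asarray([r["level"] for r in rows], dtype=float)
            series = kn.DecaySeries(np.asarray(t), levels / levels[0], rep)
        else:
            series = kn.normalize_series(
                t, [r["target_cq"] for r in rows], [r["reference_cq"] for r in rows],
                efficiency=efficiency, replicate_id=rep,
            )
        all_series.append(series)
        entry = {"fit": _fit_report(kn.fit_decay(series, include_t0=not exclude_t0, method=method))}
        if two_phase:
            p1, p2 = kn.two_phase_fit(series, breakpoint=breakpoint, method=method)
            entry["phase1"] = _fit_report(p1)
            entry["phase2"] = _fit_report(p2)
        report["replicates"][rep] = entry
    # pooled fit: geometric-mean levels across replicates at shared timepoints
    if len(all_series) > 1:
        t0 = all_series[0].timepoints
        if all(np.array_equal(s.timepoints, t0) for s in all_series):
            pooled = np.exp(np.mean([np.log(s.levels) for s in all_series], axis=0))
            series = kn.DecaySeries(t0, pooled, "pooled")
            report["pooled"] = _fit_report(
                kn.fit_decay(series, include_t0=not exclude_t0, method=method)
            )
    out_path = Path(out)
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    prov = out_path.with_suffix(".provenance.json")
    xio.write_provenance(
        prov, "decay",
        {"exclude_t0": exclude_t0, "two_phase": two_phase, "breakpoint": breakpoint,
         "method": method, "efficiency": efficiency},
        {"input": input},
    )
    return [out_path, prov]


def run_simulate(stage: str, out_dir: str, seed: int = 0, params: Dict | None = None) -> List[Path]:
    """Generate a synthetic dataset plus its truth sidecar for one stage."""
    params = dict(params or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    if stage == "interactome":
        flag, empty, truth = syn.gen_ms_scores(seed=seed, **params)
        paths = [out / "flag.tsv", out / "empty.tsv", out / "truth.json"]
        xio.write_score_table(flag, paths[0])
        xio.write_score_table(empty, paths[1])
        truth.to_json(paths[2])
    elif stage == "allelotype":
        matrix, truth = syn.gen_padlock_counts(seed=seed, **params)
        paths = [out / "snp_counts.tsv", out / "truth.json"]
        xio.write_snp_counts(matrix, paths[0])
        truth.to_json(paths[1])
    elif stage == "atac":
        sites, truth = syn.gen_atac_sites(seed=seed, **params)
        paths = [out / "sites.bed", out / "truth.json"]
        xio.write_sites_bed(sites, paths[0])
        truth.to_json(paths[1])
    elif stage == "shape":
        profiles, truth = syn.gen_shape_profiles(seed=seed, **params)
        for prof in profiles:
            p = out / f"{prof.sample_label}.tsv"
            xio.write_position_profile(prof, p)
            paths.append(p)
        truth.to_json(out / "truth.json")
        paths.append(out / "truth.json")
    elif stage == "decay":
        series, truth = syn.gen_decay_series(seed=seed, **params)
        p = out / "decay.tsv"
        with open(p, "w") as fh:
            fh.write("time_h\tlevel\treplicate\n")
            for t, y in zip(series.timepoints, series.levels):
                fh.write(f"{t:.6g}\t{y:.10g}\t{series.replicate_id or 'r1'}\n")
        truth.to_json(out / "truth.json")
        paths = [p, out / "truth.json"]
    else:
        raise ValueError(f"unknown simulation stage {stage!r}")
    return paths
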