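"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure one analysis assumes —
heavy-tailed MS scores with a planted enriched subset, beta-binomial
allelic counts with skew classes, Poisson insertion sites with per-bin
compaction factors, binomial mutation events over a true reactivity
profile, and lognormal-noise first-order decay — and returns a
:class:`SyntheticTruth` sufficient to predict every downstream statistic.

All randomness derives from a single integer seed split into independent
per-stage streams, so identical (seed, parameters) give identical output
and any stage can be regenerated alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .allelotype import SNP_COLUMNS
from .atac import DEFAULT_BIN_SIZE, InsertionSiteSet
from .interactome import ProteinScoreTable
from .kinetics import DecaySeries
from .shape import PositionProfile


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator settings plus the ground truth behind a synthetic dataset."""

    stage: str
    parameters: Dict
    truth: Dict
    seed: int

    def to_json(self, path: str) -> None:
        payload = {
            "stage": self.stage,
            "seed": int(self.seed),
            "parameters": _jsonable(self.parameters),
            "truth": _jsonable(self.truth),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# interactome: mass-spec protein score tables


def gen_ms_scores(
    n_background: int,
    n_true_binders: int,
    n_unique: int,
    score_shape: float = 1.0,
    enrichment_factor: float = 20.0,
    seed: int = 0,
    score_scale: float = 100.0,
) -> Tuple[ProteinScoreTable, ProteinScoreTable, SyntheticTruth]:
    """Two pull-down score tables with planted binders.

    Background proteins draw scores independently per sample from a common
    lognormal with log-sd ``score_shape``. True binders are sampled from
    the sub-median stratum of the same distribution (specific interactors
    are rarely among the most abundant background proteins), keep that
    baseline score in the control table, and have it multiplied by
    ``enrichment_factor`` in the flag table. ``n_unique`` extra binders
    appear in the flag table only.
    """
    for name, v in [
        ("n_background", n_background), ("n_true_binders", n_true_binders),
        ("n_unique", n_unique),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if score_shape <= 0:
        raise ValueError("score_shape must be > 0")
    rng = stage_rng(seed, "interactome")
    dist = stats.lognorm(s=score_shape, scale=score_scale)

    bg_ids = [f"BG{i:04d}" for i in range(n_background)]
    tb_ids = [f"TB{i:03d}" for i in range(n_true_binders)]
    uq_ids = [f"UQ{i:03d}" for i in range(n_unique)]

    bg_flag = dist.rvs(size=n_background, random_state=rng)
    bg_empty = dist.rvs(size=n_background, random_state=rng)
    # sub-median baseline, shared across samples, enriched in flag only
    tb_base = dist.ppf(rng.uniform(0.0, 0.5, size=n_true_binders))
    uq_scores = dist.ppf(rng.uniform(0.0, 0.5, size=n_unique)) * enrichment_factor

    flag = dict(zip(bg_ids, bg_flag))
    flag.update(zip(tb_ids, tb_base * enrichment_factor))
    flag.update(zip(uq_ids, uq_scores))
    empty = dict(zip(bg_ids, bg_empty))
    empty.update(zip(tb_ids, tb_base))

    truth = SyntheticTruth(
        stage="interactome",
        parameters={
            "n_background": n_background, "n_true_binders": n_true_binders,
            "n_unique": n_unique, "score_shape": score_shape,
            "enrichment_factor": enrichment_factor, "score_scale": score_scale,
        },
        truth={
            "true_binders": tb_ids,
            "unique_binders": uq_ids,
            "all_binders": tb_ids + uq_ids,
        },
        seed=seed,
    )
    return (
        ProteinScoreTable(scores=flag, sample_label="flag"),
        ProteinScoreTable(scores=empty, sample_label="empty"),
        truth,
    )


# ---------------------------------------------------------------------------
# allelotype: SNP allelic count matrix


def gen_padlock_counts(
    n_genes: int,
    snps_per_gene: int,
    class_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    depth_mean: float = 500.0,
    overdispersion: float = 0.0,
    seed: int = 0,
    n_samples: int = 6,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """SNP x sample allelic count table with known per-gene skew classes.

    ``class_fractions`` is a (silenced, escapee, biallelic) simplex; class
    sizes use largest-remainder rounding. Per SNP and sample, total depth
    is Poisson(``depth_mean``) and the 129-allele count is beta-binomial
    with per-gene true 129-fraction (silenced U(0.95, 1), escapee
    U(0.3, 0.7), biallelic 0.5) and intraclass correlation
    ``overdispersion`` (0 gives plain binomial).
    """
    if n_genes < 0 or snps_per_gene <= 0 or n_samples <= 0:
        raise ValueError("counts must be positive (n_genes >= 0)")
    fracs = np.asarray(class_fractions, dtype=float)
    if fracs.shape != (3,) or (fracs < 0).any() or abs(fracs.sum() - 1) > 1e-9:
        raise ValueError("class_fractions must be a length-3 simplex summing to 1")
    if not 0 <= overdispersion < 1:
        raise ValueError("overdispersion must be in [0, 1)")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = stage_rng(seed, "allelotype")

    # largest-remainder class sizes
    raw = fracs * n_genes
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n_genes - sizes.sum()]:
        sizes[i] += 1
    classes = ["silenced"] * sizes[0] + ["escapee"] * sizes[1] + ["biallelic"] * sizes[2]

    genes = [f"G{i:04d}" for i in range(n_genes)]
    p129 = np.empty(n_genes)
    for i, cls in enumerate(classes):
        if cls == "silenced":
            p129[i] = rng.uniform(0.95, 1.0)
        elif cls == "escapee":
            p129[i] = rng.uniform(0.3, 0.7)
        else:
            p129[i] = 0.5

    rows = []
    samples = [f"S{j + 1}" for j in range(n_samples)]
    for i, gene in enumerate(genes):
        p = float(np.clip(p129[i], 1e-9, 1 - 1e-9))
        for s in range(snps_per_gene):
            snp_id = f"{gene}_snp{s:02d}"
            for sample in samples:
                depth = int(rng.poisson(depth_mean))
                if depth == 0:
                    c129 = 0
                elif overdispersion > 0:
                    a = p * (1 - overdispersion) / overdispersion
                    b = (1 - p) * (1 - overdispersion) / overdispersion
                    c129 = int(stats.betabinom.rvs(depth, a, b, random_state=rng))
                else:
                    c129 = int(rng.binomial(depth, p))
                rows.append((snp_id, gene, sample, c129, depth - c129))
    matrix = pd.DataFrame(rows, columns=list(SNP_COLUMNS))
    truth = SyntheticTruth(
        stage="allelotype",
        parameters={
            "n_genes": n_genes, "snps_per_gene": snps_per_gene,
            "class_fractions": list(fracs), "depth_mean": depth_mean,
            "overdispersion": overdispersion, "n_samples": n_samples,
        },
        truth={
            "gene_class": dict(zip(genes, classes)),
            "true_129_fraction": dict(zip(genes, p129)),
            "samples": samples,
        },
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# atac: insertion sites with per-bin compaction factors


def gen_atac_sites(
    chrom_sizes: Mapping[str, int],
    base_intensity: float = 2000.0,
    compaction_factors: Mapping[Tuple[str, int], float] | None = None,
    library_scale: float = 1.0,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    sample_label: str = "",
) -> Tuple[InsertionSiteSet, SyntheticTruth]:
    """Poisson insertion sites, thinned per bin by a compaction factor.

    Per-bin site counts are Poisson(``base_intensity`` sites/Mb x bin
    length x ``library_scale`` / factor); positions are uniform and
    distinct within the bin. The emitted ``total_autosomal_reads`` is the
    realized number of sites outside chrX, so it scales with
    ``library_scale`` like a real library would.
    """
    if base_intensity <= 0 or library_scale <= 0 or bin_size <= 0:
        raise ValueError("base_intensity, library_scale and bin_size must be > 0")
    factors = dict(compaction_factors or {})
    for key, f in factors.items():
        if f <= 0:
            raise ValueError(f"compaction factor must be > 0 at bin {key}")
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
    if not any(c != "chrX" for c in chrom_sizes):
        raise ValueError("chrom_sizes must include at least one non-chrX chromosome")
    rng = stage_rng(seed, "atac")

    chroms: List[str] = []
    positions: List[np.ndarray] = []
    bin_truth: Dict[Tuple[str, int], float] = {}
    autosomal_sites = 0
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            blen = min(bin_size, size - start)
            factor = factors.get((chrom, start), 1.0)
            bin_truth[(chrom, start)] = factor
            lam = base_intensity * (blen / 1e6) * library_scale / factor
            n = min(int(rng.poisson(lam)), blen)
            pos = rng.choice(blen, size=n, replace=False) + start
            chroms.extend([chrom] * n)
            positions.append(np.sort(pos))
            if chrom != "chrX":
                autosomal_sites += n
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": np.concatenate(positions) if positions else np.array([], dtype=int),
    })
    total = max(1, autosomal_sites)
    truth = SyntheticTruth(
        stage="atac",
        parameters={
            "chrom_sizes": dict(chrom_sizes), "base_intensity": base_intensity,
            "library_scale": library_scale, "bin_size": bin_size,
        },
        truth={
            "compaction_factors": {f"{c}:{s}": f for (c, s), f in bin_truth.items()},
            "total_autosomal_reads": total,
        },
        seed=seed,
    )
    return InsertionSiteSet(sites=sites, total_autosomal_reads=total,
                            sample_label=sample_label), truth


# ---------------------------------------------------------------------------
# shape: per-position mutation counts


def gen_shape_profiles(
    seq_length: int,
    true_reactivity: float | Sequence[float],
    background_rate: float = 2e-4,
    depth: int | Sequence[int] = 50000,
    samples: Sequence[str] = ("treated", "control"),
    seed: int = 0,
    min_depth: int = 5000,
) -> Tuple[List[PositionProfile], SyntheticTruth]:
    """Binomial mutation-count profiles over a true reactivity profile.

    Control samples mutate at ``background_rate``; treated samples at
    ``background_rate + true_reactivity`` positionwise. ``depth`` may be a
    scalar or per-position array.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be > 0")
    react = np.broadcast_to(np.asarray(true_reactivity, dtype=float), (seq_length,)).copy()
    if (react < 0).any():
        raise ValueError("true_reactivity must be non-negative")
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must be in [0, 1]")
    if background_rate + react.max(initial=0.0) > 1:
        raise ValueError("background_rate + max reactivity must be <= 1")
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=np.int64), (seq_length,)).copy()
    if (depth_arr < 0).any():
        raise ValueError("depth must be non-negative")
    for s in samples:
        if s not in ("treated", "control"):
            raise ValueError(f"sample kind must be 'treated' or 'control', got {s!r}")
    rng = stage_rng(seed, "shape")

    profiles = []
    for i, kind in enumerate(samples):
        p = background_rate + (react if kind == "treated" else 0.0)
        events = rng.binomial(depth_arr, p)
        profiles.append(PositionProfile(
            depth=depth_arr.copy(), mutation_events=events,
            sample_label=f"{kind}_{i + 1}", condition=kind, min_depth=min_depth,
        ))
    truth = SyntheticTruth(
        stage="shape",
        parameters={
            "seq_length": seq_length, "background_rate": background_rate,
            "samples": list(samples), "min_depth": min_depth,
        },
        truth={
            "true_reactivity": react,
            "depth": depth_arr,
            "events": {p.sample_label: p.mutation_events for p in profiles},
        },
        seed=seed,
    )
    return profiles, truth


def write_profile_sam(
    profile: PositionProfile, path: str, primer_length: int = 30, seed: int = 0
) -> int:
    """Emit minimal aligned reads reproducing a constant-depth profile.

    Reads span a padded reference of length ``len(profile) + 2 *
    primer_length`` whose interior window is the profile; after end
    trimming with the same ``primer_length``, counting the emitted reads
    reproduces the profile's depth and events exactly. Mutations are
    encoded as X CIGAR ops on randomly chosen reads. Returns the padded
    reference length.
    """
    depth = profile.depth
    if len(np.unique(depth)) != 1:
        raise ValueError("SAM emission requires constant depth across positions")
    n_reads = int(depth[0])
    length = len(profile)
    padded = length + 2 * primer_length
    rng = np.random.default_rng(seed)
    mutated: List[set] = [set() for _ in range(n_reads)]
    for i in range(length):
        k = int(profile.mutation_events[i])
        if k:
            for r in rng.choice(n_reads, size=k, replace=False):
                mutated[r].add(primer_length + i)  # padded 0-based coordinate
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:transcript\tLN:{padded}\n")
        for r in range(n_reads):
            cig = []
            muts = sorted(mutated[r])
            prev = 0
            for m in muts:
                if m > prev:
                    cig.append(f"{m - prev}=")
                cig.append("1X")
                prev = m + 1
            if padded > prev:
                cig.append(f"{padded - prev}=")
            fh.write(
                f"read{r}\t0\ttranscript\t1\t255\t{''.join(cig)}\t*\t0\t0\t*\t*\n"
            )
    return padded


# ---------------------------------------------------------------------------
# decay: noisy first-order series


def gen_decay_series(
    n0: float,
    k: float,
    timepoints: Sequence[float],
    noise_cv: float = 0.0,
    lag_hours: float = 0.0,
    seed: int = 0,
    replicate_id: str = "",
) -> Tuple[DecaySeries, SyntheticTruth]:
    """First-order decay with optional onset lag and lognormal noise.

    level(t) = n0 exp(-k max(0, t - lag)) x unit-mean lognormal noise
    with coefficient of variation ``noise_cv``.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0 or (t < 0).any():
        raise ValueError("timepoints must be nonempty and non-negative")
    if k < 0:
        raise ValueError("decay constant k must be >= 0")
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if noise_cv < 0 or lag_hours < 0:
        raise ValueError("noise_cv and lag_hours must be >= 0")
    rng = stage_rng(seed, "decay")
    clean = n0 * np.exp(-k * np.maximum(0.0, t - lag_hours))
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=t.size)
    else:
        noise = np.ones_like(t)
    series = DecaySeries(timepoints=t, levels=clean * noise, replicate_id=replicate_id)
    truth = SyntheticTruth(
        stage="decay",
        parameters={
            "n0": n0, "k": k, "timepoints": t, "noise_cv": noise_cv,
            "lag_hours": lag_hours,
        },
        truth={"k": k, "half_life": float(np.log(2) / k) if k > 0 else float("inf")},
        seed=seed,
    )
    return series, truth
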