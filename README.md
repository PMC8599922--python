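# xcikit

Analysis toolkit for X-chromosome-inactivation sequencing assays. It
implements five self-contained pipelines plus a synthetic-data generator
that lets every stage be validated against known ground truth without any
external downloads:

| Stage | Module | What it does |
| --- | --- | --- |
| `interactome` | `xcikit.interactome` | Ranks affinity-MS protein scores per pull-down sample, computes ranking gains (rank in control − rank in tagged sample), and selects candidates as (tagged-only proteins) ∪ (shared proteins with gain ≥ threshold). |
| `allelotype` | `xcikit.allelotype` | Padlock SNP-capture allelotyping: zeroes per-allele counts below a detection floor, keeps SNPs detected in every required sample, aggregates counts per gene, drops escapees, and scores `log10((count_129 + 10)/(count_cast + 10))`. |
| `atac` | `xcikit.atac` | Chromatin-compaction scoring from ATAC insertion sites: distinct sites per 1-Mb bin ("cut counts"), depth normalization by non-chrX uniquely aligned reads, compaction score = (uninduced + 1)/(induced + 1) per bin, and transcribed/intergenic bin categorization. |
| `shape` | `xcikit.shape` | Mutational-profiling reactivity with a single vehicle control: per-position mutation rates from aligned reads (end-trimming, mismatch/indel events), reactivity = treated − control rate, profiled-position depth filter (> 10 000 reads in every sample), positive calls (rate > 0.1 %), and PCA of reactivity profiles. |
| `decay` | `xcikit.kinetics` | Transcript decay after transcription blockade: qPCR Cq normalization, first-order exponential fits with half-life = ln 2 / k (log-linear or nonlinear), optional t₀ exclusion, two-phase fitting around a breakpoint, and the ±Dox cell-survival ratio. |
| `simulate` | `xcikit.synthetic` | Generators for all five input types (heavy-tailed MS scores with planted binders, beta-binomial allelic counts with skew classes, Poisson insertion sites with per-bin compaction factors, binomial mutation events over a true reactivity profile, noisy first-order decay) with JSON ground-truth sidecars. |

Shared infrastructure lives in `xcikit.io` (schema-validated TSV/BED/SAM/JSON
readers and writers with line-precise errors) and `xcikit.pipeline`
(stage runners with provenance JSON and deterministic seeded outputs).

## CLI

All stages are exposed under one command, `xci`:

```bash
# generate a labelled synthetic dataset for any stage
xci simulate --stage interactome --seed 1 \
    --params '{"n_background": 100, "n_true_binders": 10, "n_unique": 5}' \
    --out-dir sim/

# candidate selection from two protein-score tables
xci interactome --flag sim/flag.tsv --empty sim/empty.tsv --gain-threshold 11

# gene allelotyping from SNP allelic counts
xci allelotype --counts counts.tsv --escapees escapees.txt \
    --min-reads 10 --pseudocount 10 --log-base 10

# compaction scores from insertion-site BEDs
xci atac --uninduced u.bed --induced i.bed --chrom-sizes cs.tsv \
    --uninduced-total 10000000 --induced-total 9000000 --bin-size 1000000

# reactivity / profiled positions / positive calls / PCA
xci shape --samples samples.json --min-depth 5000 \
    --profiled-depth 10000 --threshold 0.001

# decay fits and half-lives
xci decay --input decay.tsv --two-phase --breakpoint 1
```

`xci shape` takes a JSON config listing samples:
`{"transcript_length": L, "samples": [{"label", "condition":
"treated_1M7"|"control_DMSO", "path", "format": "tsv"|"sam", "offset": 0},
...]}`. TSV sample files are per-position `position depth events` tables;
SAM files are counted directly (mismatch/indel CIGARs, end trimming).

Conventions: BED coordinates are 0-based half-open; transcript positions
are 1-based; every run writes a `*.provenance.json` with parameters,
package version and input digests; identical seed and configuration give
byte-identical outputs.

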