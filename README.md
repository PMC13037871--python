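# paleomt

Ancient mitochondrial DNA analysis for serially sampled hominin data:
damage-aware consensus calling, diagnostic-SNP phylogenetic placement of
incomplete genomes, mtDNA diversity comparison, tip-to-root temporal
regression, and spatiotemporal analysis of dated archaeological locality
tables. A synthetic-data module simulates every input the pipeline consumes
— coalescent time trees, strict-clock sequence evolution, deaminated
short-read fragments, dated localities — so every stage runs and is testable
with no downloads.

## Who this is for

Researchers working with ancient mtDNA capture data (palaeogenetics,
molecular anthropology) who need a reproducible route from aligned ancient
reads to consensus genomes, phylogenetic assignment, and rate/age estimates,
and archaeologists analysing spatiotemporal patterns of dated site
assemblages (time slicing, density hotspots, rarefied geographic spread).

## What it computes

**Consensus from damaged reads.** Ancient DNA carries post-mortem cytosine
deamination, visible as C→T mismatches concentrated at 5' fragment ends
(and G→A at 3' ends under single-stranded library chemistry). Fragments
with such mismatches in the terminal 3 positions are classified as
authentically ancient. If the sample's present-day contamination estimate
exceeds 10%, only those deaminated fragments are used. Putatively deaminated
positions are masked (quality 0), sub-Q20 termini trimmed (≤3 bp per end),
and a base is called at a position only when ≥3 independent (deduplicated)
fragments cover it and ≥65% agree; otherwise N. Coordinates are 1-based and
circular on the 16,569-bp rCRS.

**Dataset curation.** Sequences with >2,600 unresolved positions (<85%
complete) are excluded; within-site duplicates (no variable site among
mutually resolved positions, transitive closure) are pruned to one
representative; the D-loop (16,024–16,569 ∪ 1–576) can be trimmed for
coding-region analyses; alignment columns are filtered by complete or
partial-*p* site deletion.

**Diagnostic-SNP placement.** Given a reference alignment and a rooted tree
with an outgroup, Fitch parsimony assigns each variable column's origin to a
branch; single-origin columns become node-defining SNPs (derived allele
carried by exactly that node's descendants). An incomplete query is walked
from the root toward the tips, descending while its derived-allele support
outweighs opposing evidence; calls that could themselves be deamination
products (T at C↔T sites, A at G↔A sites) are omitted.

**Diversity comparison.** Pairwise mismatch counts under pairwise deletion,
within-site vectors vs a branch-wide vector, two-sided Wilcoxon rank-sum
(exact for small samples) with Benjamini–Hochberg adjustment across sites.

**Temporal signal.** Root-to-tip distance d_i regressed on sampling age a_i
(years BP): d_i = β₀ + μ·(−a_i) + ε_i. Under a strict clock the slope μ̂
estimates the substitution rate (subs/bp/year), the x-intercept estimates
the root age, and undated tips get molecular ages by inverting the fitted
line with prediction intervals.

**Spatiotemporal analysis.** Localities with date ranges ≤30 ky are assigned
to all overlapping 10-ky slices; Gaussian KDE density surfaces; local
Getis–Ord Gi* hotspot z-scores on gridded counts (binary distance-band
weights, self-inclusion):

    Gi* = (Σⱼ wᵢⱼxⱼ − x̄ Σⱼ wᵢⱼ) / (S·√[(n Σⱼ wᵢⱼ² − (Σⱼ wᵢⱼ)²)/(n−1)])

with label-shuffling permutation tests of per-slice hotspot area, and
rarefaction of longitudinal spread (downsampling slices to a common n and
comparing full range, central-95% range, and 2° bin occupancy).

## Worked example

Simulate a damaged 20× read set from a random 16,569-bp genome, then call a
consensus as for a contaminated sample (15% contamination estimate, above
the 10% gate):

```bash
paleomt simulate reads --length 16569 --damage 0.35 --coverage 20 --seed 2 \
    -o fragments.tsv --genome-out genome.fasta
paleomt consensus --fragments fragments.tsv --reference genome.fasta \
    --contamination 0.15 --threshold 0.10 -o consensus.fasta
```

    completeness 0.8884 (1849 N), gate deaminated_only

The gate kept only the 1,485 deaminated fragments of 5,523 (27%), dropping
mean depth to ~5×, so 11% of positions fail the ≥3-fragment / ≥65% rule and
are reported as N — the expected cost of the deaminated-only path.

Rarefaction of longitudinal spread between two simulated time slices
(baseline 60 localities over 30° of longitude, target 150 over 45°,
downsampled to n=60, 1,000 replicates):

```bash
paleomt simulate localities --slice 80,70,60,5,30 --slice 70,60,150,8,45 \
    --seed 1 -o localities.csv
paleomt rarefy --localities localities.csv --baseline 80-70 --target 70-60 \
    -n 60 --reps 1000 --seed 1 -o rarefaction.json
```

    full_range: baseline 28.60, rarefied median 43.30, p=0.000999
    central95_range: baseline 27.47, rarefied median 41.51, p=0.000999
    occupied_bins: baseline 14.00, rarefied median 21.00, p=0.000999

At equal sample size the younger slice's longitudinal spread is genuinely
broader (43.3° vs 28.6° full range; p = 1/1001, the smallest value 1,000
replicates can report) — the spread difference is not a sample-size
artifact.

A full end-to-end run over all stages with one seed:

```bash
paleomt run --outdir demo_run --seed 1
```

writes per-stage outputs and a `report.json` with parameters, seeds, and
SHA-256 checksums of every file; identical configs reproduce byte-identical
reports.

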