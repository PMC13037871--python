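# Methods

This note documents the models, rules, and numerical choices behind
`paleomt`, in the order the pipeline runs them, together with what the
synthetic-data generators do and do not emulate.

## Synthetic data

### Serial-sample coalescent trees

`simulate_tree` draws tip ages uniformly on a configurable interval (years
before present) and runs a constant-population serial coalescent backward in
time: lineages enter at their sampling age and each pair of active lineages
coalesces at rate 1/N, with N (`pop_size`, default 50,000 years) the
population-size parameter expressed directly on the time axis (effective
female population size × generation time). The default is in the range
implied by small hominin mtDNA effective sizes (roughly 1,000–5,000 females
× ~29 y/generation) and yields root ages of a few hundred thousand years
for tips sampled at 40–120 ka. Trees are binary, rooted, with branch
lengths in years and an `age` attribute on every node.

For placement experiments, `add_outgroup` attaches an external tip above
the ingroup root (stem equal to the root age by default), mirroring the
practice of rooting an ingroup phylogeny with a distant reference
sequence; outgroup-based polarisation requires a lineage outside the
ingroup, which no coalescent tip can provide.

### Sequence evolution

`evolve_sequences` evolves a root sequence (drawn from the stationary
frequencies) down the time tree under JC69 or TN93. The rate matrix is
normalised to one expected substitution per site per unit branch "distance",
and per-branch distance is `rate × branch_length_years`, so `rate` is the
substitution rate at variable sites in subs/bp/year. A fraction
`invariant_fraction` of sites is drawn once per simulation and never
substitutes; the realized genome-wide rate is therefore
`rate × (1 − invariant_fraction)`. Transition matrices come from the
eigendecomposition of the rate matrix (clipped to [0, 1] and row-renormalised
against rounding). Defaults: TN93 with κ₁ = 4 (A↔G), κ₂ = 8 (C↔T) and base
frequencies (0.31, 0.31, 0.13, 0.25), a transition-heavy, C-rich
composition of the human mtDNA kind; the dating rate defaults to
1.57 × 10⁻⁸ subs/bp/year.

The simulation records every node's sequence and the realized substitution
count per branch. `realized_substitution_tree` converts these counts into a
tree with branch lengths in realized subs/bp — the simulation analogue of a
perfectly reconstructed parsimony tree, used by the clock-recovery
experiments. At the divergences involved (~5 × 10⁻⁴ subs/site per branch)
the difference between realized events and observed differences (multiple
hits) is O(10⁻⁷) relative and is ignored.

No indels, no recombination (mtDNA is non-recombining), no selection, no
rate heterogeneity beyond the invariant class.

### Fragmentation and damage

`fragment_and_damage` shears a genome into fragments with log-normal
lengths (mean 60 bp, sd 15 bp — typical ancient-DNA fragment scale),
uniform circular start positions, and a fragment count set so expected
coverage equals the target. Endogenous fragments receive single-stranded
library damage: C→T with probability `p_ct_5p × decay^i` at distance *i*
from the left (5') end and the mirrored G→A from the right (3') end
(defaults `p_ct_5p` = 0.30, within the empirically observed 10–58% terminal
range; `decay` = 0.5). In reference orientation the pattern is identical
for both strands, which is why the classifier checks C→T and G→A at both
ends. Contaminant fragments (probability `contamination_frac`) are faithful
substrings of a present-day contaminant genome aligned to the same
coordinates, with no damage — exactly the asymmetry the deamination filter
exploits. Base qualities are a constant high value (Q40) with a
configurable quality at damaged positions, so quality structure does not
confound the damage-filter logic under test.

Not emulated: sequencing error, mapping error and reference bias, UDG
treatment profiles, indels, strand-specific library asymmetries, and
coverage biases (GC, capture efficiency). Consensus-recovery results on
synthetic data therefore isolate the damage/contamination logic and say
nothing about mapping artifacts in real data.

### Locality tables

`simulate_localities` realizes per-slice locality counts with uniform or
clustered longitudes of stated width, uniform latitudes in a band, and date
ranges drawn strictly inside their slice window (so slice membership under
the overlap rule reproduces the scenario exactly). Real archaeological
records add research-history and preservation biases, spatially correlated
discovery, and dating uncertainty structure that the generator does not
model; spatial tests passing on synthetic data show correctness of the
statistics, not robustness to survey bias.

## Read processing and consensus

A fragment is *deaminated* if it has a C→T or G→A mismatch within 3
positions of either end (window configurable). If the sample's
contamination point estimate is ≤ 0.10 all fragments are used; strictly
above, only deaminated fragments ("above 10%" is read as strict). All
deamination-type mismatch positions are then masked by setting quality 0 —
masked bases count toward neither depth nor agreement, which realises
"lowering" their quality as outright exclusion of the evidence. Up to 3
consecutive sub-Q20 positions are trimmed from each end (cap applies even
if more are low-quality). Fragments identical in (start, end, strand) are
PCR duplicates and count once.

Consensus: at each of the 16,569 circular reference positions, the modal
base is emitted iff depth ≥ 3 and the modal fraction is ≥ 0.65 (inclusive
threshold, with a 10⁻¹² tolerance against binary-float artifacts) and the
mode is unique; otherwise N. Masking happens before tallying, including at
non-terminal positions. The monotonicity property holds: adding a fragment
supporting the current modal base can never turn a call into N.

Because masking removes every T-at-C and A-at-G observation, no position
can be *called* with a deamination product as the modal base; damage can
only cost completeness (N), not correctness. This is the structural reason
the damage-error rate at called positions is exactly zero in the recovery
experiments.

## Curation

Completeness: sequences with more than 2,600 Ns (< 85% of 16,569) are
excluded, boundary inclusive at 2,600. Duplicates within a site are
sequences with no variable site among mutually resolved positions; classes
are the transitive closure of this (non-transitive) relation — conservative
and deterministic — and the representative is the member with fewest Ns
(ties: lexicographically first id). The D-loop defaults to rCRS
16,024–16,569 ∪ 1–576 (leaving 15,447 coding columns) and is configurable;
published analyses' exact considered-position counts depend on their
specific alignments and are not constants of this package. Site deletion:
`complete` keeps columns resolved in all rows; `partial(p)` keeps columns
with resolved fraction ≥ p (inclusive, MEGA convention), default p = 0.90.

## Diagnostic SNPs and placement

Fitch parsimony runs on the fixed rooted tree (bitmask state-sets,
vectorised over columns; ambiguous bases are full sets). The root state is
pinned to the outgroup's state whenever compatible; the top-down pass
prefers the parent's state, making the reconstruction deterministic.
Columns with one inferred origin yield a diagnostic SNP on the origin
branch's child node; multi-origin columns are emitted flagged homoplasic
and are excluded from placement. A SNP is damage-susceptible iff its two
alleles are C/T or G/A, regardless of strand, because a consensus mixes
strands.

Placement walks from the root: at each step every child is tallied over its
diagnostic SNPs (derived / ancestral / missing / conflicting-third-base).
With `omit_damage` (default), a site is omitted only when the query's own
call could be a deamination product — T at a C↔T site or A at a G↔A site; C
and G calls cannot arise from deamination and remain informative. The walk
descends into the child with the most derived matches among children whose
derived count strictly exceeds ancestral + conflicting; it stops when no
child qualifies, and reports "unresolved" if it never leaves the root. A
child whose branch carries no diagnostic SNP at all is undefined by the
data and cannot be distinguished from its parent; the walk treats it as
transparent and evaluates its children in its stead. Confidence is "full"
when every accepted step had ≥ 2 derived matches and no conflicts,
"tentative" otherwise.

Placement accuracy is scored as on-path recovery: an assignment is correct
if it is the true node or a lineal ancestor of it (stopping early on the
true path is a resolution loss, not an error; overshooting or placing
off-path is an error). On reference panels where internal nodes carry tens
of diagnostic sites, ≥ 95% of queries with 30% missing data and residual
deamination are recovered on-path, the large majority exactly or at the
parent. Nodes defined by only 1–3 sites are frequently skipped at 30%
missingness — an information-theoretic floor, not an implementation limit.

## Diversity

Distances are raw mismatch counts among mutually resolved positions
(pairwise deletion), with the count of compared positions reported
alongside. Within-group vectors use all unordered pairs. The rank-sum test
uses the exact Mann–Whitney distribution when there are no ties and
n+m ≤ 25; with ties it enumerates all C(n+m, n) splits whenever that count
is ≤ 200,000, defining the two-sided p as P(|W − μ| ≥ |w − μ|) under the
permutation distribution (the distribution need not be symmetric under
ties); otherwise it uses the tie-corrected normal approximation with
continuity correction. Adjustment across sites defaults to
Benjamini–Hochberg; Bonferroni is a flag.

## Temporal signal

OLS of root-to-tip distance on −age, so the slope is the substitution rate
forward in time and the x-intercept the root age. Ages are years before
present, positive into the past. The root is an input (no root
optimisation), distances are per-bp by default. Undated tips get ages by
inverting the fitted line; the interval propagates residual variance plus
coefficient covariance through the inversion by the delta method with
t-quantiles at n−2 df (valid when the slope is clearly positive). Two dated
tips give the exact interpolating line with undefined intervals. On
strict-clock data with Gaussian noise, empirical coverage of the 95%
intervals is within 5 points of nominal at 500 replicates.

The clock-recovery experiment (also `scripts/acceptance.py`) uses 100
replicates of 30 tips (ages 40–120 ka), 15,000 bp, TN93 without invariant
sites at the default dating rate, with per-replicate seeds derived from one
master seed. The mean recovered slope is unbiased with Monte-Carlo SE ≈ 3%
(per-replicate slope sd ≈ 29%, dominated by shared-branch coalescent
noise, not by the Poisson substitution noise).

## Spatiotemporal statistics

Slices are 10-ky windows anchored at multiples of the window width; a
record belongs to every slice its date range overlaps (interval (end,
start]), the reading under which a 75–55 ka record evidences presence in
each of 80–70, 70–60, 60–50; midpoint assignment is available for
sensitivity analysis. Records with ranges > 30 ky are dropped first.

KDE is a plain Gaussian kernel on planar degrees, unit mass per point,
bandwidth by Silverman's rule averaged over the two axes unless given.
Degrees are not great-circle distances; at European latitudes the
longitudinal compression (~cos 45° ≈ 0.7) is absorbed into the bandwidth
choice, and all comparisons are within the same grid.

Gi* uses binary weights within a Euclidean distance band (default 3 cells)
with self-inclusion, on gridded counts (default 1° cells), computed by
convolution: z = (Σwx − x̄Σw) / (S·√[(nΣw² − (Σw)²)/(n−1)]). A
zero-variance field is defined as all-zero z. The analytic variance equals
the exact permutation (values-among-cells) variance, which is what the
Monte-Carlo cross-check verifies. Row-standardised weights and torus
wrapping exist for property checks.

The structured permutation test reshuffles slice labels over the pooled
locality locations (preserving per-slice counts) and compares each slice's
observed statistic with its null distribution, p = (1 + #{null ≥ obs}) /
(reps + 1). The statistic is lexicographic: (primary integer, max |z|). The
primary is the count of |z| ≥ 1.96 cells (hotspot area, default) or the
number of localities in those cells (`statistic="points"`). The continuous
secondary exists because the integer primary is heavily tied, which would
make the smoothed p conservative and miscalibrated; with tie-breaking the
p-value is discrete-uniform under the exchangeable null (measured type-I
error 0.043 at α = 0.05 over 500 null datasets). Because Gi* z-scores are
nearly scale-invariant, the hotspot-area statistic has essentially no power
against *within-slice concentration* (a label-shuffled mixture inherits the
same significant-cell footprint); the points-in-hotspot-cells statistic is
the one to use for that alternative, and the `alternative` flag
(more/less/two_sided) selects the comparison direction.

Rarefaction deduplicates localities by site id, samples n (default 60)
without replacement from the target slice, reps (default 1,000) times, and
reports medians of full longitude range, central-95% range (97.5th − 2.5th
percentile), and occupied 2° longitude bins on a fixed grid anchored at
−180°, plus one-sided p = (1 + #{replicate ≤ baseline}) / (reps + 1)
against the "target broader than baseline" alternative. The degenerate
self-comparison (target = baseline, n = |baseline|) reproduces the baseline
metrics exactly in every replicate.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed and is a pure function of
(parameters, seed); pipeline runs write a report with parameters, seeds and
SHA-256 checksums of all outputs, and identical configurations give
byte-identical reports. The test suite's simulation sizes (e.g. 50 genomes
at 20× for consensus recovery, 200 queries for placement, 500 null datasets
for permutation calibration, 100 replicates for clock recovery) were chosen
as the smallest designs whose Monte-Carlo error is comfortably below the
tolerance being checked.

## Known limitations

- No likelihood-based placement or tree search; the reference tree is an
  input and placement resolution is bounded by the diagnostic-SNP density
  per node.
- Contamination estimation itself is out of scope; the estimate is consumed
  as an input (the gate's behaviour, not the estimator, is tested).
- Planar-degree geometry throughout the spatial stack; no basemap
  rendering, no niche modelling.
- The Bayesian side of molecular dating (posterior node ages, HPD
  intervals, skyline population sizes) is deliberately not reimplemented;
  the regression provides the frequentist temporal-signal check only.
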