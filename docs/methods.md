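# Methods

`topotx` analyses genome-wide transcriptional changes in budding-yeast
topoisomerase mutants (*top1Δ*, *top2ts*, *top1Δtop2ts*) relative to wild
type, in the regime where the mutation shifts the **total** amount of mRNA
per cell.  This note records the models, conventions and numerical choices
behind every stage, and what the synthetic-data generator does and does not
emulate.

## Spike-in-anchored normalization

Conventional per-array normalization (total-intensity or quantile scaling)
assumes equal total signal per sample and therefore erases a genuine global
expression shift.  When exogenous spike-in RNAs are added per equal cell
number before extraction, the spike-in block carries the per-cell unit
across arrays and the shift is preserved.

The anchor is a median-of-ratios fit: for spike-in row *i* and array *a*,

    ref_i     = geometric mean over arrays of spike_ia
    factor_a  = median over spike rows i of ( ref_i / spike_ia )

and normalized intensities are `raw × factor_a`.  The median makes the fit
robust to individual aberrant spike-ins; the geometric-mean pseudo-array is
symmetric in the arrays.

**Scale equivariance.** Multiplying all rows of one of *K* arrays by *c*
rescales every normalized entry by the common factor *c*^(1/*K*) (the scaled
array's factor absorbs the remainder of *c*).  An absolute anchor estimated
from the arrays themselves necessarily moves when one array is rescaled, so
matrix-level identity under rescaling is unattainable for any internal
anchor; what holds exactly — and what the tests assert — is that every
derived ratio statistic (factor ratios, global mRNA level, signal log2
ratios, deregulated fractions away from the detection-floor boundary) is
invariant, and that the matrix shift is exactly the predicted *c*^(1/*K*).

**Derived statistics.**

- *Global mRNA level*: 100 × (mean mutant total of normalized non-spike-in
  signal) / (mean wild-type total), restricted to genes detectable in
  wild-type (mean normalized intensity ≥ the detection floor, default 1
  intensity unit).  Per-replicate values give an SD bar.  Wild-type against
  itself is exactly 100.
- *Signal log2 ratio (SLR)*: mean over replicates of log2(max(I, floor)),
  mutant minus wild-type, replicates unpaired (strains are arrested and
  hybridized independently); the standard error combines the two replicate
  variances under independence.
- *Deregulated fractions*: the share of detectable genes with SLR at or
  beyond cutoffs — symmetric ±1 (2-fold) and the asymmetric +0.5/−1 pair
  are both reported — with a standard error over per-replicate fractions.

## Trend analysis

Expression changes are related to per-gene covariates (wild-type abundance,
transcriptional activity, transcript length, plasticity) as a **200-gene
moving average**: genes sorted by the covariate ascending, ties broken by
gene id, trailing windows of exactly 200 genes with step 1 and no edge
padding (n − 199 points).  The dialect (trailing, step 1) is recorded in the
run manifest.

Association strength is the Pearson correlation with a **two-sided
permutation p-value** obtained by permuting the response: when n! ≤ n_perm
all permutations are enumerated and p is exact (the identity permutation
counts, so p > 0); otherwise n_perm seeded permutations give the add-one
estimate (1 + #{|r_perm| ≥ |r|}) / (n_perm + 1).

Extreme transcript-length groups (< 0.5 kb vs > 4.5 kb) are compared with a
two-sided Wilcoxon rank-sum test using midranks for ties: exact enumeration
of all label assignments for combined n ≤ 12 (the symmetric deviation
|U − E[U]| defines two-sidedness, which stays valid under ties), and the
normal approximation with continuity and tie correction above that.  At the
boundary (n = 12) the approximation agrees with enumeration to within about
0.02.

Quartile-stratified curves re-run the moving average of SLR against
plasticity inside wild-type-abundance quartiles (quartile 1 = highest
abundance; ties go to the lower quartile index).

**Monotonicity assessment.** Adjacent step-1 windows share 199 of 200 genes,
so the sign of their difference is dominated by single-gene noise; when a
trend curve is tested for monotone decrease, the comparison uses curve
points at non-overlapping strides (every 200th point), where the planted
drift dominates the window-mean noise.

## Derived gene features

- *Transcriptional activity* = wild-type mRNA abundance / mRNA half-life
  (a synthesis-rate proxy), median-normalized over genes with both
  covariates; genes with missing or non-positive half-life are excluded with
  a per-gene reason.  Normalized wild-type intensities are used for the
  abundance term.
- *Responsiveness to environmental change* = per-gene mean of squared log2
  expression ratios across a 173-condition stress compendium, then
  standardized to mean 0, sd 1 across genes.  *Transcriptional plasticity*
  is the identical statistic on a larger profile collection.  Convention
  choices (both recorded in the manifest): missing entries are ignored per
  gene (genes more than 50% missing are dropped), and standardization uses
  the sample sd (n − 1) applied to the final per-gene means — the source
  convention is ambiguous between standardizing before or after per-gene
  averaging, so the choice is declared rather than asserted.
- *Telomere distance* = min(TSS, chromosome length − TSS).
- Group comparisons use the unpaired pooled-variance two-sample t-test
  (df = nA + nB − 2), one-sided only where a directional hypothesis is
  stated (e.g. higher responsiveness of deregulated genes), two-sided
  otherwise.

## Enrichment and the profile screen

Set overlaps use the upper-tail hypergeometric probability P(X ≥ k)
(enrichment only; depletion untested), evaluated through the log survival
function.  Flat category enrichment reports categories passing a raw
p ≤ 1e-3 cutoff — mirroring stringent-raw-cutoff practice — with a
Bonferroni column for transparency; the universe defaults to all annotated
genes and is overridable.

The most deregulated genes of a vector are those at or beyond the 5th/95th
rank percentiles, ties included on the extreme side (the set may exceed its
nominal 10%; an all-equal vector returns every gene with a warning).  The
profile screen joins the SLR vector with each library profile by gene id
(≥ 100 shared genes required), reports Pearson R with the permutation P, and
the hypergeometric overlap P_o between the two percentile-deregulated sets
over the joined universe; results are sorted by P then P_o, with an optional
Benjamini–Hochberg column.

## Nucleosome meta-profiles

A binned occupancy track (bedGraph, 0-based half-open bins) is re-anchored
at each gene's TSS: plus-strand genes take the bins covering
[TSS − 500, TSS + 500), minus-strand genes take the mirror window reversed,
so negative offsets are biologically upstream for every gene.  Genes whose
window leaves the chromosome are dropped (no padding — padding biases group
means).  Group meta-profiles report the per-offset mean with a
t-distribution 95% CI (honest width at group size 100).

The nucleosome-free region (NFR) is the window [−200, 0) bp upstream of the
TSS by default — the source map's exact coordinates are not published, so
the window is configurable and recorded in the manifest.  Per-gene NFR
occupancy (mean over the window) is compared between the 100 most
down-regulated / most up-regulated / most unaffected genes (ranked by SLR,
ties by gene id, groups disjoint with priority down > up > unaffected) using
the same pooled t-test implementation as the feature comparisons.

## qPCR quantification

Quantities follow `quantity = efficiency^(−Ct)` on triplicate-averaged Ct
values with perfect efficiency 2.0 by default (one cycle = one doubling);
standard-curve efficiency estimation is out of scope and the efficiency is a
parameter.  ChIP fold enrichment is (IP/background at the target region) /
(IP/background at a control locus); the control-locus division cancels any
global Ct offset exactly.  Time courses are normalized to the 0-min point
(set to 1), to a reference series' latest point (set to 100%), or to a named
reference value; the raw fold increase (last/first) is reported alongside.

## The synthetic-data generator

The generator plants known structure in every input so each stage can be
tested against ground truth.  Defaults define the study conditions and are
not tuned per test:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_spikeins / n_replicates | 6000 / 96 / 3 | study shape; spike-ins span 3 decades |
| global_scale | 0.7 | double-mutant total mRNA relative to wild type |
| activity_effect | −0.5 | log2 SLR per unit activity rank, mean-centered |
| frac_affected / up_share | 0.2 / 0.15 | deregulated class size; share up-regulated |
| up_offset / down_offset | +2.0 / −1.0 | class log2 offsets |
| bio_sd / noise_sd | 0.25 / 0.1 | per-gene biological scatter; per-measurement log2 noise |
| n_conditions | 173 | compendium size; response sd 1.0 (affected) vs 0.2 |
| nfr_depth_affected / _unaffected | 0.5 / 0.2 | planted NFR occupancy levels (difference 0.3) |
| bin_size / track_noise_sd / nfr_jitter_sd | 10 bp / 0.1 / 0.1 | occupancy track resolution and noise |

Design choices:

- **Planted SLR.** Every gene carries a mean-centered activity-rank term
  (`activity_effect × (rank/(n−1) − 0.5)`), giving the genome-wide negative
  activity trend; affected classes add fixed log2 offsets; a per-gene
  N(0, bio_sd) scatter makes the genome-wide correlation weak (|r| ≈ 0.15 at
  defaults), as in real data where most SLR variance is not activity-linked.
  Centering keeps `global_scale` the planted total-mRNA ratio.  The stored
  ground-truth SLR includes the log2 of the global scale, so it equals the
  spike-in-normalized SLR exactly at zero noise.
- **Class assignment** is deterministic and stratified over the activity
  ranking (every ~1/frac-th rank), so classes are reproducible across runs
  yet abundance-representative: dependency correlates with plasticity, not
  with being highly expressed, and the deregulated class does not dominate
  the total-signal estimate.
- **Noise** is multiplicative log-normal on intensities (log2-scale sd),
  matching the downstream log2-ratio analysis.
- **Spike-ins** are 96 rows log-spaced over three decades with
  class-independent per-cell expectations — a stand-in panel; the real
  kit's composition is not modeled.
- **Nucleosome track.** Each gene owns a stereotyped profile: baseline 0.6,
  flat NFR in [−250, 0) at its class's depth (plus per-gene jitter), and
  periodic peaks downstream (period 165 bp); minus-strand genes are
  mirrored.  The template is closed-form, so group differences have exact
  expected values.
- **Compendium** entries are N(0, sd_class) per gene × condition;
  a separate small profile library plants two noisy linear images of the
  double-mutant SLR among null profiles for screen positives, and synthetic
  flat categories include two affected-class-biased sets for enrichment
  positives.
- **qPCR**: Ct = offset − log2(quantity) + N(0, sd) per well, triplicate
  wells; ChIP target/control quantities are constructed so the normalized
  fold equals the planted trajectory exactly at zero noise.

What the generator does **not** emulate: probe-level effects and
summarization, cell-cycle structure, sequence content, correlated
condition blocks in the compendium, spatial autocorrelation of occupancy
beyond the per-gene template, and inter-replicate batch effects.  Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to those real-data features.

## Determinism and problem sizes

All randomness flows from a single integer seed through per-stage seed
sequences; identical configurations give bit-identical outputs, and the run
manifest (configuration echo, dialect decisions, SHA-256 checksums of every
written file) suffices to re-run a study checksum-identically.

Test and demo problem sizes are the study defaults (6,000 genes) for
end-to-end checks; calibration sweeps use 100 seeded replicates at full
size, and the permutation-null uniformity check uses 1,000 small (120-gene)
datasets with 199 permutations each, sizes chosen to give stable pass/fail
margins (e.g. the Kolmogorov–Smirnov distance of 1,000 uniform p-values has
~0.027 expected deviation against the 0.05 bound).

## Known limitations

- The normalization anchor is this package's explicit substitute for the
  original study's unpublished external-normalization procedure and is
  labeled as such in reports.
- Percentile deregulation with heavy ties can select far more than 10% of
  genes; downstream overlap tests remain valid but less powerful.
- The exact rank-sum enumeration is O(C(n, nA)) and is capped at combined
  n = 12; beyond that the continuity-corrected normal approximation is used.
- Pearson correlations on raw (heavy-tailed) covariates understate monotone
  association; the moving-average curves are the primary display and the
  correlation is reported as a summary only.
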