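# Methods

This note describes the statistical models and procedures implemented in
`hicdiffkit`, the choices made where a convention had to be fixed, and
what the synthetic validation does and does not demonstrate.

## Contact matrices and normalization

All analyses operate on per-chromosome symmetric count matrices at a
fixed bin size (25 kb by default). Bins with a zero raw marginal are
masked as unmappable and propagate as *undefined* (NaN) through every
downstream statistic — never as zeros.

Two normalizations are provided. **VC_SQRT** divides each entry by the
square root of the product of its row and column marginals (computed over
valid bins) and then rescales so the total count is preserved; the
rescaling convention is arbitrary because every downstream comparison is
a ratio or log-difference. **Per-chromosome total scaling** multiplies a
matrix so its total matches a target, which is how samples sequenced to
different depths are made comparable before any between-sample statistic.
A consequence worth remembering: after per-chromosome scaling, "increase"
and "decrease" are relative statements — a genuine loss of short-range
contact mass reappears as an apparent long-range gain.

**Observed/expected (OE)** divides each entry by the mean of its diagonal
(distance class) over valid pairs; distance classes with zero mean yield
undefined entries. **Compartment PC1** is the leading eigenvector of the
Pearson correlation matrix of the OE map over valid bins (a direct OE
eigenvector is available as an option; the correlation form is the
default because it is the more widely reproduced convention). The
eigenvector sign is arbitrary, so the track is oriented to correlate
non-negatively with a user-supplied activity proxy (e.g. active-mark
coverage per bin); positive values then denote the active A compartment.
Bins are divided into four classes — StrongA/WeakA at the median of the
positive PC1 values, StrongB/WeakB at the median of the negative values —
a parameter-free rule chosen because no published threshold exists for
the strong/weak split; it is exposed as a configuration point.

## Multi-scale insulation and boundary typing

The insulation score at distance *d* and bin *i* is

    IS_d(i) = log2( mean of C over rows (i-w..i-1) x cols (i+1..i+w)
                    / chromosome-wide mean of the same sliding statistic ),

with *w = d / resolution*. The sliding square excludes bin *i*'s own row
and column; the exclusion is configurable since published descriptions
leave it open. Scores are undefined where the square leaves the
chromosome. The chromosome-mean reference makes the score invariant to
global scale, and the sign convention is fixed so that **higher IS means
more cross-position contact, i.e. a weaker boundary**: a score *increase*
after a depletion marks a *lost* boundary. The 500-kb distance is the
single-score default used for classification; the multi-scale profile
spans 100 kb to 1 Mb in 25-kb steps.

Boundary typing compares each depletion's 500-kb score to control at the
boundary's midpoint bin (midpoint mapping is symmetric and is the package
convention where an interval spans several bins) and applies, in order,
with threshold T_ins = 0.13:

1. dNIPBL > T and dCTCF > T       -> all-dependent
2. dNIPBL > T or  dRad21 > T      -> cohesin-dependent
3. dCTCF > T                      -> CTCF-dependent
4. -dCTCF > T                     -> CTCF-separated
5. -dNIPBL > T or -dRad21 > T     -> cohesin-separated
6. otherwise                      -> robust

The branches are ordered and exhaustive; the final branch is implemented
as a plain else (the printed form of the rule contains a redundant
repeated clause that is mathematically equivalent to else given branch
order). Samples beyond the four required conditions are ignored by the
rule. Boundaries on chrX, chrY and chrM are excluded, and boundaries
whose bin has an undefined score in any required sample are dropped and
counted.

## Directional relative frequency (DRF)

For a treatment and control matrix under the same normalization, the
relative interaction frequency is the natural-log ratio
M = ln C_treat - ln C_ctrl, undefined wherever either entry is zero or
masked. The DRF of bin *i* sums M over a downstream distance band minus
the same band upstream:

    DRF_i = sum_{j=jmin..jmax} M[i, i+j] - sum_{j=jmin..jmax} M[i, i-j]

with the band spanning l_min = 500 kb to l_max = 2 Mb by default.
Undefined terms contribute zero, but a bin is voided when the defined
fraction of either sum drops below `min_valid_fraction` (default 0.5) or
the band leaves the chromosome. Natural log is the default reading of
the unadorned "log" in the definition; the threshold below is interpreted
on the same scale and both are configurable.

Samples are grouped as *cohesin and loaders*, *cohesin unloaders* and
*others* (the last includes control). Per bin and group, the mean DRF
across samples is paired with a Student-t confidence interval at level
0.99 (t is the standard small-n choice; the construction is not otherwise
prescribed). The CI is computed per bin across samples rather than per
region across bins — the per-region reading of the prose is ambiguous and
the per-bin form composes naturally with region merging. A bin is called
differential when (a) the loaders' and others' 99% CIs are disjoint and
(b) the loaders' mean magnitude exceeds T_DRF = 0.7; consecutive
qualifying bins of equal sign merge into regions, with single-bin regions
allowed. No multiple-testing correction is applied across bins,
deliberately mirroring the upstream procedure.

For comparing perturbation profiles, the upper-triangle entries of M
within +/-2 Mb of each differential-region center are vectorized and each
sample pair is scored by cosine similarity over its common defined
support. Because this comparison has no group averaging to cancel
reference noise, it should be computed against a reference whose own
sampling noise is negligible (a deeply merged control); with a noisy
shared reference the common noise component dominates the similarity.

## InterTAD interaction clustering

TADs wider than 100 kb are annotated with a chromatin mark when the
union of the mark's peaks covers strictly more than 40% of the TAD
length. TAD pairs separated by at most 2 Mb (gap measured end-to-start;
center-to-center is an exposed alternative) are scored per sample by
log2(N_treat / N_ctrl), where N is the sum of (normalized, by default)
matrix entries over the rectangle between the two TADs; pairs with a
non-positive sum in any sample are dropped. Pairs are built over the
non-overlapping TAD segmentation so nested domains are not double
counted. The per-pair vectors of fold changes across samples are
clustered with k-means (k = 5 by default, k-means++ with 10 restarts and
a fixed seed); cluster ids are relabeled in decreasing order of the
cluster-mean fold change over the loader samples so the labeling is
deterministic. Cluster composition is reported as the fraction of each
unordered mark-combination pair per cluster, z-scored across clusters
(sample standard deviation; a zero-variance category maps to z = 0).

## Permutation overlap statistics

The permutation test asks whether query elements carry a nearby feature
more or less often than equally sized random draws from a background
containing them. Overlap means >= 1 bp intersection after widening by a
window (0 by default for TSS-style point queries; 50 kb for boundary
queries). Whether an element overlaps a feature is a fixed property of
the element, so the null count of a without-replacement draw of |query|
elements is exactly hypergeometric in the number of feature-carrying
background elements; null counts are therefore drawn from the
hypergeometric distribution directly, which is the same distribution a
literal resampling loop would produce at ~100x the cost. p-values are
two-tailed by doubling the smaller one-sided rank tail, with the +1
correction, so the smallest attainable p is 1/(n_perm + 1) at the default
n_perm = 1000; significance is conventionally read at p < 0.01.

DEG-overlap similarity uses the Simpson index |A∩B| / min(|A|, |B|), and
per-gene up/down/absent sign vectors across depletions are clustered with
k-means (k = 20 by default), relabeled by decreasing cluster size.

## The synthetic genome and its cohort

The simulator composes an expected intensity
lambda = base * (d+1)^-alpha * tad * plaid * loop * stripe and draws
independent Poisson counts on the upper triangle (mirrored). `base` is
set so the expected upper-triangle total — the number of simulated read
pairs — equals `depth`. Poisson noise was chosen over negative binomial
as the minimal count model; an overdispersion knob can be emulated by
pre-scaling factors, and no test depends on dispersion fitting.

The default study chromosome is 20 Mb at 25-kb bins (800 bins): four
alternating 5-Mb A/B compartment blocks (plaid contrast 1.5), twelve
TADs per block with widths 250 kb-750 kb and intra-TAD factor 2, and a
sprinkling of factor-4 corner loops. The condition panel emulates a
cohesin-perturbation screen — control; siNIPBL, siRad21, siMau2
(loaders); siCTCF; siWAPL, siPDS5 (unloaders); siESCO1 — with two
replicates each. Loaders lose eight fixed boundaries (plus three lost
jointly with siCTCF, defining all-dependent) and gain two; siCTCF loses
and gains its own sets; loaders additionally acquire one-sided stripe
depletions over a 1.05-2 Mb downstream band at four anchor regions, and
unloaders carry the inverse (enrichment) at the same anchors.

Ground truth is emitted with the cohort: boundary labels are derived
symbolically from which conditions remove or gain each edge, pushed
through the same six-branch rule; differential-DRF truth intervals are
the planted anchor regions; compartment truth is the block labels.

### Calibration of the default cohort

Several geometric constraints keep the planted effects identifiable and
mutually orthogonal, and they are deliberate design rules rather than
accidents:

- **Depth.** At 25-kb resolution the log-ratio map is undefined wherever
  either sample has a zero count, and with fewer than ~10^6 pairs on a
  20-Mb chromosome most entries of the 0.5-2 Mb band are empty, which
  first voids DRF bins (defined fraction < 0.5) and then biases the
  surviving log-ratios toward zero (Poisson zero-truncation). The default
  depth of 2.5e6 pairs per matrix is roughly a quarter of what the
  original screen's sequencing corresponds to on a 20-Mb chromosome, and
  is the smallest round value at which the DRF calling margins below are
  comfortable.
- **Stripe band start (1.05 Mb).** The 500-kb insulation square reads
  entries up to 1 Mb apart; a stripe band starting beyond that leaves
  every insulation score untouched, so boundary typing and stripe
  recovery can be validated on the same cohort without interference.
- **Removable boundaries between 10-bin TADs.** A removal merges at most
  500 kb, strictly below the DRF band's l_min, so boundary removals have
  no DRF footprint at all.
- **Mirror bands.** A one-sided depletion of rows r over distances
  [d1, d2] necessarily also perturbs the upstream sums of bins r+d1..r+d2
  (each matrix entry belongs to two bins). This "mirror" signature is
  real, with magnitude bounded by the anchor-region width times the
  per-entry log effect. Anchor regions are 5 bins wide and the stripe
  factor is 0.45, putting the mirror plateau well below the CI-disjoint
  detection bar while the anchor-region signal (~60 band terms) stays
  far above it; regions are spaced so no region falls in another's
  mirror band.

With these defaults, across independent seeds the six-type classifier
recovers 100% of planted boundary labels in every class and the
differential-DRF caller achieves bin-level precision and recall >= 0.9
(typically 1.0) against the planted anchors.

### What the synthetic validation does not show

The simulator emulates the *phenomenology* the statistics respond to —
distance decay, block domains, plaid compartments, focal loops, one-sided
band depletions, Poisson counting noise. It does not emulate mappability
gaps and copy-number variation, restriction-fragment structure,
condition-dependent decay-exponent changes, nested TAD hierarchies, or
biological replicate variability beyond counting noise (replicates share
lambda exactly). Passing recovery tests therefore demonstrates
correctness and calibration of the statistics under the stated model,
not robustness to artifacts of real Hi-C libraries — those are the
responsibility of the upstream mapping/balancing stack this package
deliberately does not reimplement.

## Numerical conventions

- Undefined is always NaN; masks mark unmappable bins; no statistic
  silently treats missing as zero except the DRF band sums, which are
  guarded by `min_valid_fraction`.
- Coordinates are 0-based half-open (BED convention); bin index =
  floor(position / resolution); boundary intervals map to the bin of
  their midpoint.
- k-means uses scikit-learn's k-means++ with `n_init=10` and a caller
  provided seed; determinism of reported ids comes from explicit
  relabeling rules (by loader-mean fold change, or by cluster size).
- The t-quantile at per-bin degrees of freedom adapts to how many
  samples are defined at that bin; bins with fewer than two defined
  samples per group are undefined.
- All randomness flows from caller-provided integer seeds through
  numpy `SeedSequence` spawning; derived seeds stay below 2^31.

## Problem sizes used in validation

The bundled validation runs at: 800-bin chromosome, 8 conditions x 2
replicates at 2.5e6 pairs per matrix (boundary and DRF recovery); 100
random 200-bin maps (DRF oracle); 20,000 random delta triples
(classifier exhaustiveness); 1,000 repetitions of a 1,000-permutation
null test (type-I calibration); 10,000 simulated bins with 5 samples per
group (CI coverage). These sizes keep the full validation under a few
minutes on one CPU while leaving the statistical bars meaningful.
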