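# Methods

## Assay model

A droplet digital PCR assay is modelled at two levels.

**Count level.** Each informative droplet independently reads mutant with
probability `p = m + (1 − m)·ε`, where `m` is the sample's true mutant
allele fraction (MAF) and `ε` the per-droplet false-mutant-call rate; the
mutant count over `n` informative droplets is Binomial(n, p). Droplets are
assumed to carry at most one template, so the MAF is read directly off
class counts with no Poisson multi-occupancy correction — consistent with
how the screening assay reports MAF as a droplet-count ratio. The default
error rate, ε = 2.15664 × 10⁻⁵, is the empirical pooled negative-control
rate of the assay family this package models, and the default assay size is
50,000 informative droplets, chosen to make simulated CI widths match the
printed two-decimal intervals of the reference tables (e.g. an 18.8% MAF
with a ±0.3-point CI needs n of this order).

**Intensity level.** For gating work the simulator draws per-droplet
two-channel fluorescence from three cluster centres — NA (1000, 1000),
WT (8000, 1200), MU (1200, 8000) arbitrary units — plus isotropic Gaussian
noise with standard deviation `noise_sd × 7000` (7000 u is the reference
cluster separation; `noise_sd` defaults to 0.05). The count-level sampler
is exactly the binomial marginal of this per-droplet model; whole-cohort
simulation uses it directly because intensities are irrelevant there, and a
test checks the two paths agree in distribution.

Deep amplicon runs (PASM-style, default depth 10,000×) are modelled as
`alt ~ Binomial(depth, m(1−e) + (1−m)e)` with a symmetric per-base error
rate `e` (default 10⁻⁴).

## Confidence intervals and the detection rule

MAF intervals are two-sided exact Clopper–Pearson at α = 0.05, computed
from beta quantiles, with the k = 0 lower bound exactly 0 and the k = n
upper bound exactly 1. Exactness matters in the operating regime (k of
order 0–10, n of order 10⁴–10⁶) where normal approximations fail, and it
is what makes printed zero-count intervals like "0.0 (0.0–0.6)" coherent.
Which interval flavour the original instrument software used is not
documented; exact intervals are the package's documented, conservative
choice, and the test suite pins the implementation to a brute-force
binomial-tail-inversion oracle at 10⁻⁶.

The positive-detection rule is: *mosaic* iff CI lower bound > 0.01% and CI
upper bound < 50.00%, both strict; *het_consistent* iff the upper bound
reaches 50%; *negative* otherwise. Comparisons are made at a fixed decimal
precision (12 places on the fraction scale) so that bounds transcribed from
printed two-decimal percents compare exactly as printed — this reproduces
every borderline call in the reference tables, including a lower bound of
exactly 0.01% being negative. No multiple-testing correction is applied:
the rule is a per-sample instrument-calibration threshold, not a hypothesis
family, and the reference analysis applies it the same way.

The 0.01% floor is itself derived from the error model:
`detection_limit_curve` reports, for each droplet number n, the CI upper
bound at the expected error-only mutant count `round(ε·n)` and whether it
falls below the floor. With ε = 2.16 × 10⁻⁵ the bound crosses below 0.01%
near n = 10⁵ informative droplets. The expected-count construction is one
of two readings of the original calibration figure (the other uses k = 0);
the operation takes ε as an argument, so both are available — pass ε = 0
for the zero-count curve.

## Gating

Default gating is explicit rectangular regions (half-open [min, max)) in
(ch1, ch2) space, mirroring manual scatter-plot gating; with no explicit
regions, per-channel splits default to the channel mid-range. Droplets in
the double-positive corner or outside all regions are counted NA and
logged, never dropped — conservative for rare-allele work, since ambiguity
can only deflate, never inflate, the mutant count. The automated
alternative fits three k-means centres initialised at the configured
prototype locations (fixed random state) and assigns droplets to the
nearest centre; fitting fails loudly if the fitted centres do not map
one-to-one onto the MU/WT/NA prototypes (e.g. on single-cluster input).

## Family simulation

Each simulated family is a trio. A member's carrier burden is a mean MAF;
exactly 0.5 marks a constitutional heterozygote (0.5 in every tissue, no
dispersion). For mosaics, per-tissue MAFs are drawn by perturbing the logit
of the carrier-cell fraction `c = 2·MAF`: one shared Gaussian shift per
germ-layer group (σ_between = 0.35) plus an independent per-tissue shift
(σ_within = 0.15), then `MAF = 0.5·logistic(·)`. This keeps mosaic MAFs
strictly inside (0, 0.5) — a postzygotic mosaic can approach but never
equal the heterozygous fraction — and makes same-layer tissues more similar
than cross-layer ones. The germ-layer table is a documented modelling
choice: blood/saliva mesoderm-dominant, buccal/hair/skin
ectoderm-containing, urine its own group, sperm germline.

Scenario kinds and their default generating values: parental somatic
mosaic 10% MAF, germline-only paternal sperm 12%, proband postzygotic 40%
— all inside the range observed for real carriers (0.03%–33% across
tissues, 44% for the mosaic proband). Sanger trio status is a hard
threshold on true blood MAF: ≥ 50% reads het, ≥ 10% (the Sanger
sensitivity floor) reads weak signal, below that undetected. No trace
simulation is attempted. Seeds are explicit arguments everywhere; the
cohort generator spawns per-family seeds deterministically from its own.

What the simulator does **not** emulate: droplet volume variation and
multi-template occupancy, spectral cross-talk and compensation, PCR
efficiency differences between the deletion and SNV assays, amplicon
read-level errors (indels, strand bias), and oocyte mosaicism (no female
germ cells are collectable, so maternal germline-only mosaicism is
unobservable — a structural asymmetry the cohort summary flags). Passing
tests therefore validate the statistical machinery under the stated
binomial model, not instrument-level artefacts.

## Inheritance classification

Decision order (first match wins): affected Sanger-heterozygous parent →
inherited; any parental somatic tissue (blood, buccal, saliva, hair, urine,
skin) called mosaic → parental somatic mosaicism with that parent as
origin; otherwise paternal sperm mosaic → germline-only (paternal by
construction); otherwise proband blood mosaic (not het-consistent) →
proband postzygotic; otherwise unresolved de novo, with origin taken from
allele-specific PCR when informative. The somatic-beats-germline order
mirrors the screening cascade (blood screen first, sperm second). Both
parents somatic-mosaic for the same variant is contradictory for a single
transmitted allele and raises a manual-review error rather than being
silently classified. Classification is a pure function of the family
record; member and sample order never matter.

Cohort percentages are rounded half-up to one decimal, matching the printed
report style (93.3, 96.8, 87.9, 12.1, 7.5). The MAF range is taken over
mosaic-called parental samples only. Counts that exist only at cohort level
(the 74+ screened families with no published per-sample data, trio Sanger
outcomes, ASPCR origin tallies) come from the packaged tally table; the
reference cohort encodes those families as screened-negative placeholders
so family-level counts are conserved.

## Clustering

MAF fractions (in [0, 1], not percents — the transform is monotone either
way, the scale is fixed for reproducibility) are square-root transformed
(variance-stabilising for binomial proportions), compared by Euclidean
distance, and merged by average linkage (UPGMA). The source analysis names
the distance but not the linkage; UPGMA is the common default for such
dendrograms and `complete`/`single` are available. Rows are sorted
lexicographically before merging so ties break deterministically. Missing
cells follow an explicit policy — `drop_feature` (default, conservative),
`drop_sample`, or `pairwise` — and are never imputed. Newick export places
each node at half its merge height, so UPGMA trees serialise as ultrametric
trees that round-trip through standard parsers.

## Problem sizes

Defaults used by the test suite and the acceptance script: 50,000
informative droplets per simulated assay, 20 × 50,000-droplet negative
controls per calibration replicate with 500 replicates, 200 families for
scenario-recovery runs, and 400 assays for sensitivity curves. These sizes
give Monte-Carlo error well inside the asserted margins while keeping a
full run in seconds.

## Known limitations

- Printed tables carry only rounded point estimates and CI bounds, not raw
  counts, so fixture-derived estimates have `k`/`n` unset and all
  comparisons on them happen at printed precision.
- The cross-platform R² computed here uses the nine fully printed blood
  pairs; the original figure's value (0.9722) pooled a larger,
  not-fully-enumerated multi-tissue sample set and is therefore not
  reproducible from the printed data.
- The reference dendrogram's exact leaf set is likewise not recoverable;
  clustering is validated by oracles and synthetic subtree-purity tests
  instead.
- Sperm positivity is treated as proof of paternal origin; maternal
  germline-only mosaicism cannot be observed and its share is
  underestimated by design.
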