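# Methods

This note documents the models and procedures implemented in
`clonedisperse`, the assumptions behind them, the parameters that matter,
and the design decisions taken where several reasonable choices existed.

## Somatic and germline filtering (`variants`)

A candidate somatic call passes when mapping quality is acceptable and
either of two routes holds:

* **standard**: tumor and normal depth ≥ 15×, tumor VAF ≥ 5%, normal
  VAF < 1% (strict);
* **relaxed high-depth**: tumor VAF ≥ 15% with both depths ≥ 100×, normal
  VAF ≤ 5% (inclusive), and tumor VAF ≥ 4× normal VAF (inclusive).  The
  relaxed route tolerates low-level variant reads in blood at very deep
  sequencing, e.g. from circulating tumor cells or technical noise.

The relaxed rule is an *alternative* acceptance route (logical OR), not a
replacement for the standard rule.  Zero-depth loci never pass; no division
error can surface.  Germline records require depth ≥ 10×, ≥ 5 variant
reads, and VAF ≥ 5%.  The numeric mapping-quality filter belongs to
upstream read processing and is represented as a boolean input flag.

Nonsilent mutations are missense, nonsense, stoploss, frameshift indels,
and splice-site changes; in-frame indels and synonymous changes are silent.
TMB is nonsilent passing mutations per megabase of target territory.  The
target size is configurable (`target_megabases`, default 50.0 Mb, the order
of magnitude of an extended exome capture); TMB values are only
interpretable up to this constant.  Samples with TMB > 12/Mb are flagged
hypermutated.

## CCF estimation and timing (`prevalence`)

CCF uses the standard purity/copy-number adjustment

    ccf = vaf · (ρ·n_t + (1 − ρ)·2) / (ρ·m)

capped at `ccf_cap` (default 1.5) so that noise above 1 is retained but
bounded.  Multiplicity `m` is estimated deterministically: among
`m ∈ {1..n_major}` the value whose expected clonal VAF is nearest the
observed VAF is chosen, provided the nearest expectation lies within a
tolerance band (default 0.15 VAF units; outside the band `m = 1`); ties go
to the smaller `m`.  This is a deterministic surrogate for probabilistic
multiplicity/timing models — adequate at several-hundred-fold depth, where
the expected VAFs of different multiplicities are many standard errors
apart, but it carries no posterior uncertainty.

Timing states: mutations with CCF below `clonal_threshold` (default 0.9)
are subclonal.  Clonal mutations on a segment with a copy gain
(`n_major ≥ 2`) are `clonal_early` when `m ≥ 2` (the mutation predates the
gain and was co-amplified) and `clonal_late` when `m = 1`; without a gain
the gain clock is uninformative (`clonal_NA`).  Copy-number aberrations are
called against the sample's length-weighted median copy number; LOH is a
minor-allele copy number of 0 (rounding tolerance 0.01).

Patient-level clonality: a mutation is clonal for the patient when it is
clonal in at least one sample *and* detected in every sample; otherwise
subclonal.  "Detected" uses a rescue rule more sensitive than discovery
(≥ 2 supporting reads at VAF ≥ 1%), because presence/absence testing
across samples must not be limited by the discovery thresholds.

## Clustering (`clustering`)

Mutations are clustered on their joint per-sample CCF vectors with a
diagonal-covariance Gaussian mixture; the component count is chosen by BIC
over `k = 1..k_max` (default 12: the realistic clone range plus headroom).
Absent entries are imputed as CCF 0 — at ~670× depth, zero supporting
reads is strong evidence of absence, not missingness.  Mutation keys are
sorted before fitting, so results are independent of input order; the seed
fixes the mixture initialization.

Two post-processing steps stabilize the model order.  Near-duplicate
centers (closer than 0.06 in max-norm) are merged: BIC occasionally splits
one clone in two, and a spurious extra "clone" would otherwise inflate the
disseminated-clone count and misclassify the dissemination mode.  Clusters
below `min_cluster_size` (default 3, the minimum detectable clone) are
merged into the nearest center when it is within 0.1 max-norm, otherwise
their members are dropped and reported.  Cluster prevalences are the
per-sample means of member CCFs, clipped to [0, 1].

The Gaussian mixture replaces Dirichlet-process binomial clustering as a
deterministic desk-scale surrogate; it does not reproduce any specific
published patient model.

## Tree enumeration and selection (`phylogeny`)

The root cluster must have prevalence ≥ `root_threshold` (default 0.9,
matching the clonal threshold) in every sample; if none qualifies the
closest candidate is named in the error.  Enumeration is exhaustive over
parent assignments with pruning, requiring parent dominance and the sum
rule per sample within `tolerance` (default 0.05 prevalence units — slack
for estimation noise in cluster centers).  Exhaustive search is bounded at
9 nodes; beyond that a greedy best-parent construction (minimizing total
sum-rule excess) is used with a warning.

Model selection ranks candidate trees by (1) fewer branching nodes (linear
over branched evolution), (2) fewer implied disseminated clones, and (3) a
lexicographic tie-break on the canonical parent map.  Because the
disseminated set is determined by prevalences and site labels, criterion
(2) rarely discriminates between full models of one patient; the tie-break
makes the choice deterministic where a manual analysis might have chosen
otherwise among equivalent models.

## Dissemination calls (`dissemination`)

A clone is present at a site when its site-mean prevalence is at least
`presence_threshold` (default 0.02 CCF — comfortably above center noise at
~670× depth, far below any real clone).  Non-root clones present at ≥ 2
sites are disseminated; the root is counted as the disseminated clone only
when no subclone is shared across sites (seeding before subclonal
diversification).  Single-site clones are local.

Direction: among sites where a disseminated clone is present, the site
with the smallest prevalence is its origin, provided the gap to the
runner-up is at least `direction_margin` (default 0.05); ties and the
initial clone at ≈ 1 everywhere are undetermined.  Direction calls are
restricted to sites where the clone is present.

Mutation time counts cumulative (root-lineage) mutations, i.e. a clone
inherits its ancestors' mutations; this makes the "most-mutated clone"
normalizer coherent and bounds the statistic in [0, 1].  The dissemination
interval is 0 for monoclonal cancers; for monophyletic cancers it is the
mutation-time span between the first and last disseminated clones (this
reads seeding order as developmental order — an assumption, see
limitations); for polyphyletic cancers it is the largest symmetric
difference of root-lineage mutation sets between two mutually non-ancestral
disseminated clones, as a fraction of all modeled mutations ("the two most
divergent clones").

Polyclonal cancer origin is declared when some pair of sites shares zero
filtered somatic mutations; the mutation-sharing site groups are then
modeled as separate cancers, and the patient report carries one subreport
per group (dissemination is still assessed within multi-site groups).

## Synthetic data (`simdata`)

The generator emulates the sampling design of a deep multi-site HGSC
study: 2–3 anatomical sites with 3–7 samples per patient, tumor purity
drawn uniformly from 0.40–0.90, sequencing depth Poisson around 670×
(600× in the noisy recovery experiments), clone trees of 3–9 clones with
Poisson private mutation counts (mean 50 per clone, floored at 3 so every
simulated clone is detectable in principle), and per-site prevalences that
satisfy the sum rule exactly by top-down construction.  Cohorts draw
dissemination modes in roughly the 6 : 12 : 5 proportions
(monoclonal : monophyletic : polyphyletic) with 2–3 (occasionally 5)
disseminated clones, and include one polyclonal-origin patient.

Prevalence patterns are arranged so the declared mode is identifiable from
prevalences alone.  Monophyletic chains use parent-child prevalence ratios
of 0.72–0.78 at the destination site: any sibling rearrangement of such a
chain then violates the sum rule by more than the tree tolerance, so
parsimony cannot re-linearize or re-branch the truth.  Polyphyletic
founders either occupy non-nested site sets (3-site patients) or have
prevalence orders that cross between the two sites, which makes any chain
over them infeasible.  Origin sites receive a damped prevalence share
(factors 0.25–0.45), keeping the smallest-prevalence direction rule
recoverable.  A seeded retry loop (up to 60 draws, best kept) enforces a
pairwise clone separation of at least `min_clone_separation` (default
0.12 CCF in max-norm) so clones are resolvable by clustering.

Read counts follow the binomial model at the allele fraction implied by
purity, prevalence, copy number, and multiplicity; matched-normal counts
use an error rate of 0.1%, below the 1% filter threshold, so true somatic
calls pass the filters by default.  In noise-free mode alt counts are the
exact expectations, stored as fractions in the TSV tables so that CCFs
back-transform to prevalences within 1e-9 (VCF export necessarily rounds
to integers).  Copy-number segments default to diploid 2 : 1; configured
gain chromosomes get 3 : 1 with truncal mutations at multiplicity 2.

What the simulator does **not** model: sequence-level reads, mutational
signature processes, copy-number evolution along the tree (segments are
static per sample), tumor-in-normal contamination beyond the flat error
rate, spatial structure within a site beyond an optional multiplicative
jitter (off by default; the within-tumor sampling density of subclones is
not an inferred property), and sample-specific purity estimation error.
Passing recovery tests therefore demonstrate correctness of the inference
chain under the stated read model, not robustness to every artifact of
real sequencing data.

## Problem sizes and numerical choices

The bundled experiments use desk-scale sizes chosen to exercise every code
path: cohorts of 23 patients (~5 samples, ~300 mutations each), 90
noise-free and 100 noisy patients for recovery rates, 100 random
prevalence matrices (3–6 clusters) for the enumeration cross-check, and
1000 random trees for the timing invariants.  A full cohort analysis runs
in well under a minute on one CPU.  All randomness flows from explicit
seeds through per-stage substreams; reruns are byte-identical.  Bootstrap
CIs of cohort medians use 1000 percentile-bootstrap replicates (the CI
method for medians is a package choice, not a reproduction of any specific
tool).  Ties in multiplicity estimation go to the smaller value; ties in
model selection are broken lexicographically; sum-rule comparisons carry a
1e-12 absolute guard against floating-point noise.

## Known limitations

* The clustering and multiplicity surrogates are deterministic
  replacements for MCMC-based tools; agreement with those tools on real
  data is not claimed.
* Monophyletic intervals assume seeding order equals clone birth order;
  the data cannot distinguish a late clone seeding before an early one.
* When several trees fit equally well, the reported topology is a
  deterministic but arbitrary representative; the dissemination mode is
  usually, but not provably, invariant across the tied set.
* TMB on real data is reproducible only up to the configured target size.
* The pairwise/greedy fallback for unmodelable patients yields a flagged,
  approximate tree rather than per-site-pair model listings.
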