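# Methods

## Problem setting

Two heterotic pools of maize inbred lines (group A and group B, e.g. Flint and
Dent) are crossed in a full factorial; each hybrid carries a mid-parent
heterosis (MPH) value for a quantitative trait such as grain yield, expressed
in percent of the mid-parent.  The pipeline relates *parental* sRNA expression
differences to *hybrid* MPH: no hybrid expression data is required for the
association itself.

## Normalization (rpmqn)

Unique-sequence count matrices from sRNA-seq are extremely sparse, and the
zeros are structural (a sequence not present in a genotype cannot be
expressed).  Classical quantile normalization would average the zero mass into
the reference distribution and/or assign nonzero counts to absent sequences.
We therefore quantile-normalize **only the nonzero entries** of each library:

* each library's sorted nonzero values are interpolated onto a common quantile
  grid (grid size = the largest per-library nonzero count);
* the reference quantile function is the mean of these curves;
* each nonzero entry is replaced by the reference evaluated at its
  within-library quantile (average ranks, so ties share one value);
* zeros are returned bit-identical.

Columns are then scaled to 1e6 (rpmqn).  Consequences used by tests: zeros are
preserved end to end, within-library rank order of nonzero values is
preserved, column sums are exactly 1e6 up to float rounding, and the transform
is equivariant under row permutation.  A single-library matrix is returned
unchanged by construction.  The exact algorithmic form of the original
zero-preserving modification is unpublished; numerical equivalence with the
original study is not claimed.

## Differential expression and distances

The DE state uses thresholds c_min = 0.5 rpmqn and fold change f_c = 2
(defaults everywhere; `DEParams` makes them explicit).  Conventions worth
stating:

* the boundary c_h = f_c·c_l counts as differentially expressed (">=");
* the presence/absence branch (c_l = 0) requires c_h ≥ f_c·c_min;
* the state is symmetric in its two arguments and monotone in the high count.

The binary distance is the mean DE state over an sRNA set.  "Euclidean"
distances for expression and SNP data use the root of summed squared
per-feature differences; a city-block option exists because monotone
transformations do not change the correlation-sign conclusions drawn from
these distances.  For SNP data the per-locus difference is 1 when calls
differ and 0 when equal — so identical lines have distance 0 and genetic
distance correlates positively with heterosis — and loci missing in either
line are excluded pairwise.

Group separation of parents is assessed by principal-coordinate analysis
(classical scaling via scikit-bio) of the binary-distance matrix; the report
carries a silhouette score by group label and whether a linear SVM separates
the groups in the first three components.  Whether the original analysis ran
PCA on the distance matrix or on a derived feature table is unknown; classical
scaling of the distance matrix is this package's declared choice.

## Association test

Hybrids are ranked by trait value and split into equal-size low/high classes;
with an odd count the median hybrid is dropped, and exact ties are broken by
hybrid id (stable and reproducible).  Per sRNA, o_L and o_H count DE hybrids
per class — a parent pair shared by several hybrids contributes once per
hybrid.  The binomial tail P = Σ_{k≥max(o_L,o_H)} C(n,k)/2^n is computed with
exact integer arithmetic in the scalar path (`binomial_p`) and with
scipy.stats.binom.sf in the vectorized pipeline path; tests pin both to an
exhaustive 2^n enumeration for n ≤ 12.  sRNAs with n = 0 are excluded before
BH-FDR so they do not dilute the correction (the tested universe size of the
original study is unstated).

Direction: positive ⇔ o_H > o_L.  A tie o_L = o_H is assigned the negative
branch and flagged; for n ≥ 1 a tie can never be significant, so the choice is
inert.

Permutation null: each run re-applies split → count → test → FDR after either
shuffling trait values across hybrids or permuting parent labels.  Parent
labels are permuted within each heterotic group so every permuted hybrid still
maps to an inter-group parent pair present in the DE matrix.  A run "reaches
significance" when any sRNA is rejected at FDR α.  Both 100 and larger run
counts are supported via a parameter.

Dominance/additivity per (parent1, parent2, hybrid) triplet:
a = |p1 − p2|/2, d = f1 − (p1 + p2)/2; d/a is 0 when the hybrid equals the
mid-parent and ±1 at the parents.  Equal parents make the ratio undefined and
are reported as such.

## Genomic analyses

Coordinates are 0-based half-open (BED convention) everywhere internally;
GFF3 is converted on read/write.  Exact mapping scans both strands with no
mismatches (minus strand via reverse complement; a palindromic query is
reported once, on the plus strand).

Clusters merge mapping positions on one chromosome whose inter-interval gap is
≤ 200 bp (single linkage, chaining allowed); clusters with < 5 distinct member
sRNAs are discarded.  Cluster expression per library is Σ over member
positions of rpmqn/n_positions (repeat-normalization), so totals over all
positions are conserved.  Cluster-level association reuses the sRNA machinery
with c_min = 5 repnorm rpmqn, f_c = 2.

Window tracks count every position of a multi-mapping sRNA (the original
study does not state its convention; per-position counting is declared here),
in the window containing the position start.

Bootstrap enrichment draws are without replacement within a draw, independent
across runs, and seeded; p-values use the add-one estimator
(#extreme + 1)/(runs + 1), hence lie in (0, 1].  Size-class enrichment uses
equal-size draws; repeat-superfamily and gene-proximity enrichment use
length-matched draws (every draw reproduces the subset's exact length
histogram).  Spatial enrichment in 1-Mbp windows flags a window only when the
observed count is ≥ 2× the bootstrap mean *and* p < 0.05.  Gene-proximity
flanks (±1 kbp around the gene body, introns/UTRs included) are closed at both
boundaries: a position starting exactly at gene start − 1 kbp counts.

Recombination rates interpolate map cM linearly to 1-Mbp window boundaries;
windows outside the marker span get rate 0 with a flag.  Correlations with
window counts are Pearson, per chromosome and genome-wide; a chromosome with a
constant track yields NaN rather than an error (only fully constant input is
rejected).

## Synthetic data generator

The generator defines the package's study conditions; its defaults are fixed
and are what the acceptance checks run on.

**Design.**  7 + 14 parents, 98 hybrids.  MPH = mph_mean + g_mother +
g_father + ε with normal components; defaults mph_mean = 90%, mph_sd = 15
(bracketing the published example hybrids at 72.5–123.7%).  Variance shares
are fixed at (0.70, 0.15, 0.15) of mph_sd² for group-A GCA, group-B GCA and
residual.  Group effects are normal scores on a quantile grid, randomly
assigned to parents: with only 7 parents, i.i.d. draws occasionally produce a
near-degenerate pool in which all parents are similar, whereas real breeding
pools are curated to span diversity; the stratified draw keeps every simulated
pool representative of its stated variance.

**Counts.**  Negative binomial around per-parent state means with
var = μ + 0.3 μ² (overdispersion matching sRNA-seq practice).  Background
sRNAs are shared between groups with probability 0.35 (mirroring the minority
of sRNAs with common expression across heterotic pools) or specific to one
group (zero counts in the other); within an expressing group each parent is
present with probability 0.95.  Mean levels are log-normal and globally scaled
so library totals land near lib_size (default 200,000 — desk scale; the real
study sequenced ≥ 9 million reads per library, so all sizes here are scaled
down and the methods are size-independent).

**Planting.**  Planting acts on per-parent expression states, because DE is a
pairwise property: a planted sRNA is expressed (high NB mean, ≈ 300 rpmqn at
the default library size) in 3 group-A parents and has zero counts everywhere
else, so every hybrid of an expressing parent is DE through the
presence/absence branch.  The 3 parents are drawn without replacement with
weights exp(−2.5·rank) on the ranking of group-A parents by the mean MPH of
their hybrids — ascending for negative sRNAs, descending for positive — so the
DE "rectangle" concentrates in one trait class.  The dominant group-A GCA
share is what makes this concentration strong; both it and the steep rank
decay are deliberate parts of the generator's *strong effect* condition.
Planted lengths default to 22 nt (negative) and 24 nt (positive), matching
the size classes most strongly featured in the motivating analyses.
Realized o_L/o_H are recomputed from the emitted matrix with the package's
own normalization/DE/split machinery and recorded as ground truth; tests
verify them against an independent naive recount.

**Genome.**  n chromosomes of equal length; centromere = middle 10%;
non-overlapping genes (log-normal ≈ 3 kbp) and repeats (≈ 0.8 kbp, five
superfamily labels) placed with Dirichlet gaps; densities exceeding ~90% of
the chromosome are rejected.  The genetic map accrues 1.5 cM/Mb on the arms
and 0.05 cM/Mb across the centromeric third — strictly monotone cM, strongly
suppressed pericentromeric recombination.  Sequence generation is optional so
large annotation-only genomes stay cheap.

**Mappings and reads.**  Position counts per sRNA follow a user-stated
profile (0 = unmapped); positions are uniform, or pericentromerically biased
(normal around the centromere, sd = chromosome length/12) for a chosen subset
— the hook for spatial-enrichment tests.  Reads are each sequence repeated
count times with the 3′ adapter appended; with zero error rate all bases are
Phred 40 and preprocessing inverts the simulation exactly; with error e,
bases substitute uniformly among the three alternatives and qualities encode
e.

**What the generator does not emulate:** realistic genome composition,
instrument error profiles, hybrid (F1) sRNA populations, expression-level
correlation structure among sRNAs, or multi-mapping that is consistent with
the generated sequences.  Passing recovery tests therefore demonstrate the
statistical machinery under the stated generative model, not performance on
real sRNA-seq data.

## Problem sizes and tolerances

The standard synthetic run uses 5,000 sRNAs, 300 of them planted
(200 negative / 100 positive), 98 hybrids, 100 permutation runs, and a
10 × 10 Mbp genome with 10,000 bootstrap runs for spatial enrichment —
sizes chosen so a full end-to-end run completes in seconds while every
statistic is comfortably away from small-sample degeneracy.  Numeric
tolerances: rpmqn column sums checked at 1e-6 relative; zero preservation and
the binomial oracle checked exactly; interpolation-based recombination rates
checked to float precision.

## Interpretation of the original equations

Three places where the printed formulas of the motivating study conflict with
its prose or figures are resolved as follows (each is also noted at the
implementation site): the symbol "c_t" in the DE rule is read as c_l; the
Euclidean distance takes the square root of the summed squares; the SNP
per-locus difference is 1 for differing calls; and "positive" association is
attached to o_H > o_L, consistent with the reported correlation directions.
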