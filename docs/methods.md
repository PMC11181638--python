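# Methods

`mirscreen` analyzes pooled negative-selection CRISPR-Cas9 knockout screens of
miRNA genes across panels of cancer cell lines.  This note describes the models
and procedures the package implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Screen model and quantities

A screen measures, per sgRNA, the log2 fold change (LFC) of its abundance after
~3 weeks of propagation relative to the plasmid library that was transduced:

    LFC_g = log2((c_g + pc) / (p_g + pc)),

on depth-normalized counts (every sample scaled to the mean of the sample
totals), with pseudocount `pc = 0.5` (a common pooled-screen convention; it
keeps zero counts finite and adds negligible bias at the depths involved).
Negative LFC = the knockout costs fitness.  Four guide classes structure every
downstream step: miRNA-targeting guides (the objects of study),
essential-control guides against pan-essential protein-coding genes (positive
controls), intergenic-control guides that cut a single non-genic locus
(modeling Cas9 cutting toxicity without knockout; the null anchor), and
non-targeting guides (no genomic site, no coordinates).

## Replicate quality gates

A replicate is excluded when (a) fewer than 60% of its reads matched the
library, or (b) its total reads fall below 100× coverage per construct.  Both
thresholds are configurable (`QcThresholds`); the defaults reflect the regime
in which pooled screens remain quantitative.  Replicate agreement is summarized
two ways: a Pearson correlation matrix over guide LFCs after pre-filtering
(essential-control guides removed, plus guides of genes showing no fitness
effect in any screen — operationalized as never dropping below scaled LFC −0.5
anywhere), and a within-vs-between (WBC) score per screen.

**WBC definition used here.**  For each screen, WBC = mean of its
within-screen replicate-pair correlations minus the 90th percentile of the
correlations its replicates show to replicates of *other* screens; a screen is
flagged when WBC ≤ 0 or undefined (single replicate).  The published versions
of this idea differ in detail; this monotone surrogate preserves the
within-vs-between contrast, is computed on both LFCs and dLFCs (LFC minus the
gene's cross-screen consensus), and the quantile is configurable.

## Effect-size and classification metrics

NNMD = (mean essential LFC − mean null LFC) / SD(null LFC); Cohen's D uses the
pooled SD.  Both are negative for a well-separated dropout screen.
Precision-recall analysis ranks genes (or guides) by an essentiality score
against labelled control sets; AUC-PR is the trapezoid over the recall grid
with the conventional (0,1) anchor.  Under the Bayes-factor rule the F measure
(harmonic mean of precision and recall) is evaluated at the smallest observed
score ≥ 5; if no score reaches 5 the top score is used and flagged.

## Copy-number (gene-independent) correction

Guides cutting inside amplified regions deplete regardless of their target —
the artifact is positional, so it is removed without copy-number data.  Per
replicate and chromosome, guide LFCs ordered by cut-site position are
recursively segmented with a CBS-style *arc* statistic: the best contiguous
window versus the rest by squared two-sample t score.  (A single binary split
cannot detect a segment embedded in a flat background; the arc statistic can,
which is why circular binary segmentation uses it.)  Significance of each
candidate arc is assessed by permutation of the region's LFCs (default 1000
permutations, seeded, early-stopped only when the decision at `seg_alpha` is
already determined — the decision is identical to running all permutations).
Recursion proceeds into the three resulting pieces.

A segment is then mean-centered when it has ≥ 3 guides, its mean differs from
0 at `seg_alpha = 0.01` (one-sample t), **and it spans ≥ 3 distinct genes**.
The last rule is a default, not an option, in this package: miRNA libraries
cluster a gene's guides within a few hundred bp of the stem-loop, so a single
strongly essential gene is itself a contiguous mean-shifted run, and centering
it would erase real biology rather than a cutting artifact.  Pass
`min_genes=None` to disable (e.g., for libraries with dispersed guides).

Corrected counts are re-derived by the exact inverse of the LFC definition,
`(plasmid_norm + pc)·2^lfc − pc`, so that recomputing LFCs from corrected
counts reproduces them to machine precision.

## Rank-biased overlap (RBO)

Alternative corrections are compared via extrapolated RBO of the corrected
guide rankings, truncated at evaluation depths 50–400.  The persistence
parameter p is tuned through the Webber prefix-mass identity

    W(p, d) = 1 − p^(d−1) + d(1−p)/p · (ln(1/(1−p)) − Σ_{i=1}^{d−1} p^i/i)

so that the top d* = 30 ranks carry 92.89% of the score mass; the solver
(bisection on (0,1)) returns p ≈ 0.95000, and re-evaluating W at the returned p
reproduces the target mass to < 1e−8.  At d = 1 the identity reduces to
(1−p)/p · ln(1/(1−p)) — ln 2 at p = ½ — which the tests use as a closed-form
anchor.  Ranking ties are broken by (score, guide_id) stable sort.

## Per-screen essentiality

Two deliberately different classifiers are intersected.

**Bayes factors (supervised).**  Gaussian KDEs (Silverman bandwidth) are fit
to the LFCs of essential-control guides (f_ess) and intergenic-control guides
(f_null); a guide scores log2 f_ess(x) − log2 f_null(x) with x clamped to the
training support (densities floored at 1e−12, evaluated on a 512-point grid
and interpolated); a gene's BF is the sum over its guides.  Training sets are
bootstrapped (default 200 rounds; reduced from the 1000 typical of heavyweight
runs, configurable) and the reported BF is the bootstrap mean ± SD.  Guide
LFCs are replicate means by default (stacking is a flag; with three replicates
and this library's depth the two are nearly indistinguishable, and averaging
keeps the gene BF scale independent of replicate count).  FDR along the
BF-descending ranking is labelled-control imprecision — 1 − precision over the
essential-control genes versus intergenic pseudo-genes seen so far —
monotonized by running maximum.

**alpha-RRA (semi-supervised).**  All coordinate-bearing guides are ranked by
depletion and percentile-normalized.  For a gene with k guides at sorted
percentiles p(1) ≤ … ≤ p(k), only guides passing the alpha gate enter, and

    rho = min over gated j of BetaCDF(p(j); j, k − j + 1).

The null distribution of rho is built by drawing k intergenic-control guide
percentiles (1000 permutations, seeded); p = (1 + #{null ≤ rho})/(n_perm + 1),
FDR by Benjamini–Hochberg.  **Alpha gate:** by default alpha is set from the
data as the fraction of guides depleted beyond the intergenic controls' own
5th percentile (floored at 0.05, capped at 0.5).  A fixed top-5% gate starves
genuinely depleted guides of rank space whenever more than ~5% of the library
drops out (dense-hit screens, or any screen with many essential controls); the
adaptive rule keeps the gate meaning "more depleted than the null controls."
A numeric alpha is honored verbatim when supplied.

A gene is a **fitness gene** in a screen when both FDRs are < 10%.  The recall
of essential-control genes at that threshold is reported as a per-screen
quality figure.  Enrichment-side RRA is computed but unused by the consensus.

## Cross-screen integration

Gene-level LFC = mean of guide LFCs (replicate-averaged).  Each screen is
affinely rescaled so the median of essential-control genes is −1 and the
median of intergenic *pseudo-genes* is 0; a gene with scaled LFC < −0.5 counts
as depleted.  Pseudo-genes partition the intergenic guides, sorted by genomic
position, into contiguous bins whose size multiset follows the miRNA library's
guides-per-gene distribution (largest-remainder allocation, leftover guides
joining the last bin — deterministic given the library).  miRNAs lying in
exons of common-essential host genes are excluded (their dropout may be a
host-gene effect); intronic residents are kept.  Off-target association is
screened by ranking guides by LFC into deciles (pairwise Welch t tests,
Holm-corrected, plus a headline bottom-decile-vs-rest contrast) and, for hit
versus non-hit gene classes, by Kruskal–Wallis with Dunn's rank post-hoc
(Bonferroni across pairs).

## Common-essential classification

Genes are ranked by depletion within each screen (rank 1 = most depleted,
average ranks on ties).  A gene's ranks are sorted ascending and the tail from
position t = ceil(0.9 · n_screens) — its least-dependent ~10% of screens — is
summarized four ways: `average` (tail mean; most stringent, used for final
calls), `fixed` (rank at position t), `auc` (trapezoidal tail mean), `slope`
(least-squares slope of the full sorted profile, divided by the gene-universe
size so thresholds are comparable across universes).

The class boundary is found on a Gaussian KDE (Silverman, 512-point grid) of
the scores.  The bulk of genes forms the global density maximum; the threshold
is the *deepest local minimum left of the bulk that still has a mode to its
own left*.  This valley rule is deliberately stated in terms of the bulk
rather than "the two largest modes": with a Silverman bandwidth the bulk is
frequently double-humped, and taking the two largest modes verbatim can place
the threshold inside the bulk and classify half the genome.  A unimodal
density yields an explicitly flagged empty set, never an arbitrary cut.
Common essentials are genes strictly below the threshold.

The non-essential reference set (used for display anchoring) is the top-k
genes by smallest summed per-screen |LFC − median(intergenic LFC)|.

## Synthetic screen generator

The generator emulates the data-generating process the pipeline assumes, with
known truth: lognormal plasmid abundance (σ = 0.5); expected replicate count
depth·N·p_g·2^(efficacy·effect + cn_bias) with negative-binomial counts
(variance μ + αμ², α = 0.01); per-guide efficacy ~ Beta(5, 1) (mean 0.83);
gene effects −1.5 LFC for common essentials (8 of 400 by default) and for
context-specific essentials (40 genes, each active in a screen with
probability 0.3); a contiguous genomic segment adding −0.8 LFC to every guide
inside it regardless of target; 12 screens × 3 replicates at depth 500
reads/guide; one shared plasmid pool.  Guides of one gene cluster within a few
hundred bp; genes, essential controls (20 × 5 guides), and single intergenic
guides (150) are shuffled along five synthetic chromosomes so genomic
neighbourhoods mix classes, as segmentation assumes.

Two generator choices deserve emphasis.  The plasmid reference is drawn
*Poisson* at 10× the replicate depth: a plasmid library prep has no
biological or bottleneck variation, so NB overdispersion is wrong for it — and
because the single reference is shared by every screen, an overdispersed
reference would imprint a ~10% multiplicative error on every gene in every
screen, correlating null-gene ranks panel-wide in a way no sequencing depth
can fix.  Deep Poisson reference keeps the (real) shared-reference artifact
present but small.  Second, the reference-composition config reproduces the
published miRNA-library bookkeeping exactly (1769 genes; 1414/135/102/71/47
genes with 5/4/3/2/1 guides; 8105 targeting guides; 93% of genes with ≥ 3
guides) while all sequences, coordinates and controls are synthetic.

**What the generator does not emulate:** PCR jackpotting and sequencing
error, lentiviral MOI and infection bottlenecks, lineage structure among
screens, expression-dependent miRNA effect sizes, and host-gene coupling of
intragenic miRNAs.  Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated model, not performance on any
particular real panel.

## Problem sizes, runtime, determinism

The default end-to-end study — 400 genes × 12 screens × 3 replicates, 1000
segmentation and RRA permutations, 200 BF bootstraps — completes in a few
minutes on one CPU; smaller configurations in the unit tests run in seconds.
All stochastic stages derive their seeds from a single global seed via stable
hashing of the stage name (CRC32, masked below 2^31), so a rerun with the same
config is byte-identical; the pipeline manifest records the seed, parameters,
and input hashes, and completed stages are reused on resume.

## Known limitations

* The labelled-precision FDR depends on the pseudo-gene count; very few
  intergenic guides make it coarse.
* The KDE valley rule needs the common-essential mode to be populated; with
  only one or two true common essentials the density is effectively unimodal
  and the classifier (correctly, but unhelpfully) returns an empty set.
* Segmentation significance is permutation-based and therefore limited to
  p ≥ 1/(n_perm+1); regional artifacts milder than the noise floor pass
  through uncorrected.
* The WBC score and the slope-variant scaling are reasonable but non-unique
  formalizations of informally described procedures; both are configurable.
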