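# Methods

This note documents the models, parameters, and design choices behind
`enhdiff`, and what the synthetic-cohort validation does and does not
demonstrate about real data.

## Element catalog and signal

Coordinates are 0-based half-open (BED) everywhere internally; the only
1-based input dialect is the optional GTF-derived gene-span helper, which
converts on ingest. Consensus elements are maximal merged intervals over all
samples' peaks, merging on ≥1 shared base — book-ended intervals stay
separate, which keeps the merge exactly equivalent to a transitive-closure
oracle over shared bases. Enhancer stitching (below) is the operation that
*does* bridge gaps.

Classification against TSSs uses full-span semantics with a ±`window`
(default 2,000 bp) rule: *promoter element* iff one TSS window contains the
whole span; *enhancer* iff every base is more than `window` from every TSS.
The two definitions leave a gap — spans straddling a window edge — which we
label *ambiguous* and exclude from both downstream sets by default
(`classify_elements` callers can fold them into promoters). Whether
midpoints or full spans should anchor the >2 kb rule is genuinely open; we
chose full spans as the stricter reading and the one consistent with the
"completely within" promoter definition.

Signal is input-subtracted RPKM, floored at 0: negative "enrichment" has no
meaning on the FC/difference scales downstream. Quantile normalization is
the classic sorted-reference algorithm (reference = row-wise mean of sorted
columns; ties receive the mean reference value over the tied span). It is a
batch-effect correction for real cohorts: it forcibly equalizes column
distributions, so on synthetic data — where columns are comparable by
construction — it is a near-no-op for mid-rank values but *remaps effects at
the extreme ranks* (a 4-fold gain on the already-highest-ranked element is
invisible after QN). The pipeline therefore exposes it as a config switch
(default on), and parameter-recovery validation feeds the caller the raw
generator output. Row z-scores use the sample standard deviation (n−1), with
constant rows mapping to zeros.

Saturation analysis permutes sample order (default 100 permutations) and
reports the mean ± sd cumulative count of distinct elements; the saturation
point is the first k whose marginal gain falls below 1% of the running
total. The 1% threshold is our quantification of "stable"; it is
configurable.

## Paired differential calling and the six classes

Fold changes use a pseudocount ε = 0.1 RPKM: small against the 0.5 RPKM
absolute-difference guard, and it keeps zero-reference pairs finite. Gain
votes require FC ≥ 2 *and* diff ≥ 0.5 in a pair; loss is defined
symmetrically (FC ≤ 1/2, diff ≤ −0.5) since the thresholds are conventionally
stated in the gain orientation only. An element is called with votes in
≥ `recurrence_min` pairs (default 6, per comparison; the LNC comparisons
have 8 available pairs, so 6-of-8). The paired *t*-test runs on raw
(normalized) RPKM differences — the same scale as the diff threshold — with
degenerate zero-variance rows mapped to p = 0 (nonzero mean) or p = 1, and
BH correction across the called elements of a comparison.

The six classes come from crossing the EC-vs-Nor and LNC-vs-Nor calls
(specific/common gain and loss). Gained-in-one/lost-in-the-other is
logically possible though never planted; we label it `discordant` rather
than forcing it into a class.

## Super-enhancers

Stitching merges enhancer runs with gaps ≤ 12,500 bp (the conventional
default; no TSS-exclusion window, both configurable). Region signal is the
length-weighted sum of constituent RPKM (RPKM × length / 1000),
approximating total signal in the region. The SE cutoff scales the
ascending rank curve to the unit square and takes the tangency point of the
slope-1 line, computed as the last rank minimizing y_scaled − x_scaled — on
a discrete curve this is the robust form of "where the slope first exceeds
1" (a pointwise discrete derivative can cross 1 several times on noisy
curves; the argmin is the global tangency). Degenerate inputs (< 3 regions,
or an all-equal curve lying on the diagonal) yield zero SEs.

Differential SEs are called by the mean strategy (group-mean difference
> 2 / < −2), which favors large-baseline SEs with big absolute shifts, and
by the paired strategy (per-pair FC ≥ 2 gain / ≤ 0.7 loss in ≥ 5 pairs; the
loss threshold is looser than 1/2 because losses are rarer), which favors
consistent relative shifts. The asymmetric union keeps either strategy's
calls; conflicts (one says gained, the other lost) become unaltered with a
flag, and high confidence requires agreement plus both thresholds.

## Expression integration

Gene linking is nearest-TSS by element midpoint (midpoint avoids span-length
bias), ties broken by lexicographic gene id. Expression FCs for ranking use
group-mean TPM with pseudocount 1. The dose–response buckets genes by their
count of linked gained (or lost) enhancers into 1 / 2 / ≥3 (configurable)
and tests adjacent buckets — starting against the dose-0 baseline — with
two-sided Wilcoxon rank-sum.

Signal–expression correlation is Spearman per link, over shared samples
(≥ 3); a per-gene summary takes the best link. Biomarker panels per class
keep genes with r > 0, take the top 100 by r, re-rank by expression FC in
the class direction (ascending for the loss class g6), and emit the top 10.
Samples are assigned tissues by sign patterns over the g1/g2/g3/g6 panel
scores (mean z-scored expression of panel genes). The sign threshold is the
cohort **mean** of each subgroup score, not the median: with 10 Nor / 10 EC
/ 8 LNC samples, a median threshold forces 14 positive signs per subgroup
regardless of how many samples are truly high, which structurally produces
spurious flips and EC/LNC Hamming ties; the mean is the natural zero line
of z-based scores. Ties in the Hamming match yield `unclassified`.

The DE test is a deliberately simple stand-in — Welch *t* on log2(TPM+1),
BH, DE iff linear FC > 1.5 and q < 0.05 — labeled `welch_bh` in outputs;
externally produced count-model DE tables (gene_id, log2FC, pvalue, padj)
are accepted interchangeably. CPM filtering keeps genes with CPM > 1 in
≥ 18 samples by default. Priming: a gene linked to a common-gain (G3)
enhancer that is *not* up in EC-vs-Nor but *is* up in LNC-vs-Nor is
pre-activated (pre-silenced symmetric with G6). PCA row-centers features and
uses SVD with a fixed sign convention (largest-magnitude loading positive);
hierarchical clustering uses average linkage on 1 − Pearson distance between
sample columns, with constant columns rejected by name.

## Survival

Kaplan–Meier estimation and the two-group log-rank test are delegated to
lifelines; the wrapper fixes a right-continuous step-function convention for
fixed-timepoint evaluation (the "2-year rate" is S(24 months)) and the
degenerate no-events case (p = 1 with a warning). Median-split
stratification sends samples strictly above/below the median to high/low
and alternates exact-median ties low/high in sorted sample-id order, so an
even cohort with ties still splits evenly.

## The synthetic cohort generator

The generator emulates the paired study design: `n_patients` = 10 with Nor
and EC profiles, the first `n_lnc_patients` = 8 also with LNC, over
`n_elements` = 5,000 consensus elements (30% promoter elements). Planted
counts default to 50/50/100/50/50/100 for G1–G6, `effect_fc` = 4,
`recurrence_fraction` = 0.8, `noise_sd` = 0.3.

Conventions, chosen once as the modeled conditions:

- Baseline RPKM is lognormal (meanlog 1.0, sdlog 0.8), floored at 0.5 RPKM —
  consensus elements are significant peaks, so baseline signal is bounded
  away from zero. Planted-*loss* elements additionally draw from the active
  tail (≥ 2 RPKM): an enhancer can only be lost where it was active in the
  reference tissue, and a "loss" on a 0.5-RPKM element would move signal by
  less than the 0.5 RPKM difference guard, i.e. would not be a loss in any
  operational sense.
- Measurement noise multiplies signal by 2^ε with ε ~ N(0, `noise_sd`):
  the noise scale lives in log2 units, the working scale of every
  fold-change threshold in the pipeline.
- The number of carrier pairs per planted element is
  ceil(`recurrence_fraction` × n_pairs) — the planted recurrence is never
  below its nominal fraction — with the carrier subset drawn per element.
  Gains multiply carrier-pair tumor signal by `effect_fc`, losses divide.
- Expression: gene baseline log2 level ~ N(5, 1.5); each planted enhancer
  shifts its linked gene by ±`expr_coupling` (default 1 log2 unit) in the
  affected tissue(s), additively in dose; sample noise N(0, 0.5) on log2;
  TPM by column scaling, counts by Poisson draws. Planted elements are
  attached to dedicated genes in a 1/2/3-enhancers-per-gene cycle, so the
  dose–response structure exists by construction.
- One seed feeds named substreams (carriers, signal, expression), so adding
  a component never perturbs another; identical config + seed reproduces
  outputs byte for byte.
- Survival simulation: exponential event times per group (baseline hazard
  0.03/month, high group × hazard ratio), administrative censoring at
  follow-up.

What passing the synthetic validation shows: the calling rules, group
logic, dose integration, panels, signatures, and survival machinery are
implemented correctly and recover planted structure at realistic noise, with
exact recovery in the noise-free limit. What it does not show: performance
under copy-number confounding, immune-cell admixture in lymph-node samples,
read-level artifacts, patient-specific baselines, or mis-specified pairing —
none of which the generator models. Real-cohort headline counts depend on
those factors and on upstream alignment/peak calling, which are out of scope
here.

## Problem sizes used in validation

The default validation cohort is 5,000 elements × 28 samples with 400
planted effects; oracle-equivalence sweeps use 1,000 random instances per
operation (intervals on coordinates < 10,000, signal vectors n ≤ 200,
p-vectors ≤ 50, universes ≤ 20); the quantile-normalization contract runs on
2,000 × 28 matrices; end-to-end determinism uses an 800-element cohort. These
sizes exercise every code path at the cohort's true dimensionality (28
samples) while keeping the full suite fast.
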