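# enhdiff

Differential enhancer and super-enhancer analysis for paired
tumor / normal / metastasis H3K27ac cohorts.

## The problem

Active enhancers and promoters carry the histone mark H3K27ac. Profiling the
mark in matched tissues from the same patients — adjacent normal esophagus
(**Nor**), primary esophageal squamous cell carcinoma (**EC**), and
lymph-node metastasis (**LNC**) — exposes the *cis*-regulatory reprogramming
of carcinogenesis and metastasis: thousands of enhancers recurrently gain or
lose acetylation, clustered super-enhancers (SEs) shift wholesale, and the
genes near these elements follow with coupled expression changes that can be
turned into tissue biomarkers and survival stratifiers.

`enhdiff` implements that analysis as a tested, reusable pipeline for anyone
with per-region H3K27ac signal over a paired cohort: epigenomics groups
working on tumor/normal designs, and methodologists who need a differential
cis-element caller with planted-truth validation. Because real cohorts ship
as multi-gigabyte raw sequencing archives, the package includes a
first-class synthetic-cohort generator that emulates the paired design with
labeled, planted effects, so every stage of the pipeline is validated
against known ground truth.

## The method

Starting from per-sample peak calls and input-subtracted RPKM signal
(RPKM = reads x 10^9 / (length_bp x library_size), ChIP minus matched
input, floored at 0):

1. **Consensus elements** — peaks from all samples are merged into maximal
   nonoverlapping intervals; an element whose span lies completely within
   ±2 kb of a TSS is a *promoter element*, one entirely >2 kb from every TSS
   is an *enhancer*; window-straddling elements are held out as ambiguous.
   Signal matrices are quantile-normalized across samples.
2. **Paired differential calling** — per patient pair, an element gets a
   *gain vote* when FC = (case + ε)/(ref + ε) ≥ 2 **and**
   diff = case − ref ≥ 0.5 RPKM (loss symmetric). Elements with votes in
   ≥ 6 of the available pairs are called gained/lost; calls are validated by
   a paired *t*-test with Benjamini–Hochberg correction (q < 0.1). The
   EC-vs-Nor and LNC-vs-Nor call sets combine into six classes: G1/G2
   (EC-/LNC-specific gain), G3 (common gain), G4/G5 (specific loss), G6
   (common loss).
3. **Super-enhancers** — enhancers within 12.5 kb are stitched; stitched
   regions are ranked by total signal and the classic hockey-stick tangency
   cutoff (slope-1 point of the rank curve scaled to the unit square) flags
   SEs. Differential SEs are called by two strategies — a group-mean signal
   difference (> 2 gain, < −2 loss) and a paired fold-change vote
   (FC ≥ 2 gain, FC ≤ 0.7 loss, ≥ 5 pairs) — and combined, with a
   high-confidence flag where both agree and both thresholds pass.
4. **Expression integration** — each element is linked to the nearest TSS;
   the package quantifies the enhancer dose–response (expression FC vs the
   number of linked gained/lost enhancers, Wilcoxon rank-sum between dose
   buckets), per-link Spearman correlation of signal and expression,
   biomarker panels per class (top positively correlated genes re-ranked by
   expression FC), tissue sign signatures
   (Nor = g1⁻g2⁻g3⁻g6⁺, EC = g1⁺g2⁻g3⁺g6⁻, LNC = g1⁻g2⁺g3⁺g6⁻),
   priming (enhancer altered in the primary tumor, expression change only in
   the metastasis), plus CPM filtering, a Welch-*t* stand-in DE test,
   hypergeometric gene-set enrichment, PCA, and hierarchical clustering.
5. **Survival** — Kaplan–Meier estimation, fixed-timepoint rates (e.g. the
   2-year rate S(24 mo)), log-rank tests, and median-split stratification of
   patients by the expression of a marker gene.

## Worked example

Simulate the default paired cohort (10 patients × {Nor, EC}, 8 with LNC;
5,000 elements of which 400 carry planted recurrent effects at 4-fold with
80% recurrence and log2-noise 0.3) and call the six classes:

```python
from enhdiff import (CohortConfig, simulate_cohort, pairwise_change,
                     call_differential, assign_groups)

cohort = simulate_cohort(CohortConfig(seed=1))
enhancer_ids = [e.element_id for e in cohort.enhancers]
signal = cohort.signal.loc[enhancer_ids]

calls = {}
for comparison in ("EC_vs_Nor", "LNC_vs_Nor"):
    pairs = cohort.sample_sheet.pairs(comparison)
    table = pairwise_change(signal, pairs, comparison)
    calls[comparison] = call_differential(table, fc_min=2.0, diff_min=0.5,
                                          recurrence_min=6)

groups = assign_groups(calls["EC_vs_Nor"], calls["LNC_vs_Nor"])
print(groups.value_counts().to_string())
```

prints

```
group
none    3101
G3       100
G6        98
G4        52
G1        50
G2        50
G5        49
```

against planted counts of 50/50/100/50/50/100 for G1–G6 (3,100 unaltered):
per-element agreement with the planted truth is 0.9991 here. The same run is
available from the shell:

```bash
enhdiff run --out myrun          # simulate + full pipeline, manifest.json
enhdiff run --config cfg.yaml --seed 7 --out myrun
```

Every stage (`simulate`, `elements`, `diff`, `se`, `integrate`, `survive`)
is also a subcommand that replays one step inside an existing run directory.

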