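# Methods

`nashsig` implements the computational backbone of a transcriptomics-driven
drug-repurposing workflow for non-alcoholic steatohepatitis (NASH): a
connectivity-map style comparison of compound expression profiles against a
disease signature (the *prediction* arm), and the statistics used to judge
whether a treatment reverses a disease expression program within and across
species (the *validation* arm), together with the histology and qPCR
endpoint statistics of the accompanying animal study.  Everything is
exercised end-to-end on a synthetic-data generator with known ground truth.

## Connectivity scoring

Compound profiles are robust z-scores over a fixed landmark feature space
(978 features by default, matching the L1000-style assay geometry).  The
default score is the classical unit-weight Kolmogorov–Smirnov
tag-enrichment connectivity statistic.  Features are ranked by z
descending (ties broken by feature id so the ranking is
platform-independent).  For a signature arm with m members among n
features, the running deviation after rank i is

    D(i) = (#members ≤ i)/m − (#non-members ≤ i)/(n − m),

and the arm's enrichment score ES is the signed extremum of D.  When the
positive and negative extremes tie exactly in magnitude — possible because
D lives on the 1/m, 1/(n−m) lattice — the arm is equally enriched at both
ends and ES is defined as 0; this convention makes the negation and
arm-swap antisymmetries exact identities rather than almost-always
properties.  The combined score is

    score = (ES_up − ES_down)/2   if ES_up and ES_down have opposite signs,
    score = 0                     otherwise,

which lies in [−1, 1]; negative scores mean the compound opposes the
disease signature (an inverse-connectivity hit).  The score is rank-based
and therefore invariant under strictly monotone transforms of z.  A
Spearman-correlation scorer restricted to signature members is provided
behind `scorer="spearman"` as a sensitivity alternative: the underlying
study reports only an "inverse correlation", so offering both the
canonical KS statistic and the literal correlation reading brackets the
ambiguity.

Significance is attached by permutation: null scores are recomputed on
random disjoint arms of the observed sizes drawn from the profile's
feature space, and

    p = (1 + #{|s*| ≥ |s_obs|}) / (n_perms + 1).

This tie-inclusive p is conservative (P(p ≤ t) ≤ t).  It is *not* uniform
under the null: the same-sign clamp gives the score a genuine atom at 0
(it fires for roughly half of pure-noise compounds), so null p-values
accumulate at 1.  For calibration diagnostics, `permutation_p` exposes
`randomized=True`, which breaks ties uniformly at random (seeded); the
randomized rank p-value is exactly uniform on its lattice for any
statistic and is what the uniformity test checks.  Reported screening
results use the conservative default.

`screen_collection` adjusts the per-compound p-values with
Benjamini–Hochberg and calls a compound *inverse* iff its score is
negative and its adjusted p ≤ α.  Note the resolution constraint: the
smallest attainable permutation p is 1/(n_perms + 1), so BH calls at
level α over k compounds require n_perms + 1 ≥ k/α.  Screening the
default 400-compound collection at α = 0.05 therefore needs n_perms ≥
8000; the power validation uses a 20-compound collection with
n_perms = 499, which respects the same bound.

## Differential expression stand-in

The package deliberately does not reimplement a negative-binomial DE
engine.  Library sizes are estimated by median-of-ratios (per-sample
factor = median over genes positive in all samples of count /
geometric-mean count, rescaled to geometric mean 1), and each gene is
tested with a Welch t-test on log2(normalized + 1), BH-adjusted.  The
pseudocount of 1 gives defined behaviour at zero; genes with zero counts
everywhere get p = p_adj = 1 and log2fc = 0 so the table stays complete
for universe accounting.  This stand-in is adequate for the synthetic
validation here; externally produced DE tables (from any engine) are
accepted as first-class input wherever a DE table is consumed.  On null
simulations at 4 samples/group its type-I error is close to nominal
(measured ≈ 5% at α = 0.05 over 4000 genes).

## Signatures

Directional signatures take the N most positive and N most negative
ranking values per arm (N = 250 per arm for the cross-species RNA-seq
signature, 500 per arm for compound-database probe-level signatures).
Zero values enter neither arm; ties at an arm boundary are broken by
|value| descending then id ascending.  Threshold sets use inclusive cuts
log2fc ≥ τ / ≤ −τ with τ = 0.5 by default.  Robust z-scoring uses
(x − median)/(1.4826·MAD) per sample; 1.4826 is the usual normal
consistency constant, and a column with MAD = 0 is rejected by name
rather than silently producing infinities.

## Cross-species overlap tests

Gene lists from the two species are placed in one identifier space via an
explicit ortholog map.  Identifiers are opaque, case-sensitive strings —
no automatic symbol normalisation, because silent case-folding corrupts
cross-species joins.  The default resolution policy (`one2one_only`)
removes every gene involved in a many-to-many relation; the mappable
universe is the set of genes measured in *both* studies and resolvable
1:1, since padding the universe with unmeasured genes only inflates the
"in neither" cell and with it the apparent enrichment.  The 2×2 table
(a = in both lists, b/c = in one, d = in neither) is tested with Fisher's
exact test, one-sided (*greater*) by default with a two-sided option.
The odds ratio is the plain sample odds ratio (a·d)/(b·c), with a
Haldane 0.5 continuity correction added to every cell iff any cell is
zero — matching how such ratios are usually printed, rather than the
conditional-MLE variant.

The *concordance* test overlaps the human up (down) arm with the mouse
disease up (down) threshold set; the *reversal* test overlaps the human
disease-up arm with the mouse treatment-down set, so a significant
enrichment means the treatment pushes down the genes that rise in human
disease.

Being exact, the Fisher test is conservative on a coarse lattice, and the
overlap tests inherit one genuine dependence worth knowing about: under a
partial null (no reversal but real cross-species concordance) the human
up-arm maps to mouse disease-up genes, whose elevated counts make their
treatment-contrast noise quieter than average, so they are
under-represented in the noise-driven treated-down threshold set and the
reversal test becomes conservative (≈2% rejection at nominal 5%).
Calibration is therefore assessed at the full null (no reversal and no
concordance), where all three tests hold their size (measured 4–5.5%).

## Reversal classification

A gene is a disease DEG when its disease-vs-healthy contrast has
FDR ≤ α (α = 0.05).  A disease DEG is *reversed* when the
treated-vs-disease contrast moves it in the opposite direction **and**
that movement is itself significant (FDR ≤ 0.1, the same threshold the
treatment contrast is thresholded at elsewhere in the workflow).  The
significance gate is the package's own choice: with pure sign opposition
a DEG whose treatment contrast is pure noise still flips sign half the
time, so the sign-only rule converges to r + (1 − r)/2 when a true
fraction r of DEGs is reversed — an estimate biased upward by the noise
base rate.  The gated rule recovers r itself when the treatment contrast
is well powered.  Both alternative readings remain available and
labelled: `treated_alpha=None` gives the literal sign rule (useful for
studying the ≈50% noise base rate), and `strict=True` additionally
requires |log2fc_disease + log2fc_treated| < |log2fc_disease|, i.e. the
treated level must end up closer to healthy than the disease level was.
Per-pathway results report n_pathway_genes ≥ n_disease_DEGs ≥ n_reversed
and percent = 100·n_reversed/n_disease_DEGs, undefined (not dropped) when
a pathway has no disease DEGs.

The marker heatmap helper reports, per marker and group,
log2(group mean normalized + 1) − log2(reference-group mean + 1), so the
reference (healthy) column is identically zero.

## Endpoint statistics

The NAFLD activity score follows the standard rubric: steatosis 0–3,
lobular inflammation 0–3, hepatocyte ballooning 0–2, summed to 0–8.  The
printed bands leave the boundaries 33 and 66 ambiguous; this
implementation uses <5 → 0, [5, 33) → 1, [33, 66] → 2, >66 → 3 (reading
"greater than 66%" literally), and 0 foci → 0, (0, 2) → 1, [2, 4] → 2,
>4 → 3.

The Wilcoxon rank-sum test uses midranks.  Exact mode enumerates the full
permutation distribution of the midrank sum via a subset-sum dynamic
programme over doubled (hence integer) midranks — equivalent to
enumerating all C(N, nA) assignments but feasible at moderate N, which is
what allows the exact/asymptotic agreement check at nA = nB = 20.  The
asymptotic mode is the tie-corrected normal approximation; `auto` picks
exact for N ≤ 12.  One-way ANOVA is followed by Fisher LSD pairwise
t-tests on the pooled MSE with N − k degrees of freedom, unadjusted, as
is conventional for that procedure.

ΔCt is Ct(target) − Ct(reference) per sample; ΔΔCt is the arithmetic-mean
difference (treated − control) and fold change 2^(−ΔΔCt).  The reference
gene is a required argument with no default because the source assay
documentation is internally inconsistent about it (ribosomal 18S vs
Rplp0); a silent default would hide that discrepancy.  Outlier exclusion
is the stated mean ± 2·SD rule with the sample SD (n − 1), applied in a
single pass over all values and never re-applied to the retained subset.

## Synthetic-data generator

The generator emulates the study design at the expression level with
every parameter under test control:

- **Mouse arm.** Three groups (healthy / disease-vehicle / treated),
  negative-binomial counts with gene-wise log-normal baselines
  (meanlog 4, sdlog 1.5 on the natural scale, median ≈ 55 counts), a
  single dispersion (0.1) and per-sample library-size factors uniform in
  [0.7, 1.4].  A fraction π (0.1) of genes receive signed log2 effects of
  mean 2 (SD 0.5, floored at 0.25) in the disease group; a fraction r
  (0.7, the headline reversal level) of those are returned a fraction ρ
  (1.0) of the way to the healthy mean in the treated group, the rest
  stay at disease level.  Reversal is implanted on the treated-group
  mean, not by resampling, so ground-truth direction is exact.
  4 samples/group by default, the real study's RNA-seq depth.
- **Human arm.** A two-group cohort (12/group) over the ortholog-map
  targets plus 10% human-only genes; a fraction c (0.8) of mapped mouse
  disease genes receive same-direction effects, the remainder none.
  The map covers 80% of mouse genes with 5% one-to-many pairs.
- **Compound collection.** Standard-normal z profiles over 978 landmarks
  for 400 compounds; one implanted inverse compound subtracts the
  inverse strength (2.0) from the signature's up tags and adds it to the
  down tags.
- **Endpoints.** Histology groups sized 7/16/7 with the treatment benefit
  driven by inflammation and ballooning rather than steatosis, and a Ct
  table with an Rplp0 reference row for every sample and optional
  injected outliers at five noise SDs.

One global seed drives named, CRC-keyed substreams, so adding a generator
never perturbs existing streams and all outputs are bit-reproducible for
a fixed seed.

What the generator does **not** emulate: batch effects, gene–gene
correlation, dispersion trends with expression, probe-to-gene mapping
noise, dose–response structure, or human cohorts with disease biology
beyond the shared mouse effects.  Passing tests therefore demonstrate the
statistical machinery behaves correctly under a clean over-dispersed
count model, not that the original study's numbers are reproduced —
those depend on the real cohorts, the original DE engine and a
proprietary pathway database, all out of scope here.

## Validation problem sizes

The test suite validates on the following problem sizes, chosen to make
each check informative while keeping the full suite fast: oracle
equivalence on every 2×2 table with universe ≤ 30 and every rank-sum
split with N ≤ 10; reversal recovery on 20 seeds of a 2000-gene,
8-samples/group study (8/group rather than 4 so the treatment contrast is
well powered; the estimate lands within a couple of points of the
implanted 70%); null calibration on 1000 simulated 4000-gene study pairs
(the larger universe keeps the exact test's lattice fine relative to the
5% ± 1.5% acceptance band) plus 200 noise-compound screens; and detection
power on 20 seeds of a 20-compound screen at 499 permutations.

## Known limitations

- The Welch-t DE stand-in is less powerful than a proper NB model at
  n = 4/group; at that depth the significance-gated percent-reversed
  estimate is power-limited (≈55% for an implanted 70%), which is why the
  recovery validation uses 8/group.
- The conservative permutation p plus BH makes large-collection screens
  insensitive unless n_perms is scaled with collection size (bound above).
- The sample odds ratio with Haldane correction is biased for extreme
  tables; it is reported for interpretability, while inference rests on
  the exact p-value.
- Exact Fisher p-values are discrete; on small universes the attained
  size can sit noticeably below nominal.
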