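# nashsig

Connectivity-map signature matching, cross-species signature reversal
statistics, and study endpoint analysis for transcriptomics-driven drug
repurposing in non-alcoholic steatohepatitis (NASH).

## What it is for

A repurposing workflow of this kind asks two questions.  *Prediction*:
does some compound's expression profile oppose a disease signature — does
it push the disease's up-regulated genes down and its down-regulated
genes up?  *Validation*: after treating a disease model with such a
compound, does the transcriptome actually move back toward the healthy
state, and does that movement line up with the human disease signature
across species?  `nashsig` implements both arms as a tested, reusable
library plus a thin CLI, and ships a synthetic-data generator with known
ground truth (implanted disease genes, reversal fraction, cross-species
concordance, an implanted inverse compound) so every statistic can be
validated end-to-end.

It is aimed at computational biologists who want the statistical
machinery — directional signatures, the weighted-KS connectivity score,
ortholog-mapped Fisher overlap tests, percent-reversed quantification,
NAS/Wilcoxon/ANOVA-LSD/ΔΔCt endpoints — without the original study's
private data or proprietary databases.

## The statistics at the core

**Connectivity.**  For a compound profile of z-scores over n landmark
features and a disease signature with up/down tag lists, rank features by
z descending and compute, per arm, the signed extremum ES of the running
deviation D(i) = hits(i)/m − misses(i)/(n−m).  The score is
(ES_up − ES_down)/2 when the arm scores disagree in sign, else 0; it lies
in [−1, 1], and negative values mean the compound *opposes* the disease
(inverse connectivity).  Significance comes from permuting the tag lists:
p = (1 + #{|s*| ≥ |s_obs|})/(B + 1), BH-adjusted across the screened
collection.

**Cross-species overlap.**  With lists placed in one id space by a 1:1
ortholog map and a universe of genes measured in both studies, the 2×2
table (a, b, c, d) is tested with Fisher's exact test (one-sided by
default) and summarised by the sample odds ratio (a·d)/(b·c) (Haldane 0.5
if any cell is zero).  Concordance overlaps human-up with mouse-up (and
down with down); reversal overlaps human-disease-up with
mouse-treatment-down.

**Reversal.**  A disease DEG (FDR ≤ 0.05 in disease vs healthy) counts as
reversed when its treatment contrast is significant (FDR ≤ 0.1) in the
opposite direction; per pathway, percent reversed =
100·n_reversed/n_disease_DEGs.  Sign-only and strict ("ends closer to
healthy") variants are available and labelled.

**Endpoints.**  NAFLD activity score = steatosis (0–3) + lobular
inflammation (0–3) + ballooning (0–2); exact/asymptotic Wilcoxon
rank-sum; one-way ANOVA with Fisher LSD; ΔΔCt with fold change 2^(−ΔΔCt)
and the mean ± 2·SD single-pass outlier rule.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Simulate a complete study (seed 1, a 20-compound collection) and run
every stage:

```sh
cat > demo.yaml <<EOF
seed: 1
n_compounds: 20
EOF
nashsig all --config demo.yaml --out-dir demo --n-perms 999
```

The screen (`demo/connectivity.json`) ranks the implanted inverse
compound first and is the only compound called:

```
CPD0002  score -0.700  p_perm 0.001  inverse
CPD0014  score -0.170  p_perm 0.053  null
CPD0003  score -0.115  p_perm 0.323  null
```

CPD0002 is exactly the compound the generator implanted
(`demo/ground_truth.json`), its negative score meaning its profile pushes
the disease signature's up-tags down and vice versa.

The cross-species tests (`demo/xspecies.json`, universe of 1520 genes
measured in both cohorts and mappable 1:1) recover the implanted
concordance and reversal:

```
concordance_up    a=68  OR=3.82  p=9.4e-14
concordance_down  a=79  OR=5.97  p=2.3e-23
reversal          a=51  OR=3.33  p=1.3e-09
```

i.e. the mouse disease state moves the same genes in the same direction
as the human cohort, and the genes up in "human NASH" are significantly
enriched among the genes the treatment pushes down in the mouse.

The endpoint report (`demo/endpoints.json`) shows the treatment benefit
on histology — mean NAS 6.0 (vehicle) vs 3.14 (treated), Wilcoxon
p = 2.1e-04 — and per-marker ΔΔCt fold changes (e.g. Ifng fold change
0.37 after treatment, outliers excluded by the mean ± 2·SD rule).
`demo/reversal.tsv` lists per-pathway percent-reversed; the
disease-enriched synthetic pathways sit near the 4-samples/group
power-limited expectation (see methods), e.g.:

```
pathway_name  n_pathway_genes  n_disease_degs  n_reversed  percent_reversed
PW01          39               17              10          58.8
```

Every artifact is bit-reproducible for a fixed seed; `manifest.json`
records the config hash and per-file checksums.

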