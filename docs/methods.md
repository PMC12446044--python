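# Methods

## The activity index

The MPEAI summarizes the coordinated expression of the four KEGG
methanogenesis modules (M00356, M00357, M00563, M00567) in one number per
sample. Genes are first filtered for robust detection — TPM strictly
greater than 1 in at least 10% of samples (inclusive on the proportion:
1 of 10 samples qualifies at the default 0.10) — then restricted to the
module-annotated set. Each retained gene is Z-scored across samples and
combined with inverse-variance weights `w_g = 1/(sigma_g^2 + eps)`,
`eps = 1e-6`; the weighted mean Z per sample is finally standardized
across the cohort. The index is therefore relative: it says which samples
transcribe the pathway above or below the cohort average, not an absolute
methane flux.

Conventions and degenerate inputs:

* All standard deviations use the sample convention (ddof = 1), for the
  per-gene sigma and for the final cross-sample normalization alike. One
  convention everywhere keeps the mean-0/sd-1 invariants exact.
* Zero-variance genes are dropped before Z-scoring (and reported), rather
  than assigned Z = 0: the epsilon guards only the weight formula, and
  0/0 in the Z-score is undefined. A constant raw-activity vector is an
  error, not a silent zero.
* The filter runs on the full expression matrix first, then intersects
  with the module annotation; with the weights' variance floor, the order
  only affects which genes are reported as filtered, not the score of any
  retained gene.
* The layer is a parameter. The index is about *expression*, so the MT
  matrix is the default input, but the API is layer-agnostic and the
  pipeline config can score the MG layer instead (`activity_layer`).
* All four modules pool into one gene set by default; any module subset
  can be requested.

The sklearn-transformer form (`MethanogenesisActivityIndex`) learns the
gene set, per-gene moments, weights and the activity location/scale on a
training cohort; `transform` then scores arbitrary samples on that fitted
scale. `fit_transform` on a single cohort reproduces the one-shot index
definition exactly.

## MG-vs-MT comparison

Module totals are per-sample sums of TPM over the module's genes (a gene
annotated to two modules contributes to both). Layer contrasts use the
two-sided Mann–Whitney rank-sum test — exact enumeration when the pooled
sample count is at most 20 with no ties, tie-corrected normal
approximation with continuity correction otherwise. A paired signed-rank
variant is available but not the default: the layers are analyzed as two
groups of samples. Group comparisons of diversity metrics use
tie-corrected Kruskal–Wallis (H = 0, p = 1 when all observations tie).
Decisions are made on raw p-values at 0.05; Benjamini–Hochberg adjusted
values are always reported alongside but never replace the raw-p rule.

Alpha diversity is the Shannon index in bits (base 2, configurable),
computed on relative abundances, optionally after rarefaction. Rarefaction
subsamples each sample's counts to a common depth without replacement
(multivariate hypergeometric draw), drops under-depth samples with a
warning, and defaults to the minimum per-sample total. Community
structure between layers is tested with ANOSIM on Bray–Curtis distances
of relative abundances; the distance is a parameter. ANOSIM ranks all
pairwise distances (midranks for ties), computes
`R = (mean between-group rank − mean within-group rank)/(M/2)` and a
permutation p-value `(1 + #{R_perm ≥ R_obs})/(1 + n_permutations)`, so
the smallest attainable p is `1/(1 + n_permutations)`. The permutation
stream is seeded; the implementation is cross-checked against
scikit-bio's ANOSIM in the test suite.

## Driver discovery

A regression random forest predicts the normalized index from per-sample
taxon relative abundances. Defaults follow common microbiome practice for
this design: `mtry = 3` candidate features per split (an absolute count)
and `ntree = 10,000`; one master seed drives per-tree randomness so any
tree count is reproducible. Importance is the total decrease in node
variance attributable to a feature, summed over all trees and scaled to
response units (the regression IncNodePurity); permutation importance is
available as an option. Taxa are ranked by descending importance with
lexicographic tie-breaks, the top 30 are screened with Pearson
correlation against the index (two-sided t-test on n − 2 df), and taxa
with r < 0 at raw p ≤ 0.05 are flagged as mitigation candidates. A
zero-variance abundance vector yields an undefined r, reported as missing.

Because the strongest associations in rumen data are typically
GTDB-placeholder lineages without cultured representatives, a second pass
removes taxa whose names match placeholder patterns — a species epithet
`sp` followed by nine or more digits (a genome accession), or an
alphanumeric placeholder genus token such as `UBA2810` or `RUG023` — and
repeats the forest and the screen on cultivated taxa only. The patterns
are configurable; names are matched verbatim (GTDB suffixes like `_D` are
part of the genus token and do not trigger the placeholder rule).

The abundance layer fed to the forest defaults to MT (the activity side)
and is switchable (`taxa_layer`).

## Synthetic data

The generator emulates the statistical structure the analysis assumes for
a 48-animal paired cohort; it does not simulate reads, sequencing error,
or phylogenetic correlation among taxa, so passing tests demonstrate that
the analysis recovers planted structure under log-normal compositional
noise — not that it is robust to alignment ambiguity, batch effects or
database incompleteness in real data.

Construction, all driven by one seed through named substreams (activity,
genes, taxa, noise):

* latent activity `a_s ~ N(0,1)`, one value per sample;
* module gene g: MT TPM `exp(b_g + beta*a_s + e)`, MG TPM
  `exp(b_g + e')/fold`, with baselines `b_g ~ N(3, 0.7)` in natural log
  (median ≈ 20 TPM, comfortably above the detection filter), noise sd 0.5
  and fold 2.5 — so MT module totals exceed MG by ≈ 2.5x and respond to
  `a_s` while MG totals do not;
* 400 background genes, i.i.d. log-normal in both layers, so the
  expression filter and module restriction operate on a realistic mix;
* 200 taxa with shared log-normal baselines across layers and per-layer
  noise; 8 driver taxa are multiplied by `exp(-gamma*a_s)` (gamma = 0.8)
  in both layers before closure; 10 archaeal taxa have their MT weights
  divided by 4 (the suppression factor) and a +0.5 log-abundance boost in
  both layers (archaea are genomically abundant); columns are closed to
  relative abundances.

Parameter choices worth noting: `beta = 0.3` keeps the per-gene coupling
moderate (per-gene correlation with `a_s` ≈ 0.5) while the 100-gene
average makes the index track the latent activity closely (r ≈ 0.93 at
n = 48), and inflates the realized MT/MG fold only by `exp(beta^2/2)` ≈
1.05, keeping the mean fold inside 2–3 for fold = 2.5. `gamma = 0.8`
against total log-noise sd 0.5 yields driver–index correlations around
−0.45 to −0.7 after compositional attenuation, the magnitude regime of
interest for mitigation candidates. Driver coupling acts multiplicatively
*before* closure, deliberately: the real analysis also operates on closed
data, so realized correlations include the compositional distortion.
Driver names mix cultivated binomials with accession placeholders so both
discovery passes are exercised; a configurable fraction (default 0.6) of
the remaining taxa get placeholder names.

With `gamma = 0` the planted drivers are exchangeable with noise taxa and
the Pearson screen's false-positive rate sits at the nominal 5%, which
the test suite checks.

## Problem sizes and determinism

The validation suite runs the full design at its native size (48 samples,
200 taxa, 500 module+background genes) but trims ensemble and replicate
counts to keep iteration fast: 1,000 trees for recovery checks (the
ranking stabilizes well below that), 100–200 replicates for power and
null-calibration estimates, 199 permutations for ANOSIM null calibration.
`scripts/acceptance.py` uses the same sizes. Every stochastic component
takes an explicit seed; file outputs print floats with `repr` so reruns
are byte-identical and round-trips are lossless.

## Limitations

* The index is cohort-relative; scores are not comparable across cohorts
  scored separately unless one is transformed onto the other's fitted
  scale.
* Inverse-variance weighting favors flat genes; a gene that is biologically
  responsive (high variance) is down-weighted by design, which stabilizes
  the index but can mute genuinely dynamic signal.
* Compositional data: correlations between closed abundances and the
  index inherit closure-induced dependence; planted-truth simulation
  quantifies but does not remove it.
* The forest's importance ranking is stable under the default ensemble
  size, but importance *values* are not calibrated effect sizes.
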