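# Methods

## The problem

Amplicon sequencing of very-low-biomass specimens (individual insect guts,
dilution series, swabs) yields libraries in which reagent-derived DNA and
well-to-well leakage account for a substantial fraction of reads. Extraction
blanks sequenced alongside the specimens record that background, but they
are imperfect witnesses: blanks also receive cross-contaminating reads
*from* the specimens, so "remove everything seen in a blank" is overly
conservative, while prevalence-only rules are underpowered when only a
handful of blanks exist. `contamscope` implements a two-part strategy:
(1) a conjunctive major-contaminant classifier that demands both high
prevalence among specimens and enrichment in the blanks, and (2) retention
of the blanks in every downstream analysis so residual contamination stays
visible instead of being declared solved.

## Contaminant classification

For taxon *i*: prevalence is the fraction of specimens with a nonzero
count; abundance means are taken over *all* specimens and *all* blanks,
zeros included, in either relative (per-sample proportions) or raw-count
mode. The flag requires prevalence ≥ τ **and** blank mean > specimen mean.

Decisions in places the rule itself is silent:

- **Prevalence comparator is inclusive (≥ τ)** with a `strict_prevalence`
  switch, and the **denominator is specimens only** (configurable to all
  libraries via `prevalence_include_controls`). Both conventions are
  exposed because field descriptions of this rule vary between "at least"
  and "more than", and between "samples" and "libraries".
- **The abundance comparison is strict (>)**: a taxon absent from every
  blank can never be flagged. Ties (mathematically equal means) are not
  flagged. Because the strict inequality sits on a knife edge under
  floating-point summation, the decision is evaluated in exact integer
  arithmetic over a common denominator (the lcm of the sample totals in
  relative mode); the reported evidence columns remain floats.
- The **prevalence rule** classifier implements only the published
  rule — flag when `P_blank/(P_blank + P_specimen) > t`, default
  `t = 0.5` — not the score-based statistic of the decontam package. Its
  evidence table uses raw-count abundance so it stays defined when a blank
  is empty.

Removal deletes flagged taxa from every sample, blanks included; samples
are never dropped, and the removal log carries each taxon's evidence row.

## Diversity

- **Chao1** uses the bias-corrected form with the (F₂+1) denominator and
  its standard variance formula (separate F₂ = 0 branch), reported with a
  standard error. Proportions are rejected: the estimator is defined on
  counts.
- **Shannon** uses the natural log by default (base configurable).
- **Bray-Curtis** is computed on proportions by default to neutralise
  depth differences; a raw-count mode exists because rarefaction or
  normalisation conventions differ between studies.
- **PCoA** is classical scaling: double-centre −d²/2, eigendecompose,
  scale eigenvectors by √λ for λ > 0. Negative eigenvalues (expected for
  semi-metric dissimilarities) are reported unchanged — no
  Lingoes/Cailliez correction — and proportion explained is relative to
  the positive spectrum only. Axes at |λ| below 1e−10 of the spectral
  radius are treated as null.
- **Control proximity** pairs each specimen with its replicate's blank via
  the `replicate` metadata field (mean distance when a replicate has
  several blanks). Flagging is either the k closest specimens (ties broken
  by distance then sample id, deterministically) or a distance threshold;
  no default numeric rule is claimed because "closest" is
  context-dependent. Summaries report mean ± SEM for flagged vs all.

## Inference

- **Wilcoxon rank-sum**: exact enumeration when n₁+n₂ ≤ 12 without ties,
  otherwise normal approximation with tie and continuity corrections
  (via `scipy.stats.mannwhitneyu`).
- **Holm** (step-down) for alpha-diversity comparison families and **BH**
  (step-up) within each differential-abundance contrast, both monotone and
  capped at 1, order-preserving.
- **PERMANOVA** follows the distance-based trace formulation: with G the
  Gower-centred matrix of −d²/2 and H the hat matrix of a sequentially
  nested design, SS(term) is the increment in tr(HG). Sums of squares are
  sequential (Type-I) in the caller's factor order, interaction last, so a
  two-factor partition is exactly additive. p-values use free permutation
  of sample labels with the add-one convention
  p = (1+#{F\* ≥ F})/(1+n_perm); when the requested permutation count
  covers all distinct reorderings (or `exact=True`), enumeration replaces
  sampling and the add-one p equals the exhaustive p. Permutations are
  vectorised (batched G reindexing) and bit-reproducible given a seed.
- **Two-way ANOVA** is OLS with Type-I SS in the order (A, B, A:B); empty
  design cells abort with the cell named.
- **NB Wald differential abundance** is an intentionally simplified
  DESeq2-style core: median-of-ratios size factors (geometric-mean
  reference over all-positive genera, positive-entry fallback), per-genus
  method-of-moments dispersion on normalised counts floored at 1e−8 (no
  shrinkage across genera), a two-group log-linear model fitted by IRLS
  with the size factor as offset, Wald z on the group coefficient, and BH
  across genera. There is no fold-change shrinkage and no independent
  filtering, so printed fold changes from shrinkage-based tools are
  context, not comparable targets. A genus with all-zero counts in one
  group gets a 0.5 pseudo-count on the normalised group means, a
  delta-method standard error, and a `boundary` flag. `size_factors`
  accepts `"unit"` or an external vector for designs where library sizes
  are known (a global composition shift is otherwise unidentifiable from
  depth — the classic compositionality caveat).
- **Gehan-Breslow-Wilcoxon** is the weighted log-rank test with weights
  equal to the number at risk, emphasising early deaths; the
  implementation delegates to `lifelines` and is cross-checked in the
  tests by a direct observed-minus-expected summation. Median survival per
  group (Kaplan-Meier) is reported alongside.

## The synthetic-data generator

The generator emulates the study design the package is built around:
3 replicates (donor codes AP4/BP3/P10; one uninfected, two
gametocyte-infected) × 3 treatments (mock, amoxicillin,
amoxicillin+clavulanate) × 2 timepoints (24/72 h) × 5 specimens = 90
specimens, plus one PBS blank per replicate.

Model, per specimen *j*:

- community composition: a global mean over 60 community taxa assigned to
  the field-familiar genera (Elizabethkingia, Wigglesworthia, Asaia,
  Serratia and others; three taxa annotated only to family to exercise
  the aggregation fallback); replicate bases are Dirichlet draws around
  the mean (concentration 50 per taxon weight), specimen compositions
  Dirichlet around their replicate base (concentration 200);
- biomass B_j ~ LogNormal(ln 2, 0.8) and contaminant mass c₀ = 1, giving
  mixture weight w_j = B_j/(B_j+c₀): the contaminant share of a library
  rises as biomass falls;
- reads ~ Multinomial(N_j, w_j·true_j + (1−w_j)·pool) with depth
  N_j ~ LogNormal(ln 30000, 0.3) floored at 500 (depths similar across
  specimens and blanks, matching the low-biomass regime where blank
  libraries amplify to comparable size);
- the contaminant pool spans 40 taxa from typical reagent-contaminant
  genera, Dirichlet(10) once per study — even enough that every pool
  taxon is expected in ≫80% of specimens, so the planted contaminants
  satisfy both classifier criteria in expectation;
- blanks draw from (1−ε)·pool + ε·(mean specimen mixture of the
  replicate) with ε = 0.05 modelling specimen→blank cross-contamination;
  blank→specimen leakage is omitted for identifiability;
- planted effects multiply designated genus proportions by 2^(−δ) before
  renormalisation in chosen treatment×timepoint cells (defaults: δ = 2 on
  Elizabethkingia in both antibiotic arms at 24 h and on Asaia in the
  amox/clav arm at 24 h); infected replicates carry a 4× Elizabethkingia
  enrichment.

Community and pool taxa are disjoint, so the contaminant-origin fraction
of any specimen is observable and equals 1−w_j in expectation, and
classifier sensitivity/specificity can be scored exactly against truth.
What the generator does **not** emulate: taxa that are simultaneously
genuine community members and reagent contaminants, sample→sample
leakage, PCR/chimera artefacts, or compositional realism of any
particular insect system — so a perfect recovery here demonstrates
correctness of the decision logic under the stated model, not performance
on arbitrary real data.

Survival records are exponential event times per group, discretised to
whole days by ceiling (deaths noticed at the next daily check) and
administratively censored at the horizon.

## Numerical and design choices

- Counts are validated at the boundary: non-negative integers, unique
  ids; zero-total samples are rejected wherever a proportion would be
  undefined unless explicitly dropped.
- TSV is canonical (human-diffable); the BIOM 1.0 JSON schema is
  supported for interchange through a minimal stdlib-JSON reader/writer.
- Lineage exclusion (mitochondria/chloroplast and the like) is
  case-insensitive substring matching on any rank.
- Genus aggregation groups taxa unannotated at the requested rank under
  their deepest available label ("lowest possible level" fallback) rather
  than dropping them; per-sample totals are conserved exactly.
- Permutation and simulation sizes used by the test-suite and the
  acceptance script (999 permutations, 500-replicate calibrations, 90+3
  sample studies) were chosen as the smallest sizes at which the
  calibration bands (e.g. type-I error 0.05 ± 0.02) are statistically
  meaningful.
- The pipeline orders contaminant removal before genus aggregation and
  applies sample subsetting before aggregation for per-cell contrasts;
  the order is logged in the manifest.

## Known limitations

- The major-contaminant rule assumes blanks and specimens were sequenced
  to comparable depth when raw-count mode is used; relative mode is the
  default for that reason.
- Dispersion estimates without shrinkage are noisy at small n; Wald
  p-values are approximate and mildly anti-conservative for very low
  counts. The test-suite's null-uniformity check (KS < 0.08 at n = 20 per
  group) bounds the practical effect at the sizes the package targets.
- PERMANOVA uses free permutations; restricted/stratified permutation
  schemes are not implemented.
- The prevalence-rule classifier is the published decision rule, not the
  full probabilistic model of the decontam package.
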