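# Methods

## Model

`fuzzyact` scores the gain/loss-of-function state of a gene in a sample by
Mamdani fuzzy inference over four inputs — mutation class, hotspot
recurrence, expression level and copy number — and one output,
`Gene_activity` on [−1, 1]. The pipeline runs in five stages:

1. **Fuzzification.** Mutation class and recurrence are categorical and
   fuzzified as singletons on integer codes (a code matches its category
   when |x − code| < 0.5; any strictly-between tolerance is equivalent on
   integer codes). Expression categories are fitted per gene (below); the
   copy-number variable is fixed for all genes.
2. **Rule firing.** Thirty IF/THEN rules (shipped in
   `data/default_rules.fcl`) are evaluated with AND = minimum and
   OR = maximum — the IEC 61131-7 FCL defaults. A rule's activation is its
   antecedent degree.
3. **Implication and aggregation.** Each rule's consequent membership
   curve is clipped (min) at its activation; clipped curves merge
   pointwise by maximum (union).
4. **Defuzzification.** The score is the centroid Σxᵢm(xᵢ)/Σm(xᵢ) of the
   aggregated curve on a uniform grid over [−1, 1], with trapezoidal
   end-weights so the value equals the ratio of trapezoidal-rule integrals
   of x·m and m. Default resolution 2001 points (configurable; agreement
   with a 10× finer grid is ~1e-4). An identically-zero curve defuzzifies
   to 0, the neutral score — this happens only when every category's
   membership underflows, e.g. between extremely well-separated expression
   clusters.
5. **Gene × sample summary.** GoF = max(0, max of the pair's variant
   scores); LoF = min(0, min). Positive-scoring variants are the pair's
   "GoF variants", negative-scoring its "LoF variants" — the only
   sign-consistent reading of max/min aggregation. Unmutated pairs (and
   samples whose only records are silent) are scored once through the
   No_Mutation rules and sign-split the same way, so every pair carries a
   usable per-sample score for downstream stratification.

## Input variables

**Expression (per gene).** Samples are ranked (stable ties) and split into
three groups as evenly as possible, the lower-rank groups taking the extra
members when n mod 3 ≠ 0. With group means m_low ≤ m_med ≤ m_high and stds
s_low, s_med, s_high (each floored at 1e-3 of the observed range):
low = sigmoid decreasing at m_low, medium = Gaussian(m_med, s_med),
high = sigmoid increasing at m_high. Sigmoid slopes are matched to the
half-maximum width of a Gaussian with the group's own std,
a = sqrt(8·ln 2)/s, so the low/high shoulders fall off like the tertile
they summarize. The variable's domain is the observed range padded by
3·s_med. Fitting requires ≥ 6 samples with ≥ 3 distinct values; constant
genes are skipped (all-NaN scores, logged). Fits are per gene across all
samples, not per lineage.

One consequence worth knowing: for unimodal (e.g. Gaussian) data the
middle-tertile std (~0.25σ) is much smaller than the spacing between
tertile means (~1.09σ), so between category anchors the best membership
degree dips well below 0.5 (to ~0.07–0.09). Every point of the observed
range still has positive membership somewhere and each category anchors at
its mean with degree ≥ 0.5, which is what the tests assert.

**Copy number (fixed).** On log2 copy-ratio scale: deleted is fully on at
≤ −0.6 and off beyond −0.2, amplified mirrors it at +0.2/+0.6, neutral is
a triangle on (−0.4, 0, 0.4). The ±0.2/±0.6 breakpoints are the
conventional SNP-array shallow/deep gain-loss cutoffs; all are
configurable through `default_cn_variable` or the rule file.

**Recurrence.** For each (gene, position) the number of *distinct* samples
carrying any variant there is counted; the flag is set when
count/n_samples strictly exceeds the threshold (default 0.01). The
denominator is the whole cohort, not just mutated samples. Position is the
amino-acid position parsed from protein-change strings, falling back to
genomic coordinate; unresolvable positions are non-recurrent with a
warning.

**Output categories.** The seven `Gene_activity` categories are evenly
spaced and symmetric: no_effect = Gaussian(0, 0.15), low_GoF/low_LoF at
±1/3, GoF/LoF at ±2/3 (same std), and high_GoF/high_LoF as sigmoids
inflecting at ±0.85 with slope sqrt(8·ln 2)/0.15. These are this package's
defaults — chosen for even spacing with neighbor overlap near
half-maximum — and are fully overridable via the FCL file.

## Dominant-negative (TP53-like) genes

For genes whose recurrent missense mutations inactivate rather than
activate (TP53 by default, configurable), every rule whose antecedent
mentions an activating class (missense, in-frame indel) has its consequent
mirrored through high_GoF↔high_LoF, GoF↔LoF, low_GoF↔low_LoF; truncating
and No_Mutation rules are untouched. Implemented as consequent mirroring
rather than hand-written extra rules, so the remapping stays consistent
with whatever rule base is loaded. Because the shipped output categories
are symmetric, the special-gene score in activating contexts is exactly
the negative of the default score.

## Gene classification

Genes mutated (≥ 1 non-silent variant) in strictly more than 1% of samples
are classified. Among a gene's mutated samples, gof_gene_score is the
fraction with GoF > |LoF| and lof_gene_score the fraction with
|LoF| > GoF; exact ties count toward neither (the two >50% majority
conditions are not exhaustive, so both-≤50% genes report `unclassified`
rather than being forced to a side).

## Drug-sensitivity evaluation

- **ROC-AUC**: Mann–Whitney formulation (ties 0.5); backed by
  scikit-learn's trapezoidal ROC, cross-checked in tests against an
  explicit pairwise count.
- **Mixture calls**: a 2-component Gaussian mixture is fitted to the
  response metric (EM via scikit-learn, median-split initialization,
  tolerance 1e-8, ≤ 200 iterations, seeded). X solves
  w₁N(x|μ₁,σ₁) = w₂N(x|μ₂,σ₂) — the *weighted* density intersection, i.e.
  the decision boundary of the fitted model (linear for equal variances;
  otherwise the quadratic root inside (μ₁, μ₂)). Calls: resistant strictly
  below min(X, μ₁+σ₁), sensitive strictly above max(X, μ₂+σ₂), else
  intermediate. A vanishing component (weight < 1e-3) raises a fit error
  advising manual thresholds.
- **Paired bootstrap**: class-stratified resampling of the paired scores,
  normal approximation on observed ΔAUC / sd(bootstrap ΔAUC), two-sided.
  Identical score vectors short-circuit to p = 1.
- **Fixed thresholds**: per-compound published cutoffs (PLX4720, AZD6244,
  Erlotinib on ActArea; Nutlin-3 on IC50; BYL719 on EC50 + Amax jointly)
  are applied directly without a mixture fit.

## Synthetic cohorts

The generator emulates the structure of a cell-line panel with matched
profiles: per-gene Gaussian background expression (means uniform in
[4, 12], stds in [0.5, 1.5], a log2-microarray-like scale), log2 copy
ratios N(0, 0.15), and planted roles. Defaults — 300 samples, 50 genes, 5
oncogenes and 5 tumor suppressors, 20% mutant fraction per driver, 80% of
a driver's mutants sharing one hotspot position, expression shift 1.5
within-gene stds, copy-number shift 0.5 — are the study conditions the
test suite runs under; they were chosen once as a realistic desk-scale
stand-in for a real panel (a 675-line panel is neither downloadable nor
necessary for structural validation). Oncogene mutants gain recurrent
missense hotspots with raised expression/CN; suppressor mutants carry
truncating classes with lowered expression/CN; TP53-like genes carry
recurrent missense hotspots with *raised* expression (stabilized mutant
protein) and neutral CN, which the mirrored rules read as high LoF.
Neutral genes receive sparse (1%) non-recurrent missense passengers.
ActArea couples to the first oncogene's mutation indicator with β = 2.5
and noise sd 0.6 (a cleanly bimodal mixture). Everything derives from one
seeded generator, so cohorts are bit-identical given the seed.

What the generator does **not** emulate: mutational signatures, zygosity
and LOH, subclonality, lineage structure, expression–CN covariation in
wild-type samples, and non-Gaussian response distributions. Passing tests
therefore demonstrate that the machinery implements the stated model and
recovers planted structure under clean conditions, not that it reaches any
particular accuracy on real tumor panels.

## Numerical notes and limitations

- **Monotonicity ripple.** Holding mutation context and CN fixed, the
  score traces the rules' consequent ordering as expression rises, but not
  strictly pointwise: between category anchors the aggregated curve thins
  and the centroid of a clipped consequent drifts with the clip level.
  The measured ripple is ≲ 0.02 (bounded by the centroid travel of a
  single clipped category, < 0.05, versus the 1/3 spacing between output
  categories). Tests assert ripple-bounded monotonicity plus exact
  ordering at the tertile anchors and range endpoints.
- **Near-neutral asymmetry.** The No_Mutation rules are deliberately
  asymmetric (low expression *or* deletion → LoF, but high expression *or*
  amplification → only low_GoF), reflecting that loss is stronger evidence
  of suppressor inactivation than gain is of oncogene activation. With
  overlapping tertiles the low/high sigmoid tails therefore shift a
  "median expression, neutral CN" sample's score by ~1e-3 below zero; the
  score is exactly 0 only when the category tails underflow.
- **Deduplication.** Repeated (sample, gene, class, position) variant rows
  score identically and are dropped on ingestion.
- **Determinism.** Scoring is fully deterministic; the only stochastic
  components (mixture EM, bootstrap) take explicit seeds.
- Allele-specific/zygosity modeling, methylation and LOH inputs, weighted
  rules, hedges and alternative defuzzifiers are out of scope; the rule
  grammar is the FCL subset documented in `fuzzy.py`.
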