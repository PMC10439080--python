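# Methods

This note documents the statistical procedures `picnorm` implements,
the choices made where a procedure is underdetermined, what the
synthetic-data generator does and does not emulate, and the problem
sizes used by the validation suite.

## Response coding

Every naming trial is assigned exactly one validity class:

* **valid** — a recognizable name with a usable latency;
* **invalid** — a name with a missing/invalid latency, or a rootless
  neologism (a name absent from the lexicon with no root mapping);
* **no response** — an empty or unrecognizable transcription.

Norms and analyses use valid trials only. Where the original workflow
relies on human judgement of audio, `picnorm` substitutes explicit
lookup tables (`UnificationMaps`): a surface-form → infinitive map, an
infinitive merge map (aspect pairs, reflexive/non-reflexive variants —
merge targets must be fixed points of the map), a root-class map, a
synonym map, and a lexicon. Names are lowercased and trimmed before any
lookup; unmapped cases degrade conservatively (identity unification,
Lexical Code 4) with a logged warning, so the coding is deterministic
and auditable but only as good as the supplied tables. Inflectional,
tense, number, and reflexivity errors are treated as valid responses by
routing them through the infinitive map. A multiword response string is
treated as a single name; no tokenization is attempted.

Verb responses can be unified under three strategies: (1) raw surface
forms; (2) recoded to the infinitive; (3) infinitives merged across
aspect and reflexivity. Strategy 3 is the default for downstream
analysis of action pictures; all three are reported side by side.
Strategy-3 output is idempotent by construction.

## Name agreement

For each picture the valid (unified) responses define a categorical
distribution (k names, proportions pᵢ). Two indices are computed:
NA% = 100·maxᵢ pᵢ and the entropy H = Σ pᵢ log₂(1/pᵢ) in bits
(0 ≤ H ≤ log₂ k, 0 iff unanimous). No small-sample bias correction or
smoothing is applied to H. Ties for the modal name are broken
lexicographically and flagged — the tie-break is arbitrary but
deterministic, and downstream lexical coding requires a unique dominant
name. Only exact (post-unification) matches count toward NA%;
same-root variants are reported separately through the Lexical Code
percentages. A picture with zero valid trials yields a flagged norm row
with missing statistics, never a silent zero.

## Complexity Index

CI = 2·(length − mean_class)/SD_class
 + [initial fricative/affricate] + [initial cluster] + [medial clusters]
 + n_stems + [derivation] + [prefix] + [suffix]
 + [not available in country] + access points + [loanword],

with access points 1 / 0.5 / 0 for *not at all or rarely* / *quite
often* / *very often* accessible to preschool children. All features
are inputs; no phoneme counting or morphological analysis is performed.
Class length mean/SD default to the supplied word table's own
per-class statistics and can be pinned to external constants (needed
when the reference word list behind published statistics is not
available). Subscores are grouped as phonology (the three cluster/
fricative flags), morphology (stems + derivation + affixes; the stem
point counts as morphology), and exposure (availability + access +
loanword), and always sum, with the length term, to the total exactly.
Cross-class standardization of CI uses the pooled sample SD (ddof=1).

## Transformations and rank statistics

Naming latencies are analysed as −1000/RT. Predictors are transformed
by sample skewness: |skew| > 1 → inverse (1/x for positive skew,
1/(max + 1 − x) for negative), 0.5 < |skew| ≤ 1 → square root (on
reflected data for negative skew), otherwise untouched; frequency is
always log-transformed. The 1 and 0.5 cut-offs are conventional
descriptive thresholds, not estimated, and are configurable. Inverse
transforms invert the sign of downstream effects; each spec records a
direction note. All continuous predictors are demeaned before
modelling.

Correlation matrices use Spearman's rho on pairwise-complete cases with
Bonferroni-corrected significance flags (family = number of unique
variable pairs). Object–action comparisons use the two-sample two-sided
Wilcoxon rank-sum test: the exact null distribution when the combined
sample is ≤ 20 without ties, a tie-corrected normal approximation
otherwise; the effect size is r = |Z|/√N from the normal approximation
in either case, and the significance threshold is Bonferroni-adjusted
(α/m; 0.005 for the conventional ten-variable family). Collinearity is
screened by VIFⱼ = 1/(1 − R²ⱼ) with an intercept in each auxiliary
regression; exact collinearity reports ∞ with a warning rather than
failing.

## The latency model

The analysis model is a Gaussian linear mixed model on the −1000/RT
scale with random intercepts for participants, pictures, and
alternative names nested within pictures (crossed with participants),
fitted by REML via statsmodels (single-group variance-component
parameterization for crossed structures). Random slopes are out of
scope: the predictors are item-level, so intercept-only structure is
maximal.

The maximal structure is reduced deterministically, smallest variance
first, with every step logged:

1. factors with fewer than two levels are excluded up front;
2. a fit that raises, fails to converge, or yields non-finite
   fixed-effect standard errors loses its smallest-variance component;
3. a component with estimated variance below 1e-6 is dropped;
4. a component whose variance falls below 15% of the residual variance
   is refitted without, and dropped when the ML likelihood-ratio
   statistic is below 3.84 (the χ²₁ 5% point — conservative, since the
   boundary null is a χ² mixture).

Step 4 exists because boundary REML estimates of truly absent
components settle at small positive values of order σ²/n rather than
exactly zero, so a fixed absolute threshold alone cannot identify them;
the likelihood check makes the reduction scale-free. A structure
reduced to a single component is refitted in the canonical grouped
parameterization, which is numerically better behaved near the
boundary; with no components left the model collapses to OLS, which is
also the exact limit of the mixed model. Rows with any missing value
are dropped (complete-case) and counted.

Fixed effects are reported as estimate, SE, t (residual degrees of
freedom, n − p; no finer approximation is attempted), and the effect
size d = 2t/√(df) — a common mixed-model convention adopted because no
canonical formula exists; d is omitted for the intercept, where it has
no clear meaning.

## The synthetic-data generator

The generator produces complete norming experiments with known ground
truth, emulating the data *structure* of a two-part study (objects
first, then actions):

* **names** — each picture owns a fixed pool of synthetic tokens; its
  true name probabilities are a single Dirichlet draw. The
  concentration (default: mass 24 on the dominant name for objects, 10
  for actions, 1 elsewhere, pool of 5) controls agreement: those
  defaults put average NA% in the low-90s/high-70s band typical of a
  curated object/action picture set. Action responses surface as one
  of two inflected forms per name, and explicit unification maps
  (surface → canonical, one aspect-pair merge and one synonym per
  pool) are generated alongside so the coding stage has real work;
* **outcomes** — i.i.d. valid/invalid/no-response labels per class.
  Defaults are the observed rates of a large Polish norming study
  (objects 98.36/0.32/1.21%, actions 95.61/0.87/3.51%), renormalized
  onto the simplex since the printed object rates sum to 99.89%;
* **latencies** — the generator inverts the analysis model exactly:
  y = −1000/location + x'β + u_participant + v_picture + w_name + ε
  with Gaussian components, RT = −1000/y. Location defaults are
  897.33 ms (objects) and 1157.70 ms (actions), matching the central
  tendency of the reference study; default β magnitudes mirror its
  object-model estimates. Draws with y ≥ 0 are resampled on the
  residual and counted; a configuration violating on more than 1% of
  trials is rejected with advice to move the intercept. Because the
  model is exactly well-specified, parameter recovery by the inference
  module is a clean oracle. The induced RT distribution is
  right-skewed (reciprocal-Gaussian), a modelling choice — the true
  trial-level RT shape is not being claimed;
* **predictors** — drawn i.i.d. Gaussian (SD 0.5) per (picture, name)
  directly on the analysis scale, i.e. already transformed and
  demeaned. They are deliberately *not* derived from the simulated
  name distributions or ratings, so the generator does not reproduce
  the correlation structure of real norming variables (e.g. the
  empirical H of a picture does not feed its latency model);
* **ratings** — integer scales (goodness of depiction 0–3, image
  agreement / familiarity / imageability 1–7, age of acquisition
  1–18), drawn as round-then-clip discretized Gaussians around item
  means; rater counts default to those of the reference rating studies
  (36/46/37/54/58). No ordinal response model is attempted;
* **word estimates** — AoA, imageability, and log frequency per name,
  with a class-specific share of missing frequencies (8.1% objects,
  17.45% actions) mirroring names that corpus lookup cannot cover.

One seed drives the whole dataset; each stage derives its own stream
deterministically (`SeedSequence` spawn keys), so identical
config + seed reproduces byte-identical tables. Consequences of the
simplifications: passing tests demonstrate the correctness of the
computational chain and the identifiability of the model under its own
assumptions — not robustness to real-data pathologies (speed-accuracy
trade-offs, non-Gaussian random effects, correlated predictors,
rater drift).

## Validation problem sizes

The parameter-recovery suite simulates 20 replicate experiments of
60 participants × 80 object pictures (pool of 3 names, all 8 fixed
effects nonzero, SDs 0.12/0.09/0.08/0.15) and requires the 2-SE
intervals to cover the true coefficients in at least 90% of the 160
(coefficient, replicate) checks — the nominal rate is ≈95%. The
zero-variance reduction check runs at 20 × 12; Monte-Carlo ordering
checks (entropy control, participant-variance ordering) use 50–200
replicate pictures or datasets; oracle comparisons use 200–1,000 random
cases. These sizes were chosen to make sampling error small relative to
the tested margins while keeping the whole suite desk-scale.

## I/O conventions

Canonical tables are tab-delimited UTF-8 with a header row and empty
fields for missing values (Polish orthography requires UTF-8
throughout); comma-delimited input is accepted. Schemas validate
required columns, semantic types, scale bounds, and key uniqueness on
read, citing offending rows. Pipeline runs write a manifest (package
version, seed, config, SHA-256 per artifact) making every run
reproducible from config + seed alone.

## Known limitations

* Coding quality is bounded by the supplied unification maps; no
  morphological analysis is performed.
* H is the plug-in entropy estimate and is biased downward at small
  n_valid.
* t statistics use residual df, which is anti-conservative for
  predictors varying mostly between pictures; the simulation suite
  shows the practical coverage is adequate at the tested sizes.
* The LRT-based structure reduction tests one component at a time
  against a fixed χ²₁ cut-off; it is deterministic and logged, but like
  any stepwise procedure it has no global optimality guarantee.
* The generator's independence assumptions (predictors ⊥ name
  distributions ⊥ ratings) mean cross-variable correlation structure in
  real norming data is not emulated.
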