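# Methods

`tiiclnc` implements a discovery pipeline for prognostic lncRNA signatures
that track tumor-infiltrating immune cells (TIIClncRNAs) in bulk tumors,
together with the survival-learning machinery the pipeline is built on and a
synthetic study generator with planted ground truth. This note records the
models, the defaults, and the design choices that were genuinely open.

## The screen

A TIIClncRNA is a lncRNA that is (i) highly expressed in purified immune
cells, (ii) expressed *generally* across immune cell types rather than in one
lineage, (iii) depleted in tumor cell lines, and (iv) prognostic in a bulk
tumor cohort. The four stages mirror those requirements:

1. **Top-expressed candidates.** In each purified immune cell line (matrix
   column), the top `fraction` (default 15%) of lncRNAs by expression are
   marked; candidates are the union over lines. The union is the most
   inclusive reading of "top expressed per line"; an intersection mode is
   available (`aggregation="intersection"`). The union is near-vacuous when
   many lines are profiled — by design the specificity stage carries the
   selectivity.
2. **Specificity index.** For lncRNA *g*, replicate lines are averaged within
   each of the *N* immune cell types on the **linear** intensity scale (log2
   input is un-logged first — the index is defined on intensities), the
   profile is normalized by its maximum, `x_i = profile_i / max(profile)`,
   and

       TSI_g = sum_{i=1..N} (1 - x_i) / (N - 1).

   TSI is 0 for a uniformly expressed ("immune cell-general") lncRNA and 1
   for a single-type ("immune cell-specific") one. Candidates with
   TSI strictly below 0.2 are retained as general immune lncRNAs (ilncRNAs).
   All-zero profiles are undefined and reported as missing.
3. **Immune-vs-tumor differential filter.** Welch's t per ilncRNA on the log2
   matrices, Benjamini–Hochberg control at α = 0.05, retaining lncRNAs that
   are additionally *up* in immune lines (positive log2 fold change). The
   test and FDR level are package choices; "significantly upregulated /
   downregulated" admits several implementations, and Welch + BH is the
   field default.
4. **Univariate Cox screen.** One proportional-hazards fit per lncRNA on
   per-lncRNA z-scored expression; retain Wald p < 0.05 (both threshold and
   z-scoring are package choices, recorded in the screen trace).

Every stage writes its statistics to a `ScreenTrace`; traces enforce the
nesting invariant (each stage's output is a subset of its input).

## Survival learners

All learners are implemented in this package and validated in the test suite
against independent oracles (brute-force enumeration, grid search, and the
reference implementations in `lifelines` / `scikit-survival`).

* **Cox partial likelihood** with Efron's tie correction, Newton–Raphson with
  step-halving, convergence at max |score| < 1e-8 (50 iterations). Monotone
  likelihood is flagged non-converged (extreme coefficient or exploding
  standard error).
* **Elastic net** (`alpha`=1 lasso … 0 ridge): proximal Newton — exact
  gradient/Hessian of the Efron partial likelihood, inner cyclic coordinate
  descent with soft-thresholding. Covariates are standardized internally; at
  λ = 0 the fit coincides with the unpenalized solution.
* **CoxBoost** — componentwise likelihood boosting: each step computes the
  penalized score statistic `U_j^2 / (I_jj + penalty)` for every covariate at
  the current linear predictor and applies a one-step ridge Newton update to
  the best covariate only. Default penalty 9 × (number of events); the step
  count can be chosen by 10-fold cross-validated partial likelihood
  (Verweij–van Houwelingen criterion).
* **Random survival forest** split by the log-rank score statistic. Subjects
  get Savage/log-rank scores

      a_j = delta_j - sum_{k=1}^{Gamma_j} delta_(k) / (n - Gamma_k + 1),

  with ties in time broken by stable original order, and a candidate split of
  covariate *x* at cutpoint *c* (left group L, n1 = |L|) is scored by

      S(x, c) = (sum_{j in L} a_j - n1 * a_bar) / sqrt(n1 (1 - n1/n) s_a^2),

  maximizing |S| over `mtry` sampled variables and all midpoints of
  consecutive distinct values (children must keep ≥ `nodesize` subjects; the
  sample variance uses ddof = 1, giving the permutation variance of the
  linear rank statistic). Terminal nodes store the Nelson–Aalen cumulative
  hazard on the grid of training event times; the risk score is the ensemble
  mortality (forest-averaged cumulative hazard summed over that grid), and
  the out-of-bag error curve 1 − C(OOB) reproduces the error-vs-trees
  selection plot. Library default 1000 trees, mtry = ⌈√p⌉, nodesize 15; the
  pipeline and the simulation studies in the test suite use 100–200 trees,
  which is where the OOB error curve flattens at these problem sizes.
* **Evaluation**: Harrell's C over usable pairs (risk ties count ½),
  Kaplan–Meier, the k-sample log-rank test, IPCW cumulative/dynamic AUC(t)
  (censoring distribution by Kaplan–Meier; case weights 1/G(T⁻)), grouped
  calibration at a horizon, and a Breslow baseline for converting linear
  scores to predicted survival.

## The combination harness

Learners are registered with roles (`selector`, `predictor`) and enumerable
variants (elastic-net α grid, stepwise directions). Combinations are all
single predictors plus every selector∘predictor composition where the
selector is a feature-selecting family (lasso, stepwise Cox, CoxBoost, RSF)
and the predictor belongs to a different family. The enumeration rule is
fixed by this package; the registry is open, and adapter slots for further
families (plsRcox, SuperPC, GBM, survival-SVM) use the same `LearnerSpec`
interface. With the full implemented registry (9 elastic-net α values, 3
stepwise directions) the rule yields 100 combinations.

For each combination: hyperparameters are tuned by event-stratified k-fold
cross-validation on the training cohort (held-out C-index; CoxBoost steps by
CV partial likelihood), the selector runs on the full training data — this
mirrors the sequential build of the published workflow; nested selection is
stricter but is not what the pipeline emulates — the predictor is refit on
the selected features, and the C-index is computed on the training cohort
and every validation cohort. Combinations are ranked by the **mean
validation** C-index (training excluded); ties prefer fewer features, then
the lexicographically first identifier. A selector returning zero features
marks the combination failed.

Cross-cohort transfer standardizes features **per cohort** by default
(z-score within the cohort, re-expressed on the training scale), which
absorbs feature-wise additive batch/platform shifts; training-parameter
standardization is available (`standardize="training"`). Neither mode is
claimed to match any published choice — the transfer convention is an open
question the package resolves explicitly.

The final `SignatureModel` holds the selected lncRNAs, the fitted predictor,
the training standardization, and a stratification cutpoint chosen by the
maximally selected log-rank statistic (|S| over candidate cutpoints keeping
at least `minprop` = 10% of samples per side; ties take the lower cutpoint).
Models serialize to JSON (trees as nested objects) and score external
cohorts deterministically; response association in immunotherapy cohorts
uses the two-sided Wilcoxon rank-sum plus a 2×2 responder-rate contingency
at the cutpoint.

## The synthetic study

No generative description of the real cohorts exists, so all generator
parameters are package choices, fixed once and documented here.

Four lncRNA classes (fractions of 2000 lncRNAs): `general_immune` (2%),
`cell_type_specific` (10%, one high type each, round-robin),
`tumor_enriched` (5%), `background` (the rest). Expression is log2-normal:
high mean 7, low mean 2, replicate SD 1.0. The general-immune class uses
replicate SD 0.2: "generally expressed" is a statement about cross-type
stability, and with 5 lines per type this puts the class's TSI around 0.1,
clear of the 0.2 threshold that defines it (at SD ≳ 0.3 the class itself
would straddle its own defining threshold). The immune panel is 19 cell
types × 5 lines = 95 lines (the real collection had 115 across 16 series);
10 tumor lines deplete general-immune lncRNAs by 4 log2 units and elevate
the tumor-enriched class symmetrically.

Bulk cohorts (3 × 500 patients) mix the immune and tumor prototype profiles
with a per-patient infiltration fraction f ~ Beta(2,2) on the log2 scale,
plus residual noise SD 1.5 and, for cohorts beyond the training cohort, a
per-cohort per-lncRNA batch offset (SD 0.3). The residual SD is deliberately
about twice the infiltration-mediated component: all general-immune lncRNAs
load on the same infiltration factor, and with less residual noise the
non-prognostic members of the class inherit so much correlation with the
planted signal that a univariate screen cannot separate them — a real
phenomenon, but one that would make "precision of the screen" meaningless as
a property.

Survival is exponential proportional hazards: h(subject) = h0 · exp(Σ β_g
z_g) with h0 = 0.02 events/month on the standardized bulk expression of 16
planted prognostic general-immune lncRNAs, β = ±0.7 per SD with balanced
signs (8 hazardous, 8 protective — balanced signs keep infiltration itself
from becoming a confounder, which keeps the generative story identifiable;
the published signature likewise mixed 11 hazardous with 5 protective
lncRNAs). Censoring is independent exponential; its rate is solved by
bisection so the expected censored fraction hits the configured 30%.
Infiltration influences survival only through expression.

**What the generator does not emulate:** probe/platform effects, realistic
lncRNA count distributions, correlated biology beyond the single
infiltration factor, non-proportional hazards, informative censoring, or
clinical covariates. Passing the recovery tests therefore demonstrates that
the pipeline's statistics behave as designed under its own assumptions — not
that the published cohort-level results are reproduced (those require the
controlled TCGA/CGGA/GEO data and annotation files and are out of scope, as
are the published stage counts 546/308/136/46/16 and AUCs).

## Numerical conventions

* Ranking ties in the top-expressed stage and in stepwise/boosting argmax
  decisions break by feature order; split and cutpoint ties take the lower
  cutpoint; `select_best` ties take fewer features, then the first id.
* Quantile-normalization ties receive the average reference value; probe
  collapse keeps the max-mean probe.
* Degenerate inputs fail loudly: all-zero TPM columns, empty feature
  intersections, zero-variance scores at a split or cutpoint, cohorts
  missing signature features (absentees listed), missing values anywhere.
* Every stochastic routine takes an explicit seed (`numpy` Generator seeded
  per stream); identical configuration + seed reproduces matrices, forests,
  fold splits and result tables bit-identically.

## Simulation-study sizes

Property and recovery tests run at deliberately chosen scales: cohorts of
120–500 patients, forests of 15–200 trees, screens over 300–2000 lncRNAs.
The recovery thresholds (screen sensitivity/precision ≥ 0.8 for the planted
class, held-out C-index ≥ 0.70, held-out log-rank p < 0.05, RSF OOB C ≥ 0.7
on a single strong covariate) are properties of this package under its
documented study conditions, not published values.
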