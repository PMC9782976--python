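# Methods

## The problem

Small radiotherapy cohorts — on the order of 80–100 hepatocellular-carcinoma
patients treated with stereotactic body radiotherapy — must support binary
outcome prediction for rare events: a liver-toxicity endpoint (an
albumin–bilirubin grade increase, prevalence near 28%) or loss of local
tumor control (prevalence near 4%). With 45–93 candidate features per
outcome and treatment phase, purely data-driven feature selection on such
imbalanced data is unstable, and black-box learners that cope better with
the imbalance cannot explain their predictions. The toolkit implements and
compares two discrete-Bayesian-network modelling pipelines on this regime:

* **PD-BN** (pure data-driven): Markov-blanket feature selection for the
  outcome, then bootstrap-averaged structure learning over the selected
  features, then conditional-probability-table (CPT) fitting.
* **HITL-BN** (human-in-the-loop): physicians flag a subset of features as
  expert-knowledge features (EKFs). Ensemble learners rank all features;
  the rankings are fused into one integrated list; the pipeline walks that
  list EKF by EKF, filtering candidates through Markov blankets and keeping
  each increment only if cross-validated AUC improves.

## Rank fusion

Each ensemble learner k (random forest, gradient boosting by default)
contributes a ranking N_j(L^k) of the J features (1 = most important, from
out-of-fold permutation importance) and a cross-validated AUC^k. The
integrated list L* orders features by the weighted ranking score

    WRS_j = Σ_k N_j(L^k) · (Σ_k' AUC^k') / AUC^k,

ascending — the minimal score ranks first. Note the weight is *inversely*
proportional to AUC^k, so weaker learners count more; this is the formula's
literal form and is the package default (`weighting="literal"`), with
`weighting="proportional"` (w_k = AUC^k / Σ AUC^k') available for
sensitivity analysis. With equal AUCs both reduce to the Borda sum of
ranks. Permutation importance is computed over out-of-fold rows with a
configurable number of shuffles per feature (default 20), all shuffled
copies batched into a single ensemble prediction per fold for speed.

## Conditional independence and Markov blankets

All structure machinery runs on discretized data. Independence X ⟂ Y | Z is
tested by the G² (likelihood-ratio) statistic with
dof = (|X|−1)(|Y|−1)·Π|Z_i|. A test whose average count per contingency
cell falls below 5 is flagged *ineffective* and treated as a non-rejection:
at n ≈ 100 this caps how large a conditioning set can be trusted and
prevents spurious additions.

Blanket discovery is Inter-IAMB: grow by adding the candidate with the
smallest p-value against the target given the current blanket (only if the
test is effective and p < α, default α = 0.05), interleaving a shrink phase
after every addition that removes any member no longer dependent given the
rest. Ineffective shrink tests keep the member — failing to measure
dependence is not evidence of independence. No multiple-testing correction
is applied inside the search, matching the classical algorithm; the
practical consequence is an α-level rate of false inclusions, visible in
the null simulations as roughly (1−α)^k empty-blanket rates with k
candidates. An exhaustive minimal-separator oracle (≤ 8 candidates) backs
the test suite.

## Structure learning

Score-based search: tabu hill-climbing over add/delete/reverse moves on the
decomposable discrete BIC, with a tabu list of recently visited structures
(length 10) and non-improving moves allowed to escape plateaus; the best
structure seen is returned. Robustness at small n comes from nonparametric
bootstrap model averaging (default R = 200 replicates, arc-strength
threshold 0.5): an arc's *strength* is the fraction of replicate networks
containing it in either direction, its orientation follows the majority
direction (ties to the lexically smaller source). Averaging can create
directed cycles; each is broken at its weakest arc, logged. Inside
cross-validated accept/reject evaluations the structure is refit with a
single tabu search per training fold (no averaging) — averaging there would
multiply cost by R while the decision only needs a comparable score; the
final reported model always uses the full bootstrap-averaged network.

## Parameters and prediction

CPTs are Bayesian estimates under a symmetric Dirichlet prior with
equivalent sample size 1 spread over each CPT's cells (so a parentless
binary node with counts (3,1) yields P = (3+0.5)/(4+1) = 0.7); no posterior
is exactly zero. Outcome posteriors are exact, by variable elimination with
a min-degree ordering; evidence is every observed network feature (features
outside the outcome's connected component cannot change the result), and
unseen levels are marginalized.

## Evaluation

Repeated stratified k-fold cross-validation (default 5 folds; the package
default is 10 repeats, the pipelines' decision evaluations use 4) with the
*entire* pipeline — blanket selection, structure, CPTs — refit inside each
training fold, so reported AUCs carry no selection leakage. A deliberately
leaky variant (selection once on the full cohort) exists solely as a
negative control in the regression suite, where it shows inflated AUC on
pure-noise cohorts. AUC is the rank-based (Mann–Whitney) estimator; 95%
intervals come from stratified bootstrap (default 2000 resamples) or
DeLong's closed-form variance; two models scored on the same units are
compared with DeLong's test for correlated AUCs via placement values.

Within one HITL-BN run every feature-set evaluation shares a single
fold-assignment seed and is memoized: comparisons are paired, and an
identical feature set can never appear to "improve" through fresh fold
noise.

## The HITL-BN increments

With N features and a faithfulness-motivated window dimension D (default
min(10, n/10)), the initial window is the top n = 100·D/N percent of L*.
EKFs in the window are filtered through the outcome's blanket computed
among the window candidates; non-EKFs through the blankets of the kept
EKFs among the window's non-EKFs. Backward elimination then (a) drops
features disconnected from the outcome in a network learned on the full
training cohort and (b) makes one greedy pass, worst-ranked first, removing
any feature whose deletion improves or preserves the cross-validated AUC
within ε (default ε = 0.001). Each subsequent step considers the next EKF
in L* plus S*, the non-EKFs ranked between the previous and the new EKF
that fall in the blanket of any selected EKF or the new one (computed over
those candidates plus that EKF alone); the refit model is accepted only if
its paired CV AUC beats the incumbent by more than ε. Iteration stops at
list exhaustion, at a target AUC, or after a configurable run of
consecutive rejections. An optional `decide` callback lets a human skip
EKFs interactively; batch runs decide by the AUC rule alone. The full trace
(candidates, blankets, AUCs, accept/reject) is serialized and replayable.

## Synthetic cohorts

Because the clinical cohorts are not deposited, the generator builds
cohorts from a known discrete network: a binary outcome with a designated
blanket covering all three roles (parents; children; spouses, i.e. 
co-parents of children), *redundant* shadow features (copies of blanket
members flipped with probability 0.2, hence conditionally independent of
the outcome given their source), and marginally independent noise. The
outcome CPT is calibrated analytically — an offset is solved by bisection
so the exact marginal event probability equals the requested prevalence.
Effect size (default contrast 0.3) shifts each child's event probability
per parent additively, so per-parent contrasts do not wash out as parents
accumulate. EKF flags cover the true blanket first, then shadows, then
pure decoys, modelling imperfect expert judgement. Presets mirror the two
study endpoints: `ialbi_like` (81 units, prevalence 23/81, 69 features, 12
EKFs, 24 during-treatment) and `lc_like` (104 units, prevalence 4/104, 93
features, 13 EKFs).

What the generator does *not* emulate: within-patient correlation between
tumors (units are independent, as the study design itself assumes),
longitudinal lab trajectories, dosimetric physics behind dose-volume
features, and real missingness patterns. Passing tests therefore show the
machinery is correct and calibrated under faithful generating models, not
that clinical AUCs will reach any particular level.

## Numerical and design choices

* Discretization: 3 quantile bins for continuous features (2 when fewer
  than 5 distinct values); binary/categorical columns pass through; cuts
  that collapse fall back to fewer bins; single-bin columns are dropped;
  missing cells are imputed by column mode after binning. Rows with a
  missing outcome are dropped.
* The minority outcome class is always coded 1 internally; the original
  labels are preserved for reporting.
* Ties everywhere (rank fusion, move selection, orientation) break on
  ascending lexical feature name, making every run platform-stable.
* One top-level seed fans out to per-stage sub-seeds via a stage-name hash,
  so stages are independently reproducible; every artifact embeds its
  config echo.
* Problem sizes in the test and acceptance studies are chosen for a
  single-CPU workstation: ranking CV 5×1 with 5 permutation shuffles,
  decision CV 5×4, single-tabu in-fold structure, R = 50 final averaging,
  held-out samples of 500 units, 10–20 replicate seeds per study.

## Known limitations

* Continuous (Gaussian) conditional-independence tests are not provided;
  everything is discretized first.
* The small-sample effectiveness guard means blankets are capped at
  conditioning sets the data can support — at n ≈ 81 with binary features
  that is 2–3 members; larger true blankets are reachable only through the
  incremental EKF walk, not a single blanket call.
* At the reference scenario's 23 events, features whose true incremental
  AUC contribution falls below what paired cross-validation can reliably
  detect (notably spouse-type blanket members acting only through
  interactions, and shadows vs. their sources) are not consistently
  retained by any AUC-gated rule; the pipeline
  returns a parsimonious, predictive set rather than the exact generating
  blanket. The regression suite records this honestly rather than relaxing
  the recovery claim.
* Exhaustive oracles (blanket, joint enumeration) are test-harness tools,
  deliberately limited to ≤ 8 variables.
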