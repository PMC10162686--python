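# Methods

## Problem and model family

`dcbnet` predicts durable clinical benefit (DCB) of immune-checkpoint
inhibitors in non-small-cell lung cancer from a small table of categorical
covariates: sex, age dichotomized at 65 years, smoking status, a
three-level histopathology label, and binary gene-variant indicators.
DCB (partial response or stable disease lasting more than six months,
RECIST v1.1) is the binary class variable `C`; progression-free survival
(PFS) with an event flag is carried alongside for stratification.

Two Bayesian-network classifiers are supported.

**Naive Bayes (NB).** The class points at every feature and

p(C | x₁…xₙ) ∝ p(C) · ∏ₖ p(xₖ | C),

i.e. features are conditionally independent given the class.

**Tree-augmented naive Bayes (TAN).** NB relaxed so that each feature may
depend on one other feature, the feature–feature edges forming a spanning
tree:

p(C | x₁…xₙ) ∝ p(C) · ∏ₖ p(xₖ | pa(xₖ), C).

The tree is the maximum-weight spanning tree under the class-conditional
mutual information

I(Xᵢ; Xⱼ | C) = Σ p(xᵢ,xⱼ,c) · log [ p(xᵢ,xⱼ|c) / (p(xᵢ|c) p(xⱼ|c)) ]

computed with plug-in (unsmoothed) empirical probabilities on
pairwise-complete cases (a listwise option exists).  Weights are in nats;
the base only rescales weights and cannot change the arg-max tree.  The
Kruskal construction breaks weight ties by lexicographic pair order so the
tree is deterministic; the root feature is then drawn uniformly at random
(seeded, recorded in the model metadata) and the tree edges oriented
outward from it.  Only the orientation, never the skeleton, depends on
this choice.

**CPT estimation.** p̂(v | pa) = (count(v,pa) + α) / (count(pa) + α·|dom|)
with Laplace pseudocount α = 1 by default.  α > 0 guarantees strictly
positive tables (required by the sampler below) and gives the uniform
distribution on unobserved parent configurations; α = 0 (pure maximum
likelihood) raises an error when a configuration is unobserved.

## Inference

* Full evidence: the closed-form class posterior above, evaluated in log
  space.
* Partial evidence, exact: full enumeration of the joint state space
  (the default 12-node network has 12 288 states; a configurable cap of
  10⁷ states guards against misuse).  Used both as a user-facing query
  and as the oracle for the sampler.
* Partial evidence, sampled: logic (rejection) sampling — ancestral
  sampling of the whole network, keeping draws that match the evidence;
  10⁶ draws by default.  Fewer than 100 accepted draws is a hard error
  (a noisy estimate is worse than an explicit failure), with the
  acceptance rate in the message.
* The binary DCB call is `benefit` iff p(benefit) ≥ 0.5 (configurable;
  ties go to `benefit`).

## Structure search and model averaging

General-DAG learning uses greedy best-improvement hill-climbing over
single-edge additions, deletions and reversals, scored by decomposable
BIC (log-likelihood at the MLE minus (log n / 2) × free parameters,
computed on family-complete rows, cached per family).  The score is
pluggable; BIC is the default.  Optionally the search runs as an iterated
local search: after convergence the optimum is perturbed by a few random
valid moves and re-climbed, keeping the best-scoring optimum.  Plain
greedy search started from a dense random graph frequently orients an
edge into the class early, after which true class→feature additions are
blocked by acyclicity; the perturbation rounds escape these traps at a
constant-factor cost.

Arc strength of an undirected pair is its relative frequency across an
ensemble of learned graphs; strengths above 0.85 are reported as strong
(strictly greater).  Two ensembles:

* **Bootstrap** (B = 500 by default): learn on nonparametric resamples,
  climbing from the empty graph.
* **MCMC random starts** (500 kept graphs, thinning 50): a Metropolis
  chain over DAG space whose stationary law is uniform — proposals drawn
  uniformly from the valid single-edge moves, accepted with probability
  min(1, |moves(g)|/|moves(g′)|) to balance neighbourhood sizes; burn-in
  10·|V|² steps.  Each kept graph seeds a hill-climb on the data (with 10
  iterated-local-search rounds, for the reason above).  Strengths can be
  weighted by normalized exp(BIC) instead of uniformly (off by default),
  and the data can be re-bootstrapped per kept graph (off by default:
  the full data are used).

Significant pairs are compared against a reference TAN: a pair is
concordant if it is a class edge or an augmenting edge, orientation
ignored (directionality of single edges is not identifiable from
observational data, so only adjacency is interpreted).

## Evaluation

ROC curves threshold the predicted p(benefit); the trapezoidal AUC
equals the Mann–Whitney concordance with ties counted ½ (an invariant
verified against a brute-force all-pairs oracle).  Survival stratification
splits a cohort by the binary DCB call and compares PFS between the
predicted groups with Kaplan–Meier curves and a two-group log-rank test
(χ² on 1 df; events precede censorings at tied times).  The survival
machinery is backed by `lifelines`; the tests check it against
hand-accumulated product-limit and O/E/V computations.

## Synthetic cohorts

The generator draws cohorts from a fixed ground-truth TAN so that every
downstream stage can be validated against a known answer.  Defaults:
290 patients (the curated real-cohort scale), class prior
p(benefit) = 0.35 (the emulated cohorts do not report prevalence; this is
a free parameter), seven genes (TP53, KRAS, TTN, KMT2C, SMARCA4, STK11,
KEAP1 — the over-10%-variant-frequency set), and an augmenting tree
rooted at smoking status containing smoker–KRAS, smoker–KMT2C,
KRAS–TP53, KRAS–histology, histology–TTN, TTN–SMARCA4, TP53–STK11,
STK11–KEAP1, smoker–age and age–sex, echoing dependency patterns
reported in this disease setting.

CPT values were designed once, before any acceptance measurement, by a
power analysis on the exact generative distribution: every edge's
conditional information n·I must exceed its BIC parameter penalty by a
comfortable factor (≥ ~2.5 at n = 5000) even when conditioned on a
mis-oriented collider child, so that structure-recovery experiments are
well posed rather than seed lotteries.  Two gene CPTs (SMARCA4 given
TTN, KEAP1 given STK11) carry effect modification — the class effect
reverses sign with the co-parent state, a stylization of co-mutation
patterns such as STK11/KEAP1 — which NB cannot represent and which is
precisely the regime where TAN should, and does, outperform NB.

Survival is exponential with proportional hazards: non-DCB patients
progress at 0.15 events/month, DCB patients at hazard ratio 0.35, with
uniform censoring on (0, 30) months — the simplest model producing two
clinically distinct prognosis groups at a realistic censoring fraction.

What the generator does **not** emulate: continuous covariates (age is
generated as a category and realised as a number only in the CSV
round-trip), missingness mechanisms (missing-data handling is tested with
synthetic holes, not a realistic pattern), cohort batch effects, and any
attempt to match the real cohorts' joint distribution.  Passing recovery
tests therefore demonstrate correctness of the algorithms under the
stated model, not performance claims about real NSCLC data — the AUCs on
synthetic cohorts (~0.9) are higher than what heterogeneous clinical data
yield.

## Numerical choices and problem sizes

* CMI floors at 0 up to −1e-12 rounding; 0·log 0 = 0.
* Sampling code guards cumulative-sum rounding so codes never exceed the
  domain.
* Hill-climbing accepts a move only if it improves the score by > 1e-10;
  move scanning order fixes tie-breaks deterministically.
* The test-suite experiment sizes — 20 000 samples for tree recovery,
  50 000 for CPT recovery, 5 000 with 200 replicates for arc strength,
  50 cohorts of 290 for the TAN-vs-NB comparison, 1 000 null simulations
  for log-rank calibration — were chosen as the smallest sizes at which
  the binomial error bounds quoted in each test are decisive.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from one global seed via `numpy.random.SeedSequence`,
  so stages are independently reproducible and two runs with the same
  seed produce byte-identical artifacts.

## Known limitations

* Exact inference is enumeration, fine at ~12 discrete nodes but not
  beyond (no junction tree).
* Hill-climbing is a local search; even with iterated restarts it carries
  no global-optimality guarantee.
* The log-rank test is two-group only; no Cox regression or multi-group
  extensions.
* Curation recognises a fixed vocabulary of clinical labels (documented
  in `cohort_io`); unrecognized histology strings map to `other` rather
  than erroring, by design.
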