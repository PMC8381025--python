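# Methods

## The classification problem

Given a binary persons × items response matrix and a simple-structure
Q-matrix (every item loads exactly one of K content strands), each of three
engines produces a persons × strands binary mastery matrix. Accuracy is
judged against the generating truth in simulation; on real data, where no
truth exists, engines are compared to each other by exact-match consistency
and by Pearson correlation of their person scores.

## Data generator

Responses follow a compensatory MIRT model restricted to simple structure
with unit slopes: `logit P(X_ij = 1) = θ_{j,k(i)} − b_i`, where k(i) is the
strand of item i. Abilities are multivariate normal with zero means, unit
variances, and a common pairwise correlation ρ (compound symmetry, positive
definite for −1/(K−1) < ρ < 1; draws via Cholesky of the correlation
matrix). Difficulties are uniform on [−3, 3] by default. True mastery of
strand k is θ_jk > 0 — the population median, chosen to mirror the Rasch
estimated-mastery rule; the cut is strict, so θ = 0 exactly is non-mastery.

Default study design: 1,000 examinees per form, four strands of 5/10/15/20
items (50 items), 50 replicate forms, ρ ∈ {0, 0.3, 0.5, 0.7, 0.9}. One
form contains all four strand lengths simultaneously, so "strand size"
effects are within-form comparisons. Random streams: each form uses the
child `SeedSequence(master_seed, spawn_key=(form_index,))`, so any single
form is reproducible in isolation and studies are byte-identical under a
fixed seed.

A structural property worth knowing when reading accuracy tables from this
generator: a strand's CTT score and its per-strand Rasch fit depend only on
that strand's items and its own θ_k, whose marginal is N(0, 1) at every ρ.
Strand-local accuracy for those two engines is therefore invariant to ρ by
construction; only the DINA model, which fits all strands jointly, can gain
from inter-strand correlation. The test suite checks CTT's behaviour in ρ
as non-increase within Monte-Carlo tolerance, which the invariant truth
satisfies.

What the generator does **not** emulate: guessing floors (no lower
asymptote), varying item discriminations, multi-attribute items, missing
responses, and person misfit such as careless responding. Passing the
simulation checks therefore says nothing about robustness to those
features; the item-fit statistics (outfit, RMSEA) are the tools intended to
surface them on real data.

The `exam_like_condition` helper produces an exam-shaped synthetic dataset
(8 domains of 45/45/45/25/154/20/20/6 items, 3,265 examinees at full
scale) for exercising the analysis pipeline. Its inter-domain correlation
is fixed at ρ = 0.7: large-scale licensing exams are essentially
unidimensional, so content domains are strongly but not perfectly related.
It is synthetic; nothing in this package reproduces any real examinee data.

## CTT engine

Subscore = proportion correct among the strand's items; master iff
strictly above the cut (default 0.5 — "above 50%" read literally, so an
exact half score on an even-length strand is non-mastery; the cut and
strictness are arguments).

## Rasch engine

One unidimensional Rasch model per strand — a joint 50-item fit would yield
a single θ and could not produce per-strand decisions.

- **Identification.** Latent density fixed at N(0, 1), difficulties free.
  This makes the θ̂ > 0 mastery cut the population median.
- **Estimation.** Bock–Aitkin EM: E-step posterior over 61 equally spaced
  quadrature nodes on [−6, 6] with renormalized normal weights; M-step
  solves each item's expected score equation by safeguarded Newton (steps
  clamped to ±2). Convergence when max |Δb| < 1e−5, cap 1,000 iterations;
  non-convergence warns with the last change, never silently. Items with
  zero observed variance carry no difficulty information and are excluded
  with a warning (reported as NaN).
- **Scoring.** MAP under the same N(0, 1) prior; the log-posterior is
  strictly concave, so vectorized Newton with step-halving converges for
  every pattern, including zero and perfect scores; tolerance 1e−6 logits.
- **Fit.** Outfit mean-square `mean_j (X_ij − P_ij)² / (P_ij(1 − P_ij))`
  with acceptance band [0.6, 1.4]. Its expectation is 1 when evaluated at
  the generating probabilities; evaluated at MAP-shrunk θ̂ it sits
  somewhat below 1 (the usual overfit direction), which the calibration
  test distinguishes from the flagging behaviour.

## DINA engine

EM over all 2^K profiles (lexicographic order; guarded at K ≤ 16) with
saturated mixing weights π_c — the standard structural model, and the one
that lets correlated attributes help classification.

- **M-step** is closed form: g_i and s_i from posterior-expected correct
  counts among η = 0 / η = 1 classes, π_c from mean posteriors. Bounds
  g, s ∈ [1e−4, 1 − 1e−4] by clipping. Monotonicity (g_i < 1 − s_i) is
  deliberately not imposed — a warning is raised instead. A consequence:
  an item whose responses depend on its η in the *opposite* direction is
  fit exactly by swapped guess/slip values and shows no lack of fit; the
  misfit the RMSEA index can detect is dependence on the wrong attributes.
- **Numerics.** All likelihoods in log space (a 360-item pattern underflows
  double precision otherwise); convergence when the largest parameter
  change < 1e−5, cap 1,000 iterations; initialization g = s = 0.2, π
  uniform.
- **Classification.** MAP profile (largest posterior; exact ties resolve
  to the lowest class index with a warning, for determinism). Marginal
  mastery probability of attribute k = posterior mass of profiles with
  α_k = 1; this is the DINA "person score" used for cross-model
  correlations, since a binary profile correlates poorly by construction
  (the MAP profile is available as an alternative).
- **Fit.** `RMSEA_i = sqrt(Σ_c π̂_c (P_i(α_c) − P̃_ic)²)` where P̃_ic is the
  posterior-weighted observed proportion correct in class c; flag above
  0.08. Classes with negligible posterior mass (< 1e−8 persons) are
  skipped with the weights renormalized.

## Evaluation

Accuracy = diagonal proportion of the per-attribute 2×2 true × observed
table; consistency = the same between two engines; both equal
1 − Hamming distance / n. Across forms, the unweighted mean is reported
with the across-form SD, so tolerance reasoning can use the replicate
dispersion. CTT's per-form accuracy is the most variable of the three
(its effective θ-cut moves with the strand's mean difficulty draw), which
is why form-averaged comparisons are the meaningful ones.

## Problem sizes in the test suite

Unit tests use forms of 150–400 persons; oracle-equivalence checks use
4-item, 10–20-person instances where brute-force enumeration is exact;
recovery and fit-calibration checks use n = 2,000–8,000. The end-to-end
accuracy checks run the full 1,000-examinee design in a 10-form fast mode
with tolerance ±0.05 (the 50-form run, tolerance ±0.03, is what
`scripts/acceptance.py` executes; one correlation level takes well under a
minute). The analysis-pipeline checks run on exam-shaped fixtures scaled
to 10–15% of full size, which preserves all eight domains.

## Known limitations

- Simple structure only: complex (multi-attribute) Q-matrices are accepted
  by the DINA engine's math but rejected by the CTT/Rasch/simulation
  surfaces, which are undefined there.
- The saturated π_c has 2^K − 1 free parameters; at K = 8 (256 classes)
  this is fine with thousands of examinees but will overfit tiny samples.
- No standard errors on b̂, ĝ, ŝ; the study's comparisons are
  classification-based and do not need them.
- Mastery cuts (score > 0.5, θ̂ > 0) are conventions, not estimated
  standards; both are arguments to the respective functions.
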