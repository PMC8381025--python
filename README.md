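# strandmastery

Licensing and achievement exams usually report one overall score, but
educators want to know *which content areas* a candidate has or has not
mastered. `strandmastery` compares three engines for turning a binary
person × item response matrix and a simple-structure Q-matrix (each item
assigned to exactly one content strand) into per-strand mastery decisions:

- **CTT subscores** — percent correct within a strand; master iff strictly
  above 50%.
- **Per-strand Rasch** — for each strand, item difficulties `b_i` are
  estimated by marginal maximum likelihood under
  `P(X_ij = 1) = exp(θ_j − b_i) / (1 + exp(θ_j − b_i))` with θ ~ N(0, 1);
  persons are scored by MAP and mastered iff θ̂ > 0. Outfit mean-squares
  flag misfitting items outside [0.6, 1.4].
- **DINA** — the conjunctive diagnostic classification model
  `P(X_ij = 1 | η_ij) = g_i^(1−η_ij) (1 − s_i)^η_ij` with
  `η_ij = Π_k α_jk^q_ik`, estimated by EM over all 2^K mastery profiles
  with saturated class weights; persons are classified by the largest
  posterior profile. An RMSEA-type index flags items above 0.08.

The package also ships the simulation study that measures how accurate each
rule is: a simple-structure multidimensional IRT generator (unit slopes,
`logit P = θ_{j,k(i)} − b_i`) draws abilities from a multivariate normal
with a configurable common inter-strand correlation ρ, and classification
accuracy is the exact-match proportion against true mastery (θ > 0). The
headline finding this reproduces: accuracy grows with strand length for
every engine, and the DINA model pulls ahead of CTT — and of per-strand
Rasch on short strands — once strands are strongly correlated, because its
latent-class weights pool information across strands.

## Worked example

Five replicate forms of the four-strand design (5/10/15/20 items, 1,000
examinees, difficulties U(−3, 3)) at strong inter-strand correlation:

```python
import strandmastery as sm

cond = sm.SimulationCondition(rho=0.9, n_forms=5, seed=1)
res = sm.run_condition(cond)
for model in ("ctt", "rasch", "dina"):
    print(f"{model:>5}: {res.mean_accuracy[model].round(3)}")
```

prints

```
  ctt: [0.723 0.73  0.736 0.753]
rasch: [0.729 0.772 0.803 0.832]
 dina: [0.834 0.837 0.848 0.859]
```

Each row is the mean classification accuracy (exact agreement with true
mastery) for the 5-, 10-, 15- and 20-item strands. Accuracy rises with
strand length for every engine; at ρ = 0.9 the DINA profile classifier
beats the strand-local CTT and Rasch rules, most visibly on the 5-item
strand where it borrows strength from the other 45 items.

The same pipeline runs from the shell:

```sh
strandmastery simulate --out results/sim --seed 1        # full factorial study
strandmastery make-fixture --out-responses x.csv --out-qmatrix q.csv --scale 0.2
strandmastery analyze --responses x.csv --qmatrix q.csv --out results/report
```

`analyze` writes, for any response + Q-matrix CSV pair, the per-model item
tables (difficulty/outfit; guess/slip/RMSEA), model deviances, per-domain
flag counts, pairwise mastery consistency (CTT–Rasch, CTT–DINA,
Rasch–DINA) and person-score correlations — the full real-data reporting
workflow. Runs are deterministic: identical config and seed give
byte-identical outputs.

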