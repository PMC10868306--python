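# Methods

## Model and procedure

`relmine` implements a two-stage relational learning pipeline for
quantitative per-protein prediction over a panel of gene-deletion
strains.

**Knowledge representation.** The background knowledge is a set of typed
ground facts (function-free Datalog): predicates such as
`involved_in(gene, go_term)`, `localizes_to(gene, compartment)`,
`null_phenotype(gene, phenotype)` and `regulated_by(gene, tf, reg_type)`.
Facts are validated against per-predicate signatures (arity and argument
types); types default to `free` and can be declared in a signature
header. Constants are lowercase tokens; uppercase initials are reserved
for variables in the pattern dialect.

**Curation.** Before mining, facts are filtered: (a) observations from a
strain background other than the reference (default S288c; modelled as
an optional trailing `strain` argument — facts without one are kept);
(b) facts referencing invalid GO terms; (c) dose-dependent phenotypes
(toxin/chemical resistance), whose severity depends on dose rather than
genotype; (d) gene–metabolite relations involving currency metabolites
(H+, H2O by default), which are ubiquitous and carry no regulatory
signal. When several rules could fire the log records the first in the
order above. Separately, every relation derived from the data used as a
prediction target is deleted (`remove_target_derived_relations`) so that
no mined descriptor can encode its own target; the applied selectors are
carried as provenance and checked downstream (adding amino-acid
concentration features to a dataset whose mining KB was not so filtered
warns).

**Pattern language and matching.** A pattern is a definite clause headed
`gene(A)` whose body is a conjunction of literals; a gene is covered
when the body is satisfiable with `A` bound to it (existential
semantics — the first grounding suffices; groundings are not counted, so
support is per-example as in WARMR). Matching is backtracking
conjunctive-query evaluation over the fact index; an exhaustive
grounding-enumeration oracle verifies it in the tests. Patterns are
canonicalized at construction: the body is reordered to the
lexicographically least connected ordering (branching only on render
ties) and variables renamed `A, B, C, …` in order of first appearance,
so variable renamings and literal permutations collapse to one canonical
string used for deduplication and identity.

**Language bias.** Mode declarations control refinement:
`regulated_by(+gene, -tf, #reg_type)` adds a literal whose `+` slot is
filled by an existing variable of that type (this enforces
connectedness), `-` slots by fresh variables, and `#` slots by each
allowed constant of the type (default: all constants of that type in the
KB, so removed constants are unreachable by construction). A fresh
variable's *layer* is 1 + the maximum layer of the literal's input
variables (the head variable has layer 0); the default bound is 10. The
alternative reading of the layer bound — total number of new variables
rather than depth — is not used; depth is the standard i-depth
interpretation, and the bound is configurable.

**Mining.** A simplified WARMR: breadth-first levelwise search from the
empty body, keeping a candidate iff its support fraction meets the
minimum (default 0.00025, i.e. 0.025% of positive examples) and refining
only kept patterns — plain Apriori over the refinement graph, without
query packs or infrequent-set reuse. Discovery order is (level
ascending, support descending, canonical form ascending); the feature
cap (default 2048) truncates in that order, making the search
deterministic and generality-first. Clause length is bounded (default
10). Coverage-identical duplicates are retained by default (an optional
flag drops them); correlated descriptors are inherent to this kind of
feature construction. `brute_force_mine` enumerates the entire bounded
language without support pruning and is the reference semantics on small
instances (≤ 12 constants per type, clause length ≤ 3).

**Propositionalization and joins.** Each kept pattern becomes a 0/1
column over the examples; column sums equal pattern supports by
construction. Target tables (and optional amino-acid concentration
columns, flagged continuous) are inner-joined on the ORF key with drop
counts reported; missing target values are preserved and handled
per-target at training time (rows with missing y dropped for that target
only). No imputation and no scaling — the learner is tree-based and
scale-invariant.

**Regression.** One XGBoost regressor per target column, evaluated by
seeded shuffled K-fold cross-validation (default 5). The reported score
is the mean of per-fold R² = 1 − SS_res/SS_tot (not pooled), with its
standard deviation; per-fold MSE is recorded alongside. A held-out fold
with constant y has undefined R² and is skipped with a warning; a target
constant overall, or with fewer usable rows than folds, is an error
(recorded per target in batch runs, which continue). Default
hyperparameters — learning rate 0.1, 100 trees, depth 4,
min_child_weight 5, subsample 0.8, colsample_bytree 0.8, lambda 1 — are
a moderately regularised configuration for sparse binary descriptors at
a few hundred to a few thousand rows. Optional tuning minimizes CV MSE
on a single target (the policy is to tune on the first target and reuse)
by Gaussian-process expected improvement: ≤ 8 uniform starts, then EI
under a Matern-5/2 GP over a 256-point candidate pool, on a documented
box (learning rate log[0.01, 0.3], trees [50, 300], depth [2, 8],
min_child_weight log[1, 16], subsample and colsample [0.5, 1]).

**Attribution.** Shapley values are computed by the exact TreeSHAP
path-weighting algorithm re-implemented in float64 over the dumped tree
ensemble (numba-compiled), with feature absence weighted by node cover.
Working in float64 makes the local-accuracy identity
`base + Σφ = margin prediction` hold to machine precision (asserted at
1e-6 throughout); the backend's own float32 `pred_contribs` is the
independent cross-check in the tests (agreement to ~1e-6). Attribution
is *out-of-fold* by default: each fold model attributes only its
held-out rows, matching the cross-validated evaluation and avoiding
optimistic attribution; a refit-on-all variant sits behind a flag. Gain
importance is the total split gain per feature summed over fold models,
L1-normalized; unused features get exactly 0. For cross-model summaries,
per-target vectors are normalized to L1 shares (max-scaling available —
which of the two an aggregated figure should use is genuinely open; L1
makes shares comparable and average-able, so it is the default) and
averaged over targets with mean R² above a threshold (default 0,
excluding models no better than predicting the mean; `None` disables the
filter), with normal-approximation 95% confidence intervals across
targets. The max-deviation report ranks features by the largest |φ| over
samples, surfacing rare descriptors that move individual predictions
strongly; ties break by feature id.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the real setting — a typed
relational schema (function, localisation, phenotype, regulation) over a
few hundred deletant genes, i.i.d. facts at configured densities, and
abundance-like targets `y = Σ effect·coverage + Normal(0, σ)` — so every
stage is testable end to end without external databases. It does not
match the marginal statistics, ontology structure, annotation
correlations or missingness patterns of the real yeast databases, nor
the scale (~4600 deletants × ~2300 proteins). Passing tests therefore
demonstrate algorithmic correctness and statistical sanity (recovery of
planted effects at the analytic ceiling, no spurious importance under
the null), not real-data predictive performance.

Planting edits the KB minimally: covered examples get only the missing
body facts (output variables grounded with per-example fresh constants
so the background density is stable); uncovered examples have matching
groundings broken by deleting one witness fact per round until no
grounding remains. Realized coverage is Binomial(n, fraction) by
independent per-example draws. All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence` spawning; fixed seeds
give byte-identical serialized artifacts, which the pipeline manifest
verifies by digest.

## Validation studies and problem sizes

The studies in `relmine.studies` (run by both the test suite and
`scripts/acceptance.py`) use these sizes, chosen to make each property
sharply testable at desk scale:

* **Miner vs oracle / anti-monotonicity / leakage:** random KBs with
  4–8 genes and 2–4 constants per other type, clause length 1–3 — small
  enough for exhaustive enumeration, varied enough to exercise variable
  chaining; 200 instances (50 for leakage).
* **Planted recovery:** 500 genes, one pattern planted at coverage 0.5,
  effect 2.0, noise sd 0.5 (variance ceiling R² = 1.0/1.25 = 0.8);
  mining at clause length 2 with a 256-descriptor cap; 20 seeds. A seed
  counts as recovered when the top aggregated-Shapley feature is
  coverage-identical to the planted pattern (the miner may return
  several syntactic variants with identical extensions; extension
  identity is the meaningful notion of recovery).
* **Null control:** 500 genes, 10 noise-only targets per seed, 20
  seeds, aggregated without the positive-R² filter (noise targets would
  otherwise all be excluded). The concentration check runs over the
  level-1 (most-general) descriptor set, ~29 balanced features: with
  deeper mining the descriptor set fills with hundreds of rare,
  highly correlated variants whose near-zero shares dilute the uniform
  baseline 1/p, making "no share above 3× uniform" a statement about
  the feature count rather than about spurious concentration.
* **Fixture pipeline:** the 9-fact toy KB with 3 examples runs the full
  five-stage pipeline with 3 folds (one row per held-out fold, so per-fold
  R² is undefined and skipped; MSE, attribution and local accuracy are
  still exercised).

## Numerical choices and degenerate inputs

* R² is computed from sums of squares directly; a cross-check against an
  independent reimplementation at 1e-10 is in the tests.
* Shapley local accuracy is asserted at 1e-6; measured error is ~1e-15.
* Fold assignment uses a seeded shuffled KFold, identical across targets
  sharing a row set and seed.
* Aggregation CI with a single qualifying target has zero width.
* Empty pattern sets (nothing frequent) are returned with a warning, not
  an error; empty target matrices yield empty result lists.
* Duplicate facts merge silently (set semantics); duplicate ORF keys in
  tabular inputs are errors naming the key.
* Pattern canonicalization is exact (global minimum over tie branches),
  so equality of canonical strings is equality of clause classes within
  the mode language.

## Known limitations

* Facts only: no recursive rules, negation, or stratified evaluation.
* Support is computed over positive examples only; there are no negative
  examples and no compression-based scoring.
* The per-example matching is existential; patterns distinguished only
  by grounding multiplicity are equivalent here.
* Mining cost grows quickly with clause length on dense KBs; the
  defaults rely on the feature cap and support threshold to bound work.
* The GP tuner is single-objective CV-MSE on one target; no nested CV,
  so tuned-vs-default comparisons on the same data are mildly optimistic.
* Real-data claims (which biological descriptors predict which proteins)
  are outside what the synthetic studies can establish.
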