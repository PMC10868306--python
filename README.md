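# relmine

Relational pattern mining and explainable boosted regression for
predicting protein abundance from structured biological knowledge.

## The problem

Decades of yeast systems biology are stored as structured, typed
relations: GO annotations, deletion phenotypes, regulatory interactions,
subcellular localisation, gene–metabolite links. `relmine` turns that
knowledge into quantitative, *interpretable* predictors of per-protein
abundance across a panel of deletant strains:

1. **Knowledge base** — ground facts in a Datalog-style dialect
   (`involved_in(ykl001c, one_carbon_metabolic_process).`), curated to a
   single strain background, with invalid GO terms, dose-dependent
   phenotypes and currency metabolites (H+, H2O) removed, and every
   relation derived from the prediction targets deleted before mining
   (no leakage).
2. **Frequent pattern mining** — a simplified WARMR: levelwise search in
   order of pattern generality under a mode-declaration language bias.
   A pattern is a definite clause such as

   ```prolog
   gene(A) :- involved_in(A, one_carbon_metabolic_process),
              regulated_by(A, B, transcription_factor),
              null_phenotype(B, abnormal_chronological_lifespan).
   ```

   read as: *genes (A) which are involved in the one-carbon metabolic
   process, and which are regulated by a transcription factor (B) whose
   deletion causes an abnormal chronological lifespan*. A pattern is kept
   when its support — the fraction of positive examples (deletant ORFs)
   it covers — meets the minimum (default 0.025%), and only kept
   patterns are refined (anti-monotone Apriori pruning). Defaults: at
   most 2048 descriptors, clause length ≤ 10, variable layers ≤ 10.
3. **Propositionalization** — each mined pattern becomes a binary
   descriptor column (`ilp1 … ilpN`); the matrix is inner-joined on ORF
   with per-protein abundance tables (and optionally 19 amino-acid
   concentration columns).
4. **Per-target regression** — one XGBoost model per protein, scored by
   5-fold cross-validation with per-fold MSE and R² = 1 − SS_res/SS_tot;
   optional Bayesian (GP expected-improvement) tuning on the first
   target only, reused everywhere.
5. **Explanation** — exact TreeSHAP Shapley values (float64; local
   accuracy `base + Σφ = prediction` holds to 1e-6 and better) computed
   out-of-fold, plus split-gain importances; per-target vectors are
   L1-normalized and averaged over all models with R² > 0, with 95%
   confidence intervals, and every reported descriptor carries its
   clause and English translation.

## Worked example

```python
import relmine as rm
from relmine import synth

kb, examples = synth.fixture_tk1()      # 9-fact toy KB, genes g1..g3
names = [e.name for e in examples]

ps = rm.mine(kb, names, synth.tk1_modes(),
             rm.MinerConstraints(min_support_fraction=0.6, max_clause_length=1))
for p, cov in ps:
    print(p.id, p.canonical, cov.support)
print(rm.propositionalize(ps, names).frame)
```

prints

```
ilp1 gene(A):-involved_in(A,one_carbon_metabolic_process) 2
ilp2 gene(A):-localizes_to(A,mitochondrion) 2
ilp3 gene(A):-regulated_by(A,B,transcription_factor) 2
     ilp1  ilp2  ilp3
orf
g1      1     0     1
g2      0     1     1
g3      1     1     0
```

i.e. exactly the three most-general patterns covering two of the three
example genes each, and the binary design matrix whose column sums equal
the pattern supports. Translating the worked three-literal pattern:

```python
P1 = rm.parse_pattern(
    "gene(A) :- regulated_by(A, B, transcription_factor), "
    "null_phenotype(B, abnormal_chronological_lifespan), "
    "involved_in(A, one_carbon_metabolic_process)")
print(rm.translate(P1))
```

```
genes (A) which are involved in the one-carbon metabolic process, and
which are regulated by a transcription factor (B), where the deletion of
B causes abnormal chronological lifespan
```

The miner also ships as a scikit-learn transformer:

```python
est = rm.RelationalPatternMiner(kb=kb, bias=synth.tk1_modes(),
                                min_support_fraction=0.6, max_clause_length=1)
X = est.fit_transform(names)            # same 3 x 3 binary matrix
```

## Command line

```bash
relmine simulate --n-genes 500 --effect 2.0 --noise-sd 0.5 --out-dir sim/
relmine run --config run.yaml   # curate -> mine -> propositionalize -> train -> explain
```

`run` executes the whole pipeline from one versioned YAML config and
writes every artifact (curated facts, patterns.json with English
translations, features.csv, leaderboard.csv, importance.csv, report.json)
plus a manifest of input/output digests; re-running a config reproduces
byte-identical artifacts.

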