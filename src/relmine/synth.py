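"""Synthetic knowledge bases and planted-signal targets.

Real inputs for this pipeline are curated yeast databases (gene function,
localisation, regulation, deletion phenotypes) joined with quantitative
proteomics of deletant strains. This module emulates that setting
structurally so every stage is testable end to end without external data:

* :func:`fixture_tk1` -- a fixed 9-fact toy knowledge base with three
  genes, built so the worked pattern (a gene involved in one-carbon
  metabolism and regulated by a transcription factor whose deletion
  perturbs chronological lifespan) covers exactly one gene.
* :func:`generate_kb` -- random ground facts sampled i.i.d. per predicate
  at a configured density over typed constant pools.
* :func:`plant_signal` -- minimally edits a KB so a chosen pattern covers
  a target fraction of the examples, giving known ground truth for
  recovery studies.
* :func:`simulate_targets` -- abundance-like targets
  ``y = sum_s effect_s * bits_s + Normal(0, sd)``.

Emulation is structural (schema plus densities), not distributional: no
attempt is made to match the marginal statistics of the real yeast
databases. All randomness flows from explicit integer seeds through
numpy ``SeedSequence`` spawning, so fixed seeds give byte-identical
serialized artifacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kb import Constant, Fact, KnowledgeBase
from .miner import ModeDeclaration
from .pattern import Pattern, Variable, coverage, find_substitution, matches

__all__ = [
    "SynthSchema",
    "PlantedSignal",
    "PlantResult",
    "fixture_tk1",
    "tk1_modes",
    "default_schema",
    "default_modes",
    "generate_kb",
    "plant_signal",
    "simulate_targets",
]


# ---------------------------------------------------------------------------
# fixed fixture

_TK1_SIGNATURES = {
    "regulated_by": ("gene", "tf", "reg_type"),
    "null_phenotype": ("free", "phenotype"),
    "involved_in": ("gene", "go_term"),
    "localizes_to": ("gene", "compartment"),
}

_TK1_FACTS = [
    ("regulated_by", ("g1", "tf1", "transcription_factor")),
    ("regulated_by", ("g2", "tf1", "transcription_factor")),
    ("null_phenotype", ("tf1", "abnormal_chronological_lifespan")),
    ("involved_in", ("g1", "one_carbon_metabolic_process")),
    ("involved_in", ("g3", "one_carbon_metabolic_process")),
    ("null_phenotype", ("g3", "decreased_resistance_to_oxidative_stress")),
    ("localizes_to", ("g2", "mitochondrion")),
    ("localizes_to", ("g3", "mitochondrion")),
    ("involved_in", ("g2", "atp_metabolic_process")),
]


def fixture_tk1() -> tuple[KnowledgeBase, list[Constant]]:
    """The 9-fact toy KB and its three positive examples g1, g2, g3."""
    kb = KnowledgeBase(
        (Fact(p, a) for p, a in _TK1_FACTS), signatures=_TK1_SIGNATURES
    )
    examples = [Constant(g, "gene") for g in ("g1", "g2", "g3")]
    return kb, examples


def tk1_modes() -> list[ModeDeclaration]:
    """The language bias matching the fixture schema."""
    return [
        ModeDeclaration.parse("involved_in(+gene, #go_term)"),
        ModeDeclaration.parse("localizes_to(+gene, #compartment)"),
        ModeDeclaration.parse("regulated_by(+gene, -tf, #reg_type)"),
        ModeDeclaration.parse("null_phenotype(+any, #phenotype)"),
    ]


# ---------------------------------------------------------------------------
# random knowledge bases


@dataclass(frozen=True)
class SynthSchema:
    """Schema and sampling densities for a random knowledge base.

    ``predicates`` maps predicate names to argument-type signatures;
    ``n_constants`` gives pool sizes per type; ``densities`` the i.i.d.
    inclusion probability of each possible ground fact of a predicate.
    Examples are all constants of ``example_type``.
    """

    predicates: Mapping[str, tuple[str, ...]]
    n_constants: Mapping[str, int]
    densities: Mapping[str, float]
    seed: int = 0
    example_type: str = "gene"

    def __post_init__(self):
        for p, d in self.densities.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"density for {p!r} outside [0, 1]")
        for t, n in self.n_constants.items():
            if n < 1:
                raise ValueError(f"need >= 1 constants of type {t!r}")
        for p in self.predicates:
            if p not in self.densities:
                raise ValueError(f"no density for predicate {p!r}")


_PREFIX = {
    "gene": "g",
    "tf": "tf",
    "go_term": "go",
    "phenotype": "ph",
    "compartment": "cp",
    "metabolite": "mb",
    "domain": "dm",
    "reg_type": "rt",
}


def _pool(type_tag: str, n: int) -> list[str]:
    prefix = _PREFIX.get(type_tag, type_tag)
    return [f"{prefix}{i:03d}" for i in range(n)]


def generate_kb(schema: SynthSchema) -> tuple[KnowledgeBase, list[Constant]]:
    """Sample a KB from the schema; deterministic per ``schema.seed``."""
    pools = {t: _pool(t, n) for t, n in schema.n_constants.items()}
    rng = np.random.default_rng(np.random.SeedSequence([schema.seed, 0x5EED]))
    facts: list[Fact] = []
    for pred in sorted(schema.predicates):
        sig = schema.predicates[pred]
        for t in sig:
            if t not in pools:
                raise ValueError(f"type {t!r} of {pred!r} has no constant pool")
        tuples = list(itertools.product(*(pools[t] for t in sig)))
        density = schema.densities[pred]
        draws = rng.random(len(tuples))
        facts.extend(
            Fact(pred, args) for args, u in zip(tuples, draws) if u < density
        )
    kb = KnowledgeBase(
        facts, signatures={p: tuple(s) for p, s in schema.predicates.items()}
    )
    examples = [
        Constant(c, schema.example_type)
        for c in pools[schema.example_type]
    ]
    return kb, examples


def default_schema(n_genes: int = 500, seed: int = 0) -> SynthSchema:
    """A yeast-like default schema: function, localisation, phenotype and
    regulation relations over a few hundred deletant genes."""
    return SynthSchema(
        predicates={
            "involved_in": ("gene", "go_term"),
            "localizes_to": ("gene", "compartment"),
            "null_phenotype": ("gene", "phenotype"),
            "regulated_by": ("gene", "tf", "reg_type"),
        },
        n_constants={
            "gene": n_genes,
            "go_term": 12,
            "compartment": 6,
            "phenotype": 10,
            "tf": 6,
            "reg_type": 1,
        },
        densities={
            "involved_in": 0.08,
            "localizes_to": 0.15,
            "null_phenotype": 0.05,
            "regulated_by": 0.04,
        },
        seed=seed,
    )


def default_modes() -> list[ModeDeclaration]:
    return [
        ModeDeclaration.parse("involved_in(+gene, #go_term)"),
        ModeDeclaration.parse("localizes_to(+gene, #compartment)"),
        ModeDeclaration.parse("null_phenotype(+gene, #phenotype)"),
        ModeDeclaration.parse("regulated_by(+gene, -tf, #reg_type)"),
    ]


# ---------------------------------------------------------------------------
# planting


@dataclass(frozen=True)
class PlantedSignal:
    """Ground truth for recovery studies: a pattern with a linear effect
    on the target (in target units per coverage bit) and the fraction of
    examples it should cover."""

    pattern: Pattern
    effect_size: float = 2.0
    noise_sd: float = 0.5
    coverage_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True, eq=False)
class PlantResult:
    kb: KnowledgeBase
    bits: np.ndarray  # realized coverage, ordered as the examples


def plant_signal(
    kb: KnowledgeBase,
    examples: Sequence[Constant | str],
    sig: PlantedSignal,
    seed: int = 0,
) -> PlantResult:
    """Edit the KB minimally so ``sig.pattern`` covers ~``coverage_fraction``.

    Each example is independently chosen covered with probability
    ``coverage_fraction`` (so realized support is Binomial). Covered
    examples get the missing body facts added, grounding output variables
    with per-example fresh constants to keep background density stable;
    uncovered examples have matching groundings broken by removing one
    witness fact at a time until the pattern no longer matches.
    """
    p = sig.pattern
    for lit in p.body:
        if lit.predicate not in kb.signatures:
            raise ValueError(
                f"pattern needs predicate {lit.predicate!r} absent from the KB"
            )
    names = [e.name if isinstance(e, Constant) else e for e in examples]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7]))
    covered = rng.random(len(names)) < sig.coverage_fraction

    facts = set(kb.facts)
    by_pred: dict[str, list[Fact]] = {}
    for f in sorted(facts):
        by_pred.setdefault(f.predicate, []).append(f)

    cur = kb
    dirty = False

    # additions first (fresh output constants cannot enable other examples)
    for e, want in zip(names, covered):
        if not want:
            continue
        if dirty:
            cur = KnowledgeBase(facts, kb.signatures)
            dirty = False
        if matches(p, e, cur):
            continue
        subst: dict[str, str] = {"A": e}
        fresh_idx = 0
        for lit in p.body:
            # try to ground this literal against existing facts
            cand = None
            for fact in by_pred.get(lit.predicate, ()):
                trial = dict(subst)
                ok = True
                for a, token in zip(lit.args, fact.args):
                    if isinstance(a, Variable):
                        if trial.setdefault(a.name, token) != token:
                            ok = False
                            break
                    elif a.name != token:
                        ok = False
                        break
                if ok:
                    cand = trial
                    break
            if cand is not None:
                subst = cand
                continue
            args = []
            for a in lit.args:
                if not isinstance(a, Variable):
                    args.append(a.name)
                elif a.name in subst:
                    args.append(subst[a.name])
                else:
                    t = p.var_types.get(a.name, "free")
                    fresh = f"{_PREFIX.get(t, t)}_{e}_{fresh_idx}"
                    fresh_idx += 1
                    subst[a.name] = fresh
                    args.append(fresh)
            fact = Fact(lit.predicate, tuple(args))
            facts.add(fact)
            by_pred.setdefault(fact.predicate, []).append(fact)
            dirty = True

    # removal rounds for examples that must not be covered
    if p.body:
        while True:
            cur = KnowledgeBase(facts, kb.signatures)
            to_remove: set[Fact] = set()
            for e, want in zip(names, covered):
                if want:
                    continue
                theta = find_substitution(p, e, cur)
                if theta is None:
                    continue
                lit = p.body[0]
                ground = tuple(
                    theta[a.name] if isinstance(a, Variable) else a.name
                    for a in lit.args
                )
                to_remove.add(Fact(lit.predicate, ground))
            if not to_remove:
                break
            facts -= to_remove

    new_kb = KnowledgeBase(facts, kb.signatures, removed_selectors=kb.removed_selectors)
    bits = coverage(p, names, new_kb).bits
    return PlantResult(new_kb, bits)


# ---------------------------------------------------------------------------
# targets


def simulate_targets(
    coverage_bits: Mapping[str, Sequence[bool]] | pd.DataFrame,
    signals: Sequence[tuple[str, float]],
    noise_sd: float,
    n_targets: int,
    seed: int = 0,
    index: Sequence[str] | None = None,
    prefix: str = "target",
) -> pd.DataFrame:
    """Simulated abundance targets ``y = sum_s effect_s * bits_s + noise``.

    ``coverage_bits`` maps feature names to 0/1 vectors (or is a
    DataFrame); ``signals`` lists ``(feature_name, effect)`` pairs shared
    by all ``n_targets`` targets, each of which draws independent
    Normal(0, ``noise_sd``) noise. An empty signal list gives pure-noise
    targets. Deterministic per seed.
    """
    if isinstance(coverage_bits, pd.DataFrame):
        frame = coverage_bits.astype(float)
    else:
        frame = pd.DataFrame(
            {k: np.asarray(v, dtype=float) for k, v in coverage_bits.items()}
        )
    if index is not None:
        frame.index = list(index)
    n = len(frame)
    base = np.zeros(n)
    for name, effect in signals:
        base = base + effect * frame[name].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A26]))
    width = len(str(max(n_targets, 1)))
    data = {}
    for t in range(n_targets):
        eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
        data[f"{prefix}_{t + 1:0{width}d}"] = base + eps
    return pd.DataFrame(data, index=frame.index)
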