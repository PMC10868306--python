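"""Levelwise frequent-pattern search over the knowledge base.

A simplified WARMR: starting from the most general clause ``gene(A)``,
patterns are specialized one literal at a time under a declared language
bias, and a candidate survives only if its support (fraction of positive
examples it covers) meets the minimum. Because support is anti-monotone
under specialization, only surviving patterns are refined -- the Apriori
pruning that makes the levelwise search feasible. No query packs or
infrequent-set reuse; plain breadth-first search over the refinement
graph.

The language bias is a list of mode declarations, e.g.
``regulated_by(+gene, -tf, #reg_type)``:

``+type``
    input slot, filled with an existing variable of that type (this is
    what keeps every pattern connected);
``-type``
    output slot, filled with a fresh variable (bounded by the variable
    layer limit);
``#type``
    constant slot, filled with each allowed constant of that type (by
    default, every constant of the type present in the KB).

:func:`brute_force_mine` enumerates the entire language within bounds
without support pruning and is the reference semantics for :func:`mine`
on small instances.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kb import Constant, KnowledgeBase
from .pattern import (
    CoverageVector,
    Literal,
    Pattern,
    PatternError,
    Variable,
    coverage,
    parse_pattern,
    translate,
)

__all__ = [
    "ArgMode",
    "ModeDeclaration",
    "MinerConstraints",
    "PatternSet",
    "refinements",
    "mine",
    "brute_force_mine",
    "InstanceTooLarge",
]

log = logging.getLogger(__name__)

_MODE_RE = re.compile(r"(?P<pred>[a-z0-9][A-Za-z0-9_]*)\((?P<slots>[^()]*)\)\s*\Z")


class InstanceTooLarge(ValueError):
    """Brute-force oracle guard tripped; instance exceeds the small-case bounds."""


@dataclass(frozen=True)
class ArgMode:
    """One argument slot of a mode declaration."""

    kind: str  # '+', '-', or '#'
    type: str
    constants: tuple[str, ...] | None = None  # only for '#'; None = all of type

    def __post_init__(self):
        if self.kind not in "+-#":
            raise ValueError(f"mode slot kind must be +, - or #, got {self.kind!r}")
        if self.constants is not None and self.kind != "#":
            raise ValueError("allowed constants only apply to # slots")

    def __str__(self) -> str:
        return f"{self.kind}{self.type}"


@dataclass(frozen=True)
class ModeDeclaration:
    """Which literals the refinement operator may add, and how to fill them."""

    predicate: str
    slots: tuple[ArgMode, ...]

    def __post_init__(self):
        if not any(s.kind == "+" for s in self.slots):
            raise ValueError(
                f"mode {self.predicate} needs at least one + slot (connectedness)"
            )

    @property
    def arity(self) -> int:
        return len(self.slots)

    @classmethod
    def parse(
        cls, text: str, constants: Mapping[int, Sequence[str]] | None = None
    ) -> "ModeDeclaration":
        """Parse ``"pred(+gene, -tf, #reg_type)"``; ``constants`` maps
        0-based slot positions to explicit allowed-constant lists."""
        m = _MODE_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed mode declaration {text!r}")
        slots = []
        for i, raw in enumerate(m.group("slots").split(",")):
            raw = raw.strip()
            if not raw or raw[0] not in "+-#":
                raise ValueError(f"malformed mode slot {raw!r} in {text!r}")
            allowed = None
            if constants and i in constants:
                allowed = tuple(constants[i])
            slots.append(ArgMode(raw[0], raw[1:], allowed))
        return cls(m.group("pred"), tuple(slots))

    def __str__(self) -> str:
        return f"{self.predicate}({', '.join(map(str, self.slots))})"


@dataclass(frozen=True)
class MinerConstraints:
    """Search bounds. Defaults: support >= 0.025% of positive examples,
    at most 2048 descriptors, clause length and variable layers <= 10."""

    min_support_fraction: float = 0.00025
    max_features: int = 2048
    max_clause_length: int = 10
    max_var_layers: int = 10
    drop_coverage_duplicates: bool = False

    def __post_init__(self):
        if not 0 < self.min_support_fraction <= 1:
            raise ValueError("min_support_fraction must be in (0, 1]")
        for name in ("max_features", "max_clause_length", "max_var_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class PatternSet:
    """Mined patterns with their coverage, in discovery order (ids ilp1..N)."""

    items: tuple[tuple[Pattern, CoverageVector], ...]
    examples: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def patterns(self) -> list[Pattern]:
        return [p for p, _ in self.items]

    @property
    def ids(self) -> list[str]:
        return [p.id for p, _ in self.items]

    def get(self, id: str) -> tuple[Pattern, CoverageVector]:
        for p, cov in self.items:
            if p.id == id:
                return p, cov
        raise KeyError(id)

    def canonical_supports(self) -> dict[str, int]:
        """Canonical form -> support; the set identity used in tests."""
        return {p.canonical: cov.support for p, cov in self.items}

    def to_json(self, vocab: Mapping | None = None) -> str:
        records = []
        for p, cov in self.items:
            records.append(
                {
                    "id": p.id,
                    "head": "gene(A)",
                    "body": [
                        {
                            "predicate": l.predicate,
                            "args": [
                                {"var": a.name}
                                if isinstance(a, Variable)
                                else {"const": a.name, "type": a.type_tag}
                                for a in l.args
                            ],
                        }
                        for l in p.body
                    ],
                    "clause": p.to_clause(),
                    "english": translate(p, vocab),
                    "support": cov.support,
                    "support_fraction": cov.support_fraction,
                    "bits": "".join("1" if b else "0" for b in cov.bits),
                }
            )
        payload = {
            "examples": list(self.examples),
            "patterns": records,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatternSet":
        payload = json.loads(text)
        examples = tuple(payload["examples"])
        items = []
        for rec in payload["patterns"]:
            p = parse_pattern(rec["clause"], id=rec["id"])
            bits = np.array([c == "1" for c in rec["bits"]], dtype=bool)
            cov = CoverageVector(
                rec["id"], bits, rec["support"], rec["support_fraction"]
            )
            items.append((p, cov))
        return cls(tuple(items), examples, payload.get("provenance", {}))


# ---------------------------------------------------------------------------
# refinement operator


def _type_compatible(mode_type: str, var_type: str) -> bool:
    return mode_type == "any" or mode_type == var_type


def _literal_extensions(
    var_types: Mapping[str, str],
    bias: Sequence[ModeDeclaration],
    kb: KnowledgeBase,
) -> Iterable[tuple[Literal, dict[str, str]]]:
    """All literals addable to a pattern with variables ``var_types``.

    Yields ``(literal, fresh-variable types)``. Fresh variables get
    placeholder names (renamed by canonicalization).
    """
    existing = sorted(var_types.items())
    for mode in bias:
        if mode.predicate not in kb.signatures:
            continue
        if mode.arity != len(kb.signatures[mode.predicate]):
            warnings.warn(
                f"mode {mode} arity does not match the signature of "
                f"{mode.predicate!r}; skipped",
                stacklevel=3,
            )
            continue
        slot_choices: list[list] = []
        feasible = True
        fresh_counter = itertools.count()
        for slot in mode.slots:
            if slot.kind == "+":
                opts = [
                    Variable(v)
                    for v, vt in existing
                    if _type_compatible(slot.type, vt)
                ]
            elif slot.kind == "-":
                opts = [("fresh", next(fresh_counter), slot.type)]
            else:  # '#'
                consts = (
                    slot.constants
                    if slot.constants is not None
                    else kb.constants_of_type(slot.type)
                )
                opts = [Constant(c, slot.type) for c in sorted(consts)]
            if not opts:
                feasible = False
                break
            slot_choices.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*slot_choices):
            fresh_types: dict[str, str] = {}
            args: list = []
            for item in combo:
                if isinstance(item, tuple) and item[0] == "fresh":
                    name = f"N{item[1]}"
                    fresh_types[name] = item[2]
                    args.append(Variable(name))
                else:
                    args.append(item)
            yield Literal(mode.predicate, tuple(args)), fresh_types


def refinements(
    p: Pattern,
    bias: Sequence[ModeDeclaration],
    kb: KnowledgeBase,
    c: MinerConstraints,
) -> list[Pattern]:
    """All one-literal specializations of ``p`` allowed by the bias.

    Results are deduplicated by canonical form; each has body length
    ``len(p) + 1``. Literals syntactically identical to one already in the
    body, and extensions violating the variable-layer bound, are skipped.
    """
    if len(p) >= c.max_clause_length:
        return []
    out: dict[str, Pattern] = {}
    body_rendered = {l.render() for l in p.body}
    for lit, fresh_types in _literal_extensions(p.var_types, bias, kb):
        if lit.render() in body_rendered:
            continue
        var_types = {**p.var_types, **fresh_types}
        q = Pattern(p.body + (lit,), var_types=var_types)
        if q.max_layer > c.max_var_layers:
            continue
        out.setdefault(q.canonical, q)
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# levelwise search


def _example_names(examples: Sequence[Constant | str]) -> list[str]:
    names = [e.name if isinstance(e, Constant) else e for e in examples]
    if not names:
        raise ValueError("examples must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError("examples must be unique")
    return names


def _provenance(kb, names, bias, c, seed):
    return {
        "kb_digest": kb.digest(),
        "examples_digest": hashlib.sha256("\n".join(names).encode()).hexdigest(),
        "n_examples": len(names),
        "bias": [str(m) for m in bias],
        "constraints": asdict(c),
        "seed": seed,
        "target_derived_removed": bool(kb.removed_selectors),
        "removed_selectors": [list(s) for s in kb.removed_selectors],
    }


def _finalize(kept, names, prov) -> PatternSet:
    items = []
    for i, (p, cov) in enumerate(kept, start=1):
        pid = f"ilp{i}"
        p2 = p.with_id(pid)
        items.append(
            (p2, CoverageVector(pid, cov.bits, cov.support, cov.support_fraction))
        )
    return PatternSet(tuple(items), tuple(names), prov)


def mine(
    kb: KnowledgeBase,
    examples: Sequence[Constant | str],
    bias: Sequence[ModeDeclaration],
    c: MinerConstraints = MinerConstraints(),
    seed: int = 0,
) -> PatternSet:
    """Breadth-first levelwise search for frequent patterns.

    A candidate is kept iff its support fraction meets
    ``c.min_support_fraction``; only kept patterns are refined. Within a
    level, discovery order is (support descending, canonical form
    ascending); the search stops when a level yields nothing, the clause
    length bound is reached, or ``c.max_features`` patterns are collected
    (truncating in discovery order). Deterministic for identical inputs;
    ``seed`` is recorded in provenance only -- the core search draws no
    random numbers.
    """
    names = _example_names(examples)
    if not bias:
        raise ValueError("bias must be non-empty")
    for mode in bias:
        if mode.predicate not in kb.signatures:
            warnings.warn(
                f"mode predicate {mode.predicate!r} absent from the KB; skipped",
                stacklevel=2,
            )
    prov = _provenance(kb, names, bias, c, seed)

    kept: list[tuple[Pattern, CoverageVector]] = []
    seen_keys: set[bytes] = set()
    frontier: list[Pattern] = [Pattern(())]
    capped = False
    for _level in range(1, c.max_clause_length + 1):
        cands: dict[str, Pattern] = {}
        for p in frontier:
            for q in refinements(p, bias, kb, c):
                cands.setdefault(q.canonical, q)
        scored = []
        for canon in sorted(cands):
            q = cands[canon]
            cov = coverage(q, names, kb)
            if cov.support_fraction >= c.min_support_fraction:
                scored.append((q, cov))
        scored.sort(key=lambda qc: (-qc[1].support, qc[0].canonical))
        log.info(
            "level %d: %d candidates, %d frequent, %d kept so far",
            _level, len(cands), len(scored), len(kept),
        )
        frontier = []
        for q, cov in scored:
            frontier.append(q)
            if c.drop_coverage_duplicates and cov.key() in seen_keys:
                continue
            if len(kept) < c.max_features:
                kept.append((q, cov))
                seen_keys.add(cov.key())
            else:
                capped = True
        if capped or not frontier:
            break
    if not kept:
        warnings.warn("no pattern meets the minimum support; empty pattern set",
                      stacklevel=2)
    return _finalize(kept, names, prov)


def brute_force_mine(
    kb: KnowledgeBase,
    examples: Sequence[Constant | str],
    bias: Sequence[ModeDeclaration],
    c: MinerConstraints = MinerConstraints(),
) -> PatternSet:
    """Exhaustive reference miner for small instances.

    Enumerates every syntactically valid connected pattern within the
    clause-length and layer bounds (no support pruning), then filters by
    support, deduplicates canonically, and applies the same discovery
    order and cap as :func:`mine`. Guards: at most 12 constants per type
    and ``max_clause_length <= 3``.
    """
    names = _example_names(examples)
    if not bias:
        raise ValueError("bias must be non-empty")
    if c.max_clause_length > 3:
        raise InstanceTooLarge("brute force requires max_clause_length <= 3")
    for t in sorted({s.type for m in bias for s in m.slots}):
        n = len(kb.constants_of_type(t))
        if n > 12:
            raise InstanceTooLarge(f"{n} constants of type {t!r} (limit 12)")

    all_patterns: dict[str, Pattern] = {}
    stack: list[Pattern] = [Pattern(())]
    while stack:
        p = stack.pop()
        if len(p) >= c.max_clause_length:
            continue
        for q in refinements(p, bias, kb, c):
            if q.canonical not in all_patterns:
                all_patterns[q.canonical] = q
                stack.append(q)

    by_level: dict[int, list[tuple[Pattern, CoverageVector]]] = {}
    for canon in sorted(all_patterns):
        q = all_patterns[canon]
        cov = coverage(q, names, kb)
        if cov.support_fraction >= c.min_support_fraction:
            by_level.setdefault(len(q), []).append((q, cov))

    kept: list[tuple[Pattern, CoverageVector]] = []
    seen_keys: set[bytes] = set()
    for level in sorted(by_level):
        scored = sorted(by_level[level], key=lambda qc: (-qc[1].support, qc[0].canonical))
        for q, cov in scored:
            if c.drop_coverage_duplicates and cov.key() in seen_keys:
                continue
            if len(kept) < c.max_features:
                kept.append((q, cov))
                seen_keys.add(cov.key())
    prov = _provenance(kb, names, bias, c, seed=None)
    prov["oracle"] = "brute_force"
    return _finalize(kept, names, prov)
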