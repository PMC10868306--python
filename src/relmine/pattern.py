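"""Definite-clause patterns: matching, canonical forms, English readings.

A pattern is a definite clause headed ``gene(A)`` whose body is a
conjunction of literals over the knowledge base, e.g.::

    gene(A) :- involved_in(A, one_carbon_metabolic_process),
               regulated_by(A, B, transcription_factor),
               null_phenotype(B, abnormal_chronological_lifespan)

A gene ``g`` is *covered* when the body is satisfiable with ``A = g``
(existential semantics -- the first grounding found suffices; groundings
are not counted). Coverage over the positive-example list is the pattern's
support and, after propositionalization, its value as a binary feature.

Patterns are canonicalized at construction: body literals are reordered
into the lexicographically least connected order and variables renamed
``A, B, C, ...`` in order of first appearance, so syntactic variants of
the same clause collapse to one :attr:`Pattern.canonical` string.
"""

from __future__ import annotations

from dataclasses import dataclass
import re
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kb import Constant, KnowledgeBase, _TOKEN_RE

__all__ = [
    "Variable",
    "Literal",
    "Pattern",
    "CoverageVector",
    "PatternError",
    "TranslationError",
    "matches",
    "find_substitution",
    "coverage",
    "translate",
    "parse_pattern",
    "DEFAULT_VOCAB",
]

HEAD_PREDICATE = "gene"
HEAD_TYPE = "gene"


class PatternError(ValueError):
    """Ill-formed pattern: disconnected body, unknown predicate, ..."""


class TranslationError(KeyError):
    """Missing phrase templates for one or more predicates."""


_VAR_RE = re.compile(r"[A-Z][A-Za-z0-9_]*\Z")


@dataclass(frozen=True)
class Variable:
    """A logical variable; names start uppercase (``A`` is the head)."""

    name: str

    def __post_init__(self) -> None:
        if not _VAR_RE.match(self.name):
            raise PatternError(f"invalid variable name {self.name!r}")


@dataclass(frozen=True)
class Literal:
    """``predicate(arg1, ..., argN)`` with variable or constant arguments."""

    predicate: str
    args: tuple[Variable | Constant, ...]

    def __post_init__(self) -> None:
        if len(self.args) < 1:
            raise PatternError(f"literal {self.predicate} must have arity >= 1")

    def variables(self) -> list[Variable]:
        return [a for a in self.args if isinstance(a, Variable)]

    def render(self) -> str:
        parts = [a.name for a in self.args]
        return f"{self.predicate}({','.join(parts)})"


def _canonical_names():
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for ch in alphabet:
        yield ch
    i = 26
    while True:
        yield f"V{i}"
        i += 1


def _canonicalize(
    body: Sequence[Literal], head_name: str
) -> tuple[tuple[Literal, ...], dict[str, str], dict[str, int]]:
    """Least connected ordering with canonical variable names.

    Returns ``(ordered body, original->canonical name map, layer map)``.
    The search branches only on render ties, keeping the globally smallest
    serialization; a body with no valid connected ordering raises.
    """
    n = len(body)
    if n == 0:
        return (), {head_name: "A"}, {"A": 0}

    best: dict = {"key": None, "order": None, "ren": None, "lay": None}

    def rec(remaining: list[int], ren: dict[str, str], names: list[str],
            lay: dict[str, int], acc: list[str], order: list[int]) -> None:
        if not remaining:
            key = ",".join(acc)
            if best["key"] is None or key < best["key"]:
                best.update(key=key, order=list(order), ren=dict(ren), lay=dict(lay))
            return
        # prune: current prefix already worse than best
        if best["key"] is not None and ",".join(acc) > best["key"]:
            return
        rendered: list[tuple[str, int, dict[str, str]]] = []
        for idx in remaining:
            lit = body[idx]
            vars_ = lit.variables()
            if not any(v.name in ren for v in vars_):
                continue  # would be disconnected here
            new_ren: dict[str, str] = {}
            k = 0
            parts = []
            for a in lit.args:
                if isinstance(a, Constant):
                    parts.append(a.name)
                elif a.name in ren:
                    parts.append(ren[a.name])
                elif a.name in new_ren:
                    parts.append(new_ren[a.name])
                else:
                    new_ren[a.name] = names[len(ren) + k]
                    k += 1
                    parts.append(new_ren[a.name])
            rendered.append((f"{lit.predicate}({','.join(parts)})", idx, new_ren))
        if not rendered:
            return  # dead end on this branch
        mr = min(r[0] for r in rendered)
        for text, idx, new_ren in rendered:
            if text != mr:
                continue
            lit = body[idx]
            bound_layers = [lay[ren[v.name]] for v in lit.variables() if v.name in ren]
            new_lay = dict(lay)
            for orig, canon in new_ren.items():
                new_lay[canon] = 1 + max(bound_layers)
            rec(
                [i for i in remaining if i != idx],
                {**ren, **new_ren},
                names,
                new_lay,
                acc + [text],
                order + [idx],
            )

    names = []
    gen = _canonical_names()
    for _ in range(n * 3 + 2):
        names.append(next(gen))
    rec(list(range(n)), {head_name: "A"}, names, {"A": 0}, [], [])

    if best["key"] is None:
        raise PatternError(
            "disconnected pattern body: " + "; ".join(l.render() for l in body)
        )
    ren = best["ren"]
    ordered = []
    for idx in best["order"]:
        lit = body[idx]
        new_args = tuple(
            Variable(ren[a.name]) if isinstance(a, Variable) else a for a in lit.args
        )
        ordered.append(Literal(lit.predicate, new_args))
    return tuple(ordered), ren, best["lay"]


class Pattern:
    """A canonicalized definite clause ``gene(A) :- body``.

    Parameters
    ----------
    body:
        Literals in any connected-orderable arrangement; reordered and
        variable-renamed at construction.
    id:
        Descriptor identifier (``ilp``-prefixed once assigned by the miner).
    var_types:
        Optional map from *original* variable names to type tags; the head
        variable is always typed ``gene``. Untyped variables are ``free``.
    head_var:
        Name of the head variable in ``body`` (default ``"A"``).
    """

    __slots__ = ("body", "id", "var_types", "var_layers", "canonical")

    def __init__(
        self,
        body: Sequence[Literal] = (),
        id: str | None = None,
        var_types: Mapping[str, str] | None = None,
        head_var: str = "A",
    ):
        ordered, ren, layers = _canonicalize(tuple(body), head_var)
        self.body: tuple[Literal, ...] = ordered
        self.id = id
        self.var_layers: dict[str, int] = layers
        vt = {"A": HEAD_TYPE}
        for orig, canon in ren.items():
            if canon == "A":
                continue
            vt[canon] = (var_types or {}).get(orig, "free")
        self.var_types: dict[str, str] = vt
        if not self.body:
            self.canonical = f"{HEAD_PREDICATE}(A):-true"
        else:
            self.canonical = (
                f"{HEAD_PREDICATE}(A):-" + ",".join(l.render() for l in self.body)
            )

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.body)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pattern) and self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __repr__(self) -> str:
        return f"Pattern({self.canonical!r}, id={self.id!r})"

    @property
    def max_layer(self) -> int:
        return max(self.var_layers.values())

    def variables(self) -> list[str]:
        """Canonical variable names in order of first appearance."""
        seen = ["A"]
        for lit in self.body:
            for v in lit.variables():
                if v.name not in seen:
                    seen.append(v.name)
        return seen

    def predicates(self) -> set[str]:
        return {l.predicate for l in self.body}

    def mentions(self, predicate: str, constant: str | None = None) -> bool:
        """Does any body literal use ``predicate`` (and ``constant``)?"""
        for lit in self.body:
            if lit.predicate != predicate:
                continue
            if constant is None:
                return True
            if any(isinstance(a, Constant) and a.name == constant for a in lit.args):
                return True
        return False

    def with_id(self, id: str) -> "Pattern":
        p = Pattern.__new__(Pattern)
        p.body = self.body
        p.id = id
        p.var_types = self.var_types
        p.var_layers = self.var_layers
        p.canonical = self.canonical
        return p

    def to_clause(self) -> str:
        if not self.body:
            return f"{HEAD_PREDICATE}(A) :- true."
        body = ", ".join(
            f"{l.predicate}({', '.join(a.name for a in l.args)})" for l in self.body
        )
        return f"{HEAD_PREDICATE}(A) :- {body}."


# ---------------------------------------------------------------------------
# matching


def find_substitution(
    p: Pattern, example: Constant | str, kb: KnowledgeBase
) -> dict[str, str] | None:
    """First substitution grounding the body with ``A = example``, or None.

    Backtracking search over the KB index; the canonical literal order
    guarantees every literal has at least one bound argument when reached,
    so each step is index-driven.
    """
    name = example.name if isinstance(example, Constant) else example
    for lit in p.body:
        if lit.predicate not in kb.signatures:
            raise PatternError(f"unknown predicate {lit.predicate!r} in pattern")
        if len(lit.args) != len(kb.signatures[lit.predicate]):
            raise PatternError(
                f"arity mismatch for {lit.predicate!r} in pattern"
            )
    return _search(p.body, 0, {"A": name}, kb)


def _search(body, i, subst, kb):
    if i == len(body):
        return dict(subst)
    lit = body[i]
    bound: list[tuple[int, str]] = []
    for pos, a in enumerate(lit.args):
        if isinstance(a, Constant):
            bound.append((pos, a.name))
        elif a.name in subst:
            bound.append((pos, subst[a.name]))
    if bound:
        pos, val = min(
            bound, key=lambda pv: len(kb.facts_matching(lit.predicate, *pv))
        )
        cands = kb.facts_matching(lit.predicate, pos, val)
    else:  # unreachable for canonical connected bodies; kept for safety
        cands = kb.facts_for(lit.predicate)
    for fact in cands:
        new = dict(subst)
        ok = True
        for a, token in zip(lit.args, fact.args):
            if isinstance(a, Constant):
                if a.name != token:
                    ok = False
                    break
            elif a.name in new:
                if new[a.name] != token:
                    ok = False
                    break
            else:
                new[a.name] = token
        if not ok:
            continue
        res = _search(body, i + 1, new, kb)
        if res is not None:
            return res
    return None


def matches(p: Pattern, example: Constant | str, kb: KnowledgeBase) -> bool:
    """True iff the pattern body is satisfiable with ``A`` bound to ``example``."""
    return find_substitution(p, example, kb) is not None


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True, eq=False)
class CoverageVector:
    """Per-example match indicators for one pattern."""

    pattern_id: str | None
    bits: np.ndarray  # bool, ordered as the example list
    support: int
    support_fraction: float

    def __post_init__(self):
        if int(self.bits.sum()) != self.support:
            raise ValueError("support inconsistent with bits")
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError("support_fraction outside [0, 1]")

    def key(self) -> bytes:
        """Hashable extension identity (for coverage-duplicate detection)."""
        return np.packbits(self.bits).tobytes()


def coverage(
    p: Pattern, examples: Sequence[Constant | str], kb: KnowledgeBase
) -> CoverageVector:
    """Coverage bits, support and support fraction over the example list."""
    names = [e.name if isinstance(e, Constant) else e for e in examples]
    if not names:
        raise ValueError("examples must be non-empty")
    if len(set(names)) != len(names):
        raise ValueError("examples must be unique")
    bits = np.fromiter(
        (matches(p, e, kb) for e in names), dtype=bool, count=len(names)
    )
    support = int(bits.sum())
    return CoverageVector(p.id, bits, support, support / len(names))


# ---------------------------------------------------------------------------
# translation

#: Phrase templates shipped with the yeast schema. ``subject`` phrases
#: read as predicates of their first argument ("genes (A) which ...");
#: ``clause`` phrases are used when the literal is about another variable.
#: ``{i}`` slots are filled with rendered argument ``i``.
DEFAULT_VOCAB: dict = {
    "predicates": {
        "involved_in": {"subject": "are involved in the {1}"},
        "localizes_to": {"subject": "localize to the {1}"},
        "regulated_by": {"subject": "are regulated by a {2} ({1})"},
        "null_phenotype": {
            "subject": "show {1} when deleted",
            "clause": "the deletion of {0} causes {1}",
        },
        "interacts_with": {
            "subject": "interact with {1}",
            "clause": "{0} interacts with {1}",
        },
        "consumes": {"subject": "consume {1}"},
        "produces": {"subject": "produce {1}"},
        "has_domain": {
            "subject": "contain a {1} domain",
            "clause": "{0} contains a {1} domain",
        },
    },
    "constants": {
        "one_carbon_metabolic_process": "one-carbon metabolic process",
        "transcription_factor": "transcription factor",
    },
}


def _render_arg(a: Variable | Constant, vocab: Mapping) -> str:
    if isinstance(a, Variable):
        return a.name
    return vocab.get("constants", {}).get(a.name, a.name.replace("_", " "))


def translate(p: Pattern, vocab: Mapping | None = None) -> str:
    """Deterministic English reading of a pattern.

    Every predicate used by the pattern must have a template in
    ``vocab["predicates"]``; unresolved constants fall back to their token
    with underscores replaced by spaces.
    """
    vocab = DEFAULT_VOCAB if vocab is None else vocab
    missing = sorted(
        pred for pred in p.predicates() if pred not in vocab.get("predicates", {})
    )
    if missing:
        raise TranslationError(f"missing phrase templates for: {', '.join(missing)}")
    if not p.body:
        return "all genes (A)"
    parts = ["genes (A)"]
    n_subject = 0
    for lit in p.body:
        tpl = vocab["predicates"][lit.predicate]
        rendered = [_render_arg(a, vocab) for a in lit.args]
        first = lit.args[0]
        if isinstance(first, Variable) and first.name == "A":
            text = tpl["subject"].format(*rendered)
            joiner = " which " if n_subject == 0 else ", and which "
            parts.append(joiner + text)
            n_subject += 1
        else:
            clause_tpl = tpl.get("clause")
            if clause_tpl is None:
                clause_tpl = "{0} " + tpl["subject"]
            parts.append(", where " + clause_tpl.format(*rendered))
    return "".join(parts)


# ---------------------------------------------------------------------------
# clause-text parsing

_LIT_RE = re.compile(r"([a-zA-Z_][A-Za-z0-9_]*)\(([^()]*)\)")


def parse_pattern(
    text: str,
    var_types: Mapping[str, str] | None = None,
    id: str | None = None,
) -> Pattern:
    """Parse Prolog-style clause text back into a :class:`Pattern`.

    Accepts ``gene(A) :- lit1, lit2.`` (the trailing period optional) and
    the empty-body forms ``gene(A).`` / ``gene(A) :- true.``; tokens with
    uppercase initials are variables.
    """
    text = text.strip().rstrip(".")
    if ":-" in text:
        head_text, body_text = text.split(":-", 1)
    else:
        head_text, body_text = text, ""
    hm = _LIT_RE.match(head_text.strip())
    if not hm or hm.group(1) != HEAD_PREDICATE:
        raise PatternError(f"pattern head must be {HEAD_PREDICATE}(Var): {text!r}")
    head_var = hm.group(2).strip()
    if not _VAR_RE.match(head_var):
        raise PatternError(f"head argument must be a variable: {head_var!r}")
    body: list[Literal] = []
    body_text = body_text.strip()
    if body_text and body_text != "true":
        found = _LIT_RE.findall(body_text)
        leftover = _LIT_RE.sub("", body_text).replace(",", "").strip()
        if not found or leftover:
            raise PatternError(f"malformed pattern body: {body_text!r}")
        for pred, argtext in found:
            args: list[Variable | Constant] = []
            for tok in (t.strip() for t in argtext.split(",")):
                if not tok:
                    raise PatternError(f"empty argument in {pred}")
                if _VAR_RE.match(tok):
                    args.append(Variable(tok))
                elif _TOKEN_RE.match(tok):
                    args.append(Constant(tok, (var_types or {}).get(tok, "free")))
                else:
                    raise PatternError(f"invalid token {tok!r} in {pred}")
            body.append(Literal(pred, tuple(args)))
    return Pattern(body, id=id, var_types=var_types, head_var=head_var)
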