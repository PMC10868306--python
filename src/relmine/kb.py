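"""Typed ground-fact knowledge base with curation and leakage filters.

The knowledge base is a Datalog-style store of ground facts such as
``involved_in(ykl001c, one_carbon_metabolic_process)`` describing yeast
systems biology: gene function (GO annotation), localisation, regulation,
deletion phenotypes, gene--metabolite relations, domains and interactions.
Facts are loaded from a small Prolog-like fact dialect (one clause per
line) or from TSV, validated against per-predicate signatures, and indexed
for conjunctive-query evaluation.

Two filter families mirror how such a database is prepared for mining:

* :func:`apply_curation` removes facts from a foreign strain background,
  facts referencing invalid GO terms, dose-dependent phenotypes (toxin or
  chemical resistance), and gene--metabolite facts involving currency
  metabolites (H+, H2O) that carry no regulatory information.
* :func:`remove_target_derived_relations` deletes every relation derived
  from the prediction targets themselves, so mined descriptors can never
  leak the quantity they are later asked to predict.

Both return a new :class:`KnowledgeBase`; the original is never mutated.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Constant",
    "Fact",
    "KnowledgeBase",
    "CurationConfig",
    "CurationResult",
    "LeakageResult",
    "RemovalRecord",
    "KBError",
    "FactSyntaxError",
    "parse_fact_file",
    "parse_fact_tsv",
    "load_facts",
    "apply_curation",
    "remove_target_derived_relations",
]

#: tokens are lowercase-led identifiers; uppercase initials are reserved
#: for variables in the pattern dialect.
_TOKEN_RE = re.compile(r"[a-z0-9][A-Za-z0-9_]*\Z")
_CLAUSE_RE = re.compile(r"(?P<pred>[^\s(]+)\((?P<args>[^()]*)\)\s*\.\s*\Z")
_SIGNATURE_RE = re.compile(
    r":-\s*signature\(\s*(?P<pred>[^\s,()]+)\s*,\s*\[(?P<types>[^\]]*)\]\s*\)\s*\.\s*\Z"
)

FREE = "free"


class KBError(ValueError):
    """Invalid fact, signature conflict or malformed knowledge base."""


class FactSyntaxError(KBError):
    """Malformed line in a fact file; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _check_token(name: str) -> str:
    if not _TOKEN_RE.match(name):
        raise KBError(
            f"invalid constant token {name!r}: must match {_TOKEN_RE.pattern} "
            "(uppercase initials are reserved for variables)"
        )
    return name


@dataclass(frozen=True, order=True)
class Constant:
    """A ground term with a semantic type tag (gene, go_term, phenotype, ...)."""

    name: str
    type_tag: str = FREE

    def __post_init__(self) -> None:
        _check_token(self.name)
        _check_token(self.type_tag)


@dataclass(frozen=True, order=True)
class Fact:
    """A ground atom ``predicate(arg1, ..., argN)`` with arity >= 1."""

    predicate: str
    args: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_token(self.predicate)
        if len(self.args) < 1:
            raise KBError(f"fact {self.predicate} must have arity >= 1")
        for a in self.args:
            _check_token(a)

    @property
    def arity(self) -> int:
        return len(self.args)

    def to_clause(self) -> str:
        return f"{self.predicate}({', '.join(self.args)})."


class KnowledgeBase:
    """Immutable set of ground facts indexed by predicate and argument slot.

    Parameters
    ----------
    facts:
        Iterable of :class:`Fact`. Duplicates are merged (set semantics).
    signatures:
        Optional map ``predicate -> tuple of type tags``. Predicates not
        listed get their signature inferred on first occurrence, with all
        argument types defaulting to ``free``.
    removed_selectors:
        Provenance of leakage filtering already applied (see
        :func:`remove_target_derived_relations`).
    """

    def __init__(
        self,
        facts: Iterable[Fact] = (),
        signatures: Mapping[str, Sequence[str]] | None = None,
        removed_selectors: Sequence[tuple[str, str | None]] = (),
    ):
        self._signatures: dict[str, tuple[str, ...]] = {
            p: tuple(t) for p, t in (signatures or {}).items()
        }
        self._facts: set[Fact] = set()
        self._by_pred: dict[str, list[Fact]] = {}
        self._by_slot: dict[tuple[str, int, str], list[Fact]] = {}
        self.removed_selectors: tuple[tuple[str, str | None], ...] = tuple(
            removed_selectors
        )
        for f in facts:
            self._add(f)
        # deterministic iteration order everywhere
        for lst in self._by_pred.values():
            lst.sort()
        for lst in self._by_slot.values():
            lst.sort()

    def _add(self, fact: Fact) -> None:
        sig = self._signatures.get(fact.predicate)
        if sig is None:
            sig = tuple(FREE for _ in fact.args)
            self._signatures[fact.predicate] = sig
        elif len(sig) != fact.arity:
            raise KBError(
                f"arity conflict for predicate {fact.predicate!r}: "
                f"declared {len(sig)}, fact has {fact.arity}"
            )
        if fact in self._facts:
            return
        self._facts.add(fact)
        self._by_pred.setdefault(fact.predicate, []).append(fact)
        for pos, arg in enumerate(fact.args):
            self._by_slot.setdefault((fact.predicate, pos, arg), []).append(fact)

    # -- queries ---------------------------------------------------------

    @property
    def facts(self) -> frozenset[Fact]:
        return frozenset(self._facts)

    @property
    def signatures(self) -> Mapping[str, tuple[str, ...]]:
        return dict(self._signatures)

    def __len__(self) -> int:
        return len(self._facts)

    def __contains__(self, fact: Fact) -> bool:
        return fact in self._facts

    def predicates(self) -> list[str]:
        return sorted(self._signatures)

    def facts_for(self, predicate: str) -> list[Fact]:
        return list(self._by_pred.get(predicate, ()))

    def facts_matching(self, predicate: str, pos: int, constant: str) -> list[Fact]:
        """All facts of ``predicate`` whose argument ``pos`` equals ``constant``."""
        return list(self._by_slot.get((predicate, pos, constant), ()))

    def constants_of_type(self, type_tag: str) -> list[str]:
        """Sorted constants occurring in argument slots declared ``type_tag``.

        ``'any'`` collects every constant in the knowledge base.
        """
        out: set[str] = set()
        for pred, sig in self._signatures.items():
            for pos, t in enumerate(sig):
                if type_tag == "any" or t == type_tag:
                    for f in self._by_pred.get(pred, ()):
                        out.add(f.args[pos])
        return sorted(out)

    def type_of_slot(self, predicate: str, pos: int) -> str:
        return self._signatures[predicate][pos]

    # -- construction helpers -------------------------------------------

    def with_facts(self, facts: Iterable[Fact]) -> "KnowledgeBase":
        """A new KB with the same signatures/provenance, different facts."""
        return KnowledgeBase(
            facts, self._signatures, removed_selectors=self.removed_selectors
        )

    # -- serialization ---------------------------------------------------

    def serialize(self) -> str:
        """Round-trippable fact-dialect text (signature header + facts)."""
        lines = [
            f":- signature({p}, [{', '.join(sig)}])."
            for p, sig in sorted(self._signatures.items())
        ]
        lines.extend(f.to_clause() for f in sorted(self._facts))
        return "\n".join(lines) + "\n"

    def digest(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()

    def __repr__(self) -> str:
        return (
            f"KnowledgeBase({len(self._facts)} facts, "
            f"{len(self._signatures)} predicates)"
        )


# ---------------------------------------------------------------------------
# parsing


def parse_fact_file(text: str) -> KnowledgeBase:
    """Parse fact-dialect source into a :class:`KnowledgeBase`.

    Grammar (one item per line): ``predicate(arg1, ..., argN).`` clauses,
    ``% ...`` comments, blank lines, and optional signature headers
    ``:- signature(predicate, [type1, ..., typeN]).`` which declare the
    argument types mining modes rely on. Signatures of undeclared
    predicates are inferred on first occurrence with ``free`` types.

    Raises
    ------
    FactSyntaxError
        Malformed line, with its 1-based line number.
    KBError
        Arity conflict across lines, or invalid token.
    """
    signatures: dict[str, tuple[str, ...]] = {}
    facts: list[tuple[int, Fact]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        if line.startswith(":-"):
            m = _SIGNATURE_RE.match(line)
            if not m:
                raise FactSyntaxError(f"malformed directive {raw.strip()!r}", lineno)
            pred = m.group("pred")
            types = tuple(t.strip() for t in m.group("types").split(",") if t.strip())
            if not types:
                raise FactSyntaxError(f"empty signature for {pred!r}", lineno)
            for t in types:
                if not _TOKEN_RE.match(t):
                    raise FactSyntaxError(f"unknown type tag {t!r}", lineno)
            if pred in signatures and signatures[pred] != types:
                raise FactSyntaxError(
                    f"conflicting signature redeclaration for {pred!r}", lineno
                )
            signatures[pred] = types
            continue
        m = _CLAUSE_RE.match(line)
        if not m:
            raise FactSyntaxError(f"malformed clause {raw.strip()!r}", lineno)
        args = tuple(a.strip() for a in m.group("args").split(",") if a.strip())
        try:
            fact = Fact(m.group("pred"), args)
        except KBError as e:
            raise FactSyntaxError(str(e), lineno) from e
        facts.append((lineno, fact))

    # arity checks with line numbers before building the KB
    arities: dict[str, int] = {p: len(sig) for p, sig in signatures.items()}
    for lineno, fact in facts:
        seen = arities.get(fact.predicate)
        if seen is None:
            arities[fact.predicate] = fact.arity
        elif seen != fact.arity:
            raise FactSyntaxError(
                f"arity conflict for predicate {fact.predicate!r} "
                f"({fact.arity} here, {seen} before)",
                lineno,
            )
    return KnowledgeBase((f for _, f in facts), signatures)


def parse_fact_tsv(text: str) -> KnowledgeBase:
    """TSV alternative: columns ``predicate, arg1, ..., argN`` (no header)."""
    facts = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = [c.strip() for c in raw.split("\t") if c.strip()]
        if len(cols) < 2:
            raise FactSyntaxError("need predicate plus >= 1 argument", lineno)
        try:
            facts.append(Fact(cols[0], tuple(cols[1:])))
        except KBError as e:
            raise FactSyntaxError(str(e), lineno) from e
    return KnowledgeBase(facts)


def load_facts(path) -> KnowledgeBase:
    """Load ``.pl``/``.datalog`` dialect or ``.tsv`` facts from a path."""
    import pathlib

    p = pathlib.Path(path)
    text = p.read_text()
    if p.suffix == ".tsv":
        return parse_fact_tsv(text)
    return parse_fact_file(text)


# ---------------------------------------------------------------------------
# curation


@dataclass(frozen=True)
class CurationConfig:
    """What to drop before mining.

    Defaults: the reference strain background is S288c and the currency
    metabolites H+ and H2O are excluded from gene--metabolite relations.
    Empty sets disable the corresponding rule.
    """

    allowed_strain_background: str = "s288c"
    invalid_go_terms: frozenset[str] = frozenset()
    dose_dependent_phenotypes: frozenset[str] = frozenset()
    currency_metabolites: frozenset[str] = frozenset({"h_plus", "h2o"})


@dataclass(frozen=True)
class RemovalRecord:
    fact: Fact
    rule: str
    selector: str


@dataclass(frozen=True)
class CurationResult:
    kb: KnowledgeBase
    log: tuple[RemovalRecord, ...]

    def log_tsv(self) -> str:
        lines = ["fact\trule\tselector"]
        lines += [f"{r.fact.to_clause()}\t{r.rule}\t{r.selector}" for r in self.log]
        return "\n".join(lines) + "\n"


def apply_curation(kb: KnowledgeBase, cfg: CurationConfig) -> CurationResult:
    """Drop facts per the curation rules; log each removal with its rule.

    Rules, in order of precedence (the log records the first that fires):

    1. ``strain_background`` -- facts whose final argument slot is declared
       type ``strain`` and whose value differs from the allowed background.
       Facts without a strain slot are kept.
    2. ``invalid_go_term`` -- facts referencing a listed GO term.
    3. ``dose_dependent_phenotype`` -- facts referencing a listed phenotype
       (toxin resistance, resistance to chemicals, ...).
    4. ``currency_metabolite`` -- facts referencing a listed ubiquitous
       metabolite (H+, H2O by default).

    An empty config is the identity.
    """
    kept: list[Fact] = []
    log: list[RemovalRecord] = []
    for fact in sorted(kb.facts):
        sig = kb.signatures[fact.predicate]
        record = None
        if sig and sig[-1] == "strain" and fact.args[-1] != cfg.allowed_strain_background:
            record = RemovalRecord(fact, "strain_background", fact.args[-1])
        if record is None:
            for arg in fact.args:
                if arg in cfg.invalid_go_terms:
                    record = RemovalRecord(fact, "invalid_go_term", arg)
                    break
        if record is None:
            for arg in fact.args:
                if arg in cfg.dose_dependent_phenotypes:
                    record = RemovalRecord(fact, "dose_dependent_phenotype", arg)
                    break
        if record is None:
            for arg in fact.args:
                if arg in cfg.currency_metabolites:
                    record = RemovalRecord(fact, "currency_metabolite", arg)
                    break
        if record is None:
            kept.append(fact)
        else:
            log.append(record)
    return CurationResult(kb.with_facts(kept), tuple(log))


@dataclass(frozen=True)
class LeakageResult:
    kb: KnowledgeBase
    removed: tuple[Fact, ...]

    @property
    def removed_count(self) -> int:
        return len(self.removed)


def remove_target_derived_relations(
    kb: KnowledgeBase,
    selectors: Sequence[tuple[str, str | None]],
) -> LeakageResult:
    """Remove facts derived from the prediction targets before mining.

    Each selector is ``(predicate, constant_or_None)``: with ``None`` every
    fact of that predicate is removed, otherwise only facts of the
    predicate mentioning the constant. Selectors naming an unknown
    predicate warn and are recorded anyway (the guarantee is vacuous). The
    applied selectors are carried on the returned KB as provenance, which
    downstream stages use to verify that mining could not leak the target.
    """
    selectors = [(p, c) for p, c in selectors]
    for pred, _ in selectors:
        if pred not in kb.signatures:
            warnings.warn(
                f"leakage selector names unknown predicate {pred!r}", stacklevel=2
            )

    def hit(fact: Fact) -> bool:
        for pred, const in selectors:
            if fact.predicate != pred:
                continue
            if const is None or const in fact.args:
                return True
        return False

    removed = tuple(f for f in sorted(kb.facts) if hit(f))
    kept = [f for f in sorted(kb.facts) if not hit(f)]
    new_kb = KnowledgeBase(
        kept,
        kb.signatures,
        removed_selectors=kb.removed_selectors + tuple(selectors),
    )
    return LeakageResult(new_kb, removed)
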