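"""Shared fixtures: the TK1 toy knowledge base, worked patterns, random
small knowledge bases for oracle comparisons, and a brute-force grounding
oracle independent of the backtracking matcher."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import relmine as rm
from relmine import synth
from relmine.kb import Fact
from relmine.miner import MinerConstraints, ModeDeclaration
from relmine.pattern import Variable


@pytest.fixture(scope="session")
def tk1():
    kb, examples = synth.fixture_tk1()
    return kb, examples


@pytest.fixture(scope="session")
def tk1_modes():
    return synth.tk1_modes()


@pytest.fixture(scope="session")
def worked_patterns():
    """P1 (the worked three-literal pattern), P2 and P3."""
    P1 = rm.parse_pattern(
        "gene(A) :- regulated_by(A, B, transcription_factor), "
        "null_phenotype(B, abnormal_chronological_lifespan), "
        "involved_in(A, one_carbon_metabolic_process)"
    )
    P2 = rm.parse_pattern("gene(A) :- involved_in(A, one_carbon_metabolic_process)")
    P3 = rm.parse_pattern("gene(A) :- localizes_to(A, mitochondrion)")
    return P1, P2, P3


# random small instances for oracle comparisons (shared with the studies)
from relmine.studies import random_small_instance  # noqa: E402,F401


# ---------------------------------------------------------------------------
# grounding-enumeration oracle


def grounding_matches(p, example, kb) -> bool:
    """Coverage by exhaustive substitution enumeration over KB constants.

    Independent of the backtracking matcher: every assignment of the
    pattern's non-head variables to constants appearing anywhere in the
    KB is tried and each body literal checked against the fact set.
    """
    name = example.name if hasattr(example, "name") else example
    consts = sorted({a for f in kb.facts for a in f.args})
    free_vars = [v for v in p.variables() if v != "A"]
    facts = kb.facts
    for combo in itertools.product(consts, repeat=len(free_vars)):
        subst = dict(zip(free_vars, combo))
        subst["A"] = name
        ok = True
        for lit in p.body:
            ground = tuple(
                subst[a.name] if isinstance(a, Variable) else a.name
                for a in lit.args
            )
            if Fact(lit.predicate, ground) not in facts:
                ok = False
                break
        if ok:
            return True
    return False
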