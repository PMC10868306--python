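"""Refinement operator, levelwise search, oracle equivalence, cap and leakage."""

import warnings

import numpy as np
import pytest

import relmine as rm
from relmine.kb import remove_target_derived_relations
from relmine.miner import (
    InstanceTooLarge,
    MinerConstraints,
    ModeDeclaration,
    PatternSet,
    brute_force_mine,
    mine,
    refinements,
)
from relmine.pattern import Pattern

from conftest import random_small_instance


class TestModeDeclarations:
    def test_parse(self):
        m = ModeDeclaration.parse("regulated_by(+gene, -tf, #reg_type)")
        assert m.predicate == "regulated_by"
        assert [s.kind for s in m.slots] == ["+", "-", "#"]
        assert [s.type for s in m.slots] == ["gene", "tf", "reg_type"]

    def test_requires_input_slot(self):
        with pytest.raises(ValueError, match=r"\+ slot"):
            ModeDeclaration.parse("involved_in(#gene, #go_term)")

    def test_explicit_constants(self):
        m = ModeDeclaration.parse(
            "involved_in(+gene, #go_term)", constants={1: ["go1", "go2"]}
        )
        assert m.slots[1].constants == ("go1", "go2")


class TestConstraints:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_support_fraction": 0.0},
            {"min_support_fraction": 1.5},
            {"max_features": 0},
            {"max_clause_length": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            MinerConstraints(**kwargs)

    def test_defaults_match_documented_bounds(self):
        c = MinerConstraints()
        assert (c.min_support_fraction, c.max_features) == (0.00025, 2048)
        assert (c.max_clause_length, c.max_var_layers) == (10, 10)


class TestRefinements:
    def test_from_empty_pattern(self, tk1, tk1_modes):
        kb, _ = tk1
        c = MinerConstraints(0.1, 2048, 3, 10)
        out = refinements(Pattern(()), tk1_modes, kb, c)
        canons = {p.canonical for p in out}
        assert "gene(A):-involved_in(A,one_carbon_metabolic_process)" in canons
        assert "gene(A):-regulated_by(A,B,transcription_factor)" in canons
        assert all(len(p) == 1 for p in out)
        # modes x constants of the fixture: 2 go + 1 compartment + 1 reg
        # chain + 2 phenotypes
        assert len(out) == 6

    def test_length_grows_by_one(self, tk1, tk1_modes):
        kb, _ = tk1
        c = MinerConstraints(0.1, 2048, 3, 10)
        for p in refinements(Pattern(()), tk1_modes, kb, c):
            for q in refinements(p, tk1_modes, kb, c):
                assert len(q) == len(p) + 1

    def test_clause_length_bound(self, tk1, tk1_modes):
        kb, _ = tk1
        c = MinerConstraints(0.1, 2048, 1, 10)
        p = refinements(Pattern(()), tk1_modes, kb, c)[0]
        assert refinements(p, tk1_modes, kb, c) == []

    def test_layer_bound_prunes_variable_chains(self, tk1):
        kb, _ = tk1
        bias = [ModeDeclaration.parse("regulated_by(+any, -tf, #reg_type)")]
        shallow = MinerConstraints(0.01, 2048, 3, 1)
        p = refinements(Pattern(()), bias, kb, shallow)[0]
        assert all(
            q.max_layer <= 1 for q in refinements(p, bias, kb, shallow)
        )


class TestMineFixture:
    def test_three_patterns_of_support_two(self, tk1, tk1_modes):
        kb, examples = tk1
        ps = mine(kb, examples, tk1_modes, MinerConstraints(0.6, 2048, 1, 10))
        assert ps.canonical_supports() == {
            "gene(A):-involved_in(A,one_carbon_metabolic_process)": 2,
            "gene(A):-localizes_to(A,mitochondrion)": 2,
            "gene(A):-regulated_by(A,B,transcription_factor)": 2,
        }
        assert ps.ids == ["ilp1", "ilp2", "ilp3"]

    def test_full_support_threshold_gives_empty_set(self, tk1, tk1_modes):
        kb, examples = tk1
        with pytest.warns(UserWarning, match="no pattern"):
            ps = mine(kb, examples, tk1_modes, MinerConstraints(1.0, 2048, 1, 10))
        assert len(ps) == 0

    def test_invariant_to_fact_order(self, tk1, tk1_modes):
        kb, examples = tk1
        c = MinerConstraints(0.3, 2048, 2, 10)
        ps1 = mine(kb, examples, tk1_modes, c)
        shuffled = rm.KnowledgeBase(
            sorted(kb.facts, key=lambda f: hash(f)), kb.signatures
        )
        ps2 = mine(shuffled, examples, tk1_modes, c)
        assert [p.canonical for p in ps1.patterns] == [
            p.canonical for p in ps2.patterns
        ]

    def test_provenance_records_inputs(self, tk1, tk1_modes):
        kb, examples = tk1
        ps = mine(kb, examples, tk1_modes, MinerConstraints(0.6, 2048, 1, 10))
        assert ps.provenance["kb_digest"] == kb.digest()
        assert ps.provenance["n_examples"] == 3
        assert not ps.provenance["target_derived_removed"]


class TestOracleEquivalence:
    def test_mine_equals_brute_force_on_fixture(self, tk1, tk1_modes):
        kb, examples = tk1
        c = MinerConstraints(0.6, 2048, 1, 10)
        assert (
            mine(kb, examples, tk1_modes, c).canonical_supports()
            == brute_force_mine(kb, examples, tk1_modes, c).canonical_supports()
        )

    def test_mine_equals_brute_force_on_random_kbs(self):
        for seed in range(25):
            kb, examples, bias, c = random_small_instance(seed)
            got = mine(kb, examples, bias, c).canonical_supports()
            want = brute_force_mine(kb, examples, bias, c).canonical_supports()
            assert got == want, f"seed {seed}"

    def test_brute_force_guard(self, tk1, tk1_modes):
        kb, examples = tk1
        with pytest.raises(InstanceTooLarge):
            brute_force_mine(kb, examples, tk1_modes, MinerConstraints(0.5, 10, 4, 10))

    def test_empty_kb_empty_result(self):
        kb = rm.KnowledgeBase(
            [], {"involved_in": ("gene", "go_term")}
        )
        bias = [ModeDeclaration.parse("involved_in(+gene, #go_term)")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = MinerConstraints(0.5, 16, 2, 10)
            assert len(brute_force_mine(kb, ["g1"], bias, c)) == 0

    def test_raising_support_never_grows_output(self, tk1, tk1_modes):
        kb, examples = tk1
        low = brute_force_mine(kb, examples, tk1_modes, MinerConstraints(0.3, 2048, 2, 10))
        high = brute_force_mine(kb, examples, tk1_modes, MinerConstraints(0.6, 2048, 2, 10))
        assert set(high.canonical_supports()) <= set(low.canonical_supports())


class TestCapAndOrder:
    def test_cap_prefix_of_uncapped_discovery_order(self):
        for seed in (1, 5):
            kb, examples, bias, c = random_small_instance(seed, max_len=2)
            full = mine(kb, examples, bias, c)
            if len(full) < 4:
                continue
            k = len(full) // 2
            capped = mine(
                kb, examples, bias,
                MinerConstraints(
                    c.min_support_fraction, k, c.max_clause_length, c.max_var_layers
                ),
            )
            assert len(capped) == k
            assert [p.canonical for p in capped.patterns] == [
                p.canonical for p in full.patterns[:k]
            ]

    def test_discovery_order_is_generality_first(self, tk1, tk1_modes):
        kb, examples = tk1
        ps = mine(kb, examples, tk1_modes, MinerConstraints(0.3, 2048, 2, 10))
        lengths = [len(p) for p in ps.patterns]
        assert lengths == sorted(lengths)
        # within a level, support is non-increasing
        for level in set(lengths):
            sups = [cov.support for p, cov in ps if len(p) == level]
            assert sups == sorted(sups, reverse=True)

    def test_drop_coverage_duplicates_flag(self, tk1, tk1_modes):
        kb, examples = tk1
        c = MinerConstraints(0.3, 2048, 2, 10, drop_coverage_duplicates=True)
        ps = mine(kb, examples, tk1_modes, c)
        keys = [cov.key() for _, cov in ps]
        assert len(keys) == len(set(keys))


class TestLeakage:
    def test_removed_predicate_never_mined(self):
        for seed in range(8):
            kb, examples, bias, c = random_small_instance(seed, max_len=2)
            res = remove_target_derived_relations(kb, [("null_phenotype", None)])
            ps = mine(res.kb, examples, bias, c)
            assert not any(p.mentions("null_phenotype") for p in ps.patterns)
            assert ps.provenance["target_derived_removed"]

    def test_removed_constant_combination_never_mined(self, tk1, tk1_modes):
        kb, examples = tk1
        res = remove_target_derived_relations(
            kb, [("involved_in", "one_carbon_metabolic_process")]
        )
        ps = mine(res.kb, examples, tk1_modes, MinerConstraints(0.3, 2048, 2, 10))
        assert not any(
            p.mentions("involved_in", "one_carbon_metabolic_process")
            for p in ps.patterns
        )


class TestPatternSetIO:
    def test_json_roundtrip(self, tk1, tk1_modes):
        kb, examples = tk1
        ps = mine(kb, examples, tk1_modes, MinerConstraints(0.3, 2048, 2, 10))
        again = PatternSet.from_json(ps.to_json())
        assert again.canonical_supports() == ps.canonical_supports()
        assert again.examples == ps.examples
        for (p1, c1), (p2, c2) in zip(ps, again):
            assert np.array_equal(c1.bits, c2.bits)
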