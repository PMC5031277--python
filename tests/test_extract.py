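"""Module extraction: closure rules, provenance, verification, materialize."""

import numpy as np
import pytest

from ontoshape import (
    ArgumentError,
    ValidationError,
    ancestors,
    extract_module,
    materialize_module,
    verify_module,
)

from conftest import build_graph, oracle_extract, random_graph


class TestAncestors:
    def test_chain(self, toy1):
        assert ancestors(toy1, "A2") == {"A1", "A", "R"}

    def test_root_has_none(self, toy1):
        assert ancestors(toy1, "R") == set()

    def test_diamond_counts_both_branches_once(self):
        g = build_graph(
            "R",
            {
                "R": ((), ()),
                "A": (("R",), ()),
                "L": (("A",), ()),
                "M": (("A",), ()),
                "D": (("L", "M"), ()),
            },
        )
        assert ancestors(g, "D") == {"L", "M", "A", "R"}

    def test_unknown_id(self, toy1):
        with pytest.raises(ArgumentError):
            ancestors(toy1, "zzz")


class TestExtract:
    def test_toy_closure_excludes_unreferenced_sibling(self, toy1):
        m = extract_module(toy1, {"A2"}, "all")
        assert m.classes == {"R", "A", "A1", "A2", "B", "B1", "B2"}
        assert "B3" not in m.classes

    def test_provenance_rule_priority(self, toy1):
        m = extract_module(toy1, {"A2"}, "all")
        assert m.provenance["A2"] == "seed"
        assert m.provenance["B2"] == "reference"
        for cid in ("R", "A", "A1", "B", "B1"):
            assert m.provenance[cid] == "ancestor"

    def test_seeding_root_gives_singleton(self, toy1):
        for policy in ("all", "seeds_and_references"):
            m = extract_module(toy1, {"R"}, policy)
            assert m.classes == {"R"}

    def test_reference_pulls_its_full_ancestor_chain(self):
        # seed 10 (one hierarchy) references 17 (another); 16, 15, 9 are 17's
        # ancestors and must all come along so 17 keeps its paths to the root
        g = build_graph(
            "root",
            {
                "root": ((), ()),
                "cf": (("root",), ()),
                "10": (("cf",), ("17",)),
                "bs": (("root",), ()),
                "9": (("bs",), ()),
                "15": (("9",), ()),
                "16": (("15",), ()),
                "17": (("16",), ()),
            },
        )
        m = extract_module(g, {"10"}, "all")
        assert {"17", "16", "15", "9"} <= m.classes
        assert m.provenance["17"] == "reference"
        assert m.provenance["16"] == "ancestor"

    def test_policies_differ_on_ancestor_references(self):
        # A1 enters only as an ancestor; its reference B3 is followed under
        # "all" but not under "seeds_and_references"
        g = build_graph(
            "R",
            {
                "R": ((), ()),
                "A": (("R",), ()),
                "A1": (("A",), ("B3",)),
                "A2": (("A1",), ()),
                "B": (("R",), ()),
                "B3": (("B",), ()),
            },
        )
        full = extract_module(g, {"A2"}, "all")
        lean = extract_module(g, {"A2"}, "seeds_and_references")
        assert "B3" in full.classes
        assert "B3" not in lean.classes
        assert not verify_module(g, full).errors
        codes = [c for c, _, _ in verify_module(g, lean).errors]
        assert "missing-reference" in codes

    def test_unknown_seed_listed(self, toy1):
        with pytest.raises(ArgumentError, match="zzz"):
            extract_module(toy1, {"A2", "zzz"}, "all")

    def test_empty_seed_set_rejected(self, toy1):
        with pytest.raises(ArgumentError):
            extract_module(toy1, set(), "all")

    @pytest.mark.parametrize("policy", ["all", "seeds_and_references"])
    def test_matches_brute_force_oracle(self, policy):
        rng = np.random.default_rng(13)
        for _ in range(25):
            g = random_graph(rng, max_classes=300)
            ids = sorted(set(g.classes) - {g.root})
            seeds = set(rng.choice(ids, size=rng.integers(1, 12), replace=False))
            got = extract_module(g, seeds, policy).classes
            assert got == oracle_extract(g, seeds, policy)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            g = random_graph(rng, max_classes=250)
            ids = sorted(set(g.classes) - {g.root})
            small = set(rng.choice(ids, size=rng.integers(1, 6), replace=False))
            big = small | set(rng.choice(ids, size=rng.integers(1, 6), replace=False))
            m_small = extract_module(g, small, "all").classes
            m_big = extract_module(g, big, "all").classes
            assert m_small <= m_big
            assert extract_module(g, m_small, "all").classes == m_small


class TestVerify:
    def test_partial_module_reports_missing(self, toy1):
        from ontoshape import ModuleResult

        bad = ModuleResult(frozenset({"R", "A2"}), {"R": "ancestor", "A2": "seed"})
        report = verify_module(toy1, bad)
        by_code = {code: msg for code, _, msg in report.errors}
        assert "A1" in by_code["missing-ancestor"]
        assert "A," in by_code["missing-ancestor"] or by_code["missing-ancestor"].endswith("A")
        assert "B2" in by_code["missing-reference"]

    def test_empty_module_is_vacuously_clean(self, toy1):
        from ontoshape import ModuleResult

        assert verify_module(toy1, ModuleResult(frozenset(), {})).ok

    def test_extracted_modules_always_verify(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            g = random_graph(rng, max_classes=250)
            ids = sorted(set(g.classes) - {g.root})
            seeds = set(rng.choice(ids, size=5, replace=False))
            m = extract_module(g, seeds, "all")
            assert verify_module(g, m).ok


class TestMaterialize:
    def test_round_trips_as_standalone_ontology(self, toy1, tmp_path):
        from ontoshape import load_ontology, write_ontology

        m = extract_module(toy1, {"A2"}, "all")
        sub = materialize_module(toy1, m)
        assert len(sub) == 7
        p = tmp_path / "module.json"
        write_ontology(sub, p)
        assert len(load_ontology(p)) == 7

    def test_root_only_module(self, toy1):
        m = extract_module(toy1, {"R"}, "all")
        assert len(materialize_module(toy1, m)) == 1

    def test_unverified_module_refused(self, toy1):
        from ontoshape import ModuleResult

        bad = ModuleResult(frozenset({"R", "A2"}), {"A2": "seed", "R": "ancestor"})
        with pytest.raises(ValidationError):
            materialize_module(toy1, bad)

    def test_empty_module_refused(self, toy1):
        from ontoshape import ModuleResult

        with pytest.raises(ArgumentError):
            materialize_module(toy1, ModuleResult(frozenset(), {}))
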