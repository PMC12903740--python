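import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symred.pathways import (
    PathwayDefinition, ReactionSlot, apply_host_imports, builtin_pathways,
    read_pathway_definition, score_pathway, supplementation_flag,
)


def defn(n_slots, markers=()):
    return PathwayDefinition(
        "pw", tuple(ReactionSlot(f"s{i}", (f"e{i}",)) for i in range(n_slots)),
        tuple(markers))


class TestScore:
    def test_all_slots_satisfied_present(self):
        d = defn(12)
        score = score_pathway(d, {f"e{i}": True for i in range(12)}, "G")
        assert score.fraction == 1.0 and score.state == "present"

    def test_no_slot_satisfied_without_substrate_absent(self):
        d = defn(12)
        presence = {f"e{i}": False for i in range(12)}
        score = score_pathway(d, presence, "G", has_initial_substrate=False)
        assert score.fraction == 0.0 and score.state == "absent"
        # with the substrate around, an empty pathway is merely partial
        assert score_pathway(d, presence, "G").state == "partial"

    def test_fraction_rounded_to_three_decimals(self):
        d = defn(12)
        presence = {f"e{i}": i < 8 for i in range(12)}
        score = score_pathway(d, presence, "G")
        assert score.fraction == 0.667 and score.state == "partial"

    def test_alternative_enzymes_have_or_semantics(self):
        d = PathwayDefinition("pw", (ReactionSlot("s0", ("e0", "e0b")),))
        assert score_pathway(d, {"e0": False, "e0b": True}).fraction == 1.0

    def test_bypass_satisfies_missing_slot(self):
        d = PathwayDefinition("pw", (
            ReactionSlot("s0", ("e0",)),
            ReactionSlot("s1", ("e1",)),
            ReactionSlot("s2", ("e2",), bypassable_by=("s0", "s1")),
        ))
        presence = {"e0": True, "e1": True, "e2": False}
        assert score_pathway(d, presence).fraction == 1.0
        presence["e1"] = False
        assert score_pathway(d, presence).fraction == round(1 / 3, 3)

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(KeyError):
            score_pathway(defn(2), {"e0": True})

    def test_brute_force_equivalence_on_random_definitions(self):
        """Fraction equals direct slot enumeration on randomized small
        definitions with alternatives and bypasses."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            slots = []
            for i in range(n):
                alts = tuple(f"e{i}_{j}" for j in range(rng.integers(1, 4)))
                bypass = ()
                if i >= 2 and rng.random() < 0.3:
                    bypass = tuple(f"s{j}" for j in
                                   rng.choice(i, rng.integers(1, 3), replace=False))
                slots.append(ReactionSlot(f"s{i}", alts, bypass))
            d = PathwayDefinition("pw", tuple(slots))
            presence = {e: bool(rng.random() < 0.6) for e in d.enzymes}
            got = score_pathway(d, presence).fraction

            # independent enumeration: fixpoint over explicit slot states
            state = {s.slot_id: any(presence[e] for e in s.alternatives)
                     for s in slots}
            for _ in range(n):
                for s in slots:
                    if s.bypassable_by and all(state[b] for b in s.bypassable_by):
                        state[s.slot_id] = True
            expected = round(sum(state.values()) / n, 3)
            assert got == expected

    @given(st.integers(2, 8), st.data())
    @settings(max_examples=60, deadline=None)
    def test_adding_enzymes_never_decreases_fraction(self, n, data):
        d = defn(n)
        presence = {f"e{i}": data.draw(st.booleans()) for i in range(n)}
        base = score_pathway(d, presence).fraction
        added = dict(presence)
        added[f"e{data.draw(st.integers(0, n - 1))}"] = True
        assert score_pathway(d, added).fraction >= base


class TestImports:
    D = PathwayDefinition("pw", tuple(
        ReactionSlot(f"s{i}", (f"e{i}",)) for i in range(4)))

    def test_single_hole_filled_completely(self):
        presence = {"e0": True, "e1": True, "e2": True, "e3": False}
        score = score_pathway(self.D, presence, "G")
        rescored = apply_host_imports(score, self.D, presence, {"e3": True})
        assert rescored.fraction == 1.0
        assert rescored.holes_filled_by_import == "all"

    def test_partial_fill_is_some(self):
        presence = {"e0": True, "e1": False, "e2": False, "e3": False}
        score = score_pathway(self.D, presence, "G")
        rescored = apply_host_imports(score, self.D, presence, {"e3": True})
        assert rescored.holes_filled_by_import == "some"

    def test_disjoint_imports_change_nothing(self):
        presence = {"e0": True, "e1": True, "e2": False, "e3": False}
        score = score_pathway(self.D, presence, "G")
        rescored = apply_host_imports(score, self.D, presence, {"zz": True})
        assert rescored.fraction == score.fraction
        assert rescored.holes_filled_by_import == "none"

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            presence = {f"e{i}": bool(rng.random() < 0.5) for i in range(4)}
            imports = {f"e{i}": bool(rng.random() < 0.5) for i in range(4)}
            score = score_pathway(self.D, presence, "G")
            once = apply_host_imports(score, self.D, presence, imports)
            merged = {e: presence[e] or imports.get(e, False) for e in presence}
            twice = apply_host_imports(once, self.D, merged, imports)
            assert twice.fraction == once.fraction


class TestSupplementation:
    def test_marker_presence_sets_flag(self):
        d = defn(2, markers=("gapN",))
        assert supplementation_flag(d, {"e0": True, "e1": True, "gapN": True})

    def test_no_markers_declared_false(self):
        assert not supplementation_flag(defn(2), {"e0": True, "e1": True})

    def test_flag_orthogonal_to_fraction(self):
        d = defn(2, markers=("gapN",))
        presence = {"e0": False, "e1": False, "gapN": True}
        score = score_pathway(d, presence, "G")
        assert score.fraction == 0.0 and score.supplemented


class TestDefinitionFiles:
    def test_parse_slots_alternatives_bypass_markers(self, tmp_path):
        path = tmp_path / "pw.txt"
        path.write_text("@pathway demo\n@supplement mx\n"
                        "s0: e0a, e0b\n"
                        "s1: e1\n"
                        "s2: e2 | bypass: s0, s1\n")
        d = read_pathway_definition(path)
        assert d.pathway_id == "demo"
        assert d.supplement_markers == ("mx",)
        assert d.slots[0].alternatives == ("e0a", "e0b")
        assert d.slots[2].bypassable_by == ("s0", "s1")

    def test_builtin_pathways_load_and_are_wellformed(self):
        defs = builtin_pathways()
        assert len(defs) == 10
        ids = {d.pathway_id for d in defs}
        assert {"glycolysis", "tca", "chlorophyll"} <= ids
        glyc = next(d for d in defs if d.pathway_id == "glycolysis")
        assert "gapN" in glyc.supplement_markers
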