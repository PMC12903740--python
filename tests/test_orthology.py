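import numpy as np
import pytest

from symred.genome_io import HitRecord, ProteinRecord, Proteome
from symred.orthology import (
    SearchParams, ThresholdPolicy, bbh_orthologs, best_hits, common_orthologs,
    internal_search, search_and_pair, OrthologTables,
)


def hit(q, s, bits, ev, qg="A", sg="B"):
    return HitRecord(q, s, qg, sg, 50.0, 100, ev, bits)


def proteome(genome, **seqs):
    return Proteome(genome, [ProteinRecord(pid, genome, seq)
                             for pid, seq in seqs.items()])


class TestBestHits:
    def test_highest_bitscore_wins(self):
        result = best_hits([hit("q1", "s1", 50, 1e-20),
                            hit("q1", "s2", 60, 1e-20)], "A", "B")
        assert result["q1"].hit.subject_id == "s2"

    def test_bitscore_tie_broken_by_evalue(self):
        result = best_hits([hit("q1", "s1", 60, 1e-20),
                            hit("q1", "s2", 60, 1e-30)], "A", "B")
        assert result["q1"].hit.subject_id == "s2"
        assert not result["q1"].ambiguous

    def test_full_tie_broken_lexicographically_and_flagged(self):
        result = best_hits([hit("q1", "s2", 60, 1e-20),
                            hit("q1", "s1", 60, 1e-20)], "A", "B")
        assert result["q1"].hit.subject_id == "s1"
        assert result["q1"].ambiguous

    def test_empty_input_empty_map(self):
        assert best_hits([], "A", "B") == {}

    def test_foreign_genome_rejected(self):
        with pytest.raises(ValueError):
            best_hits([hit("q1", "s1", 50, 1e-20, qg="C")], "A", "B")


class TestBBH:
    POLICY = ThresholdPolicy()

    def make_proteomes(self, len_a=150, len_b=200):
        return {"A": proteome("A", a="M" * len_a),
                "B": proteome("B", b="M" * len_b)}

    def test_mutual_best_large_proteins_included(self):
        table = bbh_orthologs([hit("a", "b", 300, 1e-50)],
                              [hit("b", "a", 290, 1e-40, qg="B", sg="A")],
                              self.POLICY, self.make_proteomes(), "A", "B")
        assert table.pair_set() == {("A", "a", "B", "b")}
        pair = next(iter(table))
        assert pair.evalue == 1e-40  # worse of the two directions
        assert not pair.relaxed_threshold_used

    def test_strict_threshold_excludes_weak_large_pair(self):
        table = bbh_orthologs([hit("a", "b", 40, 1e-5)],
                              [hit("b", "a", 40, 1e-6, qg="B", sg="A")],
                              self.POLICY, self.make_proteomes(150, 200),
                              "A", "B")
        assert len(table) == 0

    def test_relaxed_threshold_admits_small_protein_pair(self):
        table = bbh_orthologs([hit("a", "b", 40, 1e-5)],
                              [hit("b", "a", 40, 1e-6, qg="B", sg="A")],
                              self.POLICY, self.make_proteomes(80, 200),
                              "A", "B")
        assert len(table) == 1
        assert next(iter(table)).relaxed_threshold_used

    def test_query_only_scope_ignores_small_subject(self):
        policy = ThresholdPolicy(relaxation_scope="query_only")
        table = bbh_orthologs([hit("a", "b", 40, 1e-5)],
                              [hit("b", "a", 40, 1e-6, qg="B", sg="A")],
                              policy, self.make_proteomes(150, 80), "A", "B")
        assert len(table) == 0

    def test_non_reciprocal_pair_rejected(self):
        proteomes = {"A": proteome("A", a="M" * 150),
                     "B": proteome("B", b="M" * 150, c="M" * 150)}
        table = bbh_orthologs(
            [hit("a", "b", 100, 1e-50)],
            [hit("b", "c", 120, 1e-60, qg="B", sg="A"),
             hit("b", "a", 100, 1e-50, qg="B", sg="A")],
            self.POLICY, proteomes, "A", "B")
        # b's best is c, not a -> no pair even though a's best is b
        assert len(table) == 0

    def test_protein_missing_from_proteome_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            bbh_orthologs([hit("ghost", "b", 300, 1e-50)],
                          [hit("b", "ghost", 300, 1e-50, qg="B", sg="A")],
                          self.POLICY, self.make_proteomes(), "A", "B")

    def test_tightening_strict_threshold_never_adds_pairs(self):
        rng = np.random.default_rng(5)
        hits_ab, hits_ba, seqs_a, seqs_b = [], [], {}, {}
        for i in range(12):
            ev = 10.0 ** (-rng.integers(3, 40))
            seqs_a[f"a{i}"] = "M" * int(rng.integers(50, 300))
            seqs_b[f"b{i}"] = "M" * int(rng.integers(50, 300))
            hits_ab.append(hit(f"a{i}", f"b{i}", 100, ev))
            hits_ba.append(hit(f"b{i}", f"a{i}", 100, ev, qg="B", sg="A"))
        proteomes = {"A": proteome("A", **seqs_a), "B": proteome("B", **seqs_b)}
        previous = None
        for strict in (1e-5, 1e-10, 1e-20, 1e-30):
            policy = ThresholdPolicy(strict_evalue=strict)
            pairs = bbh_orthologs(hits_ab, hits_ba, policy, proteomes,
                                  "A", "B").pair_set()
            if previous is not None:
                assert pairs <= previous
            previous = pairs


class TestCommonOrthologs:
    def test_core_requires_every_panel_genome(self, small_bundle):
        truth = small_bundle.truth
        ref = truth.reference_relative
        from symred.pipeline import all_pairwise_tables
        genomes = [ref] + truth.endosymbionts[:2]
        tables = all_pairwise_tables(small_bundle.proteomes, genomes)
        core = common_orthologs(ref, truth.endosymbionts[:2], tables,
                                small_bundle.proteomes[ref])
        # stem-lost families have no endosymbiont orthologs at all
        lost = {truth.families[f][ref] for f in truth.planted_stem_losses}
        assert core.isdisjoint(lost)
        present_everywhere = {
            m[ref] for m in truth.families.values()
            if ref in m and all(g in m for g in truth.endosymbionts[:2])
        }
        assert core == present_everywhere

    def test_empty_panel_returns_all_reference_proteins(self):
        ref = proteome("R", p1="M" * 100, p2="K" * 100)
        assert common_orthologs("R", [], OrthologTables(), ref) == {"p1", "p2"}

    def test_missing_table_names_pair(self):
        ref = proteome("R", p1="M" * 100)
        with pytest.raises(KeyError, match="'X'"):
            common_orthologs("R", ["X"], OrthologTables(), ref)


class TestInternalSearch:
    def test_identical_sequences_give_certain_top_hit(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        a = proteome("A", p1=seq)
        b = proteome("B", q1=seq)
        hits = internal_search(a, b)
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].evalue < 1e-10

    def test_no_shared_seed_no_hit(self):
        a = proteome("A", p1="WWWWWWWWWW")
        b = proteome("B", q1="HHHHHHHHHH")
        assert internal_search(a, b) == []

    def test_empty_proteome_rejected(self):
        a = proteome("A", p1="MKVLL")
        with pytest.raises(Exception):
            internal_search(a, Proteome("B", []))

    def test_reversed_roles_yield_transposed_bbh(self):
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = {f"p{i}": "".join(rng.choice(aa, 120)) for i in range(6)}
        mutated = {}
        for i, (pid, seq) in enumerate(seqs.items()):
            chars = list(seq)
            for j in rng.choice(len(chars), 12, replace=False):
                chars[j] = aa[(aa.index(chars[j]) + 1) % 20]
            mutated[f"q{i}"] = "".join(chars)
        a = proteome("A", **seqs)
        b = proteome("B", **mutated)
        t_ab = search_and_pair(a, b)
        t_ba = search_and_pair(b, a)
        assert t_ab.pair_set() == {(ga, pa, gb, pb) for (gb, pb, ga, pa)
                                   in t_ba.pair_set()}
        assert len(t_ab) == 6
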