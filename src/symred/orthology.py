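"""Reciprocal-best-hit orthology under length-aware E-value thresholds.

The operational ortholog definition used throughout the package: proteins
A (genome X) and B (genome Y) are orthologs when A's best hit in Y is B,
B's best hit in X is A, and the worse of the two directional E-values
passes the applicable cutoff — 1e-10 by default, relaxed to 1e-3 when a
partner is shorter than 100 residues (small proteins rarely achieve
strong E-values even when genuinely homologous).

Hit evidence may come from external 12-column hit tables or from
:func:`internal_search`, a deterministic seeded local-alignment search
(k-mer seeding, Smith-Waterman extension under BLOSUM62 with affine
11/1 gaps, and a simplified Karlin-Altschul E-value
``E = m * n * 2**(-bitscore)``). A faster edit-distance scorer is
available for large synthetic panels where substitution-only divergence
makes full Smith-Waterman unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from symred.genome_io import HitRecord, Proteome

STRICT_EVALUE = 1e-10
RELAXED_EVALUE = 1e-3
SMALL_PROTEIN_CUTOFF = 100


@dataclass(frozen=True)
class ThresholdPolicy:
    """E-value acceptance policy for reciprocal best hits.

    ``relaxation_scope`` decides whose length triggers the relaxed
    threshold: ``either_partner`` (default) relaxes when either protein is
    below the cutoff, ``query_only`` when only the query is.
    """

    strict_evalue: float = STRICT_EVALUE
    relaxed_evalue: float = RELAXED_EVALUE
    small_protein_cutoff: int = SMALL_PROTEIN_CUTOFF
    relaxation_scope: Literal["either_partner", "query_only"] = "either_partner"

    def __post_init__(self) -> None:
        if self.relaxed_evalue <= self.strict_evalue:
            raise ValueError("relaxed_evalue must exceed strict_evalue")
        if self.small_protein_cutoff <= 0:
            raise ValueError("small_protein_cutoff must be positive")

    def applicable_evalue(self, len_a: int, len_b: int) -> float:
        if self.relaxation_scope == "either_partner":
            relaxed = min(len_a, len_b) < self.small_protein_cutoff
        else:
            relaxed = len_a < self.small_protein_cutoff
        return self.relaxed_evalue if relaxed else self.strict_evalue


@dataclass(frozen=True)
class OrthologPair:
    genome_a: str
    protein_a: str
    genome_b: str
    protein_b: str
    evalue: float  # worse (larger) of the two directional E-values
    bitscore: float  # smaller of the two directional bitscores
    relaxed_threshold_used: bool = False
    ambiguous: bool = False

    def transpose(self) -> "OrthologPair":
        return OrthologPair(self.genome_b, self.protein_b, self.genome_a,
                            self.protein_a, self.evalue, self.bitscore,
                            self.relaxed_threshold_used, self.ambiguous)


class OrthologTable:
    """One-to-one ortholog mapping between a fixed pair of genomes."""

    def __init__(self, genome_a: str, genome_b: str,
                 pairs: Iterable[OrthologPair] = ()):
        self.genome_a = genome_a
        self.genome_b = genome_b
        self._a_to_b: dict[str, OrthologPair] = {}
        self._b_to_a: dict[str, OrthologPair] = {}
        for pair in pairs:
            self.add(pair)

    def add(self, pair: OrthologPair) -> None:
        if (pair.genome_a, pair.genome_b) == (self.genome_b, self.genome_a):
            pair = pair.transpose()
        elif (pair.genome_a, pair.genome_b) != (self.genome_a, self.genome_b):
            raise ValueError("pair does not belong to this genome pair")
        if pair.protein_a in self._a_to_b or pair.protein_b in self._b_to_a:
            raise ValueError(
                f"one-to-one violation: {pair.protein_a!r}/{pair.protein_b!r}"
            )
        self._a_to_b[pair.protein_a] = pair
        self._b_to_a[pair.protein_b] = pair

    def __len__(self) -> int:
        return len(self._a_to_b)

    def __iter__(self):
        return iter(self._a_to_b.values())

    def partner_of(self, genome: str, protein_id: str) -> str | None:
        """Ortholog of ``protein_id`` (from ``genome``) in the other genome."""
        if genome == self.genome_a:
            pair = self._a_to_b.get(protein_id)
            return pair.protein_b if pair else None
        if genome == self.genome_b:
            pair = self._b_to_a.get(protein_id)
            return pair.protein_a if pair else None
        raise KeyError(f"genome {genome!r} not in table "
                       f"({self.genome_a!r}, {self.genome_b!r})")

    def pair_for(self, genome: str, protein_id: str) -> OrthologPair | None:
        if genome == self.genome_a:
            return self._a_to_b.get(protein_id)
        if genome == self.genome_b:
            return self._b_to_a.get(protein_id)
        raise KeyError(genome)

    def pair_set(self) -> set[tuple[str, str, str, str]]:
        return {(p.genome_a, p.protein_a, p.genome_b, p.protein_b)
                for p in self._a_to_b.values()}

    def transpose(self) -> "OrthologTable":
        return OrthologTable(self.genome_b, self.genome_a,
                             (p.transpose() for p in self))


class OrthologTables:
    """Collection of pairwise tables, symmetric under genome-pair order."""

    def __init__(self, tables: Iterable[OrthologTable] = ()):
        self._tables: dict[frozenset[str], OrthologTable] = {}
        for t in tables:
            self.add(t)

    def add(self, table: OrthologTable) -> None:
        self._tables[frozenset((table.genome_a, table.genome_b))] = table

    def get(self, genome_a: str, genome_b: str) -> OrthologTable:
        key = frozenset((genome_a, genome_b))
        if key not in self._tables:
            raise KeyError(f"no ortholog table for pair ({genome_a!r}, {genome_b!r})")
        return self._tables[key]

    def has(self, genome_a: str, genome_b: str) -> bool:
        return frozenset((genome_a, genome_b)) in self._tables

    def partner_of(self, genome: str, protein_id: str, other_genome: str) -> str | None:
        return self.get(genome, other_genome).partner_of(genome, protein_id)

    def __iter__(self):
        return iter(self._tables.values())


@dataclass(frozen=True)
class BestHit:
    hit: HitRecord
    ambiguous: bool = False


def best_hits(hits: Sequence[HitRecord], query_genome: str,
              subject_genome: str) -> dict[str, BestHit]:
    """Best hit per query: max bitscore, then min E-value, then smallest
    subject id; queries whose winner was decided lexicographically are
    flagged ambiguous."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.query_genome != query_genome or h.subject_genome != subject_genome:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} does not match genome pair "
                f"({query_genome!r}, {subject_genome!r})"
            )
        by_query.setdefault(h.query_id, []).append(h)

    result: dict[str, BestHit] = {}
    for query_id, candidates in by_query.items():
        ranked = sorted(candidates,
                        key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        best = ranked[0]
        ambiguous = (
            len(ranked) > 1
            and ranked[1].bitscore == best.bitscore
            and ranked[1].evalue == best.evalue
        )
        result[query_id] = BestHit(best, ambiguous)
    return result


def bbh_orthologs(hits_ab: Sequence[HitRecord], hits_ba: Sequence[HitRecord],
                  policy: ThresholdPolicy,
                  proteomes: Mapping[str, Proteome],
                  genome_a: str | None = None,
                  genome_b: str | None = None) -> OrthologTable:
    """Reciprocal-best-hit orthologs between two genomes.

    A pair (a, b) is accepted when a's best hit is b, b's best hit is a,
    and the worse of the two directional E-values passes the policy's
    applicable threshold given both protein lengths.
    """
    if genome_a is None or genome_b is None:
        if hits_ab:
            genome_a, genome_b = hits_ab[0].query_genome, hits_ab[0].subject_genome
        elif hits_ba:
            genome_a, genome_b = hits_ba[0].subject_genome, hits_ba[0].query_genome
        else:
            raise ValueError("genome ids required when both hit lists are empty")

    best_ab = best_hits(hits_ab, genome_a, genome_b)
    best_ba = best_hits(hits_ba, genome_b, genome_a)

    table = OrthologTable(genome_a, genome_b)
    for protein_a, fwd in sorted(best_ab.items()):
        protein_b = fwd.hit.subject_id
        rev = best_ba.get(protein_b)
        if rev is None or rev.hit.subject_id != protein_a:
            continue
        for genome, pid in ((genome_a, protein_a), (genome_b, protein_b)):
            if pid not in proteomes[genome]:
                raise KeyError(
                    f"protein {pid!r} from hits absent from proteome {genome!r}"
                )
        len_a = proteomes[genome_a].length_of(protein_a)
        len_b = proteomes[genome_b].length_of(protein_b)
        worse_evalue = max(fwd.hit.evalue, rev.hit.evalue)
        threshold = policy.applicable_evalue(len_a, len_b)
        if worse_evalue >= threshold:
            continue
        table.add(OrthologPair(
            genome_a, protein_a, genome_b, protein_b,
            evalue=worse_evalue,
            bitscore=min(fwd.hit.bitscore, rev.hit.bitscore),
            relaxed_threshold_used=threshold == policy.relaxed_evalue,
            ambiguous=fwd.ambiguous or rev.ambiguous,
        ))
    return table


def common_orthologs(reference_genome: str, panel: Sequence[str],
                     tables: OrthologTables,
                     reference_proteome: Proteome) -> set[str]:
    """Reference proteins with an ortholog pair in every panel genome.

    An empty panel is a vacuous conjunction: every reference protein
    qualifies.
    """
    core = set(reference_proteome.ids())
    for genome in panel:
        if not tables.has(reference_genome, genome):
            raise KeyError(
                f"no ortholog table for pair ({reference_genome!r}, {genome!r})"
            )
        table = tables.get(reference_genome, genome)
        core &= {pid for pid in core
                 if table.partner_of(reference_genome, pid) is not None}
    return core


# ---------------------------------------------------------------------------
# Built-in deterministic search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Parameters of the built-in seeded local-alignment search.

    ``scorer='smith_waterman'`` performs BLOSUM62 Smith-Waterman extension
    with affine gap penalties (open 11, extend 1); bitscore is the raw
    alignment score and ``E = m * n * 2**(-bitscore)`` with m the query
    length and n the summed subject length. ``scorer='edit'`` replaces the
    extension with a global edit-distance alignment (bitscore = 2 x matches)
    — much faster, adequate for substitution-only divergence, and used by
    the synthetic-clade pipeline at scale. Because a global edit alignment
    against any comparable-length subject scores proportionally to length,
    the edit scorer additionally requires ``edit_min_identity`` percent
    identity (over the longer sequence) for a hit to be reported: unrelated
    pairs sit well below this floor, genuine orthologs at the divergences
    the scorer targets sit well above it.
    """

    seed_k: int = 3
    min_seed_score: int = 11  # BLOSUM62 self-score a seed word must reach
    gap_open: int = 11
    gap_extend: int = 1
    scorer: Literal["smith_waterman", "edit"] = "smith_waterman"
    max_candidates: int = 50  # subjects with most shared seeds, per query
    edit_min_identity: float = 30.0  # %, edit scorer only
    #: optional shorter seed for queries below the small-protein cutoff,
    #: matched against subjects short enough to clear the identity floor;
    #: long seeds otherwise miss genuinely homologous short proteins
    small_seed_k: int | None = None
    small_query_cutoff: int = 100
    small_subject_limit: int = 200


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    return aligner


_SELF_SCORE: dict[str, float] = {
    aa: float(_BLOSUM62[aa, aa]) for aa in _BLOSUM62.alphabet
}


def _kmer_self_score(kmer: str) -> float:
    return sum(_SELF_SCORE.get(c, 0.0) for c in kmer)


def _kmer_index(proteome: Proteome, k: int,
                max_len: int | None = None) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for rec in proteome:
        if max_len is not None and rec.length >= max_len:
            continue
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(rec.protein_id)
    return index


@dataclass
class SeedIndexes:
    """Precomputed k-mer indexes of a subject proteome."""

    full: dict[str, set[str]]
    small: dict[str, set[str]] | None = None


def build_seed_indexes(proteome: Proteome, params: SearchParams) -> SeedIndexes:
    small = None
    if params.small_seed_k is not None:
        small = _kmer_index(proteome, params.small_seed_k,
                            params.small_subject_limit)
    return SeedIndexes(_kmer_index(proteome, params.seed_k), small)


def _alignment_identity(alignment) -> tuple[float, int]:
    """Percent identity and column count of a Bio.Align alignment."""
    counts = alignment.counts()
    ncols = alignment.length
    return (100.0 * counts.identities / ncols if ncols else 0.0), ncols


def internal_search(proteome_a: Proteome, proteome_b: Proteome,
                    params: SearchParams = SearchParams(),
                    subject_index: SeedIndexes | None = None
                    ) -> list[HitRecord]:
    """Deterministic all-vs-all search of proteome A against proteome B.

    Candidate subjects share at least one exact k-mer (with BLOSUM62
    self-score >= ``min_seed_score``) with the query; each candidate pair
    is then scored by the configured scorer. Queries below
    ``small_query_cutoff`` use the shorter ``small_seed_k`` seed when one
    is configured. Deterministic for fixed inputs and parameters.
    ``subject_index`` may carry precomputed :func:`build_seed_indexes`
    output for proteome B to amortize repeated searches.
    """
    if len(proteome_a) == 0 or len(proteome_b) == 0:
        raise ValueError("internal_search requires non-empty proteomes")

    total_subject_len = sum(rec.length for rec in proteome_b)
    indexes = subject_index if subject_index is not None \
        else build_seed_indexes(proteome_b, params)
    seed_ok: dict[str, bool] = {}

    hits: list[HitRecord] = []
    sw_aligner = (_make_aligner(params, "local")
                  if params.scorer == "smith_waterman" else None)

    for query in proteome_a:
        seq = query.sequence
        use_small = (indexes.small is not None
                     and query.length < params.small_query_cutoff)
        k = params.small_seed_k if use_small else params.seed_k
        index = indexes.small if use_small else indexes.full
        candidate_counts: dict[str, int] = {}
        seen_kmers = set()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if kmer in seen_kmers:
                continue
            seen_kmers.add(kmer)
            ok = seed_ok.get(kmer)
            if ok is None:
                ok = _kmer_self_score(kmer) >= params.min_seed_score
                seed_ok[kmer] = ok
            if not ok:
                continue
            for sid in index.get(kmer, ()):
                candidate_counts[sid] = candidate_counts.get(sid, 0) + 1
        candidates = sorted(candidate_counts,
                            key=lambda sid: (-candidate_counts[sid], sid))
        candidates = candidates[:params.max_candidates]

        for sid in sorted(candidates):
            subject = proteome_b[sid]
            if params.scorer == "smith_waterman":
                alignments = sw_aligner.align(seq, subject.sequence)
                score = alignments.score
                if score <= 0:
                    continue
                pct_id, ncols = _alignment_identity(alignments[0])
                bitscore = float(score)
            else:
                res = edlib.align(seq, subject.sequence, mode="NW", task="distance")
                maxlen = max(len(seq), subject.length)
                matches = maxlen - res["editDistance"]
                if matches <= 0:
                    continue
                bitscore = 2.0 * matches
                pct_id = 100.0 * matches / maxlen
                ncols = maxlen
                if pct_id < params.edit_min_identity:
                    continue
            evalue = len(seq) * total_subject_len * 2.0 ** (-bitscore)
            hits.append(HitRecord(
                query_id=query.protein_id, subject_id=sid,
                query_genome=proteome_a.genome_id,
                subject_genome=proteome_b.genome_id,
                percent_identity=round(pct_id, 2), aln_length=ncols,
                evalue=evalue, bitscore=bitscore,
            ))
    return hits


def search_and_pair(proteome_a: Proteome, proteome_b: Proteome,
                    policy: ThresholdPolicy = ThresholdPolicy(),
                    params: SearchParams = SearchParams()) -> OrthologTable:
    """Convenience: run the built-in search both ways and take BBH pairs."""
    hits_ab = internal_search(proteome_a, proteome_b, params)
    hits_ba = internal_search(proteome_b, proteome_a, params)
    return bbh_orthologs(hits_ab, hits_ba, policy,
                         {proteome_a.genome_id: proteome_a,
                          proteome_b.genome_id: proteome_b},
                         proteome_a.genome_id, proteome_b.genome_id)


def write_ortholog_table(table: OrthologTable, path) -> None:
    """TSV: genomeA, proteinA, genomeB, proteinB, evalue, bitscore, relaxed, ambiguous."""
    with open(path, "w") as out:
        for p in sorted(table, key=lambda p: p.protein_a):
            out.write("\t".join([
                p.genome_a, p.protein_a, p.genome_b, p.protein_b,
                f"{p.evalue:.3g}", f"{p.bitscore:.1f}",
                str(int(p.relaxed_threshold_used)), str(int(p.ambiguous)),
            ]) + "\n")


def read_ortholog_table(path) -> OrthologTable:
    pairs = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            ga, pa, gb, pb, ev, bs, relaxed, amb = line.rstrip("\n").split("\t")
            pairs.append(OrthologPair(ga, pa, gb, pb, float(ev), float(bs),
                                      bool(int(relaxed)), bool(int(amb))))
    if not pairs:
        raise ValueError(f"empty ortholog table {path}")
    return OrthologTable(pairs[0].genome_a, pairs[0].genome_b, pairs)
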