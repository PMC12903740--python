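"""Protein-set algebra and gene density for a reduced-genome panel.

Named sets follow the comparative design of the endosymbiont study:

* **core** — proteins conserved across all free-living close relatives
  of the endosymbionts (a proxy for the ancestral repertoire), anchored
  on a designated reference relative;
* **All-RE** — proteins present in every endosymbiont genome, evaluated
  through a pivot endosymbiont's proteins having orthologs in all the
  others;
* **No-RE** — reference-relative proteins with no ortholog in any
  endosymbiont (candidate losses under symbiosis);
* **unique** — proteins with no ortholog in any other panel genome;
* **small** — proteins shorter than 100 residues (the unique sets of
  reduced genomes are typically dominated by these).

Gene density — the fraction of a replicon entity's nucleotides covered
by coding and non-coding genes, overlaps counted once — serves as a
proxy for how thoroughly pseudogene debris has been purged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from symred.genome_io import GeneFeature, GenomeAnnotation, Proteome
from symred.orthology import OrthologTables

SMALL_CUTOFF = 100

#: Four-way partition used for stacked per-genome counts.
PARTITION_CATEGORIES = ("core_present", "conserved_noncore",
                        "nonconserved_shared", "unique")


@dataclass(frozen=True)
class PanelDesign:
    """Which genome plays which role in the comparative design."""

    endosymbiont_genomes: tuple[str, ...]
    free_living_relatives: tuple[str, ...]
    reference_relative: str
    outgroup_genomes: tuple[str, ...] = ()
    pivot_endosymbiont: str | None = None  # default: first endosymbiont

    def __post_init__(self) -> None:
        groups = [set(self.endosymbiont_genomes), set(self.free_living_relatives),
                  set(self.outgroup_genomes)]
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                if a & b:
                    raise ValueError(f"panel groups overlap: {sorted(a & b)}")
        if self.reference_relative not in self.free_living_relatives:
            raise ValueError("reference_relative must be a free-living relative")
        if (self.pivot_endosymbiont is not None
                and self.pivot_endosymbiont not in self.endosymbiont_genomes):
            raise ValueError("pivot_endosymbiont must be an endosymbiont")

    @property
    def pivot(self) -> str:
        return self.pivot_endosymbiont or self.endosymbiont_genomes[0]

    @property
    def all_genomes(self) -> tuple[str, ...]:
        return (self.endosymbiont_genomes + self.free_living_relatives
                + self.outgroup_genomes)


@dataclass(frozen=True)
class ProteinFlags:
    core: bool
    all_re: bool
    no_re: bool
    unique: bool
    small: bool

    @property
    def category(self) -> str:
        if self.unique:
            return "unique"
        if self.core:
            return "core_present"
        if self.all_re:
            return "conserved_noncore"
        return "nonconserved_shared"


class SetClassification:
    """Per-protein flags for every protein of every panel genome."""

    def __init__(self, panel: PanelDesign,
                 flags: Mapping[tuple[str, str], ProteinFlags]):
        self.panel = panel
        self._flags = dict(flags)

    def flags(self, genome_id: str, protein_id: str) -> ProteinFlags:
        return self._flags[(genome_id, protein_id)]

    def proteins_of(self, genome_id: str) -> list[str]:
        return [pid for (gid, pid) in self._flags if gid == genome_id]

    def members(self, genome_id: str, *, core: bool | None = None,
                all_re: bool | None = None, no_re: bool | None = None,
                unique: bool | None = None, small: bool | None = None) -> set[str]:
        """Proteins of a genome matching every non-None flag constraint."""
        wanted = {"core": core, "all_re": all_re, "no_re": no_re,
                  "unique": unique, "small": small}
        out = set()
        for (gid, pid), fl in self._flags.items():
            if gid != genome_id:
                continue
            if all(v is None or getattr(fl, k) == v for k, v in wanted.items()):
                out.add(pid)
        return out

    def category_counts(self, genome_id: str) -> dict[str, int]:
        counts = {cat: 0 for cat in PARTITION_CATEGORIES}
        for (gid, pid), fl in self._flags.items():
            if gid == genome_id:
                counts[fl.category] += 1
        return counts

    def counts_table(self) -> pd.DataFrame:
        """Per-genome stacked category counts (rows: genomes, cols: categories)."""
        rows = {g: self.category_counts(g) for g in self.panel.all_genomes}
        df = pd.DataFrame.from_dict(rows, orient="index")[list(PARTITION_CATEGORIES)]
        df["total"] = df.sum(axis=1)
        df.index.name = "genome"
        return df


def classify(panel: PanelDesign, tables: OrthologTables,
             proteomes: Mapping[str, Proteome],
             include_ambiguous: bool = True) -> SetClassification:
    """Assign core / All-RE / No-RE / unique / small flags to every protein.

    ``include_ambiguous=False`` ignores ortholog pairs that carry the
    duplicate-gene ambiguity flag when testing presence.
    """
    for genome in panel.all_genomes:
        if genome not in proteomes:
            raise KeyError(f"panel genome {genome!r} has no proteome")

    ref = panel.reference_relative
    pivot = panel.pivot
    endos = panel.endosymbiont_genomes

    def partner(genome: str, pid: str, other: str) -> str | None:
        pair = tables.get(genome, other).pair_for(genome, pid)
        if pair is None:
            return None
        if not include_ambiguous and pair.ambiguous:
            return None
        return pair.protein_b if pair.genome_a == genome else pair.protein_a

    other_relatives = [g for g in panel.free_living_relatives if g != ref]
    core_ref: set[str] = {
        pid for pid in proteomes[ref].ids()
        if all(partner(ref, pid, g) is not None for g in other_relatives)
    }
    all_re_pivot: set[str] = {
        pid for pid in proteomes[pivot].ids()
        if all(partner(pivot, pid, g) is not None for g in endos if g != pivot)
    }

    flags: dict[tuple[str, str], ProteinFlags] = {}
    for genome in panel.all_genomes:
        others = [g for g in panel.all_genomes if g != genome]
        for pid in proteomes[genome].ids():
            if genome == ref:
                is_core = pid in core_ref
            else:
                ref_partner = partner(genome, pid, ref)
                is_core = ref_partner is not None and ref_partner in core_ref
            if genome == pivot:
                is_all_re = pid in all_re_pivot
            else:
                pivot_partner = partner(genome, pid, pivot)
                is_all_re = (pivot_partner is not None
                             and pivot_partner in all_re_pivot)
            is_no_re = (genome == ref
                        and all(partner(ref, pid, e) is None for e in endos))
            is_unique = all(partner(genome, pid, g) is None for g in others)
            flags[(genome, pid)] = ProteinFlags(
                core=is_core, all_re=is_all_re, no_re=is_no_re,
                unique=is_unique,
                small=proteomes[genome].length_of(pid) < SMALL_CUTOFF,
            )
    return SetClassification(panel, flags)


def intersect_report(proteins: Iterable[str],
                     category_map: Mapping[str, str]) -> pd.DataFrame:
    """Counts per functional category for a protein set.

    Uncategorized proteins fall into "Others"; rows are alphabetical with
    "Others" last, plus a final "Total" row.
    """
    counts: dict[str, int] = {}
    total = 0
    for pid in proteins:
        cat = category_map.get(pid, "Others")
        counts[cat] = counts.get(cat, 0) + 1
        total += 1
    named = sorted(c for c in counts if c != "Others")
    rows = [(c, counts[c]) for c in named]
    if "Others" in counts:
        rows.append(("Others", counts["Others"]))
    rows.append(("Total", total))
    return pd.DataFrame(rows, columns=["category", "count"])


def small_protein_summary(cls: SetClassification,
                          proteomes: Mapping[str, Proteome],
                          cutoff: int = SMALL_CUTOFF) -> dict[str, float]:
    """Per-genome fraction of unique proteins shorter than ``cutoff``.

    Genomes with no unique proteins are omitted (the fraction is
    undefined there).
    """
    out: dict[str, float] = {}
    for genome in cls.panel.all_genomes:
        uniq = cls.members(genome, unique=True)
        if not uniq:
            continue
        n_small = sum(1 for pid in uniq
                      if proteomes[genome].length_of(pid) < cutoff)
        out[genome] = n_small / len(uniq)
    return out


# ---------------------------------------------------------------------------
# Gene density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityEntry:
    genome_id: str
    entity: str  # chromosome | plasmids_pooled | unresolved
    gene_nt: int
    entity_nt: int

    @property
    def density(self) -> float:
        return self.gene_nt / self.entity_nt


@dataclass
class DensityReport:
    entries: list[DensityEntry] = field(default_factory=list)

    def entry(self, genome_id: str, entity: str) -> DensityEntry:
        for e in self.entries:
            if e.genome_id == genome_id and e.entity == entity:
                return e
        raise KeyError((genome_id, entity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.genome_id, e.entity, e.gene_nt, e.entity_nt, e.density)
             for e in self.entries],
            columns=["genome", "entity", "gene_nt", "entity_nt", "density"],
        )


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals.

    The single site converting to half-open coordinates for the sweep.
    """
    spans = sorted((s, e + 1) for s, e in intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in spans:
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def gene_density(ann: GenomeAnnotation,
                 count_pseudogenes: bool = False) -> DensityReport:
    """Gene density per entity: union of qualifying feature spans over
    entity length.

    Qualifying features are coding and non-coding genes; pseudogene spans
    are excluded unless ``count_pseudogenes`` is set (density is read as a
    proxy for pseudogene purging, so broken genes do not count as genes by
    default). Strand is ignored: a nucleotide covered on either strand
    counts once. Plasmids are pooled into one entity.
    """
    qualifying = {"coding_gene", "noncoding_gene"}
    if count_pseudogenes:
        qualifying = qualifying | {"pseudogene"}

    entity_of = {r.replicon_id: (
        "plasmids_pooled" if r.replicon_class == "plasmid"
        else ("unresolved" if r.replicon_class == "unresolved" else "chromosome"))
        for r in ann.replicons}

    entity_nt: dict[str, int] = {}
    for rep in ann.replicons:
        ent = entity_of[rep.replicon_id]
        entity_nt[ent] = entity_nt.get(ent, 0) + rep.length_nt

    by_replicon: dict[str, list[GeneFeature]] = {}
    for feat in ann.features:
        if feat.kind in qualifying:
            by_replicon.setdefault(feat.replicon_id, []).append(feat)

    gene_nt: dict[str, int] = {ent: 0 for ent in entity_nt}
    for replicon_id, feats in by_replicon.items():
        ent = entity_of[replicon_id]
        gene_nt[ent] += _union_length((f.start, f.end) for f in feats)

    report = DensityReport()
    for ent in sorted(entity_nt):
        report.entries.append(DensityEntry(ann.genome_id, ent,
                                           gene_nt[ent], entity_nt[ent]))
    return report
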