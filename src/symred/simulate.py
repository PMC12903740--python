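"""Synthetic clade generator with recorded ground truth.

Emulates the statistical structure of a young endosymbiotic clade: six
"endosymbiont" genomes nested inside a panel of free-living relatives
and an outgroup, with

* planted ortholog families evolved along a fixed tree by i.i.d.
  substitutions (no indels, no rate matrix — enough for reciprocal-best
  -hit and distance-tree recovery, and it keeps closed forms simple:
  the expected proportion of changed sites on a path of length d is
  about 1 − e^(−d));
* a block of families deleted on the endosymbiont stem (the planted
  "lost under symbiosis" set), plus rare per-lineage losses on the
  endosymbiont leaf branches;
* per-genome invented small proteins (the unique, sub-100-residue bias
  typical of reduced genomes with inconsistent gene calling);
* pseudogene-inflated intergenic DNA: a configurable fraction of lost
  genes leave their spans behind as pseudogene features, depressing
  gene density;
* habitat labels and pathway enzyme-presence calls with planted holes.

Every emitted file is derivable from the :class:`CladeTruth` record, and
the whole bundle is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from symred.genome_io import (
    GeneFeature, GenomeAnnotation, HabitatRecord, ProteinRecord, Proteome,
    Replicon, write_annotation, write_habitat_table, write_proteome,
)
from symred.pathways import PathwayDefinition, builtin_pathways
from symred.phylogeny import TreeNode

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
N_AA = 20


@dataclass(frozen=True)
class CladeConfig:
    """Study conditions for the synthetic clade.

    Defaults model a young clade: six endosymbionts, two free-living
    relatives (the first is the reference relative), one outgroup;
    1,500 families present everywhere plus 200 deleted on the
    endosymbiont stem; 0.05 expected substitutions/site per branch
    (orthologs remain ~75-90% identical, as expected a few tens of
    millions of years after acquisition); about 120 invented unique
    proteins per endosymbiont, 90% of them under 100 residues; 30% of
    lost genes linger as pseudogenes.
    """

    n_endosymbionts: int = 6
    n_relatives: int = 2
    n_outgroups: int = 1
    n_universal_families: int = 1500
    n_re_lost_families: int = 200
    divergence_per_branch: float = 0.05
    per_endosymbiont_loss_rate: float = 0.01
    invented_per_endosymbiont: int = 120
    invented_small_fraction: float = 0.9
    small_length_range: tuple[int, int] = (30, 99)
    invented_large_range: tuple[int, int] = (100, 250)
    ancestor_small_fraction: float = 0.15
    ancestor_length_range: tuple[int, int] = (150, 600)
    pseudogene_fraction: float = 0.3
    intergenic_spacer: int = 150
    n_plasmid_bearers: int = 4
    n_plasmid_genes: int = 5
    noncoding_gene_lengths: tuple[int, ...] = (2900, 1500, 120)

    def __post_init__(self) -> None:
        for rate in (self.per_endosymbiont_loss_rate, self.pseudogene_fraction,
                     self.invented_small_fraction, self.ancestor_small_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.divergence_per_branch < 0:
            raise ValueError("divergence_per_branch must be >= 0")
        if self.n_endosymbionts < 2 or self.n_relatives < 2 or self.n_outgroups < 1:
            raise ValueError("need >=2 endosymbionts, >=2 relatives, >=1 outgroup")
        if self.n_plasmid_bearers > self.n_endosymbionts - 1:
            raise ValueError("pivot endosymbiont must stay plasmid-free")

    @property
    def endosymbionts(self) -> list[str]:
        return [f"EN{i + 1}" for i in range(self.n_endosymbionts)]

    @property
    def relatives(self) -> list[str]:
        return [f"REL{i + 1}" for i in range(self.n_relatives)]

    @property
    def outgroups(self) -> list[str]:
        return [f"OUT{i + 1}" for i in range(self.n_outgroups)]

    @property
    def taxa(self) -> list[str]:
        return self.endosymbionts + self.relatives + self.outgroups


@dataclass
class CladeTruth:
    """Ground truth recorded during generation."""

    config: dict
    tree_newick: str
    endosymbionts: list[str]
    relatives: list[str]
    reference_relative: str
    outgroups: list[str]
    pivot_endosymbiont: str
    #: family_id -> genome -> protein_id (absent genomes omitted)
    families: dict[str, dict[str, str]]
    planted_stem_losses: list[str]
    lineage_losses: dict[str, list[str]]
    invented: dict[str, list[str]]
    pseudogenes: dict[str, list[str]]
    #: genome -> entity -> {gene_nt, gene_nt_with_pseudo, entity_nt}
    density: dict[str, dict[str, dict[str, int]]]
    habitat: dict[str, list[str]]
    #: genome -> enzyme -> bool
    pathway_presence: dict[str, dict[str, bool]]
    #: genome -> pathway -> expected completeness fraction
    pathway_expected: dict[str, dict[str, float]]

    # -- derived expectations ------------------------------------------------

    def family_present(self, family_id: str, genome: str) -> bool:
        return genome in self.families[family_id]

    def expected_core(self) -> set[str]:
        """Reference-relative proteins conserved across the other relatives."""
        ref = self.reference_relative
        others = [g for g in self.relatives if g != ref]
        return {
            members[ref]
            for members in self.families.values()
            if ref in members and all(g in members for g in others)
        }

    def expected_no_re(self) -> set[str]:
        ref = self.reference_relative
        return {
            members[ref]
            for members in self.families.values()
            if ref in members
            and not any(g in members for g in self.endosymbionts)
        }

    def expected_all_re(self) -> set[str]:
        """Pivot-endosymbiont proteins whose family spans every endosymbiont."""
        pivot = self.pivot_endosymbiont
        return {
            members[pivot]
            for members in self.families.values()
            if all(g in members for g in self.endosymbionts)
        }

    def expected_unique(self, genome: str) -> set[str]:
        singles = {
            members[genome]
            for members in self.families.values()
            if list(members) == [genome]
        }
        return singles | set(self.invented.get(genome, []))

    def expected_ortholog_pairs(self, genome_a: str, genome_b: str
                                ) -> set[tuple[str, str]]:
        return {
            (members[genome_a], members[genome_b])
            for members in self.families.values()
            if genome_a in members and genome_b in members
        }

    def expected_density(self, genome: str, entity: str,
                         count_pseudogenes: bool = False) -> float:
        rec = self.density[genome][entity]
        num = rec["gene_nt_with_pseudo"] if count_pseudogenes else rec["gene_nt"]
        return num / rec["entity_nt"]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "CladeTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


@dataclass
class CladeBundle:
    """In-memory result of one simulation."""

    config: CladeConfig
    truth: CladeTruth
    proteomes: dict[str, Proteome]
    annotations: dict[str, GenomeAnnotation]
    habitats: dict[str, HabitatRecord]
    pathway_definitions: list[PathwayDefinition]
    tree: TreeNode


def _planted_topology(config: CladeConfig, bl: float) -> TreeNode:
    """Fixed ladderized topology: endosymbiont clade + relative clade +
    outgroup(s) meeting at the (unrooted) root trifurcation."""

    def leaf(name: str) -> TreeNode:
        return TreeNode(name=name, branch_length=bl)

    def cherry_ladder(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return leaf(names[0])
        if len(names) == 2:
            return TreeNode(children=[leaf(names[0]), leaf(names[1])],
                            branch_length=bl)
        mid = 2
        left = cherry_ladder(names[:mid])
        right = cherry_ladder(names[mid:])
        return TreeNode(children=[left, right], branch_length=bl)

    endo = cherry_ladder(config.endosymbionts)
    rel = cherry_ladder(config.relatives)
    children = [endo, rel] + [leaf(o) for o in config.outgroups]
    return TreeNode(children=children)


def _random_lengths(rng: np.random.Generator, n: int,
                    small_fraction: float, small_range: tuple[int, int],
                    large_range: tuple[int, int]) -> np.ndarray:
    small = rng.random(n) < small_fraction
    lows = np.where(small, small_range[0], large_range[0])
    highs = np.where(small, small_range[1], large_range[1])
    return rng.integers(lows, highs + 1)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, N_AA, size=length).astype(np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float
            ) -> np.ndarray:
    """i.i.d. substitution: each site changes with probability 1 - e^(-d),
    uniformly to one of the 19 alternative residues."""
    p = 1.0 - np.exp(-divergence)
    mask = rng.random(seq.size) < p
    out = seq.copy()
    if mask.any():
        shifts = rng.integers(1, N_AA, size=int(mask.sum()))
        out[mask] = (out[mask] + shifts) % N_AA
    return out


def _decode(seq: np.ndarray) -> str:
    return AMINO_ACIDS[seq].tobytes().decode()


def simulate_clade(config: CladeConfig = CladeConfig(),
                   seed: int = 0) -> CladeBundle:
    """Generate the full clade in memory; pure function of (config, seed)."""
    rng = np.random.default_rng(seed)
    tree = _planted_topology(config, config.divergence_per_branch)

    endos, relatives, outgroups = (config.endosymbionts, config.relatives,
                                   config.outgroups)
    ref, pivot = relatives[0], endos[0]
    plasmid_bearers = endos[config.n_endosymbionts - config.n_plasmid_bearers:]

    universal_ids = [f"F{i:04d}" for i in range(config.n_universal_families)]
    lost_ids = [f"R{i:04d}" for i in range(config.n_re_lost_families)]
    plasmid_ids = [f"P{i:04d}" for i in range(config.n_plasmid_genes)]
    all_family_ids = universal_ids + lost_ids + plasmid_ids

    # ancestor sequences, concatenated for vectorized evolution
    lengths = {}
    for fid in universal_ids + lost_ids:
        n = _random_lengths(rng, 1, config.ancestor_small_fraction,
                            config.small_length_range,
                            config.ancestor_length_range)[0]
        lengths[fid] = int(n)
    for fid in plasmid_ids:
        lengths[fid] = int(rng.integers(80, 251))
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for fid in all_family_ids:
        offsets[fid] = (pos, pos + lengths[fid])
        pos += lengths[fid]
    ancestor = _random_sequence(rng, pos)

    # evolve along the tree (preorder, deterministic traversal)
    leaf_seqs: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _mutate(rng, seq, child.branch_length)
            if child.is_leaf:
                leaf_seqs[child.name] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree, ancestor)

    # losses
    lineage_losses: dict[str, list[str]] = {g: [] for g in config.taxa}
    for genome in endos:
        lost_mask = rng.random(len(universal_ids)) < config.per_endosymbiont_loss_rate
        lineage_losses[genome] = [fid for fid, m in zip(universal_ids, lost_mask) if m]

    def present(fid: str, genome: str) -> bool:
        if fid in lost_ids:
            return genome not in endos
        if fid in plasmid_ids:
            return genome in plasmid_bearers
        return fid not in lineage_losses[genome]

    # invented unique proteins (endosymbionts only)
    invented: dict[str, list[str]] = {g: [] for g in config.taxa}
    invented_seqs: dict[str, dict[str, np.ndarray]] = {g: {} for g in config.taxa}
    for genome in endos:
        n = config.invented_per_endosymbiont
        inv_lengths = _random_lengths(rng, n, config.invented_small_fraction,
                                      config.small_length_range,
                                      config.invented_large_range)
        for i, length in enumerate(inv_lengths):
            pid = f"{genome}_U{i:04d}"
            invented[genome].append(pid)
            invented_seqs[genome][pid] = _random_sequence(rng, int(length))

    # pseudogene retention of lost loci (decays independently per lineage)
    pseudogenes: dict[str, list[str]] = {g: [] for g in config.taxa}
    for genome in endos:
        lost_here = [fid for fid in lost_ids + lineage_losses[genome]
                     if not present(fid, genome)]
        keep = rng.random(len(lost_here)) < config.pseudogene_fraction
        pseudogenes[genome] = [fid for fid, k in zip(sorted(lost_here), keep) if k]

    # assemble proteomes, annotations, density bookkeeping
    families: dict[str, dict[str, str]] = {fid: {} for fid in all_family_ids}
    proteomes: dict[str, Proteome] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    density: dict[str, dict[str, dict[str, int]]] = {}

    for genome in config.taxa:
        records: list[ProteinRecord] = []
        chrom_feats: list[GeneFeature] = []
        cursor = config.intergenic_spacer + 1
        gene_nt = 0
        pseudo_nt = 0
        pseudo_set = set(pseudogenes[genome])

        for fid in universal_ids + lost_ids:
            span = 3 * lengths[fid] + 3
            if present(fid, genome):
                pid = f"{genome}_{fid}"
                start, end = offsets[fid]
                records.append(ProteinRecord(pid, genome,
                                             _decode(leaf_seqs[genome][start:end])))
                families[fid][genome] = pid
                chrom_feats.append(GeneFeature(pid, "chr", cursor,
                                               cursor + span - 1, "+", "coding_gene"))
                gene_nt += span
                cursor += span + config.intergenic_spacer
            elif fid in pseudo_set:
                chrom_feats.append(GeneFeature(f"{genome}_{fid}_ps", "chr", cursor,
                                               cursor + span - 1, "+", "pseudogene"))
                pseudo_nt += span
                cursor += span + config.intergenic_spacer

        for pid in invented[genome]:
            seq = invented_seqs[genome][pid]
            records.append(ProteinRecord(pid, genome, _decode(seq)))
            span = 3 * seq.size + 3
            chrom_feats.append(GeneFeature(pid, "chr", cursor,
                                           cursor + span - 1, "+", "coding_gene"))
            gene_nt += span
            cursor += span + config.intergenic_spacer

        for i, span in enumerate(config.noncoding_gene_lengths):
            chrom_feats.append(GeneFeature(f"{genome}_nc{i}", "chr", cursor,
                                           cursor + span - 1, "+", "noncoding_gene"))
            gene_nt += span
            cursor += span + config.intergenic_spacer

        chrom_len = cursor - 1
        replicons = [Replicon("chr", chrom_len, "chromosome")]
        density[genome] = {"chromosome": {
            "gene_nt": gene_nt, "gene_nt_with_pseudo": gene_nt + pseudo_nt,
            "entity_nt": chrom_len,
        }}

        plasmid_feats: list[GeneFeature] = []
        if genome in plasmid_bearers:
            pcursor = config.intergenic_spacer + 1
            p_gene_nt = 0
            for fid in plasmid_ids:
                pid = f"{genome}_{fid}"
                start, end = offsets[fid]
                records.append(ProteinRecord(pid, genome,
                                             _decode(leaf_seqs[genome][start:end])))
                families[fid][genome] = pid
                span = 3 * lengths[fid] + 3
                plasmid_feats.append(GeneFeature(pid, "pls", pcursor,
                                                 pcursor + span - 1, "+",
                                                 "coding_gene"))
                p_gene_nt += span
                pcursor += span + config.intergenic_spacer
            plasmid_len = pcursor - 1
            replicons.append(Replicon("pls", plasmid_len, "plasmid"))
            density[genome]["plasmids_pooled"] = {
                "gene_nt": p_gene_nt, "gene_nt_with_pseudo": p_gene_nt,
                "entity_nt": plasmid_len,
            }

        proteomes[genome] = Proteome(genome, records)
        annotations[genome] = GenomeAnnotation(genome, replicons,
                                               chrom_feats + plasmid_feats)

    # habitats: most endosymbiont hosts are freshwater, one is marine;
    # relatives freshwater/paddy; outgroup(s) marine
    habitat: dict[str, list[str]] = {}
    for i, genome in enumerate(endos):
        habitat[genome] = ["marine"] if i == len(endos) - 1 else ["freshwater"]
    habitat[relatives[0]] = ["paddy"]
    for genome in relatives[1:]:
        habitat[genome] = ["freshwater"]
    for genome in outgroups:
        habitat[genome] = ["marine"]
    habitats = {g: HabitatRecord(g, frozenset(labels))
                for g, labels in habitat.items()}

    # pathway presence with planted holes in endosymbionts
    definitions = builtin_pathways()
    seen_pathway: dict[str, set[str]] = {}
    for defn in definitions:
        for slot in defn.slots:
            for enzyme in slot.alternatives:
                seen_pathway.setdefault(enzyme, set()).add(defn.pathway_id)
    pathway_presence: dict[str, dict[str, bool]] = {}
    pathway_expected: dict[str, dict[str, float]] = {}
    for genome in config.taxa:
        presence = {e: True for d in definitions for e in d.enzymes}
        expected: dict[str, float] = {}
        for defn in definitions:
            n_slots = len(defn.slots)
            if genome in endos:
                # holes only in slots that are neither bypassable nor bypass
                # providers and whose enzymes belong to this pathway alone,
                # so the expected fraction is a simple count
                providers = {s for slot in defn.slots for s in slot.bypassable_by}
                safe = [s for s in defn.slots
                        if not s.bypassable_by and s.slot_id not in providers
                        and all(seen_pathway[e] == {defn.pathway_id}
                                for e in s.alternatives)]
                n_holes = int(rng.integers(0, min(3, len(safe)) + 1))
                hole_slots = list(rng.choice(len(safe), size=n_holes, replace=False))
                for idx in hole_slots:
                    for enzyme in safe[int(idx)].alternatives:
                        presence[enzyme] = False
                expected[defn.pathway_id] = (n_slots - n_holes) / n_slots
            else:
                expected[defn.pathway_id] = 1.0
            if genome not in endos:
                # supplementation markers are the endosymbionts' specialty
                for marker in defn.supplement_markers:
                    presence[marker] = False
        pathway_presence[genome] = presence
        pathway_expected[genome] = expected

    truth = CladeTruth(
        config=asdict(config),
        tree_newick=tree.newick(with_support=False),
        endosymbionts=list(endos),
        relatives=list(relatives),
        reference_relative=ref,
        outgroups=list(outgroups),
        pivot_endosymbiont=pivot,
        families={fid: members for fid, members in families.items()},
        planted_stem_losses=list(lost_ids),
        lineage_losses=lineage_losses,
        invented=invented,
        pseudogenes=pseudogenes,
        density=density,
        habitat=habitat,
        pathway_presence=pathway_presence,
        pathway_expected=pathway_expected,
    )
    return CladeBundle(config, truth, proteomes, annotations, habitats,
                       definitions, tree)


def generate(config: CladeConfig = CladeConfig(), seed: int = 0,
             out_dir: str | Path = ".") -> CladeTruth:
    """Generate the clade and write every pipeline input to ``out_dir``:
    per-genome FASTA + GFF3, habitat TSV, pathway presence TSV, and the
    ground-truth JSON."""
    bundle = simulate_clade(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for genome, proteome in bundle.proteomes.items():
        write_proteome(proteome, out / f"{genome}.faa")
        write_annotation(bundle.annotations[genome], out / f"{genome}.gff3")
    write_habitat_table(bundle.habitats.values(), out / "habitats.tsv")
    enzymes = sorted({e for p in bundle.truth.pathway_presence.values() for e in p})
    with open(out / "pathway_presence.tsv", "w") as fh:
        fh.write("genome\t" + "\t".join(enzymes) + "\n")
        for genome in sorted(bundle.truth.pathway_presence):
            presence = bundle.truth.pathway_presence[genome]
            fh.write(genome + "\t"
                     + "\t".join(str(int(presence[e])) for e in enzymes) + "\n")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(bundle.truth.tree_newick + "\n")
    bundle.truth.to_json(out / "truth.json")
    return bundle.truth
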