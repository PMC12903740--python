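"""Readers and writers for the external formats the pipeline touches.

Formats handled here: FASTA proteomes, GFF3 annotations (with
``##sequence-region`` pragmas supplying replicon lengths), 12-column
tabular local-alignment hit files (BLAST ``outfmt 6`` layout), and the
habitat metadata table (``genome_id<TAB>comma-separated labels``).

Coordinates are stored 1-based inclusive, exactly as GFF3 carries them;
conversion to half-open intervals happens only inside the interval-union
arithmetic of :mod:`symred.set_algebra`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = frozenset({"coding_gene", "noncoding_gene", "pseudogene", "other"})

#: GFF3 feature types mapped onto the internal closed vocabulary.
_GFF3_KIND_MAP = {
    "gene": "coding_gene",
    "CDS": "coding_gene",
    "pseudogene": "pseudogene",
    "ncRNA_gene": "noncoding_gene",
    "rRNA": "noncoding_gene",
    "tRNA": "noncoding_gene",
    "tmRNA": "noncoding_gene",
    "ncRNA": "noncoding_gene",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence, keyed by genome and protein id."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence or any(c.isspace() for c in self.sequence):
            raise ValueError(
                f"sequence of {self.protein_id!r} must be non-empty and whitespace-free"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class Proteome:
    """Ordered collection of :class:`ProteinRecord` from one genome."""

    def __init__(self, genome_id: str, records: Iterable[ProteinRecord]):
        self.genome_id = genome_id
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.protein_id in self._records:
                raise FormatError(
                    f"duplicate protein id {rec.protein_id!r} in genome {genome_id!r}"
                )
            self._records[rec.protein_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._records

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._records[protein_id]

    def ids(self) -> list[str]:
        return list(self._records)

    def length_of(self, protein_id: str) -> int:
        return self._records[protein_id].length


@dataclass(frozen=True)
class GeneFeature:
    """A gene-like feature on a replicon, 1-based inclusive coordinates."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.feature_id!r}: unknown kind {self.kind!r}")

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    length_nt: int
    replicon_class: str = "chromosome"  # chromosome | plasmid | unresolved

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"replicon {self.replicon_id!r}: non-positive length")


@dataclass
class GenomeAnnotation:
    """Replicons plus gene features of one genome."""

    genome_id: str
    replicons: list[Replicon]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = self.replicon_lengths()
        for feat in self.features:
            if feat.replicon_id not in lengths:
                raise FormatError(
                    f"feature {feat.feature_id!r} references unknown replicon "
                    f"{feat.replicon_id!r}"
                )
            if feat.end > lengths[feat.replicon_id]:
                raise FormatError(
                    f"feature {feat.feature_id!r} extends to {feat.end} beyond "
                    f"replicon {feat.replicon_id!r} length {lengths[feat.replicon_id]}"
                )

    def replicon_lengths(self) -> dict[str, int]:
        return {r.replicon_id: r.length_nt for r in self.replicons}

    def replicon_class(self, replicon_id: str) -> str:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r.replicon_class
        raise KeyError(replicon_id)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise local-alignment hit (12-column tabular layout)."""

    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    percent_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


@dataclass(frozen=True)
class HabitatRecord:
    genome_id: str
    labels: frozenset[str]


def read_proteome(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a FASTA proteome; ids are tokenized at the first whitespace.

    Raises :class:`FormatError` on an empty file or a duplicate id.
    """
    path = Path(path)
    genome_id = genome_id if genome_id is not None else path.stem
    records = [
        ProteinRecord(rec.id, genome_id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Proteome(genome_id, records)


def write_proteome(proteome: Proteome, path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in proteome
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_annotation(path: str | Path, genome_id: str | None = None,
                    replicon_classes: Mapping[str, str] | None = None) -> GenomeAnnotation:
    """Read a GFF3 file whose ``##sequence-region`` pragmas give replicon lengths.

    ``gene`` features become ``coding_gene`` unless a ``biotype`` or
    ``gene_biotype`` attribute marks them otherwise; ``pseudogene`` features
    keep their kind so that downstream density calculations can exclude them.
    A ``replicon_class=`` attribute on the pragma line's replicon (supplied via
    ``replicon_classes`` or a ``#!replicon-class`` pragma) assigns
    chromosome/plasmid/unresolved; default is chromosome.
    """
    path = Path(path)
    genome_id = genome_id if genome_id is not None else path.stem
    replicons: dict[str, Replicon] = {}
    classes: dict[str, str] = dict(replicon_classes or {})
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: malformed sequence-region pragma")
                replicons[parts[1]] = Replicon(parts[1], int(parts[3]),
                                               classes.get(parts[1], "chromosome"))
                continue
            if line.startswith("#!replicon-class"):
                _, rid, rclass = line.split()
                classes[rid] = rclass
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            kind = _classify_gff3_type(ftype, attrs)
            if kind is None:
                continue
            feature_id = _gff3_attribute(attrs, "ID") or f"{seqid}:{start}-{end}"
            features.append(GeneFeature(feature_id, seqid, int(start), int(end),
                                        strand if strand in "+-" else "+", kind))
    if not replicons:
        raise FormatError(f"{path}: no ##sequence-region pragmas (replicon lengths unknown)")
    # re-apply classes learned from pragmas after the sequence-region lines
    replicon_list = [Replicon(r.replicon_id, r.length_nt,
                              classes.get(r.replicon_id, r.replicon_class))
                     for r in replicons.values()]
    return GenomeAnnotation(genome_id, replicon_list, features)


def _classify_gff3_type(ftype: str, attrs: str) -> str | None:
    if ftype == "gene":
        biotype = _gff3_attribute(attrs, "biotype") or _gff3_attribute(attrs, "gene_biotype")
        if biotype and biotype != "protein_coding":
            return "pseudogene" if biotype == "pseudogene" else "noncoding_gene"
        return "coding_gene"
    return _GFF3_KIND_MAP.get(ftype)


def _gff3_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + "="):
            return item[len(key) + 1:]
    return None


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write GFF3 with sequence-region and replicon-class pragmas."""
    kind_to_type = {"coding_gene": "gene", "noncoding_gene": "ncRNA_gene",
                    "pseudogene": "pseudogene", "other": "region"}
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for rep in ann.replicons:
            out.write(f"##sequence-region {rep.replicon_id} 1 {rep.length_nt}\n")
            out.write(f"#!replicon-class {rep.replicon_id} {rep.replicon_class}\n")
        for feat in ann.features:
            out.write("\t".join([
                feat.replicon_id, "symred", kind_to_type[feat.kind],
                str(feat.start), str(feat.end), ".", feat.strand, ".",
                f"ID={feat.feature_id}",
            ]) + "\n")


_HIT_COLUMNS = 12


def read_hit_table(path: str | Path,
                   genome_of: Mapping[str, str]) -> list[HitRecord]:
    """Read a 12-column tabular hit file (query, subject, %id, aln_len,
    mismatches, gapopens, qstart, qend, sstart, send, evalue, bitscore).

    ``genome_of`` maps protein ids to genome ids; every query and subject
    must be covered.
    """
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(cols)}"
                )
            query_id, subject_id = cols[0], cols[1]
            for pid in (query_id, subject_id):
                if pid not in genome_of:
                    raise FormatError(f"{path}:{lineno}: no genome mapping for {pid!r}")
            hits.append(HitRecord(
                query_id=query_id,
                subject_id=subject_id,
                query_genome=genome_of[query_id],
                subject_genome=genome_of[subject_id],
                percent_identity=float(cols[2]),
                aln_length=int(cols[3]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
            ))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for h in hits:
            out.write("\t".join([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                str(h.aln_length), "0", "0", "1", str(h.aln_length),
                "1", str(h.aln_length), f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]) + "\n")


def read_habitat_table(path: str | Path) -> dict[str, HabitatRecord]:
    """Read ``genome_id<TAB>comma-separated habitat labels`` (lower-cased, trimmed)."""
    records: dict[str, HabitatRecord] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            genome_id, labels = parts
            labelset = frozenset(
                lab.strip().lower() for lab in labels.split(",") if lab.strip()
            )
            records[genome_id] = HabitatRecord(genome_id, labelset)
    return records


def write_habitat_table(records: Iterable[HabitatRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f"{rec.genome_id}\t{','.join(sorted(rec.labels))}\n")
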