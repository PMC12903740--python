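"""Residue-level classification rules applied through profile alignment.

Two rules of this kind are implemented:

* **Anchored linkage rule** — α-glucosidase substrate specificity read
  from the residue adjacent to the universally conserved catalytic
  aspartate: alanine or threonine predict α(1→4) activity (maltose-type
  substrates), valine predicts α(1→6) (branched polysaccharides). The
  query is globally aligned to an annotated reference; the residue in
  the column next to the anchor (C-terminal side by default) is mapped
  through the decision table.

* **C-terminal conserved-residue counting** — small chlorophyll-binding
  (Scp) and extended-ferrochelatase (HemH) C-termini are scored by how
  many of a set of conserved motif residues the query matches, plus
  whether the C-terminal extension is long enough to carry the motif at
  all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from symred.genome_io import ProteinRecord, read_proteome

GAP = "-"

ALPHA_1_4 = "alpha_1_4"
ALPHA_1_6 = "alpha_1_6"
UNDETERMINED = "undetermined"

#: Residue-to-linkage decision table next to the catalytic aspartate.
DEFAULT_DECISION_MAP: dict[str, str] = {
    "A": ALPHA_1_4, "T": ALPHA_1_4, "V": ALPHA_1_6,
}


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class AnchoredMotifRule:
    """A reference sequence with an annotated anchor residue and a
    decision table over the residue adjacent to the anchor."""

    reference_sequence: str
    anchor_position: int  # 1-based position in the reference, must be Asp
    decision_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DECISION_MAP))
    direction: int = +1  # +1: C-terminal neighbor; -1: N-terminal neighbor

    def __post_init__(self) -> None:
        if not (1 <= self.anchor_position <= len(self.reference_sequence)):
            raise ValueError("anchor_position outside the reference")
        if self.reference_sequence[self.anchor_position - 1] != "D":
            raise ValueError("anchor column must carry the catalytic aspartate")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class LinkageCall:
    label: str
    reason: str = ""


def predict_linkage(seq: ProteinRecord | str, rule: AnchoredMotifRule) -> LinkageCall:
    """Classify linkage specificity from the residue next to the aligned
    catalytic aspartate.

    Undetermined when the query has a gap at the anchor column, does not
    itself carry Asp there, or shows a residue outside the decision table.
    """
    query = seq.sequence if isinstance(seq, ProteinRecord) else seq
    aligner = _global_aligner()
    alignment = aligner.align(rule.reference_sequence, query)[0]
    ref_row, query_row = str(alignment[0]), str(alignment[1])

    ref_pos = 0
    anchor_col = None
    for col, c in enumerate(ref_row):
        if c != GAP:
            ref_pos += 1
            if ref_pos == rule.anchor_position:
                anchor_col = col
                break
    if anchor_col is None:  # pragma: no cover - anchor always inside reference
        return LinkageCall(UNDETERMINED, "anchor not alignable")

    if query_row[anchor_col] == GAP:
        return LinkageCall(UNDETERMINED, "gap at anchor column")
    if query_row[anchor_col] != "D":
        return LinkageCall(UNDETERMINED, "query lacks catalytic aspartate")

    col = anchor_col + rule.direction
    while 0 <= col < len(query_row) and query_row[col] == GAP:
        col += rule.direction
    if not (0 <= col < len(query_row)):
        return LinkageCall(UNDETERMINED, "no residue adjacent to anchor")
    residue = query_row[col]
    label = rule.decision_map.get(residue, UNDETERMINED)
    reason = "" if label != UNDETERMINED else f"residue {residue!r} not in decision table"
    return LinkageCall(label, reason)


@dataclass(frozen=True)
class CTerminalMotif:
    """Conserved residues of a C-terminal motif, positioned relative to a
    reference C-terminal region."""

    reference_cterm: str  # reference C-terminal region carrying the motif
    conserved_positions: tuple[int, ...]  # 1-based positions within reference_cterm
    min_extension_length: int = 10  # residues beyond the core domain boundary

    def __post_init__(self) -> None:
        for pos in self.conserved_positions:
            if not (1 <= pos <= len(self.reference_cterm)):
                raise ValueError(f"conserved position {pos} outside the reference")

    @property
    def conserved_residues(self) -> tuple[str, ...]:
        return tuple(self.reference_cterm[p - 1] for p in self.conserved_positions)


@dataclass(frozen=True)
class CTermReport:
    matches: int
    total: int
    extension_present: bool


def count_conserved_cterm(seq: ProteinRecord | str, motif: CTerminalMotif,
                          core_domain_end: int | None = None) -> CTermReport:
    """Count conserved motif residues matched by a query's C-terminus.

    The query's C-terminal region (everything past ``core_domain_end``,
    or the trailing ``len(reference_cterm)`` residues when no boundary is
    given) is globally aligned to the reference region; a conserved
    position counts as matched when the query shows the identical residue
    in the aligned column. A query whose extension is shorter than
    ``min_extension_length`` reports no extension and zero matches.
    """
    query = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if core_domain_end is not None:
        region = query[core_domain_end:]
    else:
        region = query[-len(motif.reference_cterm):]
    total = len(motif.conserved_positions)
    if len(region) < motif.min_extension_length:
        return CTermReport(0, total, False)

    aligner = _global_aligner()
    alignment = aligner.align(motif.reference_cterm, region)[0]
    ref_row, query_row = str(alignment[0]), str(alignment[1])

    matches = 0
    ref_pos = 0
    wanted = set(motif.conserved_positions)
    for col, c in enumerate(ref_row):
        if c == GAP:
            continue
        ref_pos += 1
        if ref_pos in wanted and query_row[col] == c:
            matches += 1
    return CTermReport(matches, total, True)


def read_rule_file(fasta_path: str | Path, anchor_position: int,
                   decision_tsv: str | Path | None = None,
                   direction: int = +1) -> AnchoredMotifRule:
    """Build a rule from a reference FASTA (first record), a 1-based anchor
    index, and an optional residue->label decision TSV."""
    proteome = read_proteome(fasta_path, genome_id="reference")
    reference = next(iter(proteome)).sequence
    decision = dict(DEFAULT_DECISION_MAP)
    if decision_tsv is not None:
        decision = {}
        with open(decision_tsv) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                residue, label = line.split("\t")
                decision[residue.strip()] = label.strip()
    return AnchoredMotifRule(reference, anchor_position, decision, direction)
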