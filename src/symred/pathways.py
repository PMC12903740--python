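"""Metabolic pathway completeness scoring from enzyme presence calls.

A pathway is an ordered list of reaction slots. A slot is satisfied when
any of its alternative enzymes is present, or when all slots of a
declared bypass set are satisfied (a detour route that makes the
reaction dispensable). Completeness is the fraction of satisfied slots;
the state is ``present`` at fraction 1, ``absent`` at fraction 0 with no
initial substrate, else ``partial``.

Two annotations mirror how such scores are usually displayed: a
``supplemented`` flag marks capability beyond the free-living reference
(marker enzymes such as GapN or an alternative terminal oxidase), and
``holes_filled_by_import`` records whether host-encoded imported
proteins close all, some, or none of the genome's pathway holes.

Definition file format (plain text)::

    @pathway glycolysis
    @supplement gapN
    # slot_id: alt1, alt2 | bypass: slotA, slotB
    pgi: pgi
    pfk: pfkA, pfkB
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ReactionSlot:
    slot_id: str
    alternatives: tuple[str, ...]  # OR semantics
    bypassable_by: tuple[str, ...] = ()  # all of these slots satisfied => bypass

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError(f"slot {self.slot_id!r} needs at least one enzyme")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    slots: tuple[ReactionSlot, ...]
    supplement_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError(f"pathway {self.pathway_id!r} has no slots")
        slot_ids = {s.slot_id for s in self.slots}
        for slot in self.slots:
            unknown = set(slot.bypassable_by) - slot_ids
            if unknown:
                raise ValueError(
                    f"slot {slot.slot_id!r} bypass references unknown slots {sorted(unknown)}"
                )

    @property
    def enzymes(self) -> set[str]:
        out = set(self.supplement_markers)
        for slot in self.slots:
            out |= set(slot.alternatives)
        return out


@dataclass(frozen=True)
class PathwayScore:
    genome_id: str
    pathway_id: str
    fraction: float  # reported to 3 decimals
    state: str  # present | partial | absent
    supplemented: bool = False
    holes_filled_by_import: str = "none"  # none | some | all


def _satisfied_slots(defn: PathwayDefinition,
                     presence: Mapping[str, bool]) -> set[str]:
    unknown = defn.enzymes - set(presence)
    if unknown:
        raise KeyError(f"no presence call for enzymes {sorted(unknown)}")
    satisfied = {s.slot_id for s in defn.slots
                 if any(presence[e] for e in s.alternatives)}
    # bypass closure: iterate until stable (bypass sets may chain)
    changed = True
    while changed:
        changed = False
        for slot in defn.slots:
            if (slot.slot_id not in satisfied and slot.bypassable_by
                    and all(b in satisfied for b in slot.bypassable_by)):
                satisfied.add(slot.slot_id)
                changed = True
    return satisfied


def score_pathway(defn: PathwayDefinition, presence: Mapping[str, bool],
                  genome_id: str = "", has_initial_substrate: bool = True) -> PathwayScore:
    """Completeness fraction and state for one genome.

    ``has_initial_substrate`` feeds the 'absent' state: a pathway with no
    recognizable enzymes counts as absent only when the genome also lacks
    the pathway's initial substrate.
    """
    satisfied = _satisfied_slots(defn, presence)
    exact = len(satisfied) / len(defn.slots)
    if exact == 1.0:
        state = "present"
    elif exact == 0.0 and not has_initial_substrate:
        state = "absent"
    else:
        state = "partial"
    return PathwayScore(genome_id, defn.pathway_id, round(exact, 3), state,
                        supplemented=supplementation_flag(defn, presence))


def apply_host_imports(score: PathwayScore, defn: PathwayDefinition,
                       presence: Mapping[str, bool],
                       imports: Mapping[str, bool],
                       has_initial_substrate: bool = True) -> PathwayScore:
    """Rescore with host-imported proteins added to the presence calls.

    ``holes_filled_by_import`` reports whether imports close all, some,
    or none of the slots that were unsatisfied before. Idempotent: the
    merged presence already contains every import.
    """
    before = _satisfied_slots(defn, presence)
    merged = dict(presence)
    for enzyme, flag in imports.items():
        merged[enzyme] = merged.get(enzyme, False) or flag
    after = _satisfied_slots(defn, merged)
    holes_before = {s.slot_id for s in defn.slots} - before
    newly_filled = holes_before & after
    if not holes_before or not newly_filled:
        holes = "none"
    elif newly_filled == holes_before:
        holes = "all"
    else:
        holes = "some"
    rescored = score_pathway(defn, merged, score.genome_id, has_initial_substrate)
    return replace(rescored, supplemented=score.supplemented or rescored.supplemented,
                   holes_filled_by_import=holes)


def supplementation_flag(defn: PathwayDefinition,
                         presence: Mapping[str, bool]) -> bool:
    """True iff any supplement-marker enzyme is present (orthogonal to the
    completeness fraction)."""
    return any(presence.get(e, False) for e in defn.supplement_markers)


# ---------------------------------------------------------------------------
# Definition files and the score matrix
# ---------------------------------------------------------------------------

def read_pathway_definition(path: str | Path) -> PathwayDefinition:
    pathway_id: str | None = None
    markers: list[str] = []
    slots: list[ReactionSlot] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@pathway"):
                pathway_id = line.split(None, 1)[1].strip()
                continue
            if line.startswith("@supplement"):
                markers.extend(e.strip() for e in line.split(None, 1)[1].split(","))
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'slot_id: enzymes'")
            slot_id, rest = line.split(":", 1)
            bypass: tuple[str, ...] = ()
            if "|" in rest:
                rest, clause = rest.split("|", 1)
                clause = clause.strip()
                if not clause.startswith("bypass:"):
                    raise ValueError(f"{path}:{lineno}: unknown clause {clause!r}")
                bypass = tuple(s.strip() for s in clause[len("bypass:"):].split(","))
            alternatives = tuple(e.strip() for e in rest.split(",") if e.strip())
            slots.append(ReactionSlot(slot_id.strip(), alternatives, bypass))
    if pathway_id is None:
        raise ValueError(f"{path}: missing @pathway header")
    return PathwayDefinition(pathway_id, tuple(slots), tuple(markers))


def load_pathway_directory(directory: str | Path) -> list[PathwayDefinition]:
    return [read_pathway_definition(p)
            for p in sorted(Path(directory).glob("*.txt"))]


def builtin_pathways() -> list[PathwayDefinition]:
    """The pathway definitions shipped with the package (central carbon
    and cofactor metabolism of a diazotrophic cyanobacterium)."""
    return load_pathway_directory(Path(__file__).parent / "data" / "pathways")


def score_matrix(definitions: Sequence[PathwayDefinition],
                 presence_by_genome: Mapping[str, Mapping[str, bool]],
                 imports_by_genome: Mapping[str, Mapping[str, bool]] | None = None,
                 ) -> pd.DataFrame:
    """Genome x pathway grid of fraction/state/flags."""
    rows = []
    for genome_id in sorted(presence_by_genome):
        presence = presence_by_genome[genome_id]
        for defn in definitions:
            full = {e: presence.get(e, False) for e in defn.enzymes}
            score = score_pathway(defn, full, genome_id)
            if imports_by_genome and genome_id in imports_by_genome:
                score = apply_host_imports(score, defn, full,
                                           imports_by_genome[genome_id])
            rows.append((genome_id, defn.pathway_id, score.fraction, score.state,
                         score.supplemented, score.holes_filled_by_import))
    return pd.DataFrame(rows, columns=["genome", "pathway", "fraction", "state",
                                       "supplemented", "holes_filled_by_import"])
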