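"""Saline-habitat classification and ortholog habitat enrichment.

Genomes are classified from free-text isolation-habitat labels under a
fixed controlled vocabulary: a genome is *saline* when it carries at
least one saline label (marine, saline lake, coastal, brackish,
intertidal, estuary) and no excluding label (freshwater, bog, hot
springs, halo-intolerant, terrestrial, rock, paddy, sand, soil, root);
any excluding label makes it *non-saline*; a genome matching neither
vocabulary is *unclassified*.

For a prototype protein, the saline fraction is the share of
ortholog-bearing genomes classified saline among those classified at
all; comparing it with the panel-wide baseline reveals habitat bias in
the gene's distribution (e.g. an endosymbiont gene complement skewed
towards marine donors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from symred.genome_io import HabitatRecord

SALINE_LABELS = frozenset({
    "marine", "saline lake", "coastal", "brackish", "intertidal", "estuary",
})
EXCLUSION_LABELS = frozenset({
    "freshwater", "bog", "hot springs", "halo-intolerant", "terrestrial",
    "rock", "paddy", "sand", "soil", "root",
})


@dataclass(frozen=True)
class HabitatVocabulary:
    saline_labels: frozenset[str] = SALINE_LABELS
    exclusion_labels: frozenset[str] = EXCLUSION_LABELS

    def __post_init__(self) -> None:
        if self.saline_labels & self.exclusion_labels:
            raise ValueError("saline and exclusion vocabularies must be disjoint")


class UndefinedFraction(Exception):
    """No classified ortholog-bearing genomes: the fraction is undefined."""


def classify_habitat(rec: HabitatRecord,
                     vocab: HabitatVocabulary = HabitatVocabulary()) -> str:
    """'saline', 'non_saline', or 'unclassified'. Exclusion labels dominate."""
    if rec.labels & vocab.exclusion_labels:
        return "non_saline"
    if rec.labels & vocab.saline_labels:
        return "saline"
    return "unclassified"


def saline_fraction(ortholog_presence: Mapping[str, bool],
                    habitats: Mapping[str, HabitatRecord],
                    vocab: HabitatVocabulary = HabitatVocabulary(),
                    unclassified_as_nonsaline: bool = False) -> float:
    """Saline share among classified genomes bearing the ortholog.

    Raises :class:`UndefinedFraction` when no ortholog-bearing genome is
    classified. ``unclassified_as_nonsaline`` counts unclassified genomes
    in the denominator instead of dropping them.
    """
    n_saline = n_classified = 0
    for genome_id, present in ortholog_presence.items():
        if not present or genome_id not in habitats:
            continue
        cls = classify_habitat(habitats[genome_id], vocab)
        if cls == "saline":
            n_saline += 1
            n_classified += 1
        elif cls == "non_saline" or unclassified_as_nonsaline:
            n_classified += 1
    if n_classified == 0:
        raise UndefinedFraction("no classified ortholog-bearing genomes")
    return n_saline / n_classified


def panel_baseline(habitats: Mapping[str, HabitatRecord],
                   vocab: HabitatVocabulary = HabitatVocabulary(),
                   subset: Sequence[str] | None = None,
                   unclassified_as_nonsaline: bool = False) -> float:
    """Saline fraction over all classified genomes of the (sub)panel."""
    genomes = subset if subset is not None else list(habitats)
    presence = {g: True for g in genomes}
    return saline_fraction(presence, habitats, vocab, unclassified_as_nonsaline)


def enrichment_table(prototypes: Mapping[str, Mapping[str, bool]],
                     habitats: Mapping[str, HabitatRecord],
                     vocab: HabitatVocabulary = HabitatVocabulary(),
                     descriptions: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-prototype enrichment rows: (prototype_id, description,
    n_ortholog_genomes, saline_fraction, baseline)."""
    baseline = panel_baseline(habitats, vocab)
    rows = []
    for proto_id in sorted(prototypes):
        presence = prototypes[proto_id]
        n_bearing = sum(1 for g, p in presence.items() if p)
        try:
            frac = saline_fraction(presence, habitats, vocab)
        except UndefinedFraction:
            frac = float("nan")
        rows.append((proto_id,
                     (descriptions or {}).get(proto_id, ""),
                     n_bearing, frac, baseline))
    return pd.DataFrame(rows, columns=["prototype_id", "description",
                                       "n_ortholog_genomes", "saline_fraction",
                                       "baseline"])
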