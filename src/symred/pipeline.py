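"""End-to-end orchestration: orthology -> set algebra -> density ->
pathway scores -> habitat enrichment -> phylogeny.

:func:`run_pipeline` drives every stage over an in-memory clade (real
inputs loaded through :mod:`symred.genome_io`, or a synthetic bundle
from :mod:`symred.simulate`); :func:`truth_check` compares a pipeline
result against a :class:`~symred.simulate.CladeTruth` record and emits
machine-readable pass/fail per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from symred.genome_io import GenomeAnnotation, HabitatRecord, Proteome
from symred.habitat import HabitatVocabulary, classify_habitat, panel_baseline
from symred.orthology import (OrthologTables, SearchParams, ThresholdPolicy,
                              search_and_pair)
from symred.pathways import PathwayDefinition, score_matrix
from symred.phylogeny import (Alignment, Supermatrix, TreeNode, align_family,
                              bootstrap_support, build_supermatrix,
                              filter_columns, robinson_foulds)
from symred.set_algebra import (DensityReport, PanelDesign, SetClassification,
                                classify, gene_density, small_protein_summary)

#: Search parameters used for whole-panel runs: longer seeds and the
#: edit-distance scorer keep 30+ genome-pair searches tractable.
FAST_SEARCH = SearchParams(seed_k=6, scorer="edit", small_seed_k=3,
                           max_candidates=500)


@dataclass
class PipelineResult:
    panel: PanelDesign
    tables: OrthologTables
    classification: SetClassification | None = None
    counts: pd.DataFrame | None = None
    small_fractions: dict[str, float] | None = None
    density_reports: dict[str, DensityReport] | None = None
    pathway_scores: pd.DataFrame | None = None
    habitat_classes: dict[str, str] | None = None
    saline_baseline: float | None = None
    supermatrix: Supermatrix | None = None
    tree: TreeNode | None = None


def all_pairwise_tables(proteomes: Mapping[str, Proteome],
                        genomes: Sequence[str],
                        policy: ThresholdPolicy = ThresholdPolicy(),
                        params: SearchParams = FAST_SEARCH) -> OrthologTables:
    """Built-in search + reciprocal-best-hit pairing for every genome pair.

    Seed indexes are built once per genome and shared across pairs."""
    from symred.orthology import (bbh_orthologs, build_seed_indexes,
                                  internal_search)

    indexes = {g: build_seed_indexes(proteomes[g], params) for g in genomes}
    tables = OrthologTables()
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            hits_ab = internal_search(proteomes[ga], proteomes[gb], params,
                                      subject_index=indexes[gb])
            hits_ba = internal_search(proteomes[gb], proteomes[ga], params,
                                      subject_index=indexes[ga])
            tables.add(bbh_orthologs(hits_ab, hits_ba, policy, proteomes,
                                     ga, gb))
    return tables


def tree_families(classification: SetClassification,
                  tables: OrthologTables,
                  proteomes: Mapping[str, Proteome],
                  n_families: int = 29) -> dict[str, dict[str, str]]:
    """Pick conserved families present in every panel genome, anchored on
    the reference relative's core proteins, for the supermatrix."""
    panel = classification.panel
    ref = panel.reference_relative
    genomes = panel.all_genomes
    families: dict[str, dict[str, str]] = {}
    for pid in sorted(classification.members(ref, core=True)):
        members: dict[str, str] = {ref: pid}
        for genome in genomes:
            if genome == ref:
                continue
            partner = tables.get(ref, genome).partner_of(ref, pid)
            if partner is None:
                break
            members[genome] = partner
        if len(members) == len(genomes):
            families[pid] = {g: proteomes[g][p].sequence
                             for g, p in members.items()}
            if len(families) == n_families:
                break
    return families


def infer_tree(families: Mapping[str, Mapping[str, str]],
               taxa: Sequence[str], n_bootstrap: int = 100, seed: int = 0,
               max_gap_fraction: float = 0.0, min_block_length: int = 10,
               model: str = "poisson") -> tuple[Supermatrix, TreeNode]:
    alignments: dict[str, Alignment] = {}
    for family_id in sorted(families):
        aln = align_family(dict(families[family_id]))
        try:
            aln = filter_columns(aln, max_gap_fraction, min_block_length)
        except ValueError:
            continue  # family contributes no informative block
        alignments[family_id] = aln
    if not alignments:
        raise ValueError("no family yields informative columns")
    sm = build_supermatrix(alignments, taxa)
    tree = bootstrap_support(sm, n_replicates=n_bootstrap, seed=seed, model=model)
    return sm, tree


def run_pipeline(proteomes: Mapping[str, Proteome],
                 panel: PanelDesign,
                 annotations: Mapping[str, GenomeAnnotation] | None = None,
                 habitats: Mapping[str, HabitatRecord] | None = None,
                 pathway_definitions: Sequence[PathwayDefinition] | None = None,
                 pathway_presence: Mapping[str, Mapping[str, bool]] | None = None,
                 policy: ThresholdPolicy = ThresholdPolicy(),
                 search_params: SearchParams = FAST_SEARCH,
                 count_pseudogenes: bool = False,
                 n_tree_families: int = 29,
                 n_bootstrap: int = 100,
                 seed: int = 0,
                 tables: OrthologTables | None = None) -> PipelineResult:
    """Run every stage for which inputs were supplied.

    Stages with missing inputs (no annotations, no habitat table, ...)
    are skipped; their result fields stay ``None``.
    """
    genomes = list(panel.all_genomes)
    if tables is None:
        tables = all_pairwise_tables(proteomes, genomes, policy, search_params)
    result = PipelineResult(panel=panel, tables=tables)

    result.classification = classify(panel, tables, proteomes)
    result.counts = result.classification.counts_table()
    result.small_fractions = small_protein_summary(result.classification, proteomes)

    if annotations is not None:
        result.density_reports = {
            g: gene_density(annotations[g], count_pseudogenes)
            for g in genomes if g in annotations
        }

    if pathway_definitions is not None and pathway_presence is not None:
        result.pathway_scores = score_matrix(pathway_definitions, pathway_presence)

    if habitats is not None:
        vocab = HabitatVocabulary()
        result.habitat_classes = {
            g: classify_habitat(habitats[g], vocab)
            for g in genomes if g in habitats
        }
        result.saline_baseline = panel_baseline(
            {g: habitats[g] for g in genomes if g in habitats}, vocab)

    fams = tree_families(result.classification, tables, proteomes,
                         n_tree_families)
    if len(fams) >= 1 and len(genomes) >= 3:
        result.supermatrix, result.tree = infer_tree(
            fams, genomes, n_bootstrap=n_bootstrap, seed=seed)
    return result


# ---------------------------------------------------------------------------
# Ground-truth verification
# ---------------------------------------------------------------------------

@dataclass
class StageCheck:
    stage: str
    passed: bool
    details: dict = field(default_factory=dict)


@dataclass
class TruthCheckReport:
    checks: list[StageCheck] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def stage(self, name: str) -> StageCheck:
        for c in self.checks:
            if c.stage == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {c.stage: {"passed": c.passed, **c.details} for c in self.checks}


def truth_check(result: PipelineResult, truth, bundle=None,
                density_tol: float = 1e-9) -> TruthCheckReport:
    """Verify every computed stage against the generator's ground truth.

    ``truth`` is a :class:`~symred.simulate.CladeTruth`; ``bundle``
    (optional) supplies the planted tree for the phylogeny check when
    available. Raises ``ValueError`` when a required stage output is
    missing from ``result``.
    """
    report = TruthCheckReport()
    panel = result.panel

    # --- orthology: precision/recall of recovered pairs vs planted families
    genomes = list(panel.all_genomes)
    tp = fp = fn = 0
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            expected = truth.expected_ortholog_pairs(ga, gb)
            table = result.tables.get(ga, gb)
            # orient found pairs as (protein in ga, protein in gb)
            found = set()
            for pair in table:
                if pair.genome_a == ga:
                    found.add((pair.protein_a, pair.protein_b))
                else:
                    found.add((pair.protein_b, pair.protein_a))
            tp += len(expected & found)
            fp += len(found - expected)
            fn += len(expected - found)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    report.checks.append(StageCheck(
        "orthology", precision == 1.0 and recall == 1.0,
        {"precision": precision, "recall": recall,
         "true_pairs": tp, "spurious": fp, "missed": fn}))

    # --- set classification
    if result.classification is None:
        raise ValueError("missing stage output: classification")
    cls = result.classification
    ref = panel.reference_relative
    core = cls.members(ref, core=True)
    no_re = cls.members(ref, no_re=True)
    all_re = cls.members(panel.pivot, all_re=True)
    exp_core = truth.expected_core()
    exp_no_re = truth.expected_no_re()
    exp_all_re = truth.expected_all_re()
    unique_ok = all(
        cls.members(g, unique=True) == truth.expected_unique(g)
        for g in genomes
    )
    sums_ok = all(
        int(result.counts.loc[g, "total"]) == len(cls.proteins_of(g))
        for g in genomes
    )
    sets_ok = (core == exp_core and no_re == exp_no_re
               and all_re == exp_all_re and unique_ok and sums_ok)
    report.checks.append(StageCheck(
        "set_algebra", sets_ok,
        {"core": len(core), "core_expected": len(exp_core),
         "no_re": len(no_re), "no_re_expected": len(exp_no_re),
         "all_re": len(all_re), "all_re_expected": len(exp_all_re),
         "core_no_re": len(core & no_re),
         "core_no_re_expected": len(exp_core & exp_no_re),
         "unique_exact": unique_ok, "partition_sums": sums_ok}))

    # --- gene density
    if result.density_reports is None:
        raise ValueError("missing stage output: density")
    worst = 0.0
    for genome, rep in result.density_reports.items():
        for entry in rep.entries:
            expected = truth.expected_density(genome, entry.entity)
            worst = max(worst, abs(entry.density - expected))
    report.checks.append(StageCheck(
        "density", worst <= density_tol, {"max_abs_error": worst}))

    # --- pathway completeness
    if result.pathway_scores is None:
        raise ValueError("missing stage output: pathway scores")
    pw_ok = True
    n_checked = 0
    for _, row in result.pathway_scores.iterrows():
        expected = truth.pathway_expected[row["genome"]][row["pathway"]]
        if abs(row["fraction"] - round(expected, 3)) > 5e-4:
            pw_ok = False
        n_checked += 1
    report.checks.append(StageCheck(
        "pathways", pw_ok, {"scores_checked": n_checked}))

    # --- habitat classification
    if result.habitat_classes is None:
        raise ValueError("missing stage output: habitat classes")
    vocab = HabitatVocabulary()
    hab_ok = True
    for genome, got in result.habitat_classes.items():
        rec = HabitatRecord(genome, frozenset(truth.habitat[genome]))
        if classify_habitat(rec, vocab) != got:
            hab_ok = False
    report.checks.append(StageCheck("habitat", hab_ok, {}))

    # --- phylogeny
    if result.tree is None:
        raise ValueError("missing stage output: tree")
    if bundle is not None:
        planted = bundle.tree
    else:
        planted = None
    if planted is not None:
        rf = robinson_foulds(result.tree, planted)
        report.checks.append(StageCheck("phylogeny", rf == 0,
                                        {"rf_distance": rf}))
    else:
        supports = [n.support for n in result.tree.postorder()
                    if n.support is not None]
        report.checks.append(StageCheck(
            "phylogeny", bool(supports), {"n_supported_edges": len(supports)}))
    return report
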