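import pytest

from symred.pipeline import run_pipeline
from symred.set_algebra import PanelDesign
from symred.simulate import CladeConfig, simulate_clade

SMALL_CONFIG = CladeConfig(n_universal_families=60, n_re_lost_families=10,
                           invented_per_endosymbiont=10)


def panel_of(truth) -> PanelDesign:
    return PanelDesign(
        endosymbiont_genomes=tuple(truth.endosymbionts),
        free_living_relatives=tuple(truth.relatives),
        reference_relative=truth.reference_relative,
        outgroup_genomes=tuple(truth.outgroups),
        pivot_endosymbiont=truth.pivot_endosymbiont,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A 9-genome clade small enough for exhaustive checks."""
    return simulate_clade(SMALL_CONFIG, seed=1)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    """Full pipeline run over the small clade."""
    b = small_bundle
    return run_pipeline(b.proteomes, panel_of(b.truth), b.annotations,
                        b.habitats, b.pathway_definitions,
                        b.truth.pathway_presence,
                        n_tree_families=10, n_bootstrap=25, seed=7)
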