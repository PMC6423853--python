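import numpy as np
import pytest

from syntevo import simulate as sim
from syntevo.pipeline import PairParams, analyze_pair
from syntevo.tree import subgroup_tree

# scaled study conditions used across the suite: 1/50 of the real karyotype,
# ~400 markers/Mb, 300 bp markers
TEST_SCALE = 0.02
TEST_MARKERS_PER_MB = 400
TEST_MARKER_LEN = 300
TEST_SEED = 11


def scaled_ancestor(seed: int = TEST_SEED, with_sequence: bool = True):
    lengths = [int(L * TEST_SCALE) for L in sim.TEMPLATE_CHROM_LENGTHS]
    counts = [max(2, int(TEST_MARKERS_PER_MB * L / 1e6)) for L in lengths]
    return sim.make_ancestral_genome(
        6,
        lengths,
        counts,
        seed=seed,
        chrom_names=list(sim.TEMPLATE_CHROM_NAMES),
        marker_length=TEST_MARKER_LEN,
        with_sequence=with_sequence,
    )


@pytest.fixture(scope="session")
def tree():
    return subgroup_tree()


@pytest.fixture(scope="session")
def template_sim(tree):
    """The 12-event template history at test scale, with an outgroup tip."""
    ancestral = scaled_ancestor()
    events = sim.plan_events(ancestral, tree, sim.paper_template_specs())
    return sim.evolve_subgroup(ancestral, tree, events, outgroup="outgroup", seed=TEST_SEED)


@pytest.fixture(scope="session")
def pair_params():
    return PairParams(max_gap=50_000, flank_width=2000)


@pytest.fixture(scope="session")
def template_analysis(template_sim, pair_params):
    """Mainland vs island-lineage analysis of the template simulation."""
    return analyze_pair(
        template_sim.genomes["subobscura"],
        template_sim.genomes["guanche"],
        outgroup=template_sim.genomes["outgroup"],
        params=pair_params,
        check_reciprocal=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
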