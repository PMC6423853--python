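"""Breakpoint intervals, flank mapping, duplications, mechanisms."""

import numpy as np
import pytest

from syntevo.breakpoints import (
    BreakpointInterval,
    breakpoint_intervals,
    check_gene_disruption,
    classify_mechanism,
    detect_inverted_duplication,
    flank_query,
    flank_repeat_fraction,
    map_flank,
    reciprocal_consistency,
)
from syntevo.genome import Chromosome, Marker, MarkerGenome
from syntevo.simulate import InversionEvent, RepeatRecord, apply_inversion, random_sequence
from syntevo.synteny import SyntenyBlock, chain_blocks, find_anchors


def _rand(n, seed=0):
    return random_sequence(n, 0.45, np.random.default_rng(seed))


def _seq_genome(taxon, seq, markers=(), chrom="c1"):
    return MarkerGenome(taxon, [Chromosome(chrom, len(seq), list(markers), seq)])


# ---------------------------------------------------------------------------
# breakpoint intervals
# ---------------------------------------------------------------------------


def test_single_block_yields_no_intervals():
    b = SyntenyBlock(1, "c", "c", (0, 100), (0, 100), 1, 3)
    assert breakpoint_intervals([b]) == []


def test_interval_is_the_gap_between_adjacent_blocks():
    blocks = [
        SyntenyBlock(1, "c", "c", (0, 100), (0, 100), 1, 3),
        SyntenyBlock(2, "c", "c", (120, 200), (120, 200), -1, 3),
    ]
    (iv,) = breakpoint_intervals(blocks)
    assert (iv.start, iv.end) == (100, 120)
    assert (iv.left_block, iv.right_block) == (1, 2)


def test_abutting_blocks_yield_zero_length_interval():
    blocks = [
        SyntenyBlock(1, "c", "c", (0, 100), (0, 100), 1, 3),
        SyntenyBlock(2, "c", "c", (100, 200), (100, 200), -1, 3),
    ]
    (iv,) = breakpoint_intervals(blocks)
    assert iv.start == iv.end == 100


def _single_inversion_world(seed=3, n_markers=40, length=200_000, cut_lo=0.3, cut_hi=0.6):
    """Two genomes differing by one straight inversion with intergenic cuts;
    returns genomes and the true cut coordinates (identical in both)."""
    from syntevo.simulate import make_ancestral_genome, snap_intergenic

    g1 = make_ancestral_genome(
        1, [length], n_markers, seed=seed, chrom_names=["c1"], marker_length=500
    )
    chrom = g1.chromosomes[0]
    l = snap_intergenic(chrom, int(cut_lo * length))
    r = snap_intergenic(chrom, int(cut_hi * length))
    g2 = apply_inversion(g1.with_taxon("t2"), InversionEvent("e", "c1", l, r))
    return g1.with_taxon("t1"), g2, (l, r)


def test_straight_inversion_intervals_contain_the_true_cuts():
    g1, g2, (l, r) = _single_inversion_world()
    blocks = chain_blocks(find_anchors(g1, g2), min_anchors=3, max_gap=50_000)
    ivs = breakpoint_intervals(blocks)
    assert len(ivs) == 2
    spacing = 200_000 / 40
    for iv, cut in zip(ivs, (l, r)):
        assert iv.start <= cut <= iv.end
        # localization within twice the mean marker spacing of the truth
        assert max(cut - iv.start, iv.end - cut) <= 2 * spacing


# ---------------------------------------------------------------------------
# flank mapping
# ---------------------------------------------------------------------------


def test_unrearranged_locus_maps_as_one_full_hit_with_zero_overhangs():
    seq = _rand(40_000, seed=1)
    g1 = _seq_genome("t1", seq)
    g2 = _seq_genome("t2", seq)
    iv = BreakpointInterval("c1", 20_000, 20_000, 1, 2)
    rep = map_flank(flank_query(g1, iv, flank_width=3000), g2)
    assert len(rep.hits) == 1
    h = rep.hits[0]
    assert h.strand == "+"
    assert (h.overhang_left, h.overhang_right) == (0, 0)
    assert h.target_span == (17_000, 23_000)


def test_query_absent_from_target_gives_no_hits():
    g1 = _seq_genome("t1", _rand(20_000, seed=2))
    g2 = _seq_genome("t2", _rand(60_000, seed=3))
    iv = BreakpointInterval("c1", 10_000, 10_000, 1, 2)
    rep = map_flank(flank_query(g1, iv, flank_width=3000), g2)
    assert rep.hits == []


def test_inversion_breakpoint_query_splits_into_two_opposite_strand_hits():
    g1, g2, (l, r) = _single_inversion_world(seed=9)
    iv = BreakpointInterval("c1", l - 500, l + 500, 1, 2)  # window straddles the cut
    rep = map_flank(flank_query(g1, iv, flank_width=4000), g2, min_hit_len=500)
    strands = {h.strand for h in rep.hits}
    assert strands == {"+", "-"}
    # hit termini in target space coincide with the true cuts within the
    # alignment resolution
    from syntevo.breakpoints import implied_target_breakpoints

    est = [p for _, p in implied_target_breakpoints(rep, slack=2000)]
    assert any(abs(p - l) <= 50 for p in est)
    assert any(abs(p - r) <= 50 for p in est)


def test_reciprocal_consistency_on_a_true_breakpoint_and_its_perturbation():
    g1, g2, (l, r) = _single_inversion_world(seed=5)
    tol = 1000
    iv1 = BreakpointInterval("c1", l - 200, l + 200, 1, 2)
    r12 = map_flank(flank_query(g1, iv1, flank_width=4000), g2, min_hit_len=500)
    iv2 = BreakpointInterval("c1", l - 200, l + 200, 1, 2)  # proximal cut fixed by inversion
    r21 = map_flank(flank_query(g2, iv2, flank_width=4000), g1, min_hit_len=500)
    assert reciprocal_consistency(r12, r21, tol=tol)
    # inject a 2 x tol offset into one direction's hit coordinates: must break
    from dataclasses import replace as dc_replace

    from syntevo.breakpoints import FlankAlignmentReport

    shifted_hits = []
    for h in r21.hits:
        nh = dc_replace(h, target_span=(h.target_span[0] + 2 * tol, h.target_span[1] + 2 * tol))
        object.__setattr__(nh, "_qlen", h._qlen)
        shifted_hits.append(nh)
    r21_shift = FlankAlignmentReport(query=r21.query, hits=shifted_hits)
    assert not reciprocal_consistency(r12, r21_shift, tol=tol)


def test_one_empty_report_is_inconsistent():
    seq = _rand(30_000, seed=7)
    g1 = _seq_genome("t1", seq)
    g2 = _seq_genome("t2", seq)
    iv = BreakpointInterval("c1", 15_000, 15_000, 1, 2)
    full = map_flank(flank_query(g1, iv, flank_width=3000), g2)
    empty = map_flank(flank_query(_seq_genome("t3", _rand(20_000, 8)), iv, 3000), g2)
    assert not reciprocal_consistency(full, empty)


# ---------------------------------------------------------------------------
# inverted duplications and mechanisms
# ---------------------------------------------------------------------------


def test_unrelated_flanks_have_no_duplication():
    assert detect_inverted_duplication(_rand(2000, 1), _rand(2000, 2)) is None


@pytest.mark.parametrize("dup_len", [300, 689])
def test_staggered_flanks_recover_duplication_length(dup_len):
    """Flanks around the two junctions of a staggered inversion share the
    stagger fragment in inverted orientation; the call recovers its length
    within the alignment-end tolerance."""
    seq = _rand(60_000, seed=dup_len)
    g = _seq_genome("t", seq)
    l, r = 20_000, 40_000
    ev = InversionEvent("e", "c1", l, r, "staggered", offset_left=dup_len)
    d = apply_inversion(g, ev).chromosomes[0].sequence
    r_out = r + dup_len
    call = detect_inverted_duplication(
        d[l - 2000 : l + 2000], d[r_out - 2000 : r_out + 2000]
    )
    assert call is not None
    assert abs(call.length - dup_len) <= 5
    assert call.identity >= 0.9


def test_mechanism_classification_truth_table():
    dup = detect_inverted_duplication  # build a real call via simulation
    seq = _rand(30_000, seed=77)
    g = _seq_genome("t", seq)
    ev = InversionEvent("e", "c1", 10_000, 20_000, "staggered", offset_left=400)
    d = apply_inversion(g, ev).chromosomes[0].sequence
    call = dup(d[8000:12_000], d[18_400:22_400])
    assert call is not None

    assert classify_mechanism(call, None).mechanism == "staggered"
    assert classify_mechanism(call, None).dup_derived.presence == "derived_only"
    assert classify_mechanism(None, None).mechanism == "straight_or_nearly_straight"
    assert classify_mechanism(call, call).mechanism == "ectopic_recombination"
    assert classify_mechanism(None, call).mechanism == "undetermined"


# ---------------------------------------------------------------------------
# gene disruption and repeat content
# ---------------------------------------------------------------------------


def test_intergenic_interval_disrupts_nothing():
    markers = [Marker("g1", 0, 100, "+"), Marker("g2", 500, 600, "+")]
    iv = BreakpointInterval("c", 200, 300, 1, 2)
    call = check_gene_disruption(iv, markers)
    assert not call.disrupted and call.genes == ()


def test_forced_disruption_is_detected_with_the_marker_named():
    markers = [Marker("g1", 100, 400, "+")]
    iv = BreakpointInterval("c", 250, 250, 1, 2)  # zero-length cut inside g1
    call = check_gene_disruption(iv, markers)
    assert call.disrupted and call.genes == ("g1",)
    # a cut exactly at a gene boundary is not a disruption
    edge = BreakpointInterval("c", 400, 400, 1, 2)
    assert not check_gene_disruption(edge, markers).disrupted


def test_template_pipeline_calls_no_gene_disruptions(template_analysis):
    """With intergenic simulated breakpoints, every inversion call on the
    template history reports no disrupted gene."""
    assert len(template_analysis.calls) >= 12
    assert all(not c.disruption.disrupted for c in template_analysis.calls)


def test_flank_repeat_fraction_merges_overlaps():
    iv = BreakpointInterval("c", 1000, 1000, 1, 2)
    reps = [
        RepeatRecord("c", 500, 900, "LTR_0"),
        RepeatRecord("c", 800, 1100, "LTR_1"),
        RepeatRecord("x", 0, 5000, "LTR_2"),  # other chromosome: ignored
    ]
    frac = flank_repeat_fraction(iv, reps, flank_width=1000)
    assert frac == pytest.approx(600 / 2000)
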