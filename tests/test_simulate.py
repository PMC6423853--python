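"""Simulator: ancestral genomes, inversion mechanics, histories, repeats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from syntevo import io
from syntevo.genome import Chromosome, Marker, MarkerGenome, revcomp
from syntevo.simulate import (
    InversionEvent,
    RepeatClass,
    RepeatModel,
    apply_inversion,
    evolve_subgroup,
    make_ancestral_genome,
    paper_template_specs,
    place_inverted_repeat_pair,
    place_repeats,
    plan_events,
    random_sequence,
)

from conftest import scaled_ancestor


# ---------------------------------------------------------------------------
# ancestral genome generation
# ---------------------------------------------------------------------------


def test_zero_markers_gives_empty_marker_list():
    g = make_ancestral_genome(1, [10_000], 0, seed=0)
    assert g.chromosomes[0].markers == []
    assert g.chromosomes[0].length == 10_000


def test_same_seed_gives_byte_identical_fasta_and_gff3(tmp_path):
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        g = make_ancestral_genome(2, [30_000, 20_000], 10, seed=42)
        io.write_fasta(g, d / "g.fasta")
        io.write_gff3(g, d / "g.gff3")
    for name in ("g.fasta", "g.gff3"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_requested_chromosome_length_ratios_are_exact():
    lengths = [1_000_000 * k for k in (17, 16, 18, 15, 20, 1)]  # dot:largest = 1:20
    g = make_ancestral_genome(6, lengths, 5, seed=3)
    assert [c.length for c in g.chromosomes] == lengths


def test_infeasible_marker_packing_raises():
    with pytest.raises(ValueError, match="cannot fit"):
        make_ancestral_genome(1, [5_000], 10, seed=0, marker_length=1000)


def test_base_composition_tracks_requested_gc(rng):
    seq = random_sequence(200_000, gc=0.45, rng=rng)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.45) < 0.01


# ---------------------------------------------------------------------------
# applying single inversions
# ---------------------------------------------------------------------------


def _toy_genome(seq_len=9000, marker_spans=((1000, 1400), (3000, 3400), (5000, 5400)),
                strands=("+", "+", "+")):
    rng = np.random.default_rng(5)
    seq = random_sequence(seq_len, 0.45, rng)
    markers = [
        Marker(f"m{i}", a, b, s) for i, ((a, b), s) in enumerate(zip(marker_spans, strands))
    ]
    return MarkerGenome("toy", [Chromosome("c1", seq_len, markers, seq)])


def test_straight_inversion_reverses_marker_order_and_strands():
    g = _toy_genome()
    ev = InversionEvent("e1", "c1", 500, 6000)
    out = apply_inversion(g, ev)
    c = out.chromosomes[0]
    assert [m.id for m in c.markers] == ["m2", "m1", "m0"]
    assert all(m.strand == "-" for m in c.markers)
    assert c.length == 9000
    # sequence reverse-complemented in place
    assert c.sequence[500:6000] == revcomp(g.chromosomes[0].sequence[500:6000])


def test_straight_inversion_is_an_involution():
    g = _toy_genome()
    ev = InversionEvent("e1", "c1", 500, 6000)
    back = apply_inversion(apply_inversion(g, ev), ev)
    assert back.chromosomes[0].sequence == g.chromosomes[0].sequence
    assert back.chromosomes[0].markers == g.chromosomes[0].markers


def test_staggered_inversion_duplicates_stagger_fragments_on_both_flanks():
    g = _toy_genome()
    s = g.chromosomes[0].sequence
    l, r, off = 500, 6000, 300
    ev = InversionEvent("e1", "c1", l, r, "staggered", offset_left=off, offset_right=off)
    out = apply_inversion(g, ev)
    d = out.chromosomes[0].sequence
    assert len(d) == len(s) + 2 * off
    left_frag, right_frag = s[l : l + off], s[r - off : r]
    # left flank: the left fragment forward, then the inverted segment whose
    # start is the inverted duplicate of the right fragment
    assert d[l : l + off] == left_frag
    assert d[l + off : l + 2 * off] == revcomp(right_frag)
    # right flank mirrors it
    r_out = r + 2 * off  # realized distal junction
    assert d[r_out - off : r_out] == right_frag
    assert d[r_out - 2 * off : r_out - off] == revcomp(left_frag)


def test_stagger_offsets_exceeding_segment_raise():
    g = _toy_genome()
    with pytest.raises(ValueError, match="exceed"):
        apply_inversion(
            g, InversionEvent("e1", "c1", 500, 700, "staggered", offset_left=150, offset_right=150)
        )


def test_breakpoint_inside_marker_requires_disrupt_flag():
    g = _toy_genome()
    with pytest.raises(ValueError, match="disrupt"):
        apply_inversion(g, InversionEvent("e1", "c1", 1200, 6000))
    out = apply_inversion(g, InversionEvent("e1", "c1", 1200, 6000, disrupt=True))
    ids = [m.id for m in out.chromosomes[0].markers]
    assert "m0.5p" in ids and "m0.3p" in ids


def test_ectopic_event_without_repeat_pair_raises():
    g = _toy_genome()
    ev = InversionEvent("e1", "c1", 500, 6000, "ectopic", repeat_id="R1")
    with pytest.raises(ValueError, match="R1"):
        apply_inversion(g, ev)


def test_ectopic_inversion_keeps_repeat_copies_on_both_flanks():
    g = _toy_genome()
    g2, pair = place_inverted_repeat_pair(g, "R1", "c1", 600, 6000, 400, seed=9)
    l, r = pair.midpoints
    unit = g2.chromosomes[0].sequence[600:1000]
    assert g2.chromosomes[0].sequence[6000:6400] == revcomp(unit)
    ev = InversionEvent("e1", "c1", l, r, "ectopic", repeat_id="R1")
    out = apply_inversion(g2, ev, {"R1": pair})
    d = out.chromosomes[0].sequence
    assert len(d) == len(g2.chromosomes[0].sequence)
    # full-length copies reconstituted at both breakpoint flanks
    assert d[600:1000] == unit
    assert d[6000:6400] == revcomp(unit)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    cuts=st.tuples(st.integers(0, 8999), st.integers(0, 8999)),
    mech=st.sampled_from(["straight", "staggered"]),
    offset=st.integers(0, 200),
)
def test_marker_content_and_length_bookkeeping(cuts, mech, offset):
    """Any valid inversion conserves the marker-id multiset and grows the
    genome by exactly the stagger offsets."""
    l, r = sorted(cuts)
    g = _toy_genome()
    kwargs = dict(offset_left=offset, offset_right=offset) if mech == "staggered" else {}
    try:
        ev = InversionEvent("e", "c1", l, r, mech, **kwargs)
        out = apply_inversion(g, ev)
    except ValueError:
        return  # rejected: cut in a marker, degenerate segment, ...
    got = sorted(m.id for m in out.chromosomes[0].markers)
    assert got == sorted(m.id for m in g.chromosomes[0].markers)
    expect_growth = 2 * offset if mech == "staggered" else 0
    assert out.chromosomes[0].length == g.chromosomes[0].length + expect_growth


# ---------------------------------------------------------------------------
# subgroup histories
# ---------------------------------------------------------------------------


def test_no_events_gives_tips_identical_to_ancestor(tree):
    anc = scaled_ancestor(seed=4)
    out = evolve_subgroup(anc, tree, [], outgroup="outgroup")
    for tip in tree.tips:
        assert out.genomes[tip].chromosomes == anc.chromosomes
    assert out.alt_haplotypes == {}


def test_template_scenario_branch_partition(tree, template_sim):
    """The template history partitions as six chromosome-A events on the
    mainland lineage, three fixed autosomal events, two polymorphic events
    and one island-lineage event."""
    events = template_sim.truth.events
    a_mainland = [e for e in events if e.chrom == "A" and e.branch == "subobscura"]
    fixed_auto = [
        e for e in events
        if e.chrom != "A" and e.terminal_state == "fixed" and e.branch != "guanche"
    ]
    poly = [e for e in events if e.terminal_state == "polymorphic"]
    island = [e for e in events if e.branch == "guanche"]
    assert (len(a_mainland), len(fixed_auto), len(poly), len(island)) == (6, 3, 2, 1)
    # the polymorphic tip emits two haplotypes; the standard one lacks them
    assert set(template_sim.alt_haplotypes) == {"subobscura"}
    std = template_sim.alt_haplotypes["subobscura"]
    poly_chroms = {e.chrom for e in poly}
    for chrom in poly_chroms:
        derived = template_sim.genomes["subobscura"].chromosome(chrom)
        assert std.chromosome(chrom).markers != derived.markers


def test_realized_coordinates_track_earlier_length_changes(tree):
    anc = scaled_ancestor(seed=8)
    specs = paper_template_specs()
    events = plan_events(anc, tree, specs)
    out = evolve_subgroup(anc, tree, events, seed=8)
    # U carries two staggered events; the second one's realized span must be
    # shifted by the first one's duplication length when it lies distal
    u_events = [e for e in events if e.chrom == "U"]
    first, second = u_events
    realized = out.truth.realized[("subobscura", second.event_id)]
    shift = first.offset_left + first.offset_right
    assert realized[0] == second.left_bp  # second applied after first: coords already post-shift
    # and the first event's realized span includes its own duplication growth
    r_first = out.truth.realized[("subobscura", first.event_id)]
    assert r_first[1] - r_first[0] == (first.right_bp - first.left_bp) + shift


def test_polymorphic_event_on_internal_branch_rejected(tree):
    anc = scaled_ancestor(seed=4)
    ev = InversionEvent("e", "J", 1000, 30_000, branch="ms", terminal_state="polymorphic")
    with pytest.raises(ValueError, match="polymorphic"):
        evolve_subgroup(anc, tree, [ev])


def test_unknown_branch_rejected(tree):
    anc = scaled_ancestor(seed=4)
    ev = InversionEvent("e", "J", 1000, 30_000, branch="nowhere")
    with pytest.raises(ValueError, match="nowhere"):
        evolve_subgroup(anc, tree, [ev])


# ---------------------------------------------------------------------------
# repeat landscapes
# ---------------------------------------------------------------------------


def _flat_genome(length=1_000_000, seed=0):
    return make_ancestral_genome(1, [length], 0, seed=seed, with_sequence=False)


def test_zero_count_class_places_no_records():
    g = _flat_genome()
    model = RepeatModel((RepeatClass("LTR", 0, 400),))
    assert place_repeats(g, model, seed=1) == []


def test_uniform_class_passes_ks_uniformity_in_95_percent_of_runs():
    """With enrichment 1 and slope 0 placements are uniform: a KS test vs
    the uniform law should fail to reject at alpha = 0.01 in >= 95/100 seeded
    runs."""
    g = _flat_genome()
    model = RepeatModel((RepeatClass("LTR", 150, 400),))
    ok = 0
    for seed in range(100):
        recs = place_repeats(g, model, seed=seed)
        mids = np.array([(r.start + r.end) / 2 for r in recs]) / 1_000_000
        if stats.kstest(mids, "uniform").pvalue > 0.01:
            ok += 1
    assert ok >= 95


def test_pericentromeric_enrichment_concentrates_near_centromere():
    g = _flat_genome()
    model = RepeatModel((RepeatClass("satellite", 300, 290, pericentromeric_enrichment=8.0),))
    recs = place_repeats(g, model, seed=3)
    mids = np.array([(r.start + r.end) / 2 for r in recs])
    # first decile (centromere end) holds several times the uniform share
    assert (mids < 100_000).mean() > 0.2


def test_records_are_sorted_and_in_bounds(template_sim):
    from syntevo.simulate import default_repeat_model

    g = template_sim.genomes["guanche"]
    recs = place_repeats(g, default_repeat_model(scale=0.02), seed=5)
    by_chrom = {}
    for r in recs:
        assert 0 <= r.start < r.end <= g.chromosome(r.chrom).length
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for spans in by_chrom.values():
        assert spans == sorted(spans)
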