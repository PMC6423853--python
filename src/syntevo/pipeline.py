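"""End-to-end orchestration: genomes in, inversion calls and histories out.

`analyze_pair` runs the full comparison between a reference genome and a
second taxon: anchors, synteny blocks in both directions, per-chromosome
signed permutations, breakpoint intervals, and one InversionCall per
inverted block with duplication/mechanism/polarity/disruption evidence.
Multi-inversion regions (several sign-mixed blocks on one chromosome) are
resolved separately by the optimal reversal scenario of that chromosome's
signed permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .breakpoints import (
    BreakpointInterval,
    FlankAlignmentReport,
    GeneDisruptionCall,
    MechanismCall,
    breakpoint_intervals,
    check_gene_disruption,
    classify_mechanism,
    detect_inverted_duplication,
    flank_query,
    implied_target_breakpoints,
    map_flank,
    reciprocal_consistency,
)
from .genome import MarkerGenome
from .history import PolarityCall, ReversalScenario, infer_polarity, sort_by_reversals
from .synteny import (
    BlockStats,
    SignedPermutation,
    SyntenyBlock,
    block_stats,
    chain_blocks,
    find_anchors,
    to_signed_permutation,
)


@dataclass(frozen=True)
class PairParams:
    min_anchors: int = 3
    max_gap: int = 1_000_000
    flank_width: int = 5000
    min_dup_len: int = 50
    min_identity: float = 0.9
    tol: int = 1000
    min_hit_len: int = 100


@dataclass
class InversionCall:
    inversion_id: str
    chrom: str
    block_id: int
    proximal: BreakpointInterval | None
    distal: BreakpointInterval | None
    mechanism: MechanismCall
    polarity: PolarityCall | None
    disruption: GeneDisruptionCall
    reciprocal_consistent: bool | None = None
    reports: tuple[FlankAlignmentReport, ...] = ()


@dataclass
class PairAnalysis:
    genome1: str
    genome2: str
    blocks_1to2: list[SyntenyBlock]
    blocks_2to1: list[SyntenyBlock]
    stats: BlockStats
    permutations: dict[str, SignedPermutation]
    intervals_1: list[BreakpointInterval]
    intervals_2: list[BreakpointInterval]
    calls: list[InversionCall] = field(default_factory=list)

    def scenarios(self) -> dict[str, ReversalScenario]:
        """Optimal reversal scenario per rearranged chromosome."""
        return {
            chrom: sort_by_reversals(perm)
            for chrom, perm in self.permutations.items()
            if not perm.is_identity()
        }


def marker_order_window(
    genome: MarkerGenome, chrom: str, interval: BreakpointInterval, k: int = 3
) -> tuple[str, ...]:
    """Ids of the k markers on each side of a breakpoint interval, in
    chromosome order — the unit of polarity evidence."""
    markers = genome.chromosome(chrom).markers
    left = [m.id for m in markers if m.end <= interval.start][-k:]
    right = [m.id for m in markers if m.start >= interval.end][:k]
    return tuple(left + right)


def order_of_ids(genome: MarkerGenome, ids: tuple[str, ...]) -> tuple[str, ...]:
    """The given marker ids in the order they occur along the other genome
    (position order within each chromosome; ids missing there are skipped)."""
    wanted = set(ids)
    out = []
    for chrom in genome.chromosomes:
        for m in chrom.markers:
            if m.id in wanted:
                out.append(m.id)
    return tuple(out)


def _flank_pair(
    genome: MarkerGenome,
    chrom: str,
    prox: BreakpointInterval,
    dist: BreakpointInterval,
    width: int,
):
    """Windows spanning each breakpoint interval plus ``width`` into the
    bounding blocks — the true junction lies somewhere inside the interval,
    so the window must cover all of it."""
    c = genome.chromosome(chrom)
    return (
        c.fetch(prox.start - width, prox.end + width),
        c.fetch(dist.start - width, dist.end + width),
    )


def _adjacent(intervals: list[BreakpointInterval], block_id: int):
    prox = next((i for i in intervals if i.right_block == block_id), None)
    dist = next((i for i in intervals if i.left_block == block_id), None)
    return prox, dist


def _matching_block(block: SyntenyBlock, other_blocks: list[SyntenyBlock]) -> SyntenyBlock | None:
    """The same block seen from the other genome, matched by anchor content."""
    want = set(block.anchor_ids)
    best, best_overlap = None, 0
    for b in other_blocks:
        overlap = len(want & set(b.anchor_ids))
        if overlap > best_overlap:
            best, best_overlap = b, overlap
    return best


def analyze_pair(
    g1: MarkerGenome,
    g2: MarkerGenome,
    outgroup: MarkerGenome | None = None,
    params: PairParams = PairParams(),
    with_sequence: bool = True,
    check_reciprocal: bool = False,
) -> PairAnalysis:
    """Full pairwise analysis with ``g1`` as the reference taxon.

    Sequence-level evidence (duplications, reciprocal flank mapping) is
    gathered when the genomes carry sequence and ``with_sequence`` is true;
    otherwise mechanism calls fall back to "undetermined".
    """
    anchors12 = find_anchors(g1, g2)
    anchors21 = find_anchors(g2, g1)
    blocks12 = chain_blocks(anchors12, params.min_anchors, params.max_gap)
    blocks21 = chain_blocks(anchors21, params.min_anchors, params.max_gap)
    perms: dict[str, SignedPermutation] = {}
    for chrom in g1.chromosome_names:
        try:
            perm = to_signed_permutation(blocks12, chrom)
        except ValueError:
            continue  # translocated chromosome: no single-target permutation
        if perm.n:
            perms[chrom] = perm
    iv1 = breakpoint_intervals(blocks12)
    iv2 = breakpoint_intervals(blocks21)

    analysis = PairAnalysis(
        genome1=g1.taxon_id,
        genome2=g2.taxon_id,
        blocks_1to2=blocks12,
        blocks_2to1=blocks21,
        stats=block_stats(blocks12),
        permutations=perms,
        intervals_1=iv1,
        intervals_2=iv2,
    )

    seq_ok = with_sequence and all(c.sequence is not None for c in g1.chromosomes) and all(
        c.sequence is not None for c in g2.chromosomes
    )

    for block in blocks12:
        if block.orientation >= 0:
            continue
        prox, dist = _adjacent(iv1, block.block_id)
        call_id = f"{block.chrom1}_inv{block.block_id}"

        # polarity from marker order around the proximal breakpoint
        polarity = None
        anchor_iv = prox or dist
        if outgroup is not None and anchor_iv is not None:
            ids1 = marker_order_window(g1, block.chrom1, anchor_iv)
            order2 = order_of_ids(g2, ids1)
            order_out = order_of_ids(outgroup, ids1)
            polarity = infer_polarity(
                ids1, order2, order_out, taxon_a=g1.taxon_id, taxon_b=g2.taxon_id
            )

        # duplication footprints on both arrangements
        dup1 = dup2 = None
        reports: tuple[FlankAlignmentReport, ...] = ()
        recip = None
        mate = _matching_block(block, blocks21)
        if seq_ok and prox and dist:
            f1l, f1r = _flank_pair(g1, block.chrom1, prox, dist, params.flank_width)
            dup1 = detect_inverted_duplication(
                f1l, f1r, params.min_dup_len, params.min_identity
            )
            if mate is not None:
                prox2, dist2 = _adjacent(iv2, mate.block_id)
                if prox2 and dist2:
                    f2l, f2r = _flank_pair(g2, mate.chrom1, prox2, dist2, params.flank_width)
                    dup2 = detect_inverted_duplication(
                        f2l, f2r, params.min_dup_len, params.min_identity
                    )
                    if check_reciprocal:
                        r12 = map_flank(
                            flank_query(g1, prox, params.flank_width), g2,
                            min_hit_len=params.min_hit_len,
                        )
                        # the genome2 interval for the same junction is the
                        # one nearest the breakpoint implied by the hits
                        est = [
                            p for c, p in implied_target_breakpoints(r12)
                            if c == mate.chrom1
                        ]
                        cand = min(
                            (prox2, dist2),
                            key=lambda iv: min(
                                (abs(iv.midpoint - p) for p in est), default=0
                            ),
                        )
                        r21 = map_flank(
                            flank_query(g2, cand, params.flank_width), g1,
                            min_hit_len=params.min_hit_len,
                        )
                        recip = reciprocal_consistency(r12, r21, params.tol)
                        reports = (r12, r21)

        # orient duplication evidence by polarity (reference taxon derived
        # unless the outgroup says otherwise)
        if polarity is not None and polarity.status == "resolved" and (
            polarity.derived_taxon == g2.taxon_id
        ):
            dup_derived, dup_ancestral = dup2, dup1
        else:
            dup_derived, dup_ancestral = dup1, dup2
        if seq_ok and prox and dist:
            mech = classify_mechanism(dup_derived, dup_ancestral)
        else:
            mech = MechanismCall("undetermined")

        genes = g1.chromosome(block.chrom1).markers
        hits: list[str] = []
        for iv in (prox, dist):
            if iv is not None:
                hits.extend(check_gene_disruption(iv, genes).genes)
        disruption = GeneDisruptionCall(disrupted=bool(hits), genes=tuple(dict.fromkeys(hits)))

        analysis.calls.append(
            InversionCall(
                inversion_id=call_id,
                chrom=block.chrom1,
                block_id=block.block_id,
                proximal=prox,
                distal=dist,
                mechanism=mech,
                polarity=polarity,
                disruption=disruption,
                reciprocal_consistent=recip,
                reports=reports,
            )
        )
    return analysis


def report_frame(analysis: PairAnalysis) -> pd.DataFrame:
    """Collated per-event sheet: one row per reversal step of each rearranged
    chromosome's optimal scenario, with breakpoint/mechanism/polarity
    evidence attached where the step corresponds to a single inverted block."""
    scen = analysis.scenarios()
    calls_by_chrom: dict[str, list[InversionCall]] = {}
    for c in analysis.calls:
        calls_by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for chrom in sorted(scen):
        s = scen[chrom]
        chrom_calls = calls_by_chrom.get(chrom, [])
        simple = len(s.reversals) == len(chrom_calls)
        for step, (i, j) in enumerate(s.reversals, start=1):
            row = {
                "chrom": chrom,
                "event": f"{chrom}_h{step}",
                "reversal_start_block": i + 1,
                "reversal_end_block": j + 1,
                "scenario_distance": s.distance,
                "breakpoint_proximal": "",
                "breakpoint_distal": "",
                "mechanism": "",
                "duplication_bp": "",
                "derived_taxon": "",
                "gene_disrupted": "",
            }
            if simple and step <= len(chrom_calls):
                call = chrom_calls[step - 1]
                row.update(
                    breakpoint_proximal=(
                        f"{call.proximal.start}-{call.proximal.end}" if call.proximal else ""
                    ),
                    breakpoint_distal=(
                        f"{call.distal.start}-{call.distal.end}" if call.distal else ""
                    ),
                    mechanism=call.mechanism.mechanism,
                    duplication_bp=(
                        call.mechanism.dup_derived.length if call.mechanism.dup_derived else ""
                    ),
                    derived_taxon=(
                        call.polarity.derived_taxon
                        if call.polarity and call.polarity.status == "resolved"
                        else ""
                    ),
                    gene_disrupted=call.disruption.disrupted,
                )
            rows.append(row)
    return pd.DataFrame(rows)
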