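"""Breakpoint isolation and inversion origin-mechanism classification.

A synteny breakpoint is the nucleotide interval between two contiguous
synteny blocks. Each breakpoint's sequence, plus a flank reaching into the
two bounding blocks, is mapped against the other genome: at a true inversion
breakpoint the query splits into two local hits on opposite relative
strands, each with an overhang where homology ends, and the two mapping
directions must be reciprocally consistent.

Origin mechanisms are then read off the duplication footprint at the flanks:

* inverted duplication in the derived arrangement only  -> staggered breaks
* inverted duplication/repeats in both arrangements     -> ectopic recombination
* no duplication above the detection floor              -> straight or nearly
  straight breaks (staggered cuts too short to leave long-lasting traces)
* duplication in the ancestral arrangement only         -> undetermined (flagged)

Flank-to-genome mapping uses exact seed-and-extend (the simulator introduces
no substitutions, so hits are exact); inverted-duplication detection, where
length and identity thresholds matter, uses an affine-gap local aligner
(match +1, mismatch -2, gap open -4, extend -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .genome import Marker, MarkerGenome, revcomp
from .simulate import RepeatRecord
from .synteny import SyntenyBlock

DEFAULT_FLANK_WIDTH = 5000
DEFAULT_MIN_DUP_LEN = 50
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_RECIPROCAL_TOL = 1000


# ---------------------------------------------------------------------------
# breakpoint intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointInterval:
    """Gap between two adjacent synteny blocks on the reference genome
    (half-open; zero-length when blocks abut)."""

    chrom: str
    start: int
    end: int
    left_block: int
    right_block: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"breakpoint {self.label}: start > end")
        if self.left_block == self.right_block:
            raise ValueError(f"breakpoint {self.label}: must be flanked by distinct blocks")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def breakpoint_intervals(blocks: list[SyntenyBlock]) -> list[BreakpointInterval]:
    """One interval per adjacent block pair, per genome1 chromosome, labelled
    ``<chrom>_bp<i>`` proximal (centromere end) to distal."""
    out: list[BreakpointInterval] = []
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom1, []).append(b)
    for chrom in sorted(by_chrom):
        tiled = sorted(by_chrom[chrom], key=lambda b: b.span1)
        for i in range(len(tiled) - 1):
            left, right = tiled[i], tiled[i + 1]
            out.append(
                BreakpointInterval(
                    chrom=chrom,
                    start=left.span1[1],
                    end=max(left.span1[1], right.span1[0]),
                    left_block=left.block_id,
                    right_block=right.block_id,
                    label=f"{chrom}_bp{i + 1}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# flank mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlankQuery:
    """A breakpoint interval plus ``flank_width`` into each bounding block."""

    taxon: str
    chrom: str
    window: tuple[int, int]  # query window in genome coordinates
    breakpoints: tuple[int, int]  # the breakpoint interval inside the window
    sequence: str


def flank_query(
    genome: MarkerGenome, interval: BreakpointInterval, flank_width: int = DEFAULT_FLANK_WIDTH
) -> FlankQuery:
    chrom = genome.chromosome(interval.chrom)
    lo = max(0, interval.start - flank_width)
    hi = min(chrom.length, interval.end + flank_width)
    return FlankQuery(
        taxon=genome.taxon_id,
        chrom=interval.chrom,
        window=(lo, hi),
        breakpoints=(interval.start, interval.end),
        sequence=chrom.fetch(lo, hi),
    )


@dataclass(frozen=True)
class FlankHit:
    target_chrom: str
    target_span: tuple[int, int]
    strand: str  # relative strand of the hit
    query_span: tuple[int, int]  # offsets within the query window
    length: int
    identity: float

    @property
    def overhang_left(self) -> int:
        return self.query_span[0]

    @property
    def overhang_right(self) -> int:
        return self._qlen - self.query_span[1]

    # populated by map_flank via object.__setattr__ (frozen dataclass)
    _qlen: int = field(default=0, repr=False)


@dataclass
class FlankAlignmentReport:
    query: FlankQuery
    hits: list[FlankHit]
    reciprocal_consistent: bool | None = None


def _plus_strand_hits(
    query: str,
    target: str,
    min_hit_len: int,
    seed_len: int,
    max_occ: int,
    seed_step: int | None = None,
):
    """Exact seed-and-extend hits of ``query`` on the forward strand of
    ``target``: (qstart, qend, tstart, tend) tuples."""
    n = len(query)
    if n < seed_len or len(target) < seed_len:
        return []
    step = seed_step or seed_len
    seed_starts = list(range(0, n - seed_len + 1, step))
    if seed_starts[-1] != n - seed_len:
        seed_starts.append(n - seed_len)
    by_diag: dict[int, list[int]] = {}
    for p in seed_starts:
        seed = query[p : p + seed_len]
        pos = target.find(seed)
        occ = 0
        while pos != -1 and occ < max_occ:
            by_diag.setdefault(pos - p, []).append(p)
            occ += 1
            pos = target.find(seed, pos + 1)
    raw = []
    for diag, ps in by_diag.items():
        ps.sort()
        # extend each seeded region; merge touching extensions on the diagonal
        cur = None
        for p in ps:
            qlo, qhi = p, p + seed_len
            if cur and qlo <= cur[1]:
                cur[1] = max(cur[1], qhi)
                continue
            if cur:
                raw.append((diag, cur[0], cur[1]))
            cur = [qlo, qhi]
        if cur:
            raw.append((diag, cur[0], cur[1]))
    hits = []
    seen: set[tuple[int, int, int]] = set()
    for diag, qlo, qhi in raw:
        while qlo > 0 and diag + qlo > 0 and query[qlo - 1] == target[diag + qlo - 1]:
            qlo -= 1
        while qhi < n and diag + qhi < len(target) and query[qhi] == target[diag + qhi]:
            qhi += 1
        key = (diag, qlo, qhi)
        if key in seen or qhi - qlo < min_hit_len:
            continue
        seen.add(key)
        hits.append((qlo, qhi, diag + qlo, diag + qhi))
    return hits


def map_flank(
    query: FlankQuery,
    target: MarkerGenome,
    min_hit_len: int = 100,
    seed_len: int = 32,
    max_occ: int = 50,
    seed_step: int = 128,
) -> FlankAlignmentReport:
    """Map a flank query against every chromosome of the target genome on
    both strands. Hits are maximal exact matches (identity 1.0) sorted by
    decreasing length; overhangs are the unaligned query bases beyond each
    hit terminus. ``seed_step`` bounds the smallest reliably seeded hit to
    seed_step + seed_len bases."""
    q = query.sequence
    qlen = len(q)
    rc_q = revcomp(q)
    hits: list[FlankHit] = []
    for chrom in target.chromosomes:
        if chrom.sequence is None:
            raise ValueError(f"target chromosome {chrom.name} carries no sequence")
        t = chrom.sequence
        for qlo, qhi, tlo, thi in _plus_strand_hits(
            q, t, min_hit_len, seed_len, max_occ, seed_step
        ):
            h = FlankHit(chrom.name, (tlo, thi), "+", (qlo, qhi), qhi - qlo, 1.0)
            object.__setattr__(h, "_qlen", qlen)
            hits.append(h)
        for qlo, qhi, tlo, thi in _plus_strand_hits(
            rc_q, t, min_hit_len, seed_len, max_occ, seed_step
        ):
            # convert reverse-strand coordinates back to query space
            h = FlankHit(chrom.name, (tlo, thi), "-", (qlen - qhi, qlen - qlo), qhi - qlo, 1.0)
            object.__setattr__(h, "_qlen", qlen)
            hits.append(h)
    hits.sort(key=lambda h: (-h.length, h.target_chrom, h.target_span))
    return FlankAlignmentReport(query=query, hits=hits)


def _sided_hits(report: FlankAlignmentReport, slack: int):
    """Hits whose terminus faces the query's breakpoint interval: pairs
    (hit, side) with side "proximal" (hit covers the window start, ends near
    the interval) or "distal" (starts near the interval, covers the end)."""
    lo, _hi = report.query.window
    bl = report.query.breakpoints[0] - lo
    br = report.query.breakpoints[1] - lo
    out = []
    for h in report.hits:
        qlo, qhi = h.query_span
        if qlo < bl and bl - slack <= qhi <= br + slack:
            out.append((h, "proximal"))
        if qhi > br and bl - slack <= qlo <= br + slack:
            out.append((h, "distal"))
    return out


def implied_target_breakpoints(
    report: FlankAlignmentReport, slack: int = DEFAULT_RECIPROCAL_TOL
) -> list[tuple[str, int]]:
    """Target-space estimates of the breakpoint: for each hit facing the
    query's breakpoint interval, the target coordinate of the terminus where
    homology ends."""
    out = []
    for h, side in _sided_hits(report, slack):
        if side == "proximal":
            out.append((h.target_chrom, h.target_span[1] if h.strand == "+" else h.target_span[0]))
        else:
            out.append((h.target_chrom, h.target_span[0] if h.strand == "+" else h.target_span[1]))
    return out


def query_side_breakpoints(
    report: FlankAlignmentReport, slack: int = DEFAULT_RECIPROCAL_TOL
) -> list[tuple[str, int]]:
    """Query-genome estimates of the breakpoint: the query coordinate of
    each facing hit's terminus (alignment-resolution refinement of the
    breakpoint interval on the query's own genome)."""
    lo, _hi = report.query.window
    out = []
    for h, side in _sided_hits(report, slack):
        qpos = h.query_span[1] if side == "proximal" else h.query_span[0]
        out.append((report.query.chrom, lo + qpos))
    return out


def reciprocal_consistency(
    report_1to2: FlankAlignmentReport,
    report_2to1: FlankAlignmentReport,
    tol: int = DEFAULT_RECIPROCAL_TOL,
) -> bool:
    """True iff the breakpoint each direction implies in the other genome
    coincides, within ``tol`` bp, with the breakpoint the other direction
    refines on its own genome."""
    if not report_1to2.hits or not report_2to1.hits:
        return False
    slack = max(tol, 5 * DEFAULT_RECIPROCAL_TOL)

    def direction_ok(src: FlankAlignmentReport, dst: FlankAlignmentReport) -> bool:
        est = implied_target_breakpoints(src, slack=slack)
        own = query_side_breakpoints(dst, slack=slack)
        return any(
            ce == co and abs(pe - po) <= tol for ce, pe in est for co, po in own
        )

    return direction_ok(report_1to2, report_2to1) and direction_ok(report_2to1, report_1to2)


# ---------------------------------------------------------------------------
# inverted duplications and mechanism calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationCall:
    length: int
    identity: float
    orientation: str = "inverted"
    presence: str | None = None  # "derived_only" | "both_arrangements"


def _affine_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def detect_inverted_duplication(
    flank_left: str,
    flank_right: str,
    min_dup_len: int = DEFAULT_MIN_DUP_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> DuplicationCall | None:
    """Best affine-gap local alignment of the left flank against the reverse
    complement of the right flank; a DuplicationCall when aligned length and
    identity clear the floors, else None.

    Candidate regions are located first with short exact seeds (12 bp), so a
    reportable duplication must retain at least one 12 bp exact stretch —
    comfortably implied by the identity floor in practice — and the affine
    aligner then scores a bounded slice around the best seeded region."""
    if len(flank_left) < min_dup_len or len(flank_right) < min_dup_len:
        return None
    rc_full = revcomp(flank_right)
    seeds = _plus_strand_hits(flank_left, rc_full, min_hit_len=12, seed_len=12, max_occ=50)
    if not seeds:
        return None
    qlo, qhi, tlo, thi = max(seeds, key=lambda h: h[1] - h[0])
    pad = 2 * min_dup_len + 200
    qa, qb = max(0, qlo - pad), min(len(flank_left), qhi + pad)
    ta, tb = max(0, tlo - pad), min(len(rc_full), thi + pad)
    flank_left = flank_left[qa:qb]
    flank_right = revcomp(rc_full[ta:tb])
    aligner = _affine_local_aligner()
    alignments = aligner.align(flank_left, revcomp(flank_right))
    if alignments.score <= 0:
        return None
    best = alignments[0]
    blocks_q, blocks_t = best.aligned
    rc_right = revcomp(flank_right)
    # per-column (query position, is_match) over the aligned blocks
    columns: list[tuple[int, bool]] = []
    for (qa, qb), (ta, tb) in zip(blocks_q, blocks_t):
        for off in range(qb - qa):
            columns.append((qa + off, flank_left[qa + off] == rc_right[ta + off]))
    if not columns:
        return None
    # trim ends to solid exact-match runs: spurious extensions across
    # coincidental matches are short islands, true duplication termini are
    # long exact runs
    run = min(10, min_dup_len)
    flags = [m for _, m in columns]

    def run_start(seq_flags):
        streak = 0
        for i, m in enumerate(seq_flags):
            streak = streak + 1 if m else 0
            if streak >= run:
                return i - run + 1
        return None

    lo = run_start(flags)
    hi_rev = run_start(flags[::-1])
    if lo is None or hi_rev is None:
        return None
    hi = len(flags) - 1 - hi_rev
    if hi < lo:
        return None
    kept = columns[lo : hi + 1]
    length = int(kept[-1][0] - kept[0][0] + 1)
    identity = sum(m for _, m in kept) / len(kept)
    if length >= min_dup_len and identity >= min_identity:
        return DuplicationCall(length=length, identity=identity)
    return None


MECHANISM_LABELS = (
    "staggered",
    "straight_or_nearly_straight",
    "ectopic_recombination",
    "undetermined",
)


@dataclass(frozen=True)
class MechanismCall:
    mechanism: str
    dup_derived: DuplicationCall | None = None
    dup_ancestral: DuplicationCall | None = None


def classify_mechanism(
    dup_derived: DuplicationCall | None, dup_ancestral: DuplicationCall | None
) -> MechanismCall:
    """Read the origin mechanism off the duplication footprint (polarity must
    already be known)."""
    if dup_derived and dup_ancestral:
        mech = "ectopic_recombination"
        dup_derived = DuplicationCall(
            dup_derived.length, dup_derived.identity, presence="both_arrangements"
        )
        dup_ancestral = DuplicationCall(
            dup_ancestral.length, dup_ancestral.identity, presence="both_arrangements"
        )
    elif dup_derived:
        mech = "staggered"
        dup_derived = DuplicationCall(
            dup_derived.length, dup_derived.identity, presence="derived_only"
        )
    elif dup_ancestral:
        mech = "undetermined"
    else:
        mech = "straight_or_nearly_straight"
    return MechanismCall(mech, dup_derived, dup_ancestral)


# ---------------------------------------------------------------------------
# gene disruption and repeat content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneDisruptionCall:
    disrupted: bool
    genes: tuple[str, ...]


def check_gene_disruption(
    interval: BreakpointInterval, markers: list[Marker]
) -> GeneDisruptionCall:
    """Markers whose body overlaps the breakpoint interval (half-open
    intersection; zero-length intervals are tested as a point strictly inside
    a gene body)."""
    if interval.start == interval.end:
        hit = [m.id for m in markers if m.start < interval.start < m.end]
    else:
        hit = [m.id for m in markers if m.start < interval.end and interval.start < m.end]
    return GeneDisruptionCall(disrupted=bool(hit), genes=tuple(hit))


def flank_repeat_fraction(
    interval: BreakpointInterval,
    repeats: list[RepeatRecord],
    flank_width: int = DEFAULT_FLANK_WIDTH,
) -> float:
    """Fraction of the breakpoint's flanked window covered by annotated
    repeats (the screen used to ask whether one chromosome's faster
    structural evolution is a repeat-driven mutational bias)."""
    lo = max(0, interval.start - flank_width)
    hi = interval.end + flank_width
    if hi <= lo:
        return 0.0
    spans = sorted(
        (max(lo, r.start), min(hi, r.end))
        for r in repeats
        if r.chrom == interval.chrom and r.start < hi and r.end > lo
    )
    covered, cur_lo, cur_hi = 0, None, None
    for a, b in spans:
        if cur_hi is None or a > cur_hi:
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
        else:
            cur_hi = max(cur_hi, b)
    if cur_hi is not None:
        covered += cur_hi - cur_lo
    return covered / (hi - lo)
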