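"""Genome-rearrangement simulator with known ground truth.

Generates marker-annotated genomes, applies paracentric inversions along a
species tree, and records every event so the downstream pipeline (synteny ->
breakpoints -> history) can be validated against truth.

Three origin mechanisms are modelled, matching their molecular footprints:

* ``straight``   — two clean cuts; the segment is reverse-complemented in
  place, no duplication, length unchanged.
* ``staggered``  — offset cuts; the two stagger fragments (lengths
  ``offset_left`` / ``offset_right``) are duplicated in inverted orientation
  on the flanks of the derived arrangement, growing the genome by their sum.
* ``ectopic``    — recombination between a pre-placed pair of inverted repeat
  copies; the segment between the copy midpoints is inverted and a full
  repeat copy is reconstituted on each flank, so repeats are present at the
  breakpoints of *both* the ancestral and the derived arrangement.

Cut geometry for staggered breaks (a documented convention, since only the
resulting footprint is observable):

    derived = s[:l] + s[l:l+oL] + revcomp(s[l:r]) + s[r-oR:r] + s[r:]

Each flank of the derived segment then carries an inverted duplicate of the
opposite flank's stagger fragment.

Coordinates are 0-based half-open throughout. Position 0 of every chromosome
is the centromere end (acrocentric convention) and ``length`` the telomere
end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import Chromosome, Marker, MarkerGenome, revcomp
from .tree import SpeciesTree

MECHANISMS = ("straight", "staggered", "ectopic")
STATES = ("fixed", "polymorphic")

# paper-scale chromosome template: five large acrocentric rods plus a dot,
# lengths in bp (A, J, U, E, O, dot)
TEMPLATE_CHROM_NAMES = ("A", "J", "U", "E", "O", "dot")
TEMPLATE_CHROM_LENGTHS = (22_857_882, 23_583_473, 25_800_175, 20_818_511, 30_426_146, 1_375_632)


# ---------------------------------------------------------------------------
# event and truth types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InversionEvent:
    """One inversion on the pre-event coordinate system of its branch."""

    event_id: str
    chrom: str
    left_bp: int
    right_bp: int
    mechanism: str = "straight"
    offset_left: int = 0
    offset_right: int = 0
    repeat_id: str | None = None
    branch: str = ""
    terminal_state: str = "fixed"
    disrupt: bool = False

    def __post_init__(self) -> None:
        if self.left_bp >= self.right_bp:
            raise ValueError(f"event {self.event_id}: left_bp must be < right_bp")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"event {self.event_id}: unknown mechanism {self.mechanism!r}")
        if self.offset_left < 0 or self.offset_right < 0:
            raise ValueError(f"event {self.event_id}: negative stagger offset")
        if self.mechanism != "staggered" and (self.offset_left or self.offset_right):
            raise ValueError(f"event {self.event_id}: offsets only apply to staggered events")
        if self.mechanism == "ectopic" and not self.repeat_id:
            raise ValueError(f"event {self.event_id}: ectopic events need a repeat_id")
        if self.terminal_state not in STATES:
            raise ValueError(f"event {self.event_id}: state must be one of {STATES}")


@dataclass(frozen=True)
class RepeatPair:
    """A pre-placed pair of inverted repeat copies enabling ectopic events."""

    repeat_id: str
    chrom: str
    span1: tuple[int, int]
    span2: tuple[int, int]

    @property
    def length(self) -> int:
        return self.span1[1] - self.span1[0]

    @property
    def midpoints(self) -> tuple[int, int]:
        return ((self.span1[0] + self.span1[1]) // 2, (self.span2[0] + self.span2[1]) // 2)


@dataclass(frozen=True)
class DuplicationRecord:
    event_id: str
    length: int
    placement: str  # "left" or "right" stagger fragment


@dataclass
class TruthTable:
    """Ground truth for one simulated subgroup history."""

    events: list[InversionEvent]
    realized: dict[tuple[str, str], tuple[int, int]]  # (taxon, event_id) -> (left, right)
    arrangements: dict[str, tuple[str, ...]]  # taxon -> event ids carried (derived haplotype)
    duplications: list[DuplicationRecord]
    seed: int | None = None

    def events_on_branch(self, branch: str) -> list[InversionEvent]:
        return [e for e in self.events if e.branch == branch]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "chrom": e.chrom,
                    "left_bp": e.left_bp,
                    "right_bp": e.right_bp,
                    "mechanism": e.mechanism,
                    "offset_left": e.offset_left,
                    "offset_right": e.offset_right,
                    "branch": e.branch,
                    "state": e.terminal_state,
                }
                for e in self.events
            ]
        )


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide string with the stated GC content (default base
    composition of the generator is GC 45%)."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def make_ancestral_genome(
    n_chrom: int,
    chrom_lengths: list[int],
    n_markers: int | list[int],
    seed: int,
    chrom_names: list[str] | None = None,
    marker_length: int = 1000,
    gc: float = 0.45,
    with_sequence: bool = True,
    taxon_id: str = "ancestor",
) -> MarkerGenome:
    """Ancestral genome: markers placed uniformly without overlap, random
    strands, intergenic sequence drawn at the stated base composition.

    ``n_markers`` is the per-chromosome marker count (a single int applies to
    every chromosome). Raises if the requested markers cannot fit.
    """
    if len(chrom_lengths) != n_chrom:
        raise ValueError("chrom_lengths must have n_chrom entries")
    counts = [n_markers] * n_chrom if isinstance(n_markers, int) else list(n_markers)
    if len(counts) != n_chrom:
        raise ValueError("n_markers list must have n_chrom entries")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = np.random.SeedSequence(seed).spawn(n_chrom)
    chroms = []
    for name, length, count, ss in zip(chrom_names, chrom_lengths, counts, seqs):
        rng = np.random.default_rng(ss)
        if length <= 0:
            raise ValueError(f"chromosome {name}: non-positive length")
        free = length - count * marker_length
        if count < 0 or free < 0:
            raise ValueError(
                f"chromosome {name}: cannot fit {count} markers of {marker_length} bp in {length} bp"
            )
        u = np.sort(rng.random(count))
        starts = (u * (free + 1)).astype(np.int64) + marker_length * np.arange(count)
        markers = [
            Marker(
                id=f"m{name}_{i:04d}",
                start=int(s),
                end=int(s) + marker_length,
                strand="+" if rng.random() < 0.5 else "-",
            )
            for i, s in enumerate(starts)
        ]
        sequence = random_sequence(length, gc, rng) if with_sequence else None
        chroms.append(Chromosome(name=name, length=length, markers=markers, sequence=sequence))
    return MarkerGenome(taxon_id=taxon_id, chromosomes=chroms)


def template_genome(
    scale: float = 1.0,
    markers_per_mb: float = 100.0,
    seed: int = 0,
    with_sequence: bool = True,
    marker_length: int | None = None,
) -> MarkerGenome:
    """Paper-scale karyotype (five rods A,J,U,E,O plus the dot), optionally
    scaled down. Marker density defaults to ~100/Mb of the *scaled* genome so
    that anchor spacing shrinks with the assembly."""
    lengths = [max(2000, int(L * scale)) for L in TEMPLATE_CHROM_LENGTHS]
    counts = [max(2, int(markers_per_mb * L / 1e6)) for L in lengths]
    if marker_length is None:
        marker_length = max(50, min(1000, lengths[0] // (4 * counts[0])))
    return make_ancestral_genome(
        n_chrom=6,
        chrom_lengths=lengths,
        n_markers=counts,
        seed=seed,
        chrom_names=list(TEMPLATE_CHROM_NAMES),
        marker_length=marker_length,
        with_sequence=with_sequence,
    )


# ---------------------------------------------------------------------------
# applying events
# ---------------------------------------------------------------------------


def _split_disrupted(markers: list[Marker], cuts: tuple[int, ...]) -> list[Marker]:
    out = list(markers)
    for c in cuts:
        new = []
        for m in out:
            if m.start < c < m.end:
                new.append(Marker(m.id + ".5p", m.start, c, m.strand))
                new.append(Marker(m.id + ".3p", c, m.end, m.strand))
            else:
                new.append(m)
        out = new
    return out


def _event_geometry(
    chrom: Chromosome, event: InversionEvent, repeat_pairs: dict[str, RepeatPair] | None
) -> tuple[int, int, int, int]:
    """Resolve (l, r, oL, oR) for an event on a chromosome."""
    if event.mechanism == "ectopic":
        if not repeat_pairs or event.repeat_id not in repeat_pairs:
            raise ValueError(
                f"event {event.event_id}: no inverted repeat pair named {event.repeat_id!r}"
            )
        pair = repeat_pairs[event.repeat_id]
        if pair.chrom != event.chrom:
            raise ValueError(f"event {event.event_id}: repeat pair lies on {pair.chrom}")
        l, r = pair.midpoints
        return l, r, 0, 0
    return event.left_bp, event.right_bp, event.offset_left, event.offset_right


def apply_inversion(
    genome: MarkerGenome,
    event: InversionEvent,
    repeat_pairs: dict[str, RepeatPair] | None = None,
) -> MarkerGenome:
    """Return a new genome with ``event`` applied (see module docstring for
    the cut geometry). Breakpoints must be intergenic unless
    ``event.disrupt`` is set, in which case the straddled marker is split
    into 5'/3' pieces."""
    new_genome, _ = _apply_event(genome, event, repeat_pairs)
    return new_genome


def _apply_event(
    genome: MarkerGenome,
    event: InversionEvent,
    repeat_pairs: dict[str, RepeatPair] | None = None,
):
    chrom = genome.chromosome(event.chrom)
    l, r, oL, oR = _event_geometry(chrom, event, repeat_pairs)
    if not (0 <= l < r <= chrom.length):
        raise ValueError(f"event {event.event_id}: breakpoints outside chromosome {chrom.name}")
    if r - l < oL + oR:
        raise ValueError(f"event {event.event_id}: stagger offsets exceed the segment length")

    markers = list(chrom.markers)
    straddled = [m for m in markers for c in (l, r) if m.start < c < m.end]
    if straddled and not event.disrupt:
        raise ValueError(
            f"event {event.event_id}: breakpoint inside marker(s) "
            f"{[m.id for m in straddled]} (set disrupt=True to simulate gene disruption)"
        )
    if straddled:
        markers = _split_disrupted(markers, (l, r))
    for m in markers:
        if (l < m.end and m.start < l + oL) or (r - oR < m.end and m.start < r):
            if m.start < l or m.end > r:
                continue  # outside the segment entirely
            raise ValueError(
                f"event {event.event_id}: marker {m.id} overlaps a stagger fragment"
            )

    shift = oL + oR

    def map_cut(c: int) -> int:
        """Carry a cut coordinate through this event."""
        if c < l:
            return c
        if c <= r:
            return l + oL + (r - c)
        return c + shift

    new_markers: list[Marker] = []
    for m in markers:
        if m.end <= l:
            new_markers.append(m)
        elif m.start >= r:
            new_markers.append(replace(m, start=m.start + shift, end=m.end + shift))
        else:  # fully inside [l, r): reflect and flip strand
            ns = l + oL + (r - m.end)
            ne = l + oL + (r - m.start)
            new_markers.append(
                Marker(m.id, ns, ne, "+" if m.strand == "-" else "-")
            )

    sequence = None
    if chrom.sequence is not None:
        s = chrom.sequence
        sequence = s[:l] + s[l : l + oL] + revcomp(s[l:r]) + s[r - oR : r] + s[r:]

    new_chrom = Chromosome(
        name=chrom.name, length=chrom.length + shift, markers=new_markers, sequence=sequence
    )
    new_chroms = [new_chrom if c.name == chrom.name else c for c in genome.chromosomes]
    return MarkerGenome(genome.taxon_id, new_chroms), (l, r, oL, oR, map_cut)


def _map_interval(span: tuple[int, int], l: int, r: int, oL: int, oR: int) -> tuple[int, int]:
    """Carry an interval through an event; it must not straddle a breakpoint."""
    a, b = span
    shift = oL + oR
    if b <= l:
        return a, b
    if a >= r:
        return a + shift, b + shift
    if l <= a and b <= r:
        return l + oL + (r - b), l + oL + (r - a)
    raise ValueError(f"interval {span} straddles a breakpoint at ({l}, {r})")


# ---------------------------------------------------------------------------
# repeat pairs for ectopic events
# ---------------------------------------------------------------------------


def place_inverted_repeat_pair(
    genome: MarkerGenome,
    repeat_id: str,
    chrom: str,
    pos1: int,
    pos2: int,
    length: int,
    seed: int,
    gc: float = 0.45,
) -> tuple[MarkerGenome, RepeatPair]:
    """Write a repeat copy at ``pos1`` and its reverse complement at ``pos2``
    (both marker-free intergenic loci), returning the modified genome and the
    pair record needed by ectopic events."""
    c = genome.chromosome(chrom)
    if not (0 <= pos1 and pos1 + length <= pos2 and pos2 + length <= c.length):
        raise ValueError(f"repeat pair {repeat_id}: spans out of order or out of bounds")
    for m in c.markers:
        for a, b in ((pos1, pos1 + length), (pos2, pos2 + length)):
            if m.start < b and a < m.end:
                raise ValueError(f"repeat pair {repeat_id}: overlaps marker {m.id}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    unit = random_sequence(length, gc, rng)
    new_chroms = []
    for ch in genome.chromosomes:
        if ch.name != chrom or ch.sequence is None:
            new_chroms.append(ch)
            continue
        s = ch.sequence
        s = s[:pos1] + unit + s[pos1 + length : pos2] + revcomp(unit) + s[pos2 + length :]
        new_chroms.append(Chromosome(ch.name, ch.length, list(ch.markers), s))
    pair = RepeatPair(repeat_id, chrom, (pos1, pos1 + length), (pos2, pos2 + length))
    return MarkerGenome(genome.taxon_id, new_chroms), pair


# ---------------------------------------------------------------------------
# evolving a subgroup
# ---------------------------------------------------------------------------


@dataclass
class SubgroupSimulation:
    genomes: dict[str, MarkerGenome]  # tip -> derived haplotype (all its events)
    alt_haplotypes: dict[str, MarkerGenome]  # tip -> standard haplotype (fixed events only)
    truth: TruthTable


def evolve_subgroup(
    ancestral: MarkerGenome,
    tree: SpeciesTree,
    events: list[InversionEvent],
    repeat_pairs: list[RepeatPair] | None = None,
    outgroup: str | None = None,
    seed: int | None = None,
) -> SubgroupSimulation:
    """Run the listed events down the tree and return one genome per tip.

    Events on one branch are applied in listed order. Polymorphic events are
    allowed on terminal branches only; a tip carrying any emits a second
    "standard" haplotype that lacks them. ``outgroup``, when given, adds an
    unrearranged copy of the ancestor under that taxon name. The TruthTable
    records each event's realized breakpoint coordinates per tip after all
    coordinate shifts from earlier events.
    """
    by_branch: dict[str, list[InversionEvent]] = {}
    ids = set()
    for e in events:
        if e.event_id in ids:
            raise ValueError(f"duplicate event id {e.event_id}")
        ids.add(e.event_id)
        if e.branch not in tree.branches:
            raise ValueError(f"event {e.event_id}: unknown branch {e.branch!r}")
        if e.terminal_state == "polymorphic" and not tree.is_tip(e.branch):
            raise ValueError(
                f"event {e.event_id}: polymorphic events are only supported on terminal branches"
            )
        by_branch.setdefault(e.branch, []).append(e)

    pair_list = list(repeat_pairs or [])

    def walk(tip: str, include_polymorphic: bool):
        genome = ancestral.with_taxon(tip)
        pairs = {p.repeat_id: p for p in pair_list}
        tracked: dict[str, tuple[str, int, int]] = {}  # event -> (chrom, left, right)
        carried: list[str] = []
        for branch in tree.path_to(tip):
            for e in by_branch.get(branch, []):
                if e.terminal_state == "polymorphic" and not include_polymorphic:
                    continue
                genome, (l, r, oL, oR, map_cut) = _apply_event(genome, e, pairs)
                for eid, (chrom, a, b) in tracked.items():
                    if chrom == e.chrom:
                        tracked[eid] = (chrom, *sorted((map_cut(a), map_cut(b))))
                new_pairs = {}
                for pid, p in pairs.items():
                    if p.chrom != e.chrom:
                        new_pairs[pid] = p
                        continue
                    s1 = _map_interval(p.span1, l, r, oL, oR)
                    s2 = _map_interval(p.span2, l, r, oL, oR)
                    s1, s2 = sorted((s1, s2))
                    new_pairs[pid] = RepeatPair(pid, p.chrom, s1, s2)
                pairs = new_pairs
                tracked[e.event_id] = (e.chrom, l, r + oL + oR)
                carried.append(e.event_id)
        return genome, tracked, tuple(carried)

    genomes: dict[str, MarkerGenome] = {}
    alt: dict[str, MarkerGenome] = {}
    realized: dict[tuple[str, str], tuple[int, int]] = {}
    arrangements: dict[str, tuple[str, ...]] = {}
    for tip in tree.tips:
        g, tracked, carried = walk(tip, include_polymorphic=True)
        genomes[tip] = g
        arrangements[tip] = carried
        for eid, (chrom, a, b) in tracked.items():
            realized[(tip, eid)] = (a, b)
        has_poly = any(
            e.terminal_state == "polymorphic" for e in by_branch.get(tip, [])
        )
        if has_poly:
            alt[tip], _, _ = walk(tip, include_polymorphic=False)
    if outgroup is not None:
        genomes[outgroup] = ancestral.with_taxon(outgroup)
        arrangements[outgroup] = ()

    dups = [
        DuplicationRecord(e.event_id, off, side)
        for e in events
        if e.mechanism == "staggered"
        for side, off in (("left", e.offset_left), ("right", e.offset_right))
        if off > 0
    ]
    truth = TruthTable(
        events=list(events),
        realized=realized,
        arrangements=arrangements,
        duplications=dups,
        seed=seed,
    )
    return SubgroupSimulation(genomes=genomes, alt_haplotypes=alt, truth=truth)


# ---------------------------------------------------------------------------
# scenario planning helpers
# ---------------------------------------------------------------------------


def snap_intergenic(chrom: Chromosome, pos: int, min_room: int = 0) -> int:
    """Move ``pos`` to the midpoint of the nearest intergenic gap wide
    enough to leave ``min_room`` bp on each side of the cut. Keeps simulated
    breakpoints (and stagger fragments) out of gene bodies."""
    bounds = [0]
    for m in chrom.markers:
        bounds.extend((m.start, m.end))
    bounds.append(chrom.length)
    gaps = [
        (bounds[i], bounds[i + 1])
        for i in range(0, len(bounds) - 1, 2)
        if bounds[i + 1] - bounds[i] >= max(1, 2 * min_room)
    ]
    if not gaps:
        raise ValueError(
            f"chromosome {chrom.name}: no intergenic gap of >= {2 * min_room} bp"
        )
    for a, b in gaps:
        if a <= pos < b:
            return (a + b) // 2
    a, b = min(gaps, key=lambda g: min(abs(pos - g[0]), abs(pos - g[1])))
    return (a + b) // 2


@dataclass(frozen=True)
class EventSpec:
    """Declarative event: breakpoints as fractions of the chromosome length,
    snapped to intergenic gaps on the evolving genome at planning time."""

    event_id: str
    chrom: str
    frac_left: float
    frac_right: float
    branch: str
    mechanism: str = "straight"
    offset_left: int = 0
    offset_right: int = 0
    repeat_id: str | None = None
    terminal_state: str = "fixed"


def plan_events(
    ancestral: MarkerGenome,
    tree: SpeciesTree,
    specs: list[EventSpec],
    repeat_pairs: list[RepeatPair] | None = None,
) -> list[InversionEvent]:
    """Turn fractional EventSpecs into concrete InversionEvents by replaying
    the history branch by branch, so each event's coordinates refer to the
    genome state it actually applies to."""
    by_branch: dict[str, list[EventSpec]] = {}
    for s in specs:
        by_branch.setdefault(s.branch, []).append(s)
    pairs0 = {p.repeat_id: p for p in (repeat_pairs or [])}

    events: dict[str, InversionEvent] = {}
    order: list[str] = []

    def descend(node: str, genome: MarkerGenome, pairs: dict[str, RepeatPair]) -> None:
        for spec in by_branch.get(node, []):
            chrom = genome.chromosome(spec.chrom)
            if spec.mechanism == "ectopic":
                ev = InversionEvent(
                    event_id=spec.event_id,
                    chrom=spec.chrom,
                    left_bp=pairs[spec.repeat_id].midpoints[0],
                    right_bp=pairs[spec.repeat_id].midpoints[1],
                    mechanism="ectopic",
                    repeat_id=spec.repeat_id,
                    branch=spec.branch,
                    terminal_state=spec.terminal_state,
                )
            else:
                room_l = spec.offset_left + 50 if spec.offset_left else 0
                room_r = spec.offset_right + 50 if spec.offset_right else 0
                l = snap_intergenic(chrom, int(spec.frac_left * chrom.length), room_l)
                r = snap_intergenic(chrom, int(spec.frac_right * chrom.length), room_r)
                if l >= r:
                    raise ValueError(f"spec {spec.event_id}: snapped breakpoints collapsed")
                ev = InversionEvent(
                    event_id=spec.event_id,
                    chrom=spec.chrom,
                    left_bp=l,
                    right_bp=r,
                    mechanism=spec.mechanism,
                    offset_left=spec.offset_left,
                    offset_right=spec.offset_right,
                    branch=spec.branch,
                    terminal_state=spec.terminal_state,
                )
            genome, (el, er, oL, oR, _map) = _apply_event(genome, ev, pairs)
            new_pairs = {}
            for pid, p in pairs.items():
                if p.chrom != ev.chrom:
                    new_pairs[pid] = p
                    continue
                s1 = _map_interval(p.span1, el, er, oL, oR)
                s2 = _map_interval(p.span2, el, er, oL, oR)
                s1, s2 = sorted((s1, s2))
                new_pairs[pid] = RepeatPair(pid, p.chrom, s1, s2)
            pairs = new_pairs
            events[spec.event_id] = ev
            order.append(spec.event_id)
        for child in tree.children.get(node, []):
            descend(child, genome, pairs)

    for child in tree.children[tree.root]:
        descend(child, ancestral, dict(pairs0))
    # keep the original spec order for reporting
    spec_order = [s.event_id for s in specs]
    return sorted(events.values(), key=lambda e: spec_order.index(e.event_id))


def paper_template_specs(
    mainland: str = "subobscura",
    ancestor: str = "ms",
    island_lineage: str = "guanche",
    duplication_lengths: tuple[int, int, int, int] = (689, 1007, 513, 538),
) -> list[EventSpec]:
    """The 12-event template history: six events on chromosome A of the
    mainland lineage (four overlapping proximal + two distal), three fixed
    autosomal events (one on the pre-split ancestor branch), two polymorphic
    events on U, and one fixed event on the other island lineage. Four of the
    events are staggered with the observed duplication lengths (689, 1007,
    513 and 538 bp by default)."""
    dU1, dU2, dE, dO = duplication_lengths
    return [
        # four overlapping inversions in the proximal half of A
        EventSpec("A_h1", "A", 0.05, 0.25, mainland),
        EventSpec("A_h2", "A", 0.15, 0.35, mainland),
        EventSpec("A_h3", "A", 0.10, 0.30, mainland),
        EventSpec("A_h4", "A", 0.20, 0.42, mainland),
        # two single inversions in the distal half of A
        EventSpec("A_5", "A", 0.55, 0.72, mainland),
        EventSpec("A_6", "A", 0.78, 0.95, mainland),
        # three fixed autosomal events
        EventSpec("J_ST", "J", 0.30, 0.60, mainland),
        EventSpec("E_ST", "E", 0.40, 0.65, mainland, "staggered", offset_left=dE),
        EventSpec("O_ms", "O", 0.25, 0.55, ancestor, "staggered", offset_left=dO),
        # two polymorphic events on U in the mainland tip
        EventSpec(
            "U_1", "U", 0.20, 0.40, mainland, "staggered", offset_left=dU1,
            terminal_state="polymorphic",
        ),
        EventSpec(
            "U_2", "U", 0.55, 0.75, mainland, "staggered", offset_left=dU2,
            terminal_state="polymorphic",
        ),
        # one fixed event on the island lineage
        EventSpec("E_g1", "E", 0.10, 0.30, island_lineage),
    ]


# ---------------------------------------------------------------------------
# repeat landscapes
# ---------------------------------------------------------------------------

REPEAT_CLASSES = ("LTR", "nonLTR", "DNA_transposon", "satellite", "microsatellite")


@dataclass(frozen=True)
class RepeatClass:
    name: str
    count: int
    unit_length: int
    pericentromeric_enrichment: float = 1.0
    telomeric_gradient_slope: float = 0.0  # density change per Mb toward the telomere

    def __post_init__(self) -> None:
        if self.name not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.name!r}")
        if self.count < 0 or self.unit_length <= 0:
            raise ValueError(f"repeat class {self.name}: invalid count/unit_length")
        if self.pericentromeric_enrichment < 1.0:
            raise ValueError(f"repeat class {self.name}: enrichment must be >= 1")


@dataclass(frozen=True)
class RepeatModel:
    classes: tuple[RepeatClass, ...]


@dataclass(frozen=True)
class RepeatRecord:
    chrom: str
    start: int
    end: int
    name: str  # "<class>_<index>"

    @property
    def repeat_class(self) -> str:
        return self.name.rsplit("_", 1)[0]


def default_repeat_model(scale: float = 1.0) -> RepeatModel:
    """A repeat landscape echoing the study system: transposons and
    satellites enriched toward the centromere, microsatellites rising toward
    the telomeres. Counts are per chromosome and scale with genome size."""
    k = max(1, int(200 * scale))
    return RepeatModel(
        classes=(
            RepeatClass("LTR", k, 400, pericentromeric_enrichment=3.0),
            RepeatClass("nonLTR", k, 300, pericentromeric_enrichment=3.0),
            RepeatClass("DNA_transposon", k, 250, pericentromeric_enrichment=5.0),
            RepeatClass("satellite", k // 2 or 1, 290, pericentromeric_enrichment=8.0),
            RepeatClass("microsatellite", 2 * k, 60, telomeric_gradient_slope=0.5 / scale),
        )
    )


def _spatial_weights(length: int, cls: RepeatClass, n_bins: int = 1024) -> np.ndarray:
    x = (np.arange(n_bins) + 0.5) * (length / n_bins)
    peri = 1.0 + (cls.pericentromeric_enrichment - 1.0) * np.exp(-10.0 * x / length)
    grad = np.maximum(0.0, 1.0 + cls.telomeric_gradient_slope * (x - length / 2.0) / 1e6)
    w = peri * grad
    total = w.sum()
    if total <= 0:
        raise ValueError(f"repeat class {cls.name}: degenerate spatial density")
    return w / total


def place_repeats(genome: MarkerGenome, model: RepeatModel, seed: int) -> list[RepeatRecord]:
    """Sample repeat intervals per class from the class's spatial density
    (uniform times pericentromeric-enrichment and telomere-gradient factors,
    centromere at position 0). Counts are per chromosome. Output is sorted
    and clipped to chromosome bounds."""
    records: list[RepeatRecord] = []
    streams = np.random.SeedSequence(seed).spawn(len(genome.chromosomes))
    for chrom, ss in zip(genome.chromosomes, streams):
        rng = np.random.default_rng(ss)
        n_bins = 1024
        bin_w = chrom.length / n_bins
        for cls in model.classes:
            if cls.count == 0:
                continue
            if cls.pericentromeric_enrichment == 1.0 and cls.telomeric_gradient_slope == 0.0:
                mids = rng.random(cls.count) * chrom.length
            else:
                w = _spatial_weights(chrom.length, cls, n_bins)
                bins = rng.choice(n_bins, size=cls.count, p=w)
                mids = (bins + rng.random(cls.count)) * bin_w
            for i, mid in enumerate(np.sort(mids)):
                start = max(0, int(mid) - cls.unit_length // 2)
                end = min(chrom.length, start + cls.unit_length)
                if end > start:
                    records.append(RepeatRecord(chrom.name, start, end, f"{cls.name}_{i:05d}"))
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
    return records
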