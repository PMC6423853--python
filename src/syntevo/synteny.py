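"""Signed synteny blocks between two marker genomes.

Orthologous markers shared by id between the two genomes become anchors;
maximal collinear anchor runs (same relative strand, monotone positions,
bounded gaps) become synteny blocks; per-chromosome block order and
orientation relative to the reference genome yields a signed permutation,
the input to reversal-history reconstruction.

Runs shorter than ``min_anchors`` are treated as micro-rearrangements: their
anchors are dropped and chaining is repeated, so an isolated stray anchor
does not break an otherwise collinear block.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import MarkerGenome


@dataclass(frozen=True)
class Anchor:
    """One orthologous marker matched between the two genomes."""

    marker_id: str
    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str

    @property
    def relative_strand(self) -> int:
        """+1 if the marker keeps its orientation across genomes, else -1."""
        return 1 if self.strand1 == self.strand2 else -1


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: int
    chrom1: str
    chrom2: str
    span1: tuple[int, int]
    span2: tuple[int, int]
    orientation: int  # +1 collinear, -1 inverted
    n_anchors: int
    anchor_ids: tuple[str, ...] = ()

    @property
    def size1(self) -> int:
        return self.span1[1] - self.span1[0]


@dataclass(frozen=True)
class SignedPermutation:
    """Block order on one reference chromosome, signed by orientation.

    Elements are block ranks in genome2 order, listed in genome1 order;
    absolute values form a permutation of 1..n.
    """

    chrom: str
    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(abs(e) for e in self.elements) != list(range(1, len(self.elements) + 1)):
            raise ValueError(f"{self.chrom}: elements are not a signed permutation of 1..n")

    @property
    def n(self) -> int:
        return len(self.elements)

    def is_identity(self) -> bool:
        return all(e == i + 1 for i, e in enumerate(self.elements))


def find_anchors(g1: MarkerGenome, g2: MarkerGenome) -> list[Anchor]:
    """Anchors for exactly the marker ids shared by both genomes, in genome1
    order. Duplicate ids within one genome are an error (paralogy is not
    supported); ids private to one genome are ignored."""
    m2 = g2.all_markers()
    anchors: list[Anchor] = []
    for chrom in g1.chromosomes:
        for m in chrom.markers:
            hit = m2.get(m.id)
            if hit is None:
                continue
            c2, mk2 = hit
            anchors.append(
                Anchor(
                    marker_id=m.id,
                    chrom1=chrom.name, start1=m.start, end1=m.end, strand1=m.strand,
                    chrom2=c2, start2=mk2.start, end2=mk2.end, strand2=mk2.strand,
                )
            )
    return anchors


def _chain_once(anchors: list[Anchor], max_gap: int) -> list[list[Anchor]]:
    """One greedy left-to-right chaining pass over genome1-sorted anchors of
    a single (chrom1, chrom2) pair. A run must be consecutive in the rank
    order of *both* genomes (so chaining is symmetric under swapping the
    genomes), keep one relative strand, and keep inter-anchor gaps within
    ``max_gap`` on both sides."""
    rank2 = {
        id(a): i for i, a in enumerate(sorted(anchors, key=lambda a: (a.start2, a.end2)))
    }
    runs: list[list[Anchor]] = []
    run: list[Anchor] = []
    for a in anchors:
        if not run:
            run = [a]
            continue
        prev = run[-1]
        sign = prev.relative_strand
        ok = (
            a.relative_strand == sign
            and rank2[id(a)] - rank2[id(prev)] == sign
            and a.start1 - prev.end1 <= max_gap
            and (
                (sign > 0 and 0 <= a.start2 - prev.end2 <= max_gap)
                or (sign < 0 and 0 <= prev.start2 - a.end2 <= max_gap)
            )
        )
        if ok:
            run.append(a)
        else:
            runs.append(run)
            run = [a]
    if run:
        runs.append(run)
    return runs


def chain_blocks(
    anchors: list[Anchor], min_anchors: int = 3, max_gap: int = 1_000_000
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks.

    Anchors are grouped by chromosome pair and chained greedily; runs shorter
    than ``min_anchors`` are discarded as micro-rearrangements and chaining
    repeats on the survivors until stable. Block spans are the hulls of their
    anchors in each genome. Block ids number blocks in genome1 order.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom1, a.chrom2), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (c1, c2), grp in sorted(groups.items()):
        grp = sorted(grp, key=lambda a: a.start1)
        while True:
            runs = _chain_once(grp, max_gap)
            short = [r for r in runs if len(r) < min_anchors]
            if not short:
                break
            keep = {id(a) for r in runs if len(r) >= min_anchors for a in r}
            grp = [a for a in grp if id(a) in keep]
            if not grp:
                runs = []
                break
        for run in runs:
            blocks.append(
                SyntenyBlock(
                    block_id=0,  # assigned below in genome1 order
                    chrom1=c1,
                    chrom2=c2,
                    span1=(min(a.start1 for a in run), max(a.end1 for a in run)),
                    span2=(min(a.start2 for a in run), max(a.end2 for a in run)),
                    orientation=run[0].relative_strand,
                    n_anchors=len(run),
                    anchor_ids=tuple(a.marker_id for a in run),
                )
            )
    blocks.sort(key=lambda b: (b.chrom1, b.span1))
    return [
        SyntenyBlock(
            i + 1, b.chrom1, b.chrom2, b.span1, b.span2, b.orientation, b.n_anchors, b.anchor_ids
        )
        for i, b in enumerate(blocks)
    ]


@dataclass(frozen=True)
class BlockStats:
    n_blocks: int
    mean_size_mb: float
    n_inverted: int


def block_stats(blocks: list[SyntenyBlock]) -> BlockStats:
    """Block count, mean genome1 span in Mb, and inverted-block count."""
    if not blocks:
        return BlockStats(0, 0.0, 0)
    sizes = [b.size1 for b in blocks]
    return BlockStats(
        n_blocks=len(blocks),
        mean_size_mb=sum(sizes) / len(sizes) / 1e6,
        n_inverted=sum(1 for b in blocks if b.orientation < 0),
    )


def to_signed_permutation(blocks: list[SyntenyBlock], chrom: str) -> SignedPermutation:
    """Signed permutation of the blocks of one genome1 chromosome, numbered
    by genome2 order (ties broken by genome2 start)."""
    sel = [b for b in blocks if b.chrom1 == chrom]
    if not sel:
        return SignedPermutation(chrom, ())
    targets = {b.chrom2 for b in sel}
    if len(targets) > 1:
        raise ValueError(
            f"{chrom}: blocks map to several genome2 chromosomes {sorted(targets)} "
            "(translocations unsupported)"
        )
    sel.sort(key=lambda b: b.span1)
    rank = {
        id(b): i + 1
        for i, b in enumerate(sorted(sel, key=lambda b: (b.span2[0], b.span2[1])))
    }
    return SignedPermutation(chrom, tuple(rank[id(b)] * b.orientation for b in sel))
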