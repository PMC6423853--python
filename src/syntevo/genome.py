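"""Core containers for marker-annotated genomes.

A genome is a set of named chromosomes, each carrying an ordered list of
oriented gene markers over an (optional) nucleotide sequence. All coordinates
are 0-based half-open; strands are "+" or "-". These containers are the
substrate of every pipeline stage: the simulator produces them, synteny
mapping consumes pairs of them, and the flank mapper reads their sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Marker:
    """One oriented gene marker on a chromosome (0-based half-open)."""

    id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"marker {self.id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"marker {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Chromosome:
    """A chromosome: markers sorted by start, non-overlapping, within bounds.

    Acrocentric convention throughout: position 0 is the centromere end and
    ``length`` the telomere end.
    """

    name: str
    length: int
    markers: list[Marker] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length")
        self.markers = sorted(self.markers, key=lambda m: m.start)
        prev_end = 0
        for m in self.markers:
            if m.start < prev_end:
                raise ValueError(f"chromosome {self.name}: overlapping markers at {m.id}")
            if m.end > self.length:
                raise ValueError(f"chromosome {self.name}: marker {m.id} exceeds length")
            prev_end = m.end
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name}: sequence length {len(self.sequence)} != {self.length}"
            )

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def fetch(self, start: int, end: int) -> str:
        """Sequence slice [start, end), clipped to chromosome bounds."""
        if self.sequence is None:
            raise ValueError(f"chromosome {self.name} carries no sequence")
        return self.sequence[max(0, start) : min(self.length, end)]


@dataclass
class MarkerGenome:
    """Per-taxon genome: ordered chromosomes with unique marker ids."""

    taxon_id: str
    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for m in chrom.markers:
                if m.id in seen:
                    raise ValueError(f"taxon {self.taxon_id}: duplicate marker id {m.id}")
                seen.add(m.id)

    def chromosome(self, name: str) -> Chromosome:
        for chrom in self.chromosomes:
            if chrom.name == name:
                return chrom
        raise KeyError(f"taxon {self.taxon_id}: no chromosome named {name}")

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def all_markers(self) -> dict[str, tuple[str, Marker]]:
        """Map marker id -> (chromosome name, Marker)."""
        out: dict[str, tuple[str, Marker]] = {}
        for chrom in self.chromosomes:
            for m in chrom.markers:
                out[m.id] = (chrom.name, m)
        return out

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def with_taxon(self, taxon_id: str) -> "MarkerGenome":
        return MarkerGenome(taxon_id=taxon_id, chromosomes=[replace(c) for c in self.chromosomes])
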