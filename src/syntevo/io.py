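"""Standard-format I/O: FASTA, GFF3, BED, truth tables, result tables.

Internal coordinates are 0-based half-open everywhere; the GFF3 convention
(1-based closed) is converted at this boundary only. Readers validate
aggressively and report the offending line number; writers are
deterministic so identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Chromosome, Marker, MarkerGenome
from .simulate import InversionEvent, RepeatRecord, TruthTable

TRUTH_COLUMNS = [
    "event_id", "chrom", "left_bp", "right_bp", "mechanism",
    "offset_left", "offset_right", "branch", "state",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(genome: MarkerGenome, path: str | Path) -> None:
    records = []
    for chrom in genome.chromosomes:
        if chrom.sequence is None:
            raise ValueError(f"chromosome {chrom.name} has no sequence to write")
        records.append(SeqRecord(Seq(chrom.sequence), id=chrom.name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> sequence, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (markers, type=gene)
# ---------------------------------------------------------------------------


def write_gff3(genome: MarkerGenome, path: str | Path, source: str = "syntevo") -> None:
    lines = ["##gff-version 3"]
    for chrom in genome.chromosomes:
        lines.append(f"##sequence-region {chrom.name} 1 {chrom.length}")
    for chrom in genome.chromosomes:
        for m in chrom.markers:
            # 0-based half-open -> 1-based closed at this boundary only
            lines.append(
                f"{chrom.name}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={m.id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(
    path: str | Path,
    taxon_id: str,
    sequences: dict[str, str] | None = None,
) -> MarkerGenome:
    """Rebuild a MarkerGenome from GFF3 gene features. Chromosome lengths
    come from ##sequence-region directives (or the sequences, which win when
    provided). Malformed lines and out-of-bounds coordinates raise with the
    line number."""
    lengths: dict[str, int] = {}
    markers: dict[str, list[Marker]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            try:
                _, name, _one, end = line.split()
                lengths[name] = int(end)
                if name not in order:
                    order.append(name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed sequence-region") from exc
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
        chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "gene":
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start_i < 1 or end_i < start_i:
            raise ValueError(f"{path}:{lineno}: invalid 1-based closed interval")
        mid = None
        for item in attrs.split(";"):
            if item.startswith("ID="):
                mid = item[3:]
        if not mid:
            raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
        if chrom not in order:
            order.append(chrom)
        markers.setdefault(chrom, []).append(Marker(mid, start_i - 1, end_i, strand))
    if sequences:
        for name, seq in sequences.items():
            lengths[name] = len(seq)
            if name not in order:
                order.append(name)
    chroms = []
    for name in order:
        if name not in lengths:
            raise ValueError(f"{path}: no length known for chromosome {name}")
        for m in markers.get(name, []):
            if m.end > lengths[name]:
                raise ValueError(
                    f"{path}: marker {m.id} exceeds chromosome {name} length {lengths[name]}"
                )
        chroms.append(
            Chromosome(
                name=name,
                length=lengths[name],
                markers=markers.get(name, []),
                sequence=sequences.get(name) if sequences else None,
            )
        )
    return MarkerGenome(taxon_id=taxon_id, chromosomes=chroms)


# ---------------------------------------------------------------------------
# BED (repeats; 0-based half-open natively)
# ---------------------------------------------------------------------------


def write_bed(records: list[RepeatRecord], path: str | Path) -> None:
    lines = [f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> list[RepeatRecord]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected at least 3 BED fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start < 0 or end <= start:
            raise ValueError(f"{path}:{lineno}: invalid half-open interval [{start}, {end})")
        if chrom_lengths is not None:
            if chrom not in chrom_lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if end > chrom_lengths[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: end {end} beyond chromosome {chrom} "
                    f"length {chrom_lengths[chrom]}"
                )
        name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
        out.append(RepeatRecord(chrom, start, end, name))
    return out


# ---------------------------------------------------------------------------
# truth tables and result tables
# ---------------------------------------------------------------------------


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.to_frame()[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_events(path: str | Path) -> list[InversionEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "chrom": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: truth table missing columns {missing}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            InversionEvent(
                event_id=row.event_id,
                chrom=row.chrom,
                left_bp=int(row.left_bp),
                right_bp=int(row.right_bp),
                mechanism=row.mechanism,
                offset_left=int(row.offset_left),
                offset_right=int(row.offset_right),
                branch=row.branch,
                terminal_state=row.state,
            )
        )
    return events


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for table headers."""
    import json

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None, cfg_hash: str) -> None:
    """Write a result TSV carrying the seed and config hash so reruns are
    auditable and byte-identical."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n# config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
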