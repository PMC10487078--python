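"""Read-alignment records and SAM/BED interchange.

The pipeline starts from mapped, single-hit alignments (multi-mapper
resolution happens upstream).  Records are held as lightweight tuples with
0-based half-open coordinates; SAM is read and written through pysam and
BED6 through plain tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam


class AlignmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped read: 0-based half-open interval plus strand."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AlignmentInputError(
                f"read {self.read_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AlignmentInputError(f"read {self.read_id}: bad strand {self.strand!r}")


def read_bed6_alignments(path: str | Path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise AlignmentInputError(
                    f"{path} line {lineno}: expected 6 BED fields, got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            records.append(AlignmentRecord(name, chrom, int(start), int(end), strand))
    return records


def read_sam_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped records from a (headered) SAM file."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def write_bed6_alignments(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


def write_sam_alignments(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    chrom_sizes: Mapping[str, int],
) -> None:
    """Write records as a headered SAM file with ungapped CIGARs."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.cigarstring = f"{r.end - r.start}M"
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            a.query_sequence = "N" * (r.end - r.start)
            out.write(a)


def load_alignments(path: str | Path) -> list[AlignmentRecord]:
    """Dispatch on extension: ``.sam`` via pysam, ``.bed``/``.bed6`` as BED6."""
    suffix = Path(path).suffix.lower()
    if suffix == ".sam":
        return read_sam_alignments(path)
    if suffix in (".bed", ".bed6"):
        return read_bed6_alignments(path)
    raise AlignmentInputError(f"{path}: unrecognised alignment format {suffix!r}")
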