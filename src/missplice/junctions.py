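"""Reading and writing split-read junction tables.

Two on-disk dialects are supported:

* ``star_sj`` — STAR ``SJ.out.tab``: 1-based first and last intronic base,
  strand encoded 0/1/2 (undefined/+/-), unique-read count in column 7.
* ``bed_junctions`` — BED6 where the score column carries the read count.

Internally every junction is a 0-based half-open intronic interval with a
per-sample count map; undefined-strand records are retained but flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

STAR_STRAND = {"0": "?", "1": "+", "2": "-"}
STAR_STRAND_INV = {"?": "0", "+": "1", "-": "2"}


class JunctionFormatError(ValueError):
    pass


@dataclass
class JunctionRecord:
    """One observed exon-exon junction: the excised intronic interval."""

    chrom: str
    start: int  # 0-based first intronic base
    end: int  # exclusive
    strand: str  # '+', '-', or '?' for undefined
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise JunctionFormatError(
                f"junction {self.chrom}:{self.start}-{self.end} has length < 1"
            )
        for sample, c in self.counts.items():
            if c < 0:
                raise JunctionFormatError(f"negative count {c} for sample {sample}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def total_count(self) -> int:
        return sum(self.counts.values())


def read_junctions(
    path: str | Path, dialect: str, sample_id: str | None = None
) -> list[JunctionRecord]:
    """Read one sample's junction table into normalised records.

    ``sample_id`` defaults to the file stem and keys the count map.
    """
    if dialect not in ("star_sj", "bed_junctions"):
        raise JunctionFormatError(f"unknown dialect {dialect!r}")
    sample = sample_id if sample_id is not None else Path(path).stem
    records: list[JunctionRecord] = []
    rejected = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                if dialect == "star_sj":
                    chrom = parts[0]
                    start = int(parts[1]) - 1  # 1-based first intronic base
                    end = int(parts[2])  # 1-based last intronic base == exclusive end
                    strand = STAR_STRAND.get(parts[3])
                    if strand is None:
                        raise JunctionFormatError(f"bad strand code {parts[3]!r}")
                    count = int(parts[6]) if len(parts) > 6 else 0
                else:
                    chrom = parts[0]
                    start, end = int(parts[1]), int(parts[2])
                    count = int(parts[4])
                    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "?"
                if count < 0:
                    raise JunctionFormatError("negative count")
                records.append(
                    JunctionRecord(chrom, start, end, strand, counts={sample: count})
                )
            except (IndexError, ValueError) as exc:
                raise JunctionFormatError(f"{path}:{ln}: {exc}") from exc
    logger.info(
        "read_junctions(%s): %d records, %d rejected lines from %s",
        dialect, len(records), rejected, path,
    )
    return records


def write_junctions(
    records: Iterable[JunctionRecord], path: str | Path, dialect: str, sample_id: str
) -> None:
    """Write one sample's counts in the requested dialect (inverse of reading)."""
    if dialect not in ("star_sj", "bed_junctions"):
        raise JunctionFormatError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for rec in records:
            count = rec.counts.get(sample_id, 0)
            if dialect == "star_sj":
                fh.write(
                    f"{rec.chrom}\t{rec.start + 1}\t{rec.end}\t"
                    f"{STAR_STRAND_INV[rec.strand]}\t0\t0\t{count}\t0\t8\n"
                )
            else:
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\tjxn\t{count}\t"
                    f"{rec.strand if rec.strand in '+-' else '.'}\n"
                )


def merge_junctions(per_sample: Iterable[list[JunctionRecord]]) -> list[JunctionRecord]:
    """Pool per-sample records into one record per distinct junction key."""
    merged: dict[tuple, JunctionRecord] = {}
    for records in per_sample:
        for rec in records:
            if rec.key in merged:
                target = merged[rec.key].counts
                for s, c in rec.counts.items():
                    target[s] = target.get(s, 0) + c
            else:
                merged[rec.key] = JunctionRecord(
                    rec.chrom, rec.start, rec.end, rec.strand, dict(rec.counts)
                )
    return list(merged.values())
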