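"""Intron-centric view of a reference annotation, plus region masks and score tracks.

Introns are derived as the gaps between consecutive exons of each transcript,
then deduplicated across transcripts: one :class:`AnnotatedIntron` per distinct
``(chrom, start, end, strand)``. All coordinates are 0-based half-open
intronic intervals — ``start`` is the first intronic base, ``end`` is one past
the last. The donor (5'ss) of an intron sits at ``start`` on the plus strand
and at ``end`` on the minus strand; the acceptor (3'ss) is the opposite end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"


class AnnotationError(ValueError):
    """Raised for malformed annotation or mask input."""


@dataclass(frozen=True)
class AnnotatedIntron:
    """A single annotation-derived intron with its transcript/gene context."""

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_ids: frozenset[str]
    n_gene_transcripts: int
    pct_protein_coding: float
    is_mane: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"intron {self.intron_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"intron {self.intron_id}: bad strand {self.strand!r}")

    @property
    def intron_length(self) -> int:
        return self.end - self.start

    @property
    def donor_coord(self) -> int:
        """Genomic coordinate of the donor (5'ss) boundary."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_coord(self) -> int:
        """Genomic coordinate of the acceptor (3'ss) boundary."""
        return self.end if self.strand == "+" else self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


class GenomeAnnotation:
    """An intron index with strand-aware donor/acceptor lookup maps."""

    def __init__(self, introns: Iterable[AnnotatedIntron], version_label: str = ""):
        self.version_label = version_label
        self.introns: dict[str, AnnotatedIntron] = {}
        self.by_interval: dict[tuple[str, int, int, str], str] = {}
        self.donor_index: dict[tuple[str, str, int], list[str]] = {}
        self.acceptor_index: dict[tuple[str, str, int], list[str]] = {}
        for intron in introns:
            if intron.key in self.by_interval:
                raise AnnotationError(f"duplicate intron interval {intron.key}")
            self.introns[intron.intron_id] = intron
            self.by_interval[intron.key] = intron.intron_id
            dk = (intron.chrom, intron.strand, intron.donor_coord)
            ak = (intron.chrom, intron.strand, intron.acceptor_coord)
            self.donor_index.setdefault(dk, []).append(intron.intron_id)
            self.acceptor_index.setdefault(ak, []).append(intron.intron_id)

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self):
        return iter(self.introns.values())


def _transcript_biotype(feature) -> str:
    for key in ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return "unknown"


def load_annotation(
    gtf_path: str | Path,
    mane_ids: set[str] | None = None,
    version_label: str = "",
) -> GenomeAnnotation:
    """Derive the deduplicated intron index from an Ensembl-dialect GTF.

    Parameters
    ----------
    gtf_path:
        GTF with exon features carrying ``transcript_id``/``gene_id`` and a
        biotype attribute.
    mane_ids:
        Optional set of transcript ids regarded as MANE Select. An intron is
        flagged MANE if any transcript containing it is in this set. GTF MANE
        tags are deliberately ignored — dialects disagree on how they are
        spelled, so the caller supplies the list.
    """
    mane_ids = mane_ids or set()
    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils reports the offending line itself
        raise AnnotationError(f"malformed GTF {gtf_path}: {exc}") from exc

    # exon lists per transcript
    exons_by_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tx -> (gene, chrom, strand, biotype)
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes["transcript_id"][0]
        gene_id = exon.attributes["gene_id"][0]
        exons_by_tx.setdefault(tx_id, []).append(exon)
        tx_meta[tx_id] = (gene_id, exon.seqid, exon.strand, _transcript_biotype(exon))

    tx_per_gene: dict[str, set[str]] = {}
    for tx_id, (gene_id, *_rest) in tx_meta.items():
        tx_per_gene.setdefault(gene_id, set()).add(tx_id)

    # gap enumeration; dedupe across transcripts
    found: dict[tuple[str, int, int, str], set[str]] = {}
    for tx_id, exons in exons_by_tx.items():
        if len(exons) < 2:
            continue  # single-exon transcript: no introns
        _gene, chrom, strand, _bt = tx_meta[tx_id]
        bounds = sorted((e.start - 1, e.end) for e in exons)  # GTF 1-based closed -> half-open
        for (_, left_end), (right_start, _) in zip(bounds, bounds[1:]):
            if right_start <= left_end:
                continue  # overlapping/bookended exons leave no gap
            found.setdefault((chrom, left_end, right_start, strand), set()).add(tx_id)

    introns = []
    for i, (key, tx_ids) in enumerate(sorted(found.items())):
        chrom, start, end, strand = key
        gene_id = tx_meta[next(iter(tx_ids))][0]
        biotypes = [tx_meta[t][3] for t in tx_ids]
        introns.append(
            AnnotatedIntron(
                intron_id=f"I{i:06d}_{chrom}_{start}_{end}_{strand}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                gene_id=gene_id,
                transcript_ids=frozenset(tx_ids),
                n_gene_transcripts=len(tx_per_gene[gene_id]),
                pct_protein_coding=sum(b == PROTEIN_CODING for b in biotypes) / len(biotypes),
                is_mane=bool(tx_ids & mane_ids),
            )
        )
    logger.info("load_annotation: %d introns from %s", len(introns), gtf_path)
    return GenomeAnnotation(introns, version_label=version_label)


class RegionMask:
    """Half-open interval set with an overlap query (e.g. blacklist regions)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end < start:
                raise AnnotationError(f"mask interval {chrom}:{start}-{end} has start > end")
            if end == start:
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        self.n_intervals = n

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def read_region_mask(bed_path: str | Path) -> RegionMask:
    """Read a BED3+ file into an overlap-queryable mask (half-open semantics)."""
    intervals = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(f"{bed_path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise AnnotationError(f"{bed_path}:{ln}: non-integer coordinates") from exc
            if start > end:
                raise AnnotationError(f"{bed_path}:{ln}: start > end")
            intervals.append((parts[0], start, end))
    logger.info("read_region_mask: %d intervals from %s", len(intervals), bed_path)
    return RegionMask(intervals)


class ScoreTrack:
    """Sparse per-base numeric track (bedGraph-backed), missing != zero."""

    def __init__(self):
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if end <= start:
            return
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, float(value))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); NaN marks missing positions."""
        if end <= start:
            raise ValueError("window requires end > start")
        out = np.full(end - start, np.nan)
        tree = self._trees.get(chrom)
        if tree is None:
            return out
        for iv in tree.overlap(start, end):
            a = max(iv.begin, start) - start
            b = min(iv.end, end) - start
            out[a:b] = iv.data
        return out


def read_score_track(bedgraph_path: str | Path) -> ScoreTrack:
    """Read a bedGraph file (chrom, start, end, value) into a :class:`ScoreTrack`."""
    track = ScoreTrack()
    n = 0
    with open(bedgraph_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationError(f"{bedgraph_path}:{ln}: fewer than 4 bedGraph columns")
            track.add(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            n += 1
    logger.info("read_score_track: %d intervals from %s", n, bedgraph_path)
    return track


def mean_window_score(
    track: ScoreTrack, chrom: str, start: int, end: int, max_missing_frac: float = 0.5
) -> float:
    """Arithmetic mean over non-missing positions in [start, end).

    Returns NaN when more than ``max_missing_frac`` of the window is missing,
    so that heavily gapped conservation/constraint windows do not produce
    unstable means.
    """
    values = track.window(chrom, start, end)
    missing = np.isnan(values)
    if missing.mean() > max_missing_frac:
        return float("nan")
    return float(np.nanmean(values))
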