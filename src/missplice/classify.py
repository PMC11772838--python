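"""Quality control and classification of split-read junctions.

Each junction is compared against an intron index and labelled:

* ``annotated`` — the interval and strand exactly match an annotated intron;
* ``novel_donor`` — the acceptor boundary matches an annotated acceptor but
  the donor boundary matches no annotated donor (strand-aware);
* ``novel_acceptor`` — the symmetric condition at the donor;
* ``unassigned`` — neither or both boundaries are novel, the junction failed
  QC, or its two boundaries belong to two different introns (a putative
  exon-skipping product, which the three-class scheme deliberately excludes).

Novel junctions are then assigned uniquely to one annotated intron sharing
the matched site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotation import AnnotatedIntron, GenomeAnnotation, RegionMask
from .junctions import JunctionRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("annotated", "novel_donor", "novel_acceptor", "unassigned")

#: Minimum split-read (intron) length in bp; shorter products cannot arise
#: from clean intron excision.
DEFAULT_MIN_LENGTH = 25


class ClassificationError(RuntimeError):
    pass


@dataclass
class ClassifiedJunction:
    junction: JunctionRecord
    category: str = "unassigned"
    assigned_intron_id: str | None = None
    qc_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ReclassificationResult:
    """Junction re-annotation rate between two annotation versions."""

    label: str
    n_reclassified: int  # novel under old, annotated under new (j)
    n_retained: int  # novel under both (y)

    @property
    def rate(self) -> float:
        return self.n_reclassified / self.n_retained


def apply_qc(
    junctions: Iterable[JunctionRecord],
    blacklist: RegionMask | None = None,
    minor_introns: RegionMask | None = None,
    placed_chroms: set[str] | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[ClassifiedJunction]:
    """Flag junctions failing any QC filter; filters are independent and all
    evaluated so attrition can be reported per criterion."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    out = []
    for jxn in junctions:
        flags: set[str] = set()
        if jxn.length < min_length:
            flags.add("too_short")
        if blacklist is not None and blacklist.overlaps(jxn.chrom, jxn.start, jxn.end):
            flags.add("blacklisted")
        if minor_introns is not None and minor_introns.overlaps(jxn.chrom, jxn.start, jxn.end):
            flags.add("minor_intron")
        if placed_chroms is not None and jxn.chrom not in placed_chroms:
            flags.add("unplaced_contig")
        if jxn.strand not in ("+", "-"):
            flags.add("undefined_strand")
        out.append(ClassifiedJunction(junction=jxn, qc_flags=flags))
    n_flagged = sum(1 for c in out if c.qc_flags)
    logger.info("apply_qc: %d/%d junctions flagged", n_flagged, len(out))
    return out


def _boundary_coords(jxn: JunctionRecord) -> tuple[int, int]:
    """(donor, acceptor) genomic coordinates of a strand-defined junction."""
    if jxn.strand == "+":
        return jxn.start, jxn.end
    return jxn.end, jxn.start


def classify(
    classified: Sequence[ClassifiedJunction], annotation: GenomeAnnotation
) -> list[ClassifiedJunction]:
    """Assign categories in place (QC-flagged junctions stay unassigned)."""
    for cj in classified:
        if cj.qc_flags:
            cj.category = "unassigned"
            continue
        jxn = cj.junction
        if jxn.key in annotation.by_interval:
            cj.category = "annotated"
            cj.assigned_intron_id = annotation.by_interval[jxn.key]
            continue
        donor, acceptor = _boundary_coords(jxn)
        donor_known = (jxn.chrom, jxn.strand, donor) in annotation.donor_index
        acceptor_known = (jxn.chrom, jxn.strand, acceptor) in annotation.acceptor_index
        if acceptor_known and not donor_known:
            cj.category = "novel_donor"
        elif donor_known and not acceptor_known:
            cj.category = "novel_acceptor"
        else:
            cj.category = "unassigned"
    return list(classified)


def assign_unique(
    classified: Sequence[ClassifiedJunction], annotation: GenomeAnnotation
) -> list[ClassifiedJunction]:
    """Attach exactly one annotated intron to every novel junction.

    Candidates are the introns whose annotated-side site matches the
    junction's. When several introns share that site the one with the highest
    total annotated read support (summed over samples in this batch) wins;
    ties go to the shortest intron, then the lexicographically smallest id.
    """
    support: dict[str, int] = {}
    for cj in classified:
        if cj.category == "annotated" and cj.assigned_intron_id is not None:
            support[cj.assigned_intron_id] = (
                support.get(cj.assigned_intron_id, 0) + cj.junction.total_count()
            )

    for cj in classified:
        if cj.category not in ("novel_donor", "novel_acceptor"):
            continue
        jxn = cj.junction
        donor, acceptor = _boundary_coords(jxn)
        if cj.category == "novel_donor":
            candidates = annotation.acceptor_index.get((jxn.chrom, jxn.strand, acceptor))
        else:
            candidates = annotation.donor_index.get((jxn.chrom, jxn.strand, donor))
        if not candidates:
            raise ClassificationError(
                f"novel junction {jxn.key} has no intron at its annotated-side site"
            )
        cj.assigned_intron_id = min(
            candidates,
            key=lambda iid: (
                -support.get(iid, 0),
                annotation.introns[iid].intron_length,
                iid,
            ),
        )
    return list(classified)


def classify_junctions(
    junctions: Iterable[JunctionRecord],
    annotation: GenomeAnnotation,
    blacklist: RegionMask | None = None,
    minor_introns: RegionMask | None = None,
    placed_chroms: set[str] | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[ClassifiedJunction]:
    """QC, classify and uniquely assign in one call."""
    classified = apply_qc(junctions, blacklist, minor_introns, placed_chroms, min_length)
    classify(classified, annotation)
    return assign_unique(classified, annotation)


def reclassification_rate(
    old: GenomeAnnotation,
    new: GenomeAnnotation,
    junctions: Iterable[JunctionRecord],
    label: str = "",
) -> ReclassificationResult:
    """Rate at which novel junctions under ``old`` become annotated under ``new``.

    ``j / y`` where ``j`` counts junctions that are novel (donor or acceptor)
    under the old annotation and annotated under the new, and ``y`` counts
    junctions remaining novel under both.
    """
    junctions = list(junctions)
    under_old = classify(apply_qc(junctions), old)
    under_new = classify(apply_qc(junctions), new)
    novel = {"novel_donor", "novel_acceptor"}
    j = y = 0
    for co, cn in zip(under_old, under_new):
        if co.category in novel:
            if cn.category == "annotated":
                j += 1
            elif cn.category in novel:
                y += 1
    if y == 0:
        raise ClassificationError("reclassification rate undefined: no retained novel junctions")
    return ReclassificationResult(label=label, n_reclassified=j, n_retained=y)
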