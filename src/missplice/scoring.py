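"""Splice-site motif extraction and strength scoring.

Sites are scored on the MaxEntScan framing: a donor (5'ss) is a 9-mer of
3 exonic + 6 intronic bases (canonical GT at intronic positions 1-2) and an
acceptor (3'ss) is a 23-mer of 20 intronic + 3 exonic bases (canonical AG at
intronic positions 19-20). Minus-strand sites are reverse-complemented so
every extracted motif reads in transcript orientation.

Two model kinds sit behind one scoring interface:

* ``maxent_tables`` — externally supplied lookup tables mapping each k-mer to
  its precomputed maximum-entropy score (self-contained, background-free);
* ``logodds_pwm`` — a position weight matrix of per-position log2 odds versus
  background base frequencies, trained from the annotated sites of the input
  annotation with +1 pseudocounts.

Delta scores compare the annotated site of an intron with the paired novel
site (annotated minus novel): a positive delta means the novel site is the
weaker motif under the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import AnnotatedIntron, GenomeAnnotation
from .classify import ClassifiedJunction

logger = logging.getLogger(__name__)

DONOR_LEN = 9
ACCEPTOR_LEN = 23
DONOR_EXONIC = 3  # bases of upstream exon in the donor 9-mer
ACCEPTOR_EXONIC = 3  # bases of downstream exon in the acceptor 23-mer

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ScoringError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def site_interval(coord: int, strand: str, kind: str) -> tuple[int, int]:
    """Genomic half-open interval covered by the motif of a site.

    ``coord`` is the junction boundary: the first intronic base of the donor
    side, or one past the last intronic base of the acceptor side, in the
    strand-aware sense used throughout (donor = start on +, end on -).
    """
    if kind == "donor":
        if strand == "+":
            return coord - DONOR_EXONIC, coord + (DONOR_LEN - DONOR_EXONIC)
        return coord - (DONOR_LEN - DONOR_EXONIC), coord + DONOR_EXONIC
    if kind == "acceptor":
        if strand == "+":
            return coord - (ACCEPTOR_LEN - ACCEPTOR_EXONIC), coord + ACCEPTOR_EXONIC
        return coord - ACCEPTOR_EXONIC, coord + (ACCEPTOR_LEN - ACCEPTOR_EXONIC)
    raise ScoringError(f"unknown site kind {kind!r}")


def extract_site_sequence(genome, chrom: str, coord: int, strand: str, kind: str) -> str:
    """Extract the donor 9-mer or acceptor 23-mer around a splice site.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (a ``pyfaidx.Fasta`` works directly). Minus-strand motifs are returned
    reverse-complemented. Non-ACGT bases are replaced by ``N`` with a warning.
    """
    start, end = site_interval(coord, strand, kind)
    chrom_seq = genome[chrom]
    if start < 0 or end > len(chrom_seq):
        raise ScoringError(
            f"{kind} site {chrom}:{coord}({strand}): motif window [{start},{end}) "
            f"out of chromosome bounds"
        )
    seq = str(chrom_seq[start:end]).upper()
    if strand == "-":
        seq = reverse_complement(seq)
    if any(b not in _BASES for b in seq):
        logger.warning("non-ACGT base in %s site %s:%d(%s)", kind, chrom, coord, strand)
        seq = "".join(b if b in _BASES else "N" for b in seq)
    return seq


def intron_site_sequence(genome, intron: AnnotatedIntron, kind: str) -> str:
    coord = intron.donor_coord if kind == "donor" else intron.acceptor_coord
    return extract_site_sequence(genome, intron.chrom, coord, intron.strand, kind)


@dataclass
class SpliceSiteModel:
    """Donor/acceptor scoring model behind a single ``score`` interface."""

    kind: str  # {maxent_tables, logodds_pwm}
    donor: object  # 9x4 ndarray (pwm) or Mapping[str, float] (tables)
    acceptor: object  # 23x4 ndarray or Mapping[str, float]
    background: np.ndarray | None = None  # ACGT frequencies for the pwm kind
    provenance: str = ""

    def score(self, seq: str, kind: str) -> float:
        expected = DONOR_LEN if kind == "donor" else ACCEPTOR_LEN
        if len(seq) != expected:
            raise ScoringError(
                f"{kind} sequence length {len(seq)}, expected {expected}: {seq!r}"
            )
        seq = seq.upper()
        table = self.donor if kind == "donor" else self.acceptor
        if self.kind == "maxent_tables":
            try:
                return float(table[seq])
            except KeyError as exc:
                raise ScoringError(f"sequence {seq!r} absent from maxent table") from exc
        # log-odds PWM: N contributes the background expectation (zero log-odds)
        total = 0.0
        for pos, base in enumerate(seq):
            if base in _BASE_IDX:
                total += float(table[pos, _BASE_IDX[base]])
        return total


def train_logodds_model(
    donor_seqs: Sequence[str],
    acceptor_seqs: Sequence[str],
    background: Sequence[float] | None = None,
    min_sites: int = 50,
    provenance: str = "trained",
) -> SpliceSiteModel:
    """Train the log-odds PWM fallback from annotated site sequences.

    Per-position base frequencies with +1 pseudocounts, log2 odds against
    the background composition (default: pooled composition of the training
    sequences). Requires at least ``min_sites`` sequences of each kind.
    """
    if len(donor_seqs) < min_sites or len(acceptor_seqs) < min_sites:
        raise ScoringError(
            f"need >= {min_sites} sites of each kind to train "
            f"(got {len(donor_seqs)} donors, {len(acceptor_seqs)} acceptors)"
        )
    if background is None:
        pooled = np.ones(4)
        for seq in list(donor_seqs) + list(acceptor_seqs):
            for base in seq.upper():
                if base in _BASE_IDX:
                    pooled[_BASE_IDX[base]] += 1
        bg = pooled / pooled.sum()
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    def pwm(seqs: Sequence[str], length: int) -> np.ndarray:
        counts = np.ones((length, 4))  # +1 pseudocount
        for seq in seqs:
            seq = seq.upper()
            if len(seq) != length:
                raise ScoringError(f"training sequence {seq!r} not of length {length}")
            for pos, base in enumerate(seq):
                if base in _BASE_IDX:
                    counts[pos, _BASE_IDX[base]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return np.log2(freqs / bg[None, :])

    return SpliceSiteModel(
        kind="logodds_pwm",
        donor=pwm(donor_seqs, DONOR_LEN),
        acceptor=pwm(acceptor_seqs, ACCEPTOR_LEN),
        background=bg,
        provenance=provenance,
    )


def train_from_annotation(
    annotation: GenomeAnnotation, genome, min_sites: int = 50
) -> SpliceSiteModel:
    """Train the log-odds model from every annotated donor/acceptor in ``annotation``."""
    donors, acceptors = [], []
    for intron in annotation:
        try:
            donors.append(intron_site_sequence(genome, intron, "donor"))
            acceptors.append(intron_site_sequence(genome, intron, "acceptor"))
        except ScoringError:
            continue  # site too close to a contig edge
    return train_logodds_model(
        donors, acceptors, min_sites=min_sites,
        provenance=f"annotation:{annotation.version_label}",
    )


def load_maxent_tables(directory: str | Path) -> SpliceSiteModel:
    """Load precomputed k-mer score tables (``donor.tsv`` / ``acceptor.tsv``,
    two columns: sequence, score)."""
    directory = Path(directory)

    def load(name: str, length: int) -> dict[str, float]:
        table: dict[str, float] = {}
        with open(directory / name) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                seq, score = parts[0].upper(), float(parts[1])
                if len(seq) != length:
                    raise ScoringError(f"{name}:{ln}: sequence length != {length}")
                table[seq] = score
        return table

    return SpliceSiteModel(
        kind="maxent_tables",
        donor=load("donor.tsv", DONOR_LEN),
        acceptor=load("acceptor.tsv", ACCEPTOR_LEN),
        provenance=str(directory),
    )


@dataclass(frozen=True)
class DeltaScore:
    intron_id: str
    novel_junction_key: tuple
    site_kind: str
    annotated_score: float
    novel_score: float

    @property
    def delta(self) -> float:
        """Annotated minus novel: positive when the novel site is weaker."""
        return self.annotated_score - self.novel_score


def delta_scores(
    model: SpliceSiteModel,
    classified: Iterable[ClassifiedJunction],
    annotation: GenomeAnnotation,
    genome,
) -> list[DeltaScore]:
    """Annotated-minus-novel site scores for every assigned novel junction."""
    out = []
    for cj in classified:
        if cj.category not in ("novel_donor", "novel_acceptor") or cj.assigned_intron_id is None:
            continue
        intron = annotation.introns[cj.assigned_intron_id]
        kind = "donor" if cj.category == "novel_donor" else "acceptor"
        jxn = cj.junction
        if kind == "donor":
            novel_coord = jxn.start if jxn.strand == "+" else jxn.end
        else:
            novel_coord = jxn.end if jxn.strand == "+" else jxn.start
        ann_seq = intron_site_sequence(genome, intron, kind)
        nov_seq = extract_site_sequence(genome, jxn.chrom, novel_coord, jxn.strand, kind)
        out.append(
            DeltaScore(
                intron_id=intron.intron_id,
                novel_junction_key=jxn.key,
                site_kind=kind,
                annotated_score=model.score(ann_seq, kind),
                novel_score=model.score(nov_seq, kind),
            )
        )
    return out
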