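"""Geometry of novel splice sites relative to their annotated sites.

The raw distance follows a 0-based genomic-interval convention:
``gcIntron - gcNovel`` where ``gcIntron`` is the annotated boundary
coordinate and ``gcNovel`` the novel one. The strand-adjusted distance flips
the sign on the minus strand so that mirrored fixtures on opposite strands
produce identical signed values; for donors positive values point into the
upstream exon, and for acceptors positive values point into the intron
(the AG-exclusion-zone side). Both are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import GenomeAnnotation
from .classify import ClassifiedJunction


@dataclass(frozen=True)
class SiteDistance:
    novel_junction_key: tuple
    intron_id: str
    site_kind: str  # {donor, acceptor}
    gc_intron: int
    gc_novel: int
    strand: str

    @property
    def raw_distance(self) -> int:
        """gcIntron - gcNovel, irrespective of strand."""
        return self.gc_intron - self.gc_novel

    @property
    def distance(self) -> int:
        """Strand-adjusted signed distance (sign flipped on the minus strand)."""
        return self.raw_distance if self.strand == "+" else -self.raw_distance

    @property
    def mod3(self) -> int:
        return abs(self.distance) % 3


def site_distances(
    classified: Iterable[ClassifiedJunction], annotation: GenomeAnnotation
) -> list[SiteDistance]:
    """Distances between each assigned novel site and its annotated counterpart."""
    out = []
    for cj in classified:
        if cj.category not in ("novel_donor", "novel_acceptor") or cj.assigned_intron_id is None:
            continue
        intron = annotation.introns[cj.assigned_intron_id]
        jxn = cj.junction
        if cj.category == "novel_donor":
            kind = "donor"
            gc_intron = intron.donor_coord
            gc_novel = jxn.start if jxn.strand == "+" else jxn.end
        else:
            kind = "acceptor"
            gc_intron = intron.acceptor_coord
            gc_novel = jxn.end if jxn.strand == "+" else jxn.start
        out.append(
            SiteDistance(
                novel_junction_key=jxn.key,
                intron_id=intron.intron_id,
                site_kind=kind,
                gc_intron=gc_intron,
                gc_novel=gc_novel,
                strand=jxn.strand,
            )
        )
    return out


@dataclass(frozen=True)
class Mod3Profile:
    counts: tuple[int, int, int]  # classes 0, 1, 2 of |distance| mod 3

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def proportions(self) -> tuple[float, float, float]:
        n = self.n
        return tuple(c / n for c in self.counts) if n else (float("nan"),) * 3

    @property
    def frame_disrupting_fraction(self) -> float:
        p = self.proportions
        return p[1] + p[2]


def mod3_profile(
    distances: Iterable[SiteDistance],
    annotation: GenomeAnnotation,
    max_abs_distance: int = 100,
    mane_only: bool = True,
) -> Mod3Profile:
    """Reading-frame profile of novel-site offsets.

    Restricted to introns of MANE Select transcripts (exon structures agreed
    between RefSeq and Ensembl) and to offsets strictly closer than
    ``max_abs_distance`` bp, so the novel product confidently lies within the
    adjacent exon/intron.
    """
    counts = [0, 0, 0]
    for d in distances:
        if mane_only and not annotation.introns[d.intron_id].is_mane:
            continue
        if abs(d.distance) >= max_abs_distance:
            continue
        counts[d.mod3] += 1
    return Mod3Profile(counts=tuple(counts))


@dataclass(frozen=True)
class PositionalDensity:
    window: int
    donor_hist: dict[int, int]
    acceptor_hist: dict[int, int]

    @property
    def acceptor_asymmetry(self) -> float:
        """Upstream/downstream count ratio at acceptors.

        Upstream means the intronic side of the acceptor (positive adjusted
        distance), where the AG exclusion zone suppresses usable sites; a
        ratio well below 1 reproduces that depletion.
        """
        up = sum(c for d, c in self.acceptor_hist.items() if d > 0)
        down = sum(c for d, c in self.acceptor_hist.items() if d < 0)
        if down == 0:
            return float("inf") if up else float("nan")
        return up / down

    @property
    def n_in_window(self) -> int:
        return sum(self.donor_hist.values()) + sum(self.acceptor_hist.values())


def positional_density(
    distances: Iterable[SiteDistance], window: int = 30
) -> PositionalDensity:
    """Histogram of strand-adjusted distances within ±``window`` bp per site kind."""
    donor: dict[int, int] = {}
    acceptor: dict[int, int] = {}
    for d in distances:
        v = d.distance
        if abs(v) > window:
            continue
        hist = donor if d.site_kind == "donor" else acceptor
        hist[v] = hist.get(v, 0) + 1
    return PositionalDensity(window=window, donor_hist=donor, acceptor_hist=acceptor)
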