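"""Shared fixtures: hand-built annotations, random intron indexes, and a
reusable simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from missplice.annotation import AnnotatedIntron, GenomeAnnotation
from missplice.junctions import JunctionRecord


def write_gtf(path, transcripts):
    """Write a minimal Ensembl-dialect GTF.

    ``transcripts``: list of (tx_id, gene_id, chrom, strand, biotype, exons)
    with exons as 0-based half-open (start, end) tuples.
    """
    with open(path, "w") as fh:
        for tx_id, gene_id, chrom, strand, biotype, exons in transcripts:
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                f'gene_biotype "protein_coding"; transcript_biotype "{biotype}";'
            )
            for start, end in exons:
                fh.write(
                    f"{chrom}\ttest\texon\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
                )
    return path


def brute_force_introns(transcripts):
    """Independent oracle: per-transcript gap enumeration, then dedupe."""
    found = {}
    for tx_id, gene_id, chrom, strand, _biotype, exons in transcripts:
        exons = sorted(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                found.setdefault((chrom, e1, s2, strand), set()).add(tx_id)
    return found


def make_intron(i, chrom, start, end, strand, gene="G", **kw):
    defaults = dict(
        intron_id=f"I{i:05d}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        gene_id=gene,
        transcript_ids=frozenset({f"{gene}.t0"}),
        n_gene_transcripts=1,
        pct_protein_coding=1.0,
        is_mane=True,
    )
    defaults.update(kw)
    return AnnotatedIntron(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_annotation(rng, n_introns=100, chroms=("chr1", "chr2"), span=100_000):
    """A random intron index with occasional shared donor/acceptor sites."""
    introns = []
    seen = set()
    i = 0
    while len(introns) < n_introns:
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1000, span))
        length = int(rng.integers(80, 5000))
        key = (chrom, start, start + length, strand)
        if key in seen:
            continue
        seen.add(key)
        introns.append(make_intron(i, chrom, start, start + length, strand, gene=f"G{i % 37}"))
        i += 1
        # sometimes add a second intron sharing this one's donor site
        if rng.random() < 0.15:
            length2 = int(rng.integers(80, 5000))
            key2 = (chrom, start, start + length2, strand) if strand == "+" else (
                chrom, start + length - length2, start + length, strand)
            if key2 not in seen and key2[2] > key2[1]:
                seen.add(key2)
                introns.append(
                    make_intron(i, key2[0], key2[1], key2[2], strand, gene=f"G{i % 37}")
                )
                i += 1
    return GenomeAnnotation(introns)


def random_junctions(rng, annotation, n=1000, novel_frac=0.6):
    """Junctions around a random annotation: a mix of exact, one-side-shared,
    and unrelated intervals."""
    introns = list(annotation)
    out = []
    for k in range(n):
        u = rng.random()
        count = int(rng.integers(1, 50))
        if u < 0.25:  # exact annotated interval
            intron = introns[int(rng.integers(len(introns)))]
            rec = JunctionRecord(intron.chrom, intron.start, intron.end, intron.strand,
                                 {"s": count})
        elif u < 0.25 + novel_frac:  # shift one boundary of a real intron
            intron = introns[int(rng.integers(len(introns)))]
            delta = int(rng.integers(1, 40)) * (1 if rng.random() < 0.5 else -1)
            if rng.random() < 0.5:
                start, end = intron.start + delta, intron.end
            else:
                start, end = intron.start, intron.end + delta
            if end - start < 1:
                start, end = intron.start, intron.end + abs(delta)
            rec = JunctionRecord(intron.chrom, start, end, intron.strand, {"s": count})
        else:  # unrelated interval
            chrom = intron = introns[int(rng.integers(len(introns)))].chrom
            start = int(rng.integers(0, 90_000))
            rec = JunctionRecord(chrom, start, start + int(rng.integers(30, 3000)),
                                 "+" if rng.random() < 0.5 else "-", {"s": count})
        out.append(rec)
    return out


def brute_force_classify(junctions, annotation):
    """All-pairs oracle for junction categories and unique assignment."""
    introns = list(annotation)
    ann_support = {}
    results = []
    for jxn in junctions:
        exact = [i for i in introns if i.key == jxn.key]
        if exact:
            ann_support[exact[0].intron_id] = (
                ann_support.get(exact[0].intron_id, 0) + jxn.total_count()
            )
    for jxn in junctions:
        donor = jxn.start if jxn.strand == "+" else jxn.end
        acceptor = jxn.end if jxn.strand == "+" else jxn.start
        exact = [i for i in introns if i.key == jxn.key]
        if exact:
            results.append(("annotated", exact[0].intron_id))
            continue
        donor_hits = [
            i for i in introns
            if i.chrom == jxn.chrom and i.strand == jxn.strand and i.donor_coord == donor
        ]
        acceptor_hits = [
            i for i in introns
            if i.chrom == jxn.chrom and i.strand == jxn.strand and i.acceptor_coord == acceptor
        ]
        if acceptor_hits and not donor_hits:
            pick = min(
                acceptor_hits,
                key=lambda i: (-ann_support.get(i.intron_id, 0), i.intron_length, i.intron_id),
            )
            results.append(("novel_donor", pick.intron_id))
        elif donor_hits and not acceptor_hits:
            pick = min(
                donor_hits,
                key=lambda i: (-ann_support.get(i.intron_id, 0), i.intron_length, i.intron_id),
            )
            results.append(("novel_acceptor", pick.intron_id))
        else:
            results.append(("unassigned", None))
    return results
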