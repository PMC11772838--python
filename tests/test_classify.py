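"""QC filters, junction classification, unique assignment, reclassification."""

from collections import Counter

import pytest

from missplice.annotation import GenomeAnnotation, RegionMask
from missplice.classify import (
    ClassificationError,
    apply_qc,
    assign_unique,
    classify,
    classify_junctions,
    reclassification_rate,
)
from missplice.junctions import JunctionRecord

from conftest import (
    brute_force_classify,
    make_intron,
    random_annotation,
    random_junctions,
)


def jxn(chrom, start, end, strand, count=10, sample="s"):
    return JunctionRecord(chrom, start, end, strand, {sample: count})


class TestQc:
    def test_length_24_flagged_too_short(self):
        (cj,) = apply_qc([jxn("chr1", 100, 124, "+")])
        assert cj.qc_flags == {"too_short"}

    def test_length_25_boundary_passes(self):
        (cj,) = apply_qc([jxn("chr1", 100, 125, "+")], placed_chroms={"chr1"})
        assert cj.qc_flags == set()

    def test_filters_are_independent(self):
        mask = RegionMask([("chr1", 0, 200)])
        minor = RegionMask([("chr1", 100, 150)])
        (cj,) = apply_qc([jxn("chr1", 100, 150, "+")], blacklist=mask, minor_introns=minor)
        assert cj.qc_flags == {"blacklisted", "minor_intron"}

    def test_undefined_strand_and_unplaced_flags(self):
        (cj,) = apply_qc([jxn("chrUn_scaffold", 100, 200, "?")], placed_chroms={"chr1"})
        assert cj.qc_flags == {"undefined_strand", "unplaced_contig"}

    def test_flagged_junctions_stay_unassigned(self):
        ann = GenomeAnnotation([make_intron(0, "chr1", 100, 200, "+")])
        classified = classify(apply_qc([jxn("chr1", 100, 200, "?")]), ann)
        assert classified[0].category == "unassigned"


class TestClassify:
    @pytest.fixture
    def ann(self):
        return GenomeAnnotation(
            [
                make_intron(0, "chr1", 200, 300, "+"),
                make_intron(1, "chr1", 200, 300, "-"),
            ]
        )

    def test_exact_match_is_annotated(self, ann):
        (cj,) = classify(apply_qc([jxn("chr1", 200, 300, "+")]), ann)
        assert cj.category == "annotated"

    def test_shared_donor_means_novel_acceptor_plus_strand(self, ann):
        (cj,) = classify(apply_qc([jxn("chr1", 200, 350, "+")]), ann)
        assert cj.category == "novel_acceptor"

    def test_strand_mirror_of_shared_donor(self, ann):
        # on the minus strand the donor sits at the interval end
        (cj,) = classify(apply_qc([jxn("chr1", 150, 300, "-")]), ann)
        assert cj.category == "novel_acceptor"

    def test_shared_acceptor_means_novel_donor(self, ann):
        (cj,) = classify(apply_qc([jxn("chr1", 150, 300, "+")]), ann)
        assert cj.category == "novel_donor"

    def test_no_shared_boundary_unassigned(self, ann):
        (cj,) = classify(apply_qc([jxn("chr1", 150, 350, "+")]), ann)
        assert cj.category == "unassigned"

    def test_exon_skipping_product_unassigned(self):
        # donor of one intron + acceptor of another: both boundaries annotated
        ann = GenomeAnnotation(
            [
                make_intron(0, "chr1", 200, 300, "+"),
                make_intron(1, "chr1", 400, 500, "+"),
            ]
        )
        (cj,) = classify(apply_qc([jxn("chr1", 200, 500, "+")]), ann)
        assert cj.category == "unassigned"

    def test_categories_match_allpairs_bruteforce(self, rng):
        ann = random_annotation(rng, n_introns=100)
        junctions = random_junctions(rng, ann, n=1000)
        classified = assign_unique(classify(apply_qc(junctions), ann), ann)
        expected = brute_force_classify(junctions, ann)
        got = [
            (cj.category, cj.assigned_intron_id if cj.category != "annotated" else None)
            for cj in classified
        ]
        want = [
            (cat, iid if cat != "annotated" else None) for cat, iid in expected
        ]
        assert got == want

    def test_category_conservation(self, rng):
        ann = random_annotation(rng, n_introns=60)
        junctions = random_junctions(rng, ann, n=500)
        classified = classify(apply_qc(junctions), ann)
        counts = Counter(c.category for c in classified)
        assert sum(counts.values()) == 500

    def test_strand_mirror_preserves_category_multiset(self, rng):
        span = 100_000
        ann = random_annotation(rng, n_introns=60)
        junctions = random_junctions(rng, ann, n=400)
        flip = {"+": "-", "-": "+", "?": "?"}
        mirrored_ann = GenomeAnnotation(
            [
                make_intron(k, i.chrom, span - i.end + 5000, span - i.start + 5000,
                            flip[i.strand], gene=i.gene_id)
                for k, i in enumerate(ann)
            ]
        )
        mirrored_jxn = [
            JunctionRecord(j.chrom, span - j.end + 5000, span - j.start + 5000,
                           flip[j.strand], dict(j.counts))
            for j in junctions
        ]
        orig = Counter(c.category for c in classify(apply_qc(junctions), ann))
        mirr = Counter(c.category for c in classify(apply_qc(mirrored_jxn), mirrored_ann))
        assert orig == mirr

    def test_raising_min_length_only_removes(self, rng):
        ann = random_annotation(rng, n_introns=60)
        junctions = random_junctions(rng, ann, n=400)
        kept_at = {}
        for min_length in (25, 50, 100, 500):
            classified = classify(apply_qc(junctions, min_length=min_length), ann)
            kept_at[min_length] = {
                j.junction.key for j in classified if j.category != "unassigned"
            }
        assert kept_at[500] <= kept_at[100] <= kept_at[50] <= kept_at[25]


class TestAssignUnique:
    def test_single_candidate(self):
        ann = GenomeAnnotation([make_intron(0, "chr1", 200, 300, "+")])
        classified = classify_junctions([jxn("chr1", 200, 350, "+")], ann)
        assert classified[0].assigned_intron_id == "I00000"

    def test_annotated_support_breaks_competition(self):
        # two introns share the donor at 200; support 100 vs 10
        ann = GenomeAnnotation(
            [
                make_intron(0, "chr1", 200, 700, "+"),
                make_intron(1, "chr1", 200, 300, "+"),
            ]
        )
        junctions = [
            jxn("chr1", 200, 700, "+", count=100),
            jxn("chr1", 200, 300, "+", count=10),
            jxn("chr1", 200, 900, "+", count=1),  # novel acceptor, shares the donor
        ]
        classified = classify_junctions(junctions, ann)
        novel = [c for c in classified if c.category == "novel_acceptor"]
        assert novel[0].assigned_intron_id == "I00000"

    def test_tie_broken_by_shortest_intron(self):
        ann = GenomeAnnotation(
            [
                make_intron(0, "chr1", 200, 700, "+"),  # 500 bp
                make_intron(1, "chr1", 200, 500, "+"),  # 300 bp
            ]
        )
        junctions = [
            jxn("chr1", 200, 700, "+", count=10),
            jxn("chr1", 200, 500, "+", count=10),
            jxn("chr1", 200, 900, "+", count=1),
        ]
        classified = classify_junctions(junctions, ann)
        novel = [c for c in classified if c.category == "novel_acceptor"]
        assert novel[0].assigned_intron_id == "I00001"

    def test_missing_site_is_internal_error(self):
        ann = GenomeAnnotation([make_intron(0, "chr1", 200, 300, "+")])
        classified = classify(apply_qc([jxn("chr1", 150, 300, "+")]), ann)
        classified[0].junction.end = 999  # corrupt after classification
        with pytest.raises(ClassificationError):
            assign_unique(classified, ann)


class TestReclassification:
    def test_rate_arithmetic(self):
        # old: one intron; new: adds the previously-novel acceptor interval
        old = GenomeAnnotation([make_intron(0, "chr1", 200, 300, "+")])
        new = GenomeAnnotation(
            [
                make_intron(0, "chr1", 200, 300, "+"),
                make_intron(1, "chr1", 200, 400, "+"),
            ]
        )
        junctions = [jxn("chr1", 200, 400, "+")] + [
            jxn("chr1", 200, 400 + 3 * k, "+") for k in range(1, 101)
        ]
        res = reclassification_rate(old, new, junctions)
        assert (res.n_reclassified, res.n_retained) == (1, 100)
        assert res.rate == pytest.approx(0.01)

    def test_identical_annotations_give_zero_rate(self):
        ann = GenomeAnnotation([make_intron(0, "chr1", 200, 300, "+")])
        junctions = [jxn("chr1", 200, 400 + k, "+") for k in range(60)]
        res = reclassification_rate(ann, ann, junctions)
        assert res.n_reclassified == 0 and res.rate == 0.0

    def test_hand_counted_two_version_fixture(self):
        old_introns = [make_intron(i, "chr1", 1000 * (i + 1), 1000 * (i + 1) + 200, "+")
                       for i in range(10)]
        old = GenomeAnnotation(old_introns)
        # new annotation adopts 3 specific novel intervals
        adopted = [(1000, 1300), (2000, 2350), (3000, 3400)]
        new = GenomeAnnotation(
            old_introns
            + [make_intron(100 + k, "chr1", s, e, "+") for k, (s, e) in enumerate(adopted)]
        )
        junctions = [jxn("chr1", s, e, "+") for s, e in adopted]
        # 60 novel-acceptor junctions that stay novel under both versions
        junctions += [
            jxn("chr1", 1000 * (1 + k % 10), 1000 * (1 + k % 10) + 500 + k, "+")
            for k in range(60)
        ]
        res = reclassification_rate(old, new, junctions)
        assert (res.n_reclassified, res.n_retained) == (3, 60)
        assert res.rate == pytest.approx(0.05)
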