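"""Synthetic reference and cohort generator: determinism, construction
guarantees and estimator consistency."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from missplice.annotation import load_annotation
from missplice.classify import classify_junctions
from missplice.junctions import merge_junctions, read_junctions
from missplice.metrics import msr_table
from missplice.scoring import extract_site_sequence
from missplice.simulate import (
    SimulationConfig,
    generate_reference,
    intron_key_str,
    preset_config,
    sample_table,
    simulate_count_matrices,
    simulate_junction_counts,
    true_msr,
)


def file_hashes(directory):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(directory).iterdir())
        if p.is_file()
    }


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    cfg = preset_config("null", n_genes=15, n_samples_per_group=4)
    ref = generate_reference(cfg, seed=3, outdir=outdir)
    metas, truth, paths = simulate_junction_counts(ref, seed=4, outdir=outdir)
    return cfg, ref, metas, truth, paths, outdir


class TestReference:
    def test_seeded_runs_are_byte_identical(self, tmp_path):
        cfg = preset_config("null", n_genes=10, n_samples_per_group=3)
        for d in ("a", "b"):
            ref = generate_reference(cfg, seed=9, outdir=tmp_path / d)
            simulate_junction_counts(ref, seed=10, outdir=tmp_path / d)
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_annotated_sites_carry_canonical_dinucleotides(self, small_run):
        _, ref, *_ = small_run
        genome = {c: ref.sequence_str(c) for c in ref.sequences}
        for intron in ref.introns[:30]:
            donor = extract_site_sequence(
                genome, intron.chrom,
                intron.start if intron.strand == "+" else intron.end,
                intron.strand, "donor",
            )
            acceptor = extract_site_sequence(
                genome, intron.chrom,
                intron.end if intron.strand == "+" else intron.start,
                intron.strand, "acceptor",
            )
            assert donor[3:5] == "GT"
            assert acceptor[18:20] == "AG"

    def test_gtf_reproduces_planted_introns(self, small_run):
        _, ref, _, _, _, outdir = small_run
        ann = load_annotation(outdir / "annotation.gtf")
        assert set(ann.by_interval) == {i.key for i in ref.introns}

    def test_intron_lengths_respect_minimum(self, small_run):
        _, ref, *_ = small_run
        assert all(i.end - i.start >= ref.config.intron_length_min for i in ref.introns)

    def test_cryptic_junctions_classify_to_their_introns(self, small_run):
        _, ref, _, truth, paths, outdir = small_run
        ann = load_annotation(outdir / "annotation.gtf")
        junctions = merge_junctions(
            read_junctions(p, "star_sj", sample_id=s)
            for s, p in paths.items() if s != "metadata"
        )
        classified = classify_junctions(junctions, ann)
        by_key = {c.junction.key: c for c in classified}
        checked = 0
        for _, row in truth.cryptic_sites.iterrows():
            # parse the emitted junction key back
            chrom, rest = row["junction"].split(":")
            coords, strand = rest[:-3], rest[-2]
            start, end = map(int, coords.split("-"))
            cj = by_key.get((chrom, start, end, strand))
            if cj is None:
                continue  # site received no reads in this cohort
            expected_cat = "novel_donor" if row["site_kind"] == "donor" else "novel_acceptor"
            assert cj.category == expected_cat
            assert intron_key_str(
                (lambda i: i.key)(ann.introns[cj.assigned_intron_id])
            ) == row["intron"]
            checked += 1
        assert checked > 10

    def test_zero_cryptic_sites_give_only_annotated(self, tmp_path):
        cfg = preset_config(
            "null", n_genes=8, n_samples_per_group=3,
            n_cryptic_donor=0, n_cryptic_acceptor=0, n_minor_introns=0,
        )
        ref = generate_reference(cfg, seed=21, outdir=tmp_path)
        _, _, paths = simulate_junction_counts(ref, seed=22, outdir=tmp_path)
        ann = load_annotation(tmp_path / "annotation.gtf")
        junctions = merge_junctions(
            read_junctions(p, "star_sj", sample_id=s)
            for s, p in paths.items() if s != "metadata"
        )
        classified = classify_junctions(junctions, ann)
        assert {c.category for c in classified} == {"annotated"}


class TestCounts:
    def test_category_totals_conserve_depth(self, small_run):
        cfg, ref, metas, _, _, _ = small_run
        rng = np.random.default_rng(77)
        metas2 = sample_table(cfg, rng)
        mats = simulate_count_matrices(ref, metas2, rng)
        totals = (
            mats["novel_donor"].sum(axis=0)
            + mats["novel_acceptor"].sum(axis=0)
            + mats["annotated"].sum(axis=0)
        )
        for meta in metas2:
            assert totals[meta.sample_id] == meta.mapped_depth

    def test_zero_error_probabilities_give_zero_msr(self, tmp_path):
        cfg = preset_config("null", n_genes=8, n_samples_per_group=3,
                            p_d_mean=0.0, p_a_mean=0.0)
        ref = generate_reference(cfg, seed=31, outdir=tmp_path)
        rng = np.random.default_rng(32)
        mats = simulate_count_matrices(ref, sample_table(cfg, rng), rng)
        assert int(mats["novel_donor"].to_numpy().sum()) == 0
        assert int(mats["novel_acceptor"].to_numpy().sum()) == 0

    def test_acceptor_to_donor_ratio_recovered(self, tmp_path):
        cfg = preset_config("null", n_genes=30, n_samples_per_group=10,
                            p_d_mean=0.002, p_a_mean=0.004, depth_mean=8000.0)
        ref = generate_reference(cfg, seed=41, outdir=tmp_path)
        rng = np.random.default_rng(42)
        mats = simulate_count_matrices(ref, sample_table(cfg, rng), rng)
        nd = mats["novel_donor"].to_numpy().sum()
        na = mats["novel_acceptor"].to_numpy().sum()
        ann = mats["annotated"].to_numpy().sum()
        ratio = (na / (na + ann)) / (nd / (nd + ann))
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_group_multiplier_scales_msr_estimand(self, tmp_path):
        cfg = preset_config("age", n_genes=10, n_samples_per_group=3)
        ref = generate_reference(cfg, seed=51, outdir=tmp_path)
        for intron in ref.introns[:5]:
            young_d, young_a = true_msr(intron, "young", cfg)
            old_d, old_a = true_msr(intron, "old", cfg)
            assert old_d == pytest.approx(1.5 * young_d)
            assert old_a == pytest.approx(1.5 * young_a)

    def test_frame_preservation_weight_is_monotone(self):
        """Raising w0 raises the planted mod3=0 proportion across seeds."""
        props = []
        for w0 in (0.2, 0.374, 0.6):
            zero = total = 0
            for seed in range(3):
                cfg = SimulationConfig(n_genes=40, frame_preservation_weight=w0)
                import tempfile

                ref = generate_reference(cfg, seed=seed, outdir=tempfile.mkdtemp())
                for intron in ref.introns:
                    for s in intron.cryptic_donors + intron.cryptic_acceptors:
                        zero += abs(s.distance) % 3 == 0
                        total += 1
            props.append(zero / total)
        assert props[0] < props[1] < props[2]

    def test_truth_probabilities_recovered_by_pooled_msr(self, tmp_path):
        cfg = preset_config("null", n_genes=20, n_samples_per_group=10,
                            p_concentration=30.0, depth_mean=8000.0)
        ref = generate_reference(cfg, seed=61, outdir=tmp_path)
        rng = np.random.default_rng(62)
        mats = simulate_count_matrices(ref, sample_table(cfg, rng), rng)
        nd = mats["novel_donor"].sum(axis=1)
        ann = mats["annotated"].sum(axis=1)
        covered = 0
        eligible = 0
        for intron in ref.introns:
            key = intron_key_str(intron.key)
            n = nd[key] + ann[key]
            if ann[key] < 1000:
                continue
            eligible += 1
            p_true, _ = true_msr(intron, "a", cfg)
            msr = nd[key] / n
            half = 1.96 * np.sqrt(p_true * (1 - p_true) / n)
            covered += abs(msr - p_true) <= half
        assert eligible > 10
        assert covered / eligible >= 0.9
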