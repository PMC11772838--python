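"""Synthetic reference and junction-count cohorts with known ground truth.

The generator builds a small genome in which every pipeline stage is
exercised end-to-end using only standard file formats:

* a multi-gene, multi-transcript annotation (GTF) whose introns carry
  canonical GT/AG dinucleotides and strong donor/acceptor motifs in the
  genome sequence (FASTA);
* cryptic splice sites planted near annotated boundaries at controlled
  signed distances (reading-frame preference and AG-exclusion-zone
  suppression are tunable) with deliberately weaker motifs;
* conservation and constraint tracks (bedGraph) over the proximal intronic
  windows, correlated with the planted per-intron error rates;
* blacklist / minor-intron masks (BED) and a MANE transcript list;
* per-sample junction count tables (STAR ``SJ.out.tab`` dialect) drawn from
  a negative-binomial depth model in which novel reads are a multinomial
  split of each intron's total flux — so the pooled mis-splicing ratio is
  the natural estimand of the planted error probability;
* a sample metadata table with group labels, ages, RIN and factor TPMs.

Group-level multipliers emulate the study designs: an ageing effect, a
knockdown effect restricted to a targeted intron set, and a disease effect
driven by the fold-change of a causal expression factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import SampleMeta
from .junctions import JunctionRecord, write_junctions

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DONOR_CONSENSUS = "CAGGTAAGT"  # 3 exonic + 6 intronic
ACCEPTOR_CONSENSUS = "CTTTTTTTTTTTTTTTTCAGGTG"  # 20 intronic + 3 exonic
DONOR_FIXED = {3: "G", 4: "T"}  # canonical GT, never mutated
ACCEPTOR_FIXED = {18: "A", 19: "G"}  # canonical AG, never mutated


@dataclass
class SimulationConfig:
    """All knobs of the generator; seeded runs are bit-reproducible."""

    # reference geometry
    n_genes: int = 30
    n_chroms: int = 2
    introns_per_gene_mean: float = 3.0
    extra_transcripts_mean: float = 1.0
    exon_length_mean: float = 120.0
    exon_length_min: int = 40
    intron_length_mu: float = 7.57  # log-scale; echoes the genome-wide length landscape
    intron_length_sigma: float = 1.71
    intron_length_min: int = 80
    intron_length_max: int = 50_000
    intergenic_gap: int = 300

    # cryptic-site landscape
    n_cryptic_donor: int = 2
    n_cryptic_acceptor: int = 2
    max_cryptic_distance: int = 60
    frame_preservation_weight: float = 0.374  # P(|distance| % 3 == 0)
    acceptor_upstream_suppression: float = 0.3  # intronic-side odds factor (< 1 = depleted)
    annotated_mutation_rate: float = 0.10
    cryptic_mutation_rate: float = 0.45
    cryptic_score_gap_scale: float = 3.0  # Exp scale of strength deficit vs annotated
    softmax_temperature: float = 2.0

    # error probabilities
    p_d_mean: float = 0.002
    p_a_mean: float = 0.005
    p_concentration: float | None = None  # None = constant across introns; else Beta

    # cohort
    group_multipliers: dict[str, float] = field(default_factory=lambda: {"control": 1.0})
    group_ages: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_samples_per_group: int = 20
    depth_mean: float = 5000.0  # mean annotated+novel flux per intron per sample
    depth_dispersion: float = 0.3
    expression_sigma: float = 0.5
    rin_range: tuple[float, float] = (6.0, 10.0)

    # knockdown design: multiplier applies only to targeted introns in these groups
    kd_groups: frozenset = frozenset()
    kd_multiplier: float = 1.0
    kd_targeted_fraction: float = 0.5

    # expression factors for the correction/ranking design
    factor_names: tuple[str, ...] = ()
    causal_factor: str | None = None
    causal_fold_change: float = 0.5  # case/control TPM ratio of the causal factor
    factor_tpm_base: float = 100.0
    factor_tpm_sigma: float = 0.1
    case_groups: frozenset = frozenset()

    # masks and tracks
    n_minor_introns: int = 2
    n_blacklist_regions: int = 2
    cons_base: float = 0.85
    cons_slope: float = 0.4
    cdts_slope: float = 1.0
    track_noise_sd: float = 0.05


def preset_config(name: str, **overrides) -> SimulationConfig:
    """Named study designs: ``null``, ``age``, ``knockdown``, ``disease``."""
    if name == "null":
        cfg = SimulationConfig(group_multipliers={"a": 1.0, "b": 1.0})
    elif name == "age":
        cfg = SimulationConfig(
            group_multipliers={"young": 1.0, "mid": 1.2, "old": 1.5},
            group_ages={"young": (20, 39), "mid": (40, 59), "old": (60, 79)},
        )
    elif name == "knockdown":
        cfg = SimulationConfig(
            group_multipliers={"control": 1.0, "case": 1.0},
            kd_groups=frozenset({"case"}),
            kd_multiplier=5.0,
        )
    elif name == "disease":
        # 24 + 24 depth-matched samples; per-intron junction coverage of a few
        # hundred reads reflects a typical polyA bulk brain library
        cfg = SimulationConfig(
            group_multipliers={"control": 1.0, "case": 2.0},
            case_groups=frozenset({"case"}),
            factor_names=("SF1", "SF2", "SF3", "SF4", "SF5"),
            causal_factor="SF1",
            causal_fold_change=0.5,
            n_samples_per_group=24,
            depth_mean=500.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return dataclasses.replace(cfg, **overrides)


@dataclass
class CrypticSite:
    position: int  # boundary coordinate of the novel junction at this site
    distance: int  # strand-adjusted signed distance from the annotated site
    strength: float  # latent motif strength driving read allocation
    junction: tuple[str, int, int, str]  # (chrom, start, end, strand)


@dataclass
class SimIntron:
    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    upstream_exon: tuple[int, int]  # exon on the donor side (transcript 5')
    downstream_exon: tuple[int, int]
    expression: float
    p_d: float
    p_a: float
    cryptic_donors: list[CrypticSite] = field(default_factory=list)
    cryptic_acceptors: list[CrypticSite] = field(default_factory=list)
    targeted: bool = False
    is_minor: bool = False

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class SimReference:
    config: SimulationConfig
    sequences: dict[str, np.ndarray]  # chrom -> array of single characters
    introns: list[SimIntron]
    gtf_lines: list[str]
    mane_transcripts: set[str]
    blacklist: list[tuple[str, int, int]]
    paths: dict[str, Path] = field(default_factory=dict)

    def sequence_str(self, chrom: str) -> str:
        return "".join(self.sequences[chrom])


@dataclass
class GroundTruth:
    """Per-intron true error probabilities per group and novel-site provenance."""

    intron_probs: pd.DataFrame  # index: intron key str; columns: group -> (p_d, p_a)
    cryptic_sites: pd.DataFrame
    targeted: set[tuple[str, int, int, str]]
    causal_factor: str | None
    factor_fold_changes: dict[str, float]


def intron_key_str(key: tuple[str, int, int, str]) -> str:
    chrom, start, end, strand = key
    return f"{chrom}:{start}-{end}({strand})"


def _mutate(rng, motif: str, rate: float, fixed: Mapping[int, str]) -> str:
    out = []
    for i, base in enumerate(motif):
        if i in fixed:
            out.append(fixed[i])
        elif rng.random() < rate:
            out.append(str(rng.choice(_BASES)))
        else:
            out.append(base)
    return "".join(out)


def _write_motif(seq: np.ndarray, start: int, motif: str, strand: str) -> None:
    if strand == "-":
        motif = "".join(_COMPLEMENT[b] for b in reversed(motif))
    seq[start : start + len(motif)] = list(motif)


def _plant_donor(seq: np.ndarray, coord: int, strand: str, motif: str) -> None:
    # motif is in transcript orientation: 3 exonic + 6 intronic around the boundary
    start = coord - 3 if strand == "+" else coord - 6
    _write_motif(seq, start, motif, strand)


def _plant_acceptor(seq: np.ndarray, coord: int, strand: str, motif: str) -> None:
    start = coord - 20 if strand == "+" else coord - 3
    _write_motif(seq, start, motif, strand)


def _draw_length(rng, cfg: SimulationConfig) -> int:
    raw = int(round(rng.lognormal(cfg.intron_length_mu, cfg.intron_length_sigma)))
    return int(np.clip(raw, cfg.intron_length_min, cfg.intron_length_max))


def _draw_distance(
    rng, cfg: SimulationConfig, limit: int
) -> int | None:
    """Magnitude respecting the frame-preservation weight, bounded by ``limit``."""
    limit = min(limit, cfg.max_cryptic_distance)
    if limit < 1:
        return None
    w0 = cfg.frame_preservation_weight
    probs = np.array([w0, (1 - w0) / 2, (1 - w0) / 2])
    for _ in range(10):
        cls = rng.choice(3, p=probs)
        candidates = [m for m in range(1, limit + 1) if m % 3 == cls]
        if candidates:
            return int(candidates[rng.integers(len(candidates))])
    return None


def _exon_interval_on_side(
    exons: Sequence[tuple[int, int]], idx: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(left exon, right exon) flanking intron idx in genomic order."""
    return exons[idx], exons[idx + 1]


def generate_reference(cfg: SimulationConfig, seed: int, outdir: str | Path) -> SimReference:
    """Build and write the synthetic genome, annotation, tracks and masks."""
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursors = {c: 200 for c in chrom_names}
    gene_layouts = []  # (gene_id, chrom, strand, exons, n_introns)

    for g in range(cfg.n_genes):
        chrom = chrom_names[g % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = 1 + rng.poisson(max(cfg.introns_per_gene_mean - 1, 0))
        exon_lens = [
            max(cfg.exon_length_min, int(round(rng.lognormal(np.log(cfg.exon_length_mean), 0.3))))
            for _ in range(n_introns + 1)
        ]
        intron_lens = [_draw_length(rng, cfg) for _ in range(n_introns)]
        pos = cursors[chrom]
        exons = []
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < n_introns:
                pos += intron_lens[i]
        cursors[chrom] = pos + cfg.intergenic_gap
        gene_layouts.append((f"G{g:04d}", chrom, strand, exons, n_introns))

    chrom_lengths = {c: cursors[c] + 200 for c in chrom_names}
    sequences = {
        c: rng.choice(_BASES, size=chrom_lengths[c]) for c in chrom_names
    }

    # per-intron error probabilities
    def draw_p(mean: float) -> float:
        if cfg.p_concentration is None:
            return mean
        a = mean * cfg.p_concentration
        b = (1 - mean) * cfg.p_concentration
        return float(rng.beta(a, b))

    introns: list[SimIntron] = []
    gtf_lines: list[str] = []
    mane: set[str] = set()

    for gene_id, chrom, strand, exons, n_introns in gene_layouts:
        seq = sequences[chrom]
        gene_start, gene_end = exons[0][0], exons[-1][1]
        gtf_lines.append(
            _gtf_line(chrom, "gene", gene_start, gene_end, strand,
                      f'gene_id "{gene_id}"; gene_biotype "protein_coding";')
        )
        # transcripts: primary spans all exons; extras span contiguous sub-chains
        n_extra = rng.poisson(cfg.extra_transcripts_mean)
        tx_defs = [(f"{gene_id}.t0", 0, len(exons) - 1, "protein_coding")]
        for t in range(n_extra):
            lo = int(rng.integers(0, len(exons) - 1))
            hi = int(rng.integers(lo + 1, len(exons)))
            biotype = "protein_coding" if rng.random() < 0.7 else "lncRNA"
            tx_defs.append((f"{gene_id}.t{t + 1}", lo, hi, biotype))
        mane.add(tx_defs[0][0])
        for tx_id, lo, hi, biotype in tx_defs:
            gtf_lines.append(
                _gtf_line(chrom, "transcript", exons[lo][0], exons[hi][1], strand,
                          f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                          f'gene_biotype "protein_coding"; transcript_biotype "{biotype}";')
            )
            for ex in exons[lo : hi + 1]:
                gtf_lines.append(
                    _gtf_line(chrom, "exon", ex[0], ex[1], strand,
                              f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                              f'gene_biotype "protein_coding"; transcript_biotype "{biotype}";')
                )

        gene_expr = float(rng.lognormal(0.0, cfg.expression_sigma))
        for i in range(n_introns):
            left, right = _exon_interval_on_side(exons, i)
            start, end = left[1], right[0]
            donor_coord = start if strand == "+" else end
            acceptor_coord = end if strand == "+" else start
            intron = SimIntron(
                chrom=chrom, start=start, end=end, strand=strand, gene=gene_id,
                upstream_exon=left if strand == "+" else right,
                downstream_exon=right if strand == "+" else left,
                expression=gene_expr * float(rng.lognormal(0.0, 0.2)),
                p_d=draw_p(cfg.p_d_mean),
                p_a=draw_p(cfg.p_a_mean),
            )
            # cryptic donors
            intron.cryptic_donors = _make_cryptic_sites(
                rng, cfg, intron, kind="donor", seq=seq
            )
            intron.cryptic_acceptors = _make_cryptic_sites(
                rng, cfg, intron, kind="acceptor", seq=seq
            )
            # annotated motifs planted last so they always win overlaps
            _plant_donor(seq, donor_coord, strand,
                         _mutate(rng, DONOR_CONSENSUS, cfg.annotated_mutation_rate, DONOR_FIXED))
            _plant_acceptor(seq, acceptor_coord, strand,
                            _mutate(rng, ACCEPTOR_CONSENSUS, cfg.annotated_mutation_rate,
                                    ACCEPTOR_FIXED))
            introns.append(intron)

    # targeted set for knockdown designs
    n_target = int(round(cfg.kd_targeted_fraction * len(introns)))
    for idx in rng.choice(len(introns), size=n_target, replace=False):
        introns[int(idx)].targeted = True

    # minor-spliceosome introns: masked out of the analysis
    if cfg.n_minor_introns > 0:
        for idx in rng.choice(len(introns), size=min(cfg.n_minor_introns, len(introns)),
                              replace=False):
            introns[int(idx)].is_minor = True

    blacklist = []
    for _ in range(cfg.n_blacklist_regions):
        chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(0, 150))  # upstream margin: never overlaps a gene
        blacklist.append((chrom, pos, pos + 40))

    ref = SimReference(
        config=cfg, sequences=sequences, introns=introns, gtf_lines=gtf_lines,
        mane_transcripts=mane, blacklist=blacklist,
    )
    _write_reference(ref, outdir, rng)
    return ref


def _make_cryptic_sites(rng, cfg, intron: SimIntron, kind: str, seq) -> list[CrypticSite]:
    n = cfg.n_cryptic_donor if kind == "donor" else cfg.n_cryptic_acceptor
    strand = intron.strand
    length = intron.end - intron.start
    sites: list[CrypticSite] = []
    used: set[int] = set()
    for _ in range(n):
        if kind == "donor":
            exonic = rng.random() < 0.5
        else:
            s = cfg.acceptor_upstream_suppression
            exonic = rng.random() >= s / (1 + s)  # upstream (intronic) side suppressed
        if kind == "donor":
            side_limit = (
                (intron.upstream_exon[1] - intron.upstream_exon[0]) - 4
                if exonic else length - 26
            )
        else:
            side_limit = (
                (intron.downstream_exon[1] - intron.downstream_exon[0]) - 4
                if exonic else length - 26
            )
        m = _draw_distance(rng, cfg, side_limit)
        if m is None:
            continue
        # adjusted distance: positive = exonic side for donors, intronic for acceptors
        if kind == "donor":
            adj = m if exonic else -m
            anchor = intron.start if strand == "+" else intron.end
            step = -m if exonic else m  # genomic offset on + strand
            if strand == "-":
                step = -step
        else:
            adj = m if not exonic else -m
            anchor = intron.end if strand == "+" else intron.start
            step = -m if not exonic else m
            if strand == "-":
                step = -step
        pos = anchor + step
        if pos in used:
            continue
        used.add(pos)
        if kind == "donor":
            jxn_start, jxn_end = (
                (pos, intron.end) if strand == "+" else (intron.start, pos)
            )
            motif = _mutate(rng, DONOR_CONSENSUS, cfg.cryptic_mutation_rate, DONOR_FIXED)
            _plant_donor(seq, pos, strand, motif)
        else:
            jxn_start, jxn_end = (
                (intron.start, pos) if strand == "+" else (pos, intron.end)
            )
            motif = _mutate(rng, ACCEPTOR_CONSENSUS, cfg.cryptic_mutation_rate, ACCEPTOR_FIXED)
            _plant_acceptor(seq, pos, strand, motif)
        strength = -float(rng.exponential(cfg.cryptic_score_gap_scale))
        sites.append(
            CrypticSite(
                position=pos, distance=adj, strength=strength,
                junction=(intron.chrom, jxn_start, jxn_end, strand),
            )
        )
    return sites


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    # half-open internal -> 1-based closed GTF
    return f"{chrom}\tsim\t{feature}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"


def _write_reference(ref: SimReference, outdir: Path, rng) -> None:
    cfg = ref.config
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(ref.sequences):
            fh.write(f">{chrom}\n")
            s = ref.sequence_str(chrom)
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        fh.write("\n".join(ref.gtf_lines) + "\n")
    (outdir / "mane.txt").write_text("".join(t + "\n" for t in sorted(ref.mane_transcripts)))
    with open(outdir / "blacklist.bed", "w") as fh:
        for chrom, s, e in ref.blacklist:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(outdir / "minor_introns.bed", "w") as fh:
        for intron in ref.introns:
            if intron.is_minor:
                fh.write(f"{intron.chrom}\t{intron.start}\t{intron.end}\t.\t0\t{intron.strand}\n")

    # conservation (in [0,1], high near accurate sites) and constraint (CDTS-like,
    # positive = weakly constrained) over the 100-bp proximal windows
    cons_lines, cdts_lines = [], []
    for intron in ref.introns:
        rel_d = intron.p_d / max(cfg.p_d_mean, 1e-9)
        rel_a = intron.p_a / max(cfg.p_a_mean, 1e-9)
        for (a, b), rel in zip(_proximal(intron), (rel_d, rel_a)):
            cons = float(np.clip(
                cfg.cons_base - cfg.cons_slope * (rel - 1) / 2
                + rng.normal(0, cfg.track_noise_sd), 0, 1))
            cdts = float(cfg.cdts_slope * (rel - 1) / 2 + rng.normal(0, cfg.track_noise_sd))
            cons_lines.append(f"{intron.chrom}\t{a}\t{b}\t{cons:.4f}")
            cdts_lines.append(f"{intron.chrom}\t{a}\t{b}\t{cdts:.4f}")
    (outdir / "conservation.bedGraph").write_text("\n".join(cons_lines) + "\n")
    (outdir / "constraint.bedGraph").write_text("\n".join(cdts_lines) + "\n")

    ref.paths = {
        "fasta": fasta, "gtf": gtf, "mane": outdir / "mane.txt",
        "blacklist": outdir / "blacklist.bed",
        "minor_introns": outdir / "minor_introns.bed",
        "conservation": outdir / "conservation.bedGraph",
        "constraint": outdir / "constraint.bedGraph",
    }


def _proximal(intron: SimIntron) -> list[tuple[int, int]]:
    if intron.strand == "+":
        return [(intron.start, intron.start + 100), (intron.end - 100, intron.end)]
    return [(intron.end - 100, intron.end), (intron.start, intron.start + 100)]


# ---------------------------------------------------------------------------
# cohort simulation


def sample_table(cfg: SimulationConfig, rng) -> list[SampleMeta]:
    """Draw the sample sheet: groups, ages, RIN and factor TPMs."""
    metas = []
    fold = factor_fold_changes(cfg)
    for group in cfg.group_multipliers:
        lo, hi = cfg.group_ages.get(group, (20, 79))
        for k in range(cfg.n_samples_per_group):
            expression = {}
            for name in cfg.factor_names:
                mean = cfg.factor_tpm_base
                if group in cfg.case_groups:
                    mean *= fold[name]
                expression[name] = float(mean * rng.lognormal(0.0, cfg.factor_tpm_sigma))
            metas.append(
                SampleMeta(
                    sample_id=f"{group}_{k:03d}",
                    group=group,
                    age=float(rng.integers(lo, hi + 1)),
                    rin=float(np.round(rng.uniform(*cfg.rin_range), 2)),
                    mapped_depth=0,
                    expression=expression,
                )
            )
    return metas


def factor_fold_changes(cfg: SimulationConfig) -> dict[str, float]:
    """True case/control TPM fold change per factor (non-causal factors = 1)."""
    return {
        name: (cfg.causal_fold_change if name == cfg.causal_factor else 1.0)
        for name in cfg.factor_names
    }


def effective_probs(intron: SimIntron, group: str, cfg: SimulationConfig) -> tuple[float, float]:
    """Channel probabilities whose implied MSR is the base MSR times the
    group multiplier.

    The multiplier acts on the MSR estimand (``p_d / (1 - p_a)`` under the
    multinomial split), not on the raw channel probabilities, so that a
    group effect of ``m`` scales the measured mis-splicing ratio by exactly
    ``m``; the channel probabilities are recovered by inverting the ratio
    equations.
    """
    mult = cfg.group_multipliers[group]
    if group in cfg.kd_groups and intron.targeted:
        mult *= cfg.kd_multiplier
    msr_d = min(mult * intron.p_d / (1 - intron.p_a), 0.45)
    msr_a = min(mult * intron.p_a / (1 - intron.p_d), 0.45)
    denom = 1 - msr_d * msr_a
    p_d = msr_d * (1 - msr_a) / denom
    p_a = msr_a * (1 - msr_d) / denom
    return p_d, p_a


def true_msr(intron: SimIntron, group: str, cfg: SimulationConfig) -> tuple[float, float]:
    """The exact pooled-MSR estimands implied by :func:`effective_probs`."""
    p_d, p_a = effective_probs(intron, group, cfg)
    return p_d / (1 - p_a), p_a / (1 - p_d)


def simulate_count_matrices(
    ref: SimReference, metas: Sequence[SampleMeta], rng
) -> dict[str, pd.DataFrame]:
    """Intron x sample count matrices for the three read categories.

    Per sample and intron the total junction flux is negative-binomial
    (Poisson with a gamma size factor per sample); novel donor / novel
    acceptor / annotated reads are its multinomial split with the group's
    effective error probabilities. Matrices are indexed by intron key string.
    """
    cfg = ref.config
    introns = ref.introns
    index = [intron_key_str(i.key) for i in introns]
    cols = [m.sample_id for m in metas]
    shape = (len(introns), len(metas))
    nd = np.zeros(shape, dtype=np.int64)
    na = np.zeros(shape, dtype=np.int64)
    ann = np.zeros(shape, dtype=np.int64)
    disp = cfg.depth_dispersion
    expr = np.array([i.expression for i in introns])
    probs = {
        group: np.array([effective_probs(i, group, cfg) for i in introns])
        for group in cfg.group_multipliers
    }
    for j, meta in enumerate(metas):
        size_factor = rng.gamma(1 / disp, disp) if disp > 0 else 1.0
        total = rng.poisson(cfg.depth_mean * expr * size_factor)
        p_d = probs[meta.group][:, 0]
        p_a = probs[meta.group][:, 1]
        # multinomial split via the binomial chain rule, vectorised over introns
        nd[:, j] = rng.binomial(total, p_d)
        na[:, j] = rng.binomial(total - nd[:, j], p_a / (1 - p_d))
        ann[:, j] = total - nd[:, j] - na[:, j]
        meta.mapped_depth = int(total.sum())
    return {
        "novel_donor": pd.DataFrame(nd, index=index, columns=cols),
        "novel_acceptor": pd.DataFrame(na, index=index, columns=cols),
        "annotated": pd.DataFrame(ann, index=index, columns=cols),
    }


def _allocate_to_sites(rng, total: int, sites: list[CrypticSite], temp: float) -> np.ndarray:
    strengths = np.array([s.strength for s in sites])
    w = np.exp(strengths / temp)
    return rng.multinomial(total, w / w.sum())


def simulate_junction_counts(
    ref: SimReference,
    seed: int,
    outdir: str | Path,
) -> tuple[list[SampleMeta], GroundTruth, dict[str, Path]]:
    """Emit per-sample STAR-dialect junction files, the sample sheet and truth.

    Every emitted novel read traces to exactly one planted cryptic site; the
    per-sample file contains the annotated junction of each intron plus any
    cryptic junction with non-zero count.
    """
    cfg = ref.config
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metas = sample_table(cfg, rng)
    matrices = simulate_count_matrices(ref, metas, rng)

    paths: dict[str, Path] = {}
    for j, meta in enumerate(metas):
        records: dict[tuple, int] = {}
        for i, intron in enumerate(ref.introns):
            ann = int(matrices["annotated"].iat[i, j])
            if ann > 0:
                records[intron.key] = records.get(intron.key, 0) + ann
            for mat_name, sites in (
                ("novel_donor", intron.cryptic_donors),
                ("novel_acceptor", intron.cryptic_acceptors),
            ):
                total = int(matrices[mat_name].iat[i, j])
                if total == 0:
                    continue
                if not sites:
                    continue
                alloc = _allocate_to_sites(rng, total, sites, cfg.softmax_temperature)
                for site, c in zip(sites, alloc):
                    if c > 0:
                        records[site.junction] = records.get(site.junction, 0) + int(c)
        recs = [
            JunctionRecord(chrom, start, end, strand, counts={meta.sample_id: c})
            for (chrom, start, end, strand), c in sorted(records.items())
        ]
        path = outdir / f"{meta.sample_id}.SJ.out.tab"
        write_junctions(recs, path, dialect="star_sj", sample_id=meta.sample_id)
        paths[meta.sample_id] = path

    meta_path = outdir / "samples.tsv"
    with open(meta_path, "w") as fh:
        factor_cols = "".join(f"\ttpm_{n}" for n in cfg.factor_names)
        fh.write(f"sample_id\tgroup\tage\trin\tdepth{factor_cols}\n")
        for m in metas:
            tpms = "".join(f"\t{m.expression[n]:.4f}" for n in cfg.factor_names)
            fh.write(f"{m.sample_id}\t{m.group}\t{m.age:.0f}\t{m.rin:.2f}\t{m.mapped_depth}{tpms}\n")
    paths["metadata"] = meta_path

    probs = {}
    for intron in ref.introns:
        row = {}
        for group in cfg.group_multipliers:
            p_d, p_a = effective_probs(intron, group, cfg)
            msr_d, msr_a = true_msr(intron, group, cfg)
            row[f"p_d_{group}"] = p_d
            row[f"p_a_{group}"] = p_a
            row[f"msr_d_{group}"] = msr_d
            row[f"msr_a_{group}"] = msr_a
        probs[intron_key_str(intron.key)] = row
    cryptic_rows = []
    for intron in ref.introns:
        for kind, sites in (("donor", intron.cryptic_donors),
                            ("acceptor", intron.cryptic_acceptors)):
            for s in sites:
                cryptic_rows.append(
                    {
                        "intron": intron_key_str(intron.key),
                        "site_kind": kind,
                        "position": s.position,
                        "distance": s.distance,
                        "strength": s.strength,
                        "junction": intron_key_str(s.junction),
                    }
                )
    truth = GroundTruth(
        intron_probs=pd.DataFrame.from_dict(probs, orient="index"),
        cryptic_sites=pd.DataFrame(cryptic_rows),
        targeted={i.key for i in ref.introns if i.targeted},
        causal_factor=cfg.causal_factor,
        factor_fold_changes=factor_fold_changes(cfg),
    )
    return metas, truth, paths
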