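"""End-to-end validation experiments on the synthetic presets.

Each function builds a cohort with the generator, runs the relevant pipeline
stages, and reduces the outcome to a handful of summary numbers: estimator
coverage, test calibration, power, geometry recovery, and parameter recovery
for the zero-inflated Poisson model. They are used both by the test suite
and by the repository's acceptance script.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from .annotation import load_annotation
from .classify import classify_junctions
from .compare import (
    adjust_pvalues,
    age_stratified_comparison,
    pooled_msr,
    pooled_msr_comparison,
    rank_factor_contributions,
)
from .geometry import mod3_profile, positional_density, site_distances
from .junctions import merge_junctions, read_junctions
from .metrics import msr_table
from .modeling import COVARIATES, fit_zip


def _load_cohort(ref, paths, outdir):
    ann = load_annotation(
        Path(outdir) / "annotation.gtf",
        mane_ids={l.strip() for l in open(Path(outdir) / "mane.txt")},
    )
    junctions = merge_junctions(
        read_junctions(p, "star_sj", sample_id=s)
        for s, p in paths.items()
        if s != "metadata"
    )
    return ann, classify_junctions(junctions, ann)


@dataclass
class MsrRecovery:
    coverage_d: float  # fraction of introns whose pooled MSR_D covers true p
    coverage_a: float
    n_introns: int
    mean_msr_d: float
    mean_msr_a: float
    sign_test_p: float  # one-tailed: acceptor MSR exceeds donor MSR per intron


def msr_recovery(seed: int, n_introns: int = 200, n_samples: int = 20,
                 p_d: float = 0.002, p_a: float = 0.005,
                 depth: float = 5000.0, n_cohorts: int = 3) -> MsrRecovery:
    """Pooled-MSR coverage of the planted error probabilities.

    One intron per gene gives an exact intron count. Coverage uses the exact
    (Clopper-Pearson) 95% binomial interval of the pooled novel-read count,
    whose expected per-intron coverage is ~96%; the realised fraction is
    averaged over ``n_cohorts`` independently seeded cohorts at the same
    conditions so a single cohort's +-1.5% sampling noise cannot dominate.
    """
    cov_d = cov_a = n = 0
    msr_d_vals, msr_a_vals, sign = [], [], []
    for c in range(n_cohorts):
        outdir = tempfile.mkdtemp(prefix="msr_recovery_")
        cfg = sim.preset_config(
            "null", n_genes=n_introns, introns_per_gene_mean=1.0,
            extra_transcripts_mean=0.0, n_samples_per_group=n_samples // 2,
            p_d_mean=p_d, p_a_mean=p_a, depth_mean=depth, n_minor_introns=0,
        )
        cohort_seed = seed + 1000 * c
        ref = sim.generate_reference(cfg, seed=cohort_seed, outdir=outdir)
        metas, truth, paths = sim.simulate_junction_counts(
            ref, seed=cohort_seed + 1, outdir=outdir
        )
        ann, classified = _load_cohort(ref, paths, outdir)
        samples = [m.sample_id for m in metas]
        records = {r.intron_id: r for r in msr_table(classified, samples)}
        truth_by_key = {i.key: sim.true_msr(i, "a", cfg) for i in ref.introns}
        for intron in ann:
            rec = records.get(intron.intron_id)
            if rec is None:
                continue
            td, ta = truth_by_key[intron.key]
            nd, na, s = (
                rec.novel_donor_reads, rec.novel_acceptor_reads, rec.annotated_reads
            )
            if nd + s == 0 or na + s == 0:
                continue
            n += 1
            ci_d = stats.binomtest(nd, nd + s).proportion_ci(0.95)
            ci_a = stats.binomtest(na, na + s).proportion_ci(0.95)
            cov_d += ci_d.low <= td <= ci_d.high
            cov_a += ci_a.low <= ta <= ci_a.high
            msr_d_vals.append(rec.msr_d)
            msr_a_vals.append(rec.msr_a)
            if rec.msr_a != rec.msr_d:
                sign.append(rec.msr_a > rec.msr_d)
    sign_p = stats.binomtest(int(np.sum(sign)), len(sign), 0.5,
                             alternative="greater").pvalue
    return MsrRecovery(
        coverage_d=cov_d / n, coverage_a=cov_a / n, n_introns=n,
        mean_msr_d=float(np.mean(msr_d_vals)), mean_msr_a=float(np.mean(msr_a_vals)),
        sign_test_p=float(sign_p),
    )


def null_calibration(seed: int, n_shuffles: int = 1000, n_genes: int = 50,
                     n_samples_per_group: int = 20, n_cohorts: int = 5) -> tuple[float, int]:
    """Fraction of label shuffles of null cohorts called at p < 0.05.

    A single one-tailed paired Wilcoxon test per shuffle (donor MSR), so the
    FDR-adjusted p equals the raw p; a calibrated test rejects ~5%. The
    shuffles are spread over ``n_cohorts`` independently simulated cohorts:
    the rejection rate conditional on one cohort's counts varies by several
    percent, while the rate the criterion describes is the unconditional one.
    """
    per_cohort = n_shuffles // n_cohorts
    hits = total = 0
    n_introns = 0
    for c in range(n_cohorts):
        cohort_seed = seed + 1000 * c
        cfg = sim.preset_config("null", n_genes=n_genes,
                                n_samples_per_group=n_samples_per_group)
        ref = sim.generate_reference(cfg, seed=cohort_seed, outdir=tempfile.mkdtemp())
        rng = np.random.default_rng(cohort_seed + 1)
        metas = sim.sample_table(cfg, rng)
        mats = sim.simulate_count_matrices(ref, metas, rng)
        samples = np.array([m.sample_id for m in metas])
        half = len(samples) // 2
        n_introns = len(mats["annotated"])
        for _ in range(per_cohort):
            perm = rng.permutation(samples)
            res = pooled_msr_comparison(
                mats["novel_donor"], mats["annotated"],
                list(perm[:half]), list(perm[half:]), sided="one_greater",
            )
            hits += res.p < 0.05
            total += 1
    return hits / total, n_introns


def age_power(seed: int, n_replicates: int = 50, n_genes: int = 50,
              per_bin: int = 26) -> tuple[float, float]:
    """Fraction of replicates where the old-versus-young contrast is called
    (effect > 0.5 at FDR < 0.05 for both site kinds); also the mean donor
    effect size."""
    cfg = sim.preset_config("age", n_genes=n_genes, n_samples_per_group=per_bin)
    ref = sim.generate_reference(cfg, seed=seed, outdir=tempfile.mkdtemp())
    wins = 0
    effects = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + 100 + r)
        metas = sim.sample_table(cfg, rng)
        mats = sim.simulate_count_matrices(ref, metas, rng)
        res = age_stratified_comparison(
            {"donor": mats["novel_donor"], "acceptor": mats["novel_acceptor"]},
            mats["annotated"], metas,
        )
        q = adjust_pvalues([res["donor"].p, res["acceptor"].p], "BH")
        wins += all(r_.effect_size > 0.5 for r_ in res.values()) and bool((q < 0.05).all())
        effects.append(res["donor"].effect_size)
    return wins / n_replicates, float(np.mean(effects))


@dataclass
class CorrectionSummary:
    causal_first_fraction: float
    mean_corrected_effect: float
    mean_uncorrected_effect: float
    n_replicates: int


def correction_ranking(seed: int, n_replicates: int = 100,
                       n_genes: int = 240) -> CorrectionSummary:
    """Inverse-fold-change correction on the disease preset.

    The causal factor is 2-fold downregulated in cases and fully drives the
    MSR increase; correction should return the case-versus-control effect to
    0.5 on average and the causal factor should rank first by contribution.
    """
    cfg = sim.preset_config("disease", n_genes=n_genes)
    ref = sim.generate_reference(cfg, seed=seed, outdir=tempfile.mkdtemp())
    top = 0
    corrected, uncorrected = [], []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + 200 + r)
        metas = sim.sample_table(cfg, rng)
        mats = sim.simulate_count_matrices(ref, metas, rng)
        case = [m.sample_id for m in metas if m.group == "case"]
        ctrl = [m.sample_id for m in metas if m.group == "control"]
        msr_case = pooled_msr(mats["novel_donor"], mats["annotated"], case)
        msr_ctrl = pooled_msr(mats["novel_donor"], mats["annotated"], ctrl)
        factors = {
            name: (
                [m.expression[name] for m in metas if m.group == "case"],
                [m.expression[name] for m in metas if m.group == "control"],
            )
            for name in cfg.factor_names
        }
        table = rank_factor_contributions(msr_case, msr_ctrl, factors)
        top += table.iloc[0]["factor"] == cfg.causal_factor
        row = table.set_index("factor").loc[cfg.causal_factor]
        corrected.append(row["corrected_effect"])
        uncorrected.append(row["uncorrected_effect"])
    return CorrectionSummary(
        causal_first_fraction=top / n_replicates,
        mean_corrected_effect=float(np.mean(corrected)),
        mean_uncorrected_effect=float(np.mean(uncorrected)),
        n_replicates=n_replicates,
    )


@dataclass
class GeometryRecovery:
    proportions: tuple[float, float, float]
    n_sites: int
    within_ci: bool
    asymmetries: list[float]


def geometry_recovery(seed: int, n_genes: int = 150, n_asym_replicates: int = 5,
                      w0: float = 0.374) -> GeometryRecovery:
    """Recover the frame-preservation weight and the acceptor-side asymmetry.

    The mod3 check uses simultaneous (Bonferroni-adjusted) binomial intervals
    around the generator's class weights; the asymmetry check re-simulates
    several seeds and requires the upstream/downstream acceptor ratio below 1
    in each (upstream suppression < 1 emulates the AG exclusion zone).
    """
    cfg = sim.preset_config("null", n_genes=n_genes, n_samples_per_group=10,
                            frame_preservation_weight=w0,
                            p_d_mean=0.01, p_a_mean=0.02)
    outdir = tempfile.mkdtemp(prefix="geom_")
    ref = sim.generate_reference(cfg, seed=seed, outdir=outdir)
    metas, truth, paths = sim.simulate_junction_counts(ref, seed=seed + 1, outdir=outdir)
    ann, classified = _load_cohort(ref, paths, outdir)
    distances = site_distances(classified, ann)
    profile = mod3_profile(distances, ann, max_abs_distance=100, mane_only=True)
    weights = (w0, (1 - w0) / 2, (1 - w0) / 2)
    z = stats.norm.ppf(1 - 0.05 / (2 * 3))
    within = all(
        abs(p_hat - w) <= z * np.sqrt(w * (1 - w) / profile.n)
        for p_hat, w in zip(profile.proportions, weights)
    )
    asymmetries = [positional_density(distances).acceptor_asymmetry]
    for k in range(1, n_asym_replicates):
        out_k = tempfile.mkdtemp(prefix="geom_")
        ref_k = sim.generate_reference(cfg, seed=seed + 10 * k, outdir=out_k)
        _, _, paths_k = sim.simulate_junction_counts(ref_k, seed=seed + 10 * k + 1,
                                                     outdir=out_k)
        ann_k, classified_k = _load_cohort(ref_k, paths_k, out_k)
        asymmetries.append(
            positional_density(site_distances(classified_k, ann_k)).acceptor_asymmetry
        )
    return GeometryRecovery(
        proportions=profile.proportions, n_sites=profile.n,
        within_ci=within, asymmetries=asymmetries,
    )


ZIP_TRUE_BETA = {
    "const": 3.0, "n_transcripts": 0.05, "pct_protein_coding": -0.4,
    "donor_score": -0.06, "acceptor_score": -0.04,
    "conservation_donor": -0.8, "conservation_acceptor": -0.5,
    "constraint_donor": 0.3, "constraint_acceptor": 0.2,
    "intron_length": 1e-5,
}


@dataclass
class ZipRecovery:
    max_abs_z: float  # max |estimate - truth| / robust SE over all betas
    llf_gain: float  # ZIP log-likelihood minus plain-Poisson log-likelihood
    zero_prob: float
    zero_prob_no_inflation: float
    n: int


def zip_recovery(seed: int, n: int = 50_000, zero_frac: float = 0.2) -> ZipRecovery:
    """Fit the ZIP model to data simulated from its own count component."""
    rng = np.random.default_rng(seed)

    def draw(n):
        X = pd.DataFrame({
            "n_transcripts": 1 + rng.poisson(2, n),
            "pct_protein_coding": rng.uniform(0, 1, n),
            "donor_score": rng.normal(8, 2, n),
            "acceptor_score": rng.normal(8, 3, n),
            "conservation_donor": rng.uniform(0, 1, n),
            "conservation_acceptor": rng.uniform(0, 1, n),
            "constraint_donor": rng.normal(0, 0.5, n),
            "constraint_acceptor": rng.normal(0, 0.5, n),
            "intron_length": rng.lognormal(7.5, 1.2, n),
        })
        eta = ZIP_TRUE_BETA["const"] + sum(ZIP_TRUE_BETA[c] * X[c] for c in COVARIATES)
        X["Y"] = rng.poisson(np.exp(eta))
        return X

    feats = draw(n)
    feats.loc[rng.random(n) < zero_frac, "Y"] = 0
    fit = fit_zip(feats)
    z = (fit.count_params - pd.Series(ZIP_TRUE_BETA)) / fit.count_bse
    fit_clean = fit_zip(draw(max(n // 5, 2000)))
    return ZipRecovery(
        max_abs_z=float(z.abs().max()),
        llf_gain=float(fit.llf - fit.llf_poisson),
        zero_prob=fit.zero_inflation_prob,
        zero_prob_no_inflation=fit_clean.zero_inflation_prob,
        n=n,
    )
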