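"""Zero-inflated Poisson modelling of per-intron mis-splicing ratios.

The response is the pooled MSR of an intron scaled to an integer,
``Y = round(MSR * 100000)`` (round-half-even), and the nine covariates are:

====  ==========================================================
X1    number of transcripts of the gene in the annotation
X2    fraction of protein-coding transcripts containing the intron
X3    donor (5'ss) motif score of the intron
X4    acceptor (3'ss) motif score of the intron
X5    mean conservation, first 100 intronic bp after the donor
X6    mean conservation, last 100 intronic bp before the acceptor
X7    mean constraint (CDTS-like), donor-proximal window
X8    mean constraint (CDTS-like), acceptor-proximal window
X9    intron length in bp
====  ==========================================================

Introns shorter than 200 bp are dropped before modelling so the two
100-bp proximal windows never overlap. The count component uses a log link;
the structural-zero component is intercept-only by default (the full
covariate set is available behind ``zero_formula="full"``). Standard errors
are sandwich (robust), p-values are two-sided Wald, and q-values are
Benjamini-Hochberg within the model. Covariates are not centred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedPoisson
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation, ScoreTrack, mean_window_score
from .metrics import MsrRecord
from .scoring import SpliceSiteModel, intron_site_sequence

logger = logging.getLogger(__name__)

MSR_SCALE = 100_000
MIN_MODEL_INTRON_LENGTH = 200
PROXIMAL_WINDOW = 100

COVARIATES = [
    "n_transcripts",
    "pct_protein_coding",
    "donor_score",
    "acceptor_score",
    "conservation_donor",
    "conservation_acceptor",
    "constraint_donor",
    "constraint_acceptor",
    "intron_length",
]


class ModelingError(RuntimeError):
    pass


def scale_msr(msr: float) -> int:
    """Integer response: MSR scaled by 100,000, round-half-even."""
    return int(np.rint(msr * MSR_SCALE))


def proximal_windows(intron) -> dict[str, tuple[int, int]]:
    """Strand-aware 100-bp intronic windows at each boundary.

    The donor-proximal window is the first 100 intronic bases downstream of
    the 5'ss; the acceptor-proximal window is the last 100 intronic bases
    upstream of the 3'ss.
    """
    if intron.strand == "+":
        donor = (intron.start, intron.start + PROXIMAL_WINDOW)
        acceptor = (intron.end - PROXIMAL_WINDOW, intron.end)
    else:
        donor = (intron.end - PROXIMAL_WINDOW, intron.end)
        acceptor = (intron.start, intron.start + PROXIMAL_WINDOW)
    return {"donor": donor, "acceptor": acceptor}


def build_feature_table(
    msr_records: Iterable[MsrRecord],
    annotation: GenomeAnnotation,
    model: SpliceSiteModel,
    genome,
    conservation: ScoreTrack,
    constraint: ScoreTrack,
    msr_kind: str = "donor",
) -> pd.DataFrame:
    """Per-intron response and covariates, indexed by intron id.

    Introns shorter than 200 bp and rows with any missing covariate are
    dropped (counts logged).
    """
    if msr_kind not in ("donor", "acceptor"):
        raise ValueError("msr_kind must be 'donor' or 'acceptor'")
    rows = {}
    n_short = n_missing = 0
    for rec in msr_records:
        intron = annotation.introns.get(rec.intron_id)
        if intron is None:
            continue
        if intron.intron_length < MIN_MODEL_INTRON_LENGTH:
            n_short += 1
            continue
        msr = rec.msr_d if msr_kind == "donor" else rec.msr_a
        if np.isnan(msr):
            n_missing += 1
            continue
        wins = proximal_windows(intron)
        row = {
            "Y": scale_msr(msr),
            "n_transcripts": intron.n_gene_transcripts,
            "pct_protein_coding": intron.pct_protein_coding,
            "donor_score": model.score(intron_site_sequence(genome, intron, "donor"), "donor"),
            "acceptor_score": model.score(
                intron_site_sequence(genome, intron, "acceptor"), "acceptor"
            ),
            "conservation_donor": mean_window_score(conservation, intron.chrom, *wins["donor"]),
            "conservation_acceptor": mean_window_score(
                conservation, intron.chrom, *wins["acceptor"]
            ),
            "constraint_donor": mean_window_score(constraint, intron.chrom, *wins["donor"]),
            "constraint_acceptor": mean_window_score(constraint, intron.chrom, *wins["acceptor"]),
            "intron_length": intron.intron_length,
        }
        if any(np.isnan(v) for v in row.values()):
            n_missing += 1
            continue
        rows[rec.intron_id] = row
    logger.info(
        "build_feature_table(%s): %d rows kept, %d short introns, %d with missing values",
        msr_kind, len(rows), n_short, n_missing,
    )
    if not rows:
        raise ModelingError("no introns left after the length/missing-value filters")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "intron_id"
    return df


@dataclass
class ZipFit:
    """Fitted zero-inflated Poisson model with robust inference."""

    count_params: pd.Series
    count_bse: pd.Series
    zero_params: pd.Series
    pvalues: pd.Series  # count-model coefficients, two-sided Wald
    qvalues: pd.Series  # BH within this model
    llf: float
    llf_poisson: float
    converged: bool
    zero_inflation_prob: float  # structural-zero mass at the intercept
    n_obs: int
    unidentifiable: bool = False

    @property
    def exp_params(self) -> pd.Series:
        """Multiplicative effect on the scaled MSR per unit covariate."""
        return np.exp(self.count_params)


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def fit_zip(
    features: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    zero_formula: str = "intercept",
    maxiter: int = 500,
) -> ZipFit:
    """Maximum-likelihood ZIP fit of the scaled MSR on the covariates.

    ``zero_formula='intercept'`` keeps the structural-zero component to a
    single intercept; ``'full'`` puts every covariate in both components.
    """
    y = features["Y"].to_numpy(dtype=float)
    X = features[list(covariates)].to_numpy(dtype=float)
    names = ["const"] + list(covariates)
    X = np.column_stack([np.ones(len(y)), X])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ModelingError(f"design matrix rank deficient; collinear columns: {bad}")

    if (y == 0).all():
        return ZipFit(
            count_params=pd.Series(np.nan, index=names),
            count_bse=pd.Series(np.nan, index=names),
            zero_params=pd.Series([np.inf], index=["inflate_const"]),
            pvalues=pd.Series(np.nan, index=names),
            qvalues=pd.Series(np.nan, index=names),
            llf=0.0,
            llf_poisson=0.0,
            converged=True,
            zero_inflation_prob=1.0,
            n_obs=len(y),
            unidentifiable=True,
        )

    exog_infl = X if zero_formula == "full" else np.ones((len(y), 1))
    infl_names = (["inflate_" + n for n in names]
                  if zero_formula == "full" else ["inflate_const"])

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimiser chatter; convergence checked below
        pois_res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        zero_excess = max((y == 0).mean() - np.mean(np.exp(-pois_res.mu)), 1e-4)
        start = np.concatenate(
            [
                [np.log(zero_excess / (1 - zero_excess))] + [0.0] * (len(infl_names) - 1),
                pois_res.params,
            ]
        )

        model = ZeroInflatedPoisson(y, X, exog_infl=exog_infl, inflation="logit")
        res = model.fit(
            start_params=start, method="bfgs", maxiter=maxiter, disp=0, cov_type="HC0"
        )
        if not res.mle_retvals.get("converged", False):
            res = model.fit(
                start_params=res.params, method="nm", maxiter=5000, disp=0, cov_type="HC0"
            )
            if not res.mle_retvals.get("converged", False):
                raise ModelingError(
                    f"ZIP fit did not converge after bfgs+nm; retvals={res.mle_retvals}"
                )

    k_infl = len(infl_names)
    zero_params = pd.Series(res.params[:k_infl], index=infl_names)
    count_params = pd.Series(res.params[k_infl:], index=names)
    count_bse = pd.Series(res.bse[k_infl:], index=names)
    z = count_params / count_bse
    from scipy.stats import norm

    pvalues = pd.Series(2 * norm.sf(np.abs(z)), index=names)
    qvalues = pd.Series(_bh(pvalues.to_numpy()), index=names)
    return ZipFit(
        count_params=count_params,
        count_bse=count_bse,
        zero_params=zero_params,
        pvalues=pvalues,
        qvalues=qvalues,
        llf=float(res.llf),
        llf_poisson=float(pois_res.llf),  # GLM Poisson llf is the full log-likelihood
        converged=True,
        zero_inflation_prob=float(1 / (1 + np.exp(-zero_params.iloc[0]))),
        n_obs=len(y),
    )


def summarize_betas(
    fits: Mapping[str, ZipFit], q_threshold: float = 0.05
) -> pd.DataFrame:
    """Exponentiated count-model betas across groups, masked at q >= threshold.

    Rows are groups, columns covariates (plus intercept); a NaN entry means
    the coefficient did not reach significance in that group's model.
    """
    if not fits:
        raise ModelingError("summarize_betas requires at least one fit")
    rows = {}
    for label, fit in fits.items():
        masked = fit.exp_params.where(fit.qvalues < q_threshold)
        rows[label] = masked
    return pd.DataFrame(rows).T
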