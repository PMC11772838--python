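"""Matched-group comparisons of mis-splicing ratios.

Covers the designs used on real cohorts: paired tissue contrasts, shRNA
knockdown case/control testing, age-stratified contrasts with RIN-matched
subsampling, and disease/control contrasts with expression-matched introns.
Every rank test reports a probability-of-superiority effect size: the chance
that a random value from the first group exceeds one from the second (ties
counted half), 0.5 meaning no difference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AGE_BINS = {"20-39": (20, 39), "40-59": (40, 59), "60-79": (60, 79)}
MIN_RIN = 6.0
RIN_TOLERANCE = 0.05
EXPR_MATCH_LOG10 = 0.005
MIN_SAMPLES_PER_BIN = 25


class ComparisonError(RuntimeError):
    pass


@dataclass
class SampleMeta:
    sample_id: str
    group: str
    age: float | None = None
    rin: float | None = None
    mapped_depth: int | None = None
    expression: dict[str, float] = field(default_factory=dict)

    @property
    def age_bin(self) -> str | None:
        if self.age is None:
            return None
        for label, (lo, hi) in AGE_BINS.items():
            if lo <= self.age <= hi:
                return label
        return None


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the mandatory metadata table (sample_id, group, age, rin, depth)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "age", "rin", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ComparisonError(f"metadata table missing columns: {sorted(missing)}")
    factor_cols = [c for c in df.columns if c.startswith("tpm_")]
    return [
        SampleMeta(
            sample_id=str(row.sample_id),
            group=str(row.group),
            age=float(row.age),
            rin=float(row.rin),
            mapped_depth=int(row.depth),
            expression={c[4:]: float(getattr(row, c)) for c in factor_cols},
        )
        for row in df.itertuples()
    ]


def filter_rin(samples: Iterable[SampleMeta], min_rin: float = MIN_RIN) -> list[SampleMeta]:
    return [s for s in samples if s.rin is not None and s.rin >= min_rin]


@dataclass(frozen=True)
class ComparisonResult:
    unit: str  # {intron, distribution}
    test: str  # {wilcoxon_paired, wilcoxon_unpaired, chi_square}
    sidedness: str  # {one_greater, two}
    statistic: float
    p: float
    effect_size: float  # probability of superiority in [0, 1]
    n: int
    adjusted_p: float | None = None
    method: str | None = None  # {BH, bonferroni}
    flagged: bool = False
    extra: dict = field(default_factory=dict)

    def with_adjustment(self, adjusted_p: float, method: str) -> "ComparisonResult":
        return ComparisonResult(
            unit=self.unit, test=self.test, sidedness=self.sidedness,
            statistic=self.statistic, p=self.p, effect_size=self.effect_size,
            n=self.n, adjusted_p=adjusted_p, method=method,
            flagged=self.flagged, extra=self.extra,
        )


def match_samples(
    keys_a: Mapping[str, float],
    keys_b: Mapping[str, float],
    tolerance: float,
) -> list[tuple[str, str]]:
    """Greedy nearest-neighbour pairing of two sample groups on one key.

    All cross-group pairs are ranked by absolute key difference (ties broken
    by sample ids) and accepted greedily while both members are unused and
    the difference does not exceed ``tolerance``. Deterministic for any input
    order; yields equal group sizes by construction.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    candidates = sorted(
        (
            (abs(va - vb), a, b)
            for (a, va), (b, vb) in itertools.product(keys_a.items(), keys_b.items())
            if abs(va - vb) <= tolerance
        ),
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        pairs.append((a, b))
        used_a.add(a)
        used_b.add(b)
    if not pairs:
        raise ComparisonError("sample matching produced zero pairs")
    return pairs


def match_introns_by_expression(
    mean_expr_a: pd.Series,
    mean_expr_b: pd.Series,
    max_log10_diff: float = EXPR_MATCH_LOG10,
) -> pd.Index:
    """Introns present in both groups whose log10 mean annotated support
    differs by at most ``max_log10_diff`` (symmetric in the two groups)."""
    common = mean_expr_a.index.intersection(mean_expr_b.index)
    a = mean_expr_a.loc[common]
    b = mean_expr_b.loc[common]
    ok = (a > 0) & (b > 0)
    a, b = a[ok], b[ok]
    keep = (np.log10(a) - np.log10(b)).abs() <= max_log10_diff
    return a.index[keep]


def _superiority_unpaired(a: np.ndarray, b: np.ndarray) -> float:
    # P(a > b) + 0.5 P(a = b), computed exactly via the rank-sum statistic
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u) / (len(a) * len(b))


def _superiority_paired(diffs: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation mapped to [0, 1] as (r + 1) / 2."""
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 0.5
    ranks = stats.rankdata(np.abs(nz))
    w_pos = ranks[nz > 0].sum()
    w_neg = ranks[nz < 0].sum()
    r = (w_pos - w_neg) / (w_pos + w_neg)
    return float((r + 1) / 2)


def wilcoxon_superiority(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool,
    sided: str = "two",
) -> ComparisonResult:
    """Rank test of group A versus group B with a superiority effect size.

    ``sided='one_greater'`` tests the alternative that A exceeds B. Paired
    inputs are aligned element-wise (NaN pairs dropped); the paired effect
    size maps the matched-pairs rank-biserial correlation onto [0, 1], the
    unpaired one counts superior pairs directly.
    """
    if sided not in ("one_greater", "two"):
        raise ValueError(f"bad sidedness {sided!r}")
    alternative = "greater" if sided == "one_greater" else "two-sided"
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ComparisonError("paired comparison requires equal lengths")
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if len(a) < 3:
            raise ComparisonError(f"insufficient data: {len(a)} usable pairs")
        diffs = a - b
        if np.all(diffs == 0):
            return ComparisonResult(
                unit="intron", test="wilcoxon_paired", sidedness=sided,
                statistic=0.0, p=1.0, effect_size=0.5, n=len(a),
            )
        res = stats.wilcoxon(
            a, b, alternative=alternative, correction=True, zero_method="wilcox"
        )
        return ComparisonResult(
            unit="intron", test="wilcoxon_paired", sidedness=sided,
            statistic=float(res.statistic), p=float(res.pvalue),
            effect_size=_superiority_paired(diffs), n=len(a),
        )
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ComparisonError("insufficient data for unpaired comparison")
    res = stats.mannwhitneyu(a, b, alternative=alternative, use_continuity=True)
    return ComparisonResult(
        unit="distribution", test="wilcoxon_unpaired", sidedness=sided,
        statistic=float(res.statistic), p=float(res.pvalue),
        effect_size=_superiority_unpaired(a, b), n=len(a) + len(b),
    )


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    raise ValueError(f"unknown method {method!r}")


def pooled_msr(novel: pd.DataFrame, annotated: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
    """Group-pooled MSR per intron from per-sample count matrices."""
    cols = list(samples)
    j = novel[cols].sum(axis=1)
    s = annotated[cols].sum(axis=1)
    denom = j + s
    return j / denom.where(denom > 0)


def pooled_msr_comparison(
    novel: pd.DataFrame,
    annotated: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    sided: str = "one_greater",
) -> ComparisonResult:
    """Paired-by-intron comparison of group-pooled MSR (A versus B)."""
    msr_a = pooled_msr(novel, annotated, samples_a)
    msr_b = pooled_msr(novel, annotated, samples_b)
    return wilcoxon_superiority(msr_a.to_numpy(), msr_b.to_numpy(), paired=True, sided=sided)


def expression_fold_change(tpm_case: Sequence[float], tpm_control: Sequence[float]) -> float:
    mc = float(np.mean(tpm_case))
    mk = float(np.mean(tpm_control))
    if mk <= 0:
        raise ComparisonError("control expression mean must be positive")
    if mc <= 0:
        raise ComparisonError("case expression mean must be positive")
    return mc / mk


def expression_corrected_msr(
    msr_case: pd.Series | np.ndarray,
    tpm_case: Sequence[float],
    tpm_control: Sequence[float],
    mode: str = "scale_by_foldchange",
) -> tuple[pd.Series | np.ndarray, float]:
    """Normalise case MSR by a factor's expression fold-change.

    ``f = mean TPM(case) / mean TPM(control)``. The default mode divides the
    case MSR by the inverse fold-change (i.e. multiplies by ``f``), so that
    when reduced factor expression inflates the MSR in proportion, the
    correction restores it to the control scale; ``mode='divide_by_foldchange'``
    applies the reciprocal reading (MSR / f). Results are clipped to [0, 1).
    """
    f = expression_fold_change(tpm_case, tpm_control)
    if mode == "scale_by_foldchange":
        corrected = msr_case * f
    elif mode == "divide_by_foldchange":
        corrected = msr_case / f
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return np.clip(corrected, 0.0, np.nextafter(1.0, 0.0)), f


def expression_corrected_comparison(
    msr_case: pd.Series,
    msr_control: pd.Series,
    tpm_case: Sequence[float],
    tpm_control: Sequence[float],
    sided: str = "one_greater",
    mode: str = "scale_by_foldchange",
) -> tuple[ComparisonResult, float]:
    """Re-run the paired case-versus-control comparison on corrected case MSR."""
    corrected, f = expression_corrected_msr(msr_case, tpm_case, tpm_control, mode=mode)
    result = wilcoxon_superiority(
        np.asarray(corrected, dtype=float),
        msr_control.to_numpy() if hasattr(msr_control, "to_numpy") else np.asarray(msr_control),
        paired=True,
        sided=sided,
    )
    return result, f


def rank_factor_contributions(
    msr_case: pd.Series,
    msr_control: pd.Series,
    factor_expression: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    sided: str = "one_greater",
    mode: str = "scale_by_foldchange",
) -> pd.DataFrame:
    """Rank candidate factors by how much correcting for their expression
    shrinks the case-versus-control effect size.

    ``factor_expression`` maps factor id to (case TPMs, control TPMs).
    Contribution = uncorrected effect size - corrected effect size; the table
    is sorted by descending contribution, ties broken by factor id.
    """
    if not factor_expression:
        raise ComparisonError("need at least one factor")
    uncorrected = wilcoxon_superiority(
        msr_case.to_numpy(), msr_control.to_numpy(), paired=True, sided=sided
    )
    rows = []
    for factor, (tc, tk) in factor_expression.items():
        corrected, f = expression_corrected_comparison(
            msr_case, msr_control, tc, tk, sided=sided, mode=mode
        )
        rows.append(
            {
                "factor": factor,
                "fold_change": f,
                "uncorrected_effect": uncorrected.effect_size,
                "corrected_effect": corrected.effect_size,
                "contribution": uncorrected.effect_size - corrected.effect_size,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["contribution", "factor"], ascending=[False, True]
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


def binding_density_chisq(table: np.ndarray | Sequence[Sequence[int]]) -> ComparisonResult:
    """Pearson chi-square (no continuity correction) on a 2x2 intron table.

    Rows: MSR higher vs lower under knockdown; columns: intron has vs lacks a
    binding site within the intron and ±flank of its boundaries. The odds
    ratio reports the direction; results with any expected cell below 1 are
    flagged.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)
    odds = (
        (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        if t[0, 1] > 0 and t[1, 0] > 0
        else float("inf")
    )
    flagged = bool((expected < 1).any())
    if flagged:
        logger.warning("chi-square table has expected cell < 1; result flagged")
    # direction as a superiority-style effect: odds ratio mapped to [0, 1]
    return ComparisonResult(
        unit="intron", test="chi_square", sidedness="two",
        statistic=float(chi2), p=float(p),
        effect_size=float(odds / (1 + odds)) if np.isfinite(odds) else 1.0,
        n=int(t.sum()), flagged=flagged, extra={"odds_ratio": float(odds)},
    )


def binding_contingency(
    msr_case: pd.Series, msr_control: pd.Series, has_binding: Mapping[str, bool]
) -> np.ndarray:
    """Build the knockdown-change x binding-site 2x2 table over shared introns."""
    common = [
        i
        for i in msr_case.index.intersection(msr_control.index)
        if i in has_binding
        and not (np.isnan(msr_case[i]) or np.isnan(msr_control[i]))
    ]
    table = np.zeros((2, 2), dtype=int)
    for i in common:
        higher = msr_case[i] > msr_control[i]
        table[0 if higher else 1, 0 if has_binding[i] else 1] += 1
    return table


def tpm(counts: Sequence[float], effective_lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million from per-gene counts and effective lengths."""
    c = np.asarray(counts, dtype=float)
    L = np.asarray(effective_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / L
    return rate / rate.sum() * 1e6


def age_stratified_comparison(
    novel_by_kind: Mapping[str, pd.DataFrame],
    annotated: pd.DataFrame,
    samples: Sequence[SampleMeta],
    rin_tolerance: float = RIN_TOLERANCE,
    min_per_bin: int = MIN_SAMPLES_PER_BIN,
) -> dict[str, ComparisonResult]:
    """Old-versus-young MSR contrast per site kind.

    Samples are binned by age (20-39 / 40-59 / 60-79); the two older bins are
    subsampled by greedy RIN matching against the youngest bin; introns are
    restricted to those with junction support in all three bins; the extreme
    bins are then compared with a one-tailed paired Wilcoxon test (old >
    young) paired by intron on group-pooled MSR.
    """
    bins: dict[str, list[SampleMeta]] = {b: [] for b in AGE_BINS}
    for s in samples:
        if s.age_bin is not None:
            bins[s.age_bin].append(s)
    for label, members in bins.items():
        if len(members) < min_per_bin:
            raise ComparisonError(
                f"age bin {label} has {len(members)} samples (< {min_per_bin})"
            )
    young = {s.sample_id: s.rin for s in bins["20-39"]}
    matched: dict[str, list[str]] = {"20-39": list(young)}
    for label in ("40-59", "60-79"):
        other = {s.sample_id: s.rin for s in bins[label]}
        pairs = match_samples(young, other, tolerance=rin_tolerance)
        matched[label] = [b for _, b in pairs]
    # restrict the youngest bin to samples that found an old-bin partner
    pairs_extreme = match_samples(
        young, {s.sample_id: s.rin for s in bins["60-79"]}, tolerance=rin_tolerance
    )
    young_ids = [a for a, _ in pairs_extreme]
    old_ids = [b for _, b in pairs_extreme]

    results = {}
    for kind, novel in novel_by_kind.items():
        present = np.ones(len(annotated), dtype=bool)
        for label in matched:
            cols = matched[label] if label != "20-39" else list(young)
            support = novel[cols].sum(axis=1) + annotated[cols].sum(axis=1)
            present &= (support > 0).to_numpy()
        idx = annotated.index[present]
        results[kind] = pooled_msr_comparison(
            novel.loc[idx], annotated.loc[idx], old_ids, young_ids, sided="one_greater"
        )
    return results
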