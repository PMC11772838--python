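"""Mis-splicing ratio (MSR) and category summary statistics.

For an annotated intron, pooling reads over the samples of a group:

    MSR_D = sum(novel donor reads) / (sum(novel donor reads) + sum(annotated reads))

and analogously MSR_A with novel acceptor reads. Both are bounded in [0, 1)
whenever annotated support exists; an intron with neither novel nor annotated
reads at a site has no evidence either way and its MSR is missing (NaN),
never 0/0-coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedJunction


@dataclass(frozen=True)
class MsrRecord:
    intron_id: str
    group_label: str
    novel_donor_reads: int
    novel_acceptor_reads: int
    annotated_reads: int
    n_samples: int

    @property
    def msr_d(self) -> float:
        return _ratio(self.novel_donor_reads, self.annotated_reads)

    @property
    def msr_a(self) -> float:
        return _ratio(self.novel_acceptor_reads, self.annotated_reads)


@dataclass(frozen=True)
class CategorySummary:
    """Group-level unique-junction and read-count percentages per category."""

    group_label: str
    n_unique_novel_donor: int
    n_unique_novel_acceptor: int
    n_unique_annotated: int
    reads_novel_donor: int
    reads_novel_acceptor: int
    reads_annotated: int

    def _pj(self, x: int) -> float:
        total = (
            self.n_unique_novel_donor + self.n_unique_novel_acceptor + self.n_unique_annotated
        )
        return 100.0 * x / total

    def _pr(self, a: int) -> float:
        total = self.reads_novel_donor + self.reads_novel_acceptor + self.reads_annotated
        return 100.0 * a / total

    @property
    def pct_unique(self) -> dict[str, float]:
        return {
            "novel_donor": self._pj(self.n_unique_novel_donor),
            "novel_acceptor": self._pj(self.n_unique_novel_acceptor),
            "annotated": self._pj(self.n_unique_annotated),
        }

    @property
    def pct_reads(self) -> dict[str, float]:
        return {
            "novel_donor": self._pr(self.reads_novel_donor),
            "novel_acceptor": self._pr(self.reads_novel_acceptor),
            "annotated": self._pr(self.reads_annotated),
        }


def _ratio(novel: int, annotated: int) -> float:
    denom = novel + annotated
    if denom == 0:
        return float("nan")
    return novel / denom


def _sum_counts(counts: dict[str, int], sample_ids: Sequence[str] | None) -> int:
    if sample_ids is None:
        return sum(counts.values())
    return sum(counts.get(s, 0) for s in sample_ids)


def count_table(
    classified: Iterable[ClassifiedJunction],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-intron pooled counts: columns novel_donor, novel_acceptor, annotated."""
    rows: dict[str, list[int]] = {}
    for cj in classified:
        if cj.assigned_intron_id is None:
            continue
        if cj.category not in ("annotated", "novel_donor", "novel_acceptor"):
            continue
        c = _sum_counts(cj.junction.counts, sample_ids)
        row = rows.setdefault(cj.assigned_intron_id, [0, 0, 0])
        idx = {"novel_donor": 0, "novel_acceptor": 1, "annotated": 2}[cj.category]
        row[idx] += c
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["novel_donor", "novel_acceptor", "annotated"]
    )
    df.index.name = "intron_id"
    return df.sort_index()


def msr_table(
    classified: Iterable[ClassifiedJunction],
    sample_ids: Sequence[str],
    group_label: str = "",
) -> list[MsrRecord]:
    """Pooled MSR per intron over the given samples."""
    df = count_table(classified, sample_ids)
    return [
        MsrRecord(
            intron_id=iid,
            group_label=group_label,
            novel_donor_reads=int(row.novel_donor),
            novel_acceptor_reads=int(row.novel_acceptor),
            annotated_reads=int(row.annotated),
            n_samples=len(sample_ids),
        )
        for iid, row in df.iterrows()
    ]


def msr_frame(records: Iterable[MsrRecord]) -> pd.DataFrame:
    """Tabular view of MSR records (one row per intron)."""
    return pd.DataFrame(
        [
            {
                "intron_id": r.intron_id,
                "group": r.group_label,
                "novel_donor_reads": r.novel_donor_reads,
                "novel_acceptor_reads": r.novel_acceptor_reads,
                "annotated_reads": r.annotated_reads,
                "n_samples": r.n_samples,
                "msr_d": r.msr_d,
                "msr_a": r.msr_a,
            }
            for r in records
        ]
    ).set_index("intron_id")


def msr_matrix_by_sample(
    classified: Iterable[ClassifiedJunction],
    sample_ids: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Per-sample count matrices (intron x sample) for each category.

    Returns ``{"novel_donor": ..., "novel_acceptor": ..., "annotated": ...}``.
    Per-sample MSR is the single-sample evaluation of the pooled ratio, and
    summing columns before forming ratios reproduces :func:`msr_table`.
    """
    classified = list(classified)
    introns = sorted(
        {
            cj.assigned_intron_id
            for cj in classified
            if cj.assigned_intron_id is not None
            and cj.category in ("annotated", "novel_donor", "novel_acceptor")
        }
    )
    idx = {iid: i for i, iid in enumerate(introns)}
    mats = {
        cat: np.zeros((len(introns), len(sample_ids)), dtype=np.int64)
        for cat in ("novel_donor", "novel_acceptor", "annotated")
    }
    col = {s: k for k, s in enumerate(sample_ids)}
    for cj in classified:
        if cj.assigned_intron_id is None or cj.category not in mats:
            continue
        i = idx[cj.assigned_intron_id]
        for s, c in cj.junction.counts.items():
            if s in col:
                mats[cj.category][i, col[s]] += c
    return {
        cat: pd.DataFrame(m, index=introns, columns=list(sample_ids))
        for cat, m in mats.items()
    }


def msr_from_matrices(
    novel: pd.DataFrame, annotated: pd.DataFrame, sample_ids: Sequence[str] | None = None
) -> pd.Series:
    """Pooled MSR per intron from count matrices (optionally a sample subset)."""
    cols = list(sample_ids) if sample_ids is not None else list(novel.columns)
    j = novel[cols].sum(axis=1)
    s = annotated[cols].sum(axis=1)
    denom = j + s
    return (j / denom.where(denom > 0)).rename("msr")


def category_percentages(
    classified: Iterable[ClassifiedJunction],
    sample_ids: Sequence[str] | None = None,
    group_label: str = "",
) -> CategorySummary:
    """Unique-junction and read-count percentages across a group's samples.

    A junction observed in several samples counts once toward the unique
    totals; read totals sum every count.
    """
    unique: dict[str, set] = {c: set() for c in ("annotated", "novel_donor", "novel_acceptor")}
    reads = {c: 0 for c in ("annotated", "novel_donor", "novel_acceptor")}
    for cj in classified:
        if cj.category not in unique:
            continue
        c = _sum_counts(cj.junction.counts, sample_ids)
        if c > 0:
            unique[cj.category].add(cj.junction.key)
            reads[cj.category] += c
    return CategorySummary(
        group_label=group_label,
        n_unique_novel_donor=len(unique["novel_donor"]),
        n_unique_novel_acceptor=len(unique["novel_acceptor"]),
        n_unique_annotated=len(unique["annotated"]),
        reads_novel_donor=reads["novel_donor"],
        reads_novel_acceptor=reads["novel_acceptor"],
        reads_annotated=reads["annotated"],
    )
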