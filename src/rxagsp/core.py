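"""Gene-set-pair enumeration and the individualized prognostic index.

A gene-set pair (GSP) couples a subset ``m_plus`` of the poor-prognostic
candidates with a subset ``m_minus`` of the good-prognostic candidates,
each of size >= 2.  A sample's index is

    Is = median(expression of m_plus) - median(expression of m_minus)

computed within that sample, so any constant added to all of a sample's
genes cancels; Is > 0 assigns the sample to the poor-prognosis group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator
import warnings

import numpy as np

from .io import CandidateSets, ExpressionCohort

__all__ = [
    "GeneSetPair",
    "IndexVector",
    "count_gsps",
    "enumerate_gsps",
    "compute_index",
]

POOR, GOOD = "poor", "good"


@dataclass(frozen=True)
class GeneSetPair:
    """One poor-prognostic subset paired with one good-prognostic subset."""

    m_plus: tuple[str, ...]
    m_minus: tuple[str, ...]

    def __post_init__(self):
        if len(self.m_plus) < 2 or len(self.m_minus) < 2:
            raise ValueError("each side of a gene-set pair needs at least 2 genes")
        if set(self.m_plus) & set(self.m_minus):
            raise ValueError("gene-set pair sides overlap")

    @property
    def label(self) -> str:
        return "+".join(self.m_plus) + "|" + "+".join(self.m_minus)

    def swapped(self) -> "GeneSetPair":
        return GeneSetPair(self.m_minus, self.m_plus)


@dataclass
class IndexVector:
    """Per-sample prognostic index and derived group labels.

    ``index`` is NaN for unevaluable samples (fewer than two non-missing
    member genes on either side).  ``group`` is "poor" where index > 0,
    "good" where index <= 0, and "" for unevaluable samples.
    """

    sample_ids: list[str]
    index: np.ndarray
    poor_mask: np.ndarray  # boolean; False for unevaluable samples too
    evaluable: np.ndarray  # boolean

    @property
    def group(self) -> list[str]:
        return [
            (POOR if p else GOOD) if ok else ""
            for p, ok in zip(self.poor_mask, self.evaluable)
        ]

    @property
    def n_unevaluable(self) -> int:
        return int((~self.evaluable).sum())


def count_gsps(n_poor: int, n_good: int) -> int:
    """Number of gene-set pairs from candidate sets of the given sizes.

    Each side contributes its subsets of size >= 2, i.e. 2**n - n - 1 of
    them, and the two sides combine freely.
    """
    if n_poor < 2 or n_good < 2:
        raise ValueError("candidate sets must have at least 2 genes each")
    return (2 ** n_poor - n_poor - 1) * (2 ** n_good - n_good - 1)


def _subsets(genes: tuple[str, ...]) -> Iterator[tuple[str, ...]]:
    # canonical order: by size, then by lexicographic member positions
    for size in range(2, len(genes) + 1):
        yield from combinations(genes, size)


def enumerate_gsps(cands: CandidateSets) -> list[GeneSetPair]:
    """All qualifying gene-set pairs in canonical order.

    Order: poor subsets vary slowest, each side ordered by (size, position
    of members in the candidate list).  The result has exactly
    ``count_gsps(len(poor), len(good))`` entries with no duplicates.
    """
    good_subsets = list(_subsets(cands.good))
    return [
        GeneSetPair(mp, mm)
        for mp in _subsets(cands.poor)
        for mm in good_subsets
    ]


def compute_index(cohort: ExpressionCohort, gsp: GeneSetPair) -> IndexVector:
    """Individualized prognostic index for every sample of a cohort.

    Member genes absent from the cohort are dropped with a warning as long
    as at least two remain on each side; otherwise every sample is
    unevaluable.  Samples with fewer than two non-missing values on either
    side are flagged unevaluable (NaN index).
    """
    present_plus = [g for g in gsp.m_plus if g in cohort._gene_index]
    present_minus = [g for g in gsp.m_minus if g in cohort._gene_index]
    dropped = (set(gsp.m_plus) - set(present_plus)) | (set(gsp.m_minus) - set(present_minus))
    if dropped:
        warnings.warn(
            f"cohort {cohort.cohort_id!r}: gene-set members not measured: {sorted(dropped)}",
            stacklevel=2,
        )
    n = cohort.n_samples
    if len(present_plus) < 2 or len(present_minus) < 2:
        return IndexVector(
            sample_ids=list(cohort.samples),
            index=np.full(n, np.nan),
            poor_mask=np.zeros(n, dtype=bool),
            evaluable=np.zeros(n, dtype=bool),
        )
    plus = cohort.expression(present_plus)
    minus = cohort.expression(present_minus)
    ok = (np.sum(~np.isnan(plus), axis=0) >= 2) & (np.sum(~np.isnan(minus), axis=0) >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        index = np.nanmedian(plus, axis=0) - np.nanmedian(minus, axis=0)
    index = np.where(ok, index, np.nan)
    return IndexVector(
        sample_ids=list(cohort.samples),
        index=index,
        poor_mask=ok & (index > 0),
        evaluable=ok,
    )


def write_index(iv: IndexVector, path) -> None:
    """Export an index vector as TSV (sample_id, index, group)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tindex\tgroup\n")
        for sid, val, grp in zip(iv.sample_ids, iv.index, iv.group):
            v = "" if np.isnan(val) else repr(float(val))
            fh.write(f"{sid}\t{v}\t{grp}\n")
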