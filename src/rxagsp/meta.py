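"""Multi-cohort combination of screen results and the selection criteria.

Per-cohort one-sided p-values are combined with the Liptak--Stouffer
weighted inverse-normal method, weights proportional to cohort sample
size.  A pair is selected when (i) its Bonferroni-adjusted combined p is
below the familywise level, (ii) the index split is balanced (smaller
group >= 20% of the cohort) in every cohort, and (iii) the hazard ratio
exceeds 1 with cohort-level log-rank p below the per-cohort level in every
cohort.  Survivors are ranked by combined p ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GeneSetPair
from .survival import CohortScreenRecord

__all__ = ["MetaRecord", "liptak_stouffer", "bonferroni", "combine_records", "select_gsps"]

P_CLAMP = 1e-15


def liptak_stouffer(p_values, weights) -> tuple[float, float]:
    """Weighted inverse-normal (Liptak--Stouffer) combination.

    Z = sum(W_i * Phi^-1(1 - p_i)) / sqrt(sum(W_i^2)); the combined
    p-value is 1 - Phi(Z).  p-values are clamped to
    [1e-15, 1 - 1e-15] before transformation.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.ndim != 1 or p.shape != w.shape or p.size < 1:
        raise ValueError("p_values and weights must be equal-length 1-D, length >= 1")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    z = float(np.sum(w * stats.norm.isf(p)) / np.sqrt(np.sum(w * w)))
    return z, float(stats.norm.sf(z))


def bonferroni(p: float, n_tests: int) -> float:
    """Familywise adjustment: min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


@dataclass
class MetaRecord:
    """Combined evidence and selection status for one gene-set pair."""

    gsp: GeneSetPair
    z_combined: float
    p_meta: float
    p_bonferroni: float
    meta_sig: bool
    all_balanced: bool
    all_direction_ok: bool
    selected: bool
    order: int  # canonical enumeration position, used as ranking tie-break


def combine_records(
    per_cohort: dict[str, list[CohortScreenRecord]],
    n_tests: int | None = None,
    familywise_alpha: float = 0.05,
    cohort_alpha: float = 0.05,
) -> list[MetaRecord]:
    """Meta-analyze screen records and apply the three selection criteria.

    ``per_cohort`` maps cohort ID to that cohort's screen output; every
    cohort must carry a record for every pair, in the same (canonical)
    order.  Weights are the per-cohort evaluable sample counts of each
    pair.  ``n_tests`` defaults to the number of pairs screened.
    """
    cohort_ids = list(per_cohort)
    if not cohort_ids:
        raise ValueError("no cohorts")
    lengths = {cid: len(recs) for cid, recs in per_cohort.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"cohorts screened different pair counts: {lengths}")
    n_pairs = lengths[cohort_ids[0]]
    if n_tests is None:
        n_tests = n_pairs
    out: list[MetaRecord] = []
    for i in range(n_pairs):
        rows = [per_cohort[cid][i] for cid in cohort_ids]
        gsp = rows[0].gsp
        for r in rows[1:]:
            if r.gsp != gsp:
                raise ValueError(f"pair order mismatch across cohorts at position {i}: "
                                 f"{r.gsp.label} vs {gsp.label}")
        weights = [r.n_poor_group + r.n_good_group for r in rows]
        if any(w <= 0 for w in weights):
            z, p_meta = 0.0, 1.0
        else:
            z, p_meta = liptak_stouffer([r.p_cox_onesided for r in rows], weights)
        p_bonf = bonferroni(p_meta, n_tests)
        meta_sig = p_bonf < familywise_alpha
        all_balanced = all(r.balanced for r in rows)
        all_direction = all(r.direction_ok and r.p_logrank < cohort_alpha for r in rows)
        out.append(MetaRecord(
            gsp=gsp, z_combined=z, p_meta=p_meta, p_bonferroni=p_bonf,
            meta_sig=meta_sig, all_balanced=all_balanced,
            all_direction_ok=all_direction,
            selected=meta_sig and all_balanced and all_direction,
            order=i,
        ))
    return out


def select_gsps(meta_records: list[MetaRecord]) -> list[MetaRecord]:
    """Selected pairs ranked by combined p ascending (canonical order breaks ties)."""
    return sorted(
        (m for m in meta_records if m.selected),
        key=lambda m: (m.p_meta, m.order),
    )
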