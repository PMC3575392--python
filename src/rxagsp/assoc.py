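"""Association of the pair-defined prognosis groups with clinical covariates.

Categorical covariates are tested against the two prognosis groups with an
exact conditional r x 2 test (Freeman--Halton generalization of Fisher's
test): with both margins fixed, the p-value sums the hypergeometric
probabilities of every table no more probable than the observed one.
Continuous gene expression against ordinal clinical variables uses
Spearman rank correlation, and two-group comparisons the Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "fisher_exact_rx2",
    "spearman_assoc",
    "two_group_t",
    "crosstab",
]

_MAX_TOTAL = 10_000
_MAX_TABLES = 50_000_000
_REL_EPS = 1e-7  # tolerance when comparing table probabilities


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 counts of a clinical category against the good/poor groups."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, str]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), 2):
            raise ValueError("counts must be r x 2 matching the row labels")
        if (counts < 0).any():
            raise ValueError("negative count")


def fisher_exact_rx2(table) -> float:
    """Exact conditional p-value for an r x 2 contingency table.

    With all margins fixed, each table's probability is
    prod_i C(R_i, a_i) / C(N, C_1) where a_i is the first-column entry of
    row i.  The two-sided p-value sums probabilities over every
    margin-consistent table whose probability does not exceed the observed
    one (within a small relative tolerance).  For 2 x 2 tables this is the
    classic two-sided Fisher test.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("expected an r x 2 table with r >= 2")
    if (counts < 0).any():
        raise ValueError("negative count")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: every row and column must have a positive total")
    n = int(counts.sum())
    if n > _MAX_TOTAL:
        raise ValueError(f"table total {n} exceeds exact-enumeration bound {_MAX_TOTAL}")
    c1 = int(cols[0])

    # log C(R_i, a) for each row, a = 0..min(R_i, c1)
    log_choose = [
        gammaln(r + 1) - gammaln(np.arange(min(r, c1) + 1) + 1) - gammaln(r - np.arange(min(r, c1) + 1) + 1)
        for r in rows
    ]
    size = int(np.prod([lc.size for lc in log_choose[:-1]])) if len(log_choose) > 1 else 1
    if size > _MAX_TABLES:
        raise ValueError("table too large for dense enumeration")

    # broadcast the first r-1 rows over a dense grid; the last row is implied
    shape = [lc.size for lc in log_choose[:-1]]
    grid = np.zeros(shape)
    partial = np.zeros(shape, dtype=int)
    for axis, lc in enumerate(log_choose[:-1]):
        dims = [1] * len(shape)
        dims[axis] = lc.size
        grid = grid + lc.reshape(dims)
        partial = partial + np.arange(lc.size).reshape(dims)
    a_last = c1 - partial
    valid = (a_last >= 0) & (a_last <= rows[-1])
    lc_last = log_choose[-1]
    log_p = np.full(shape, -np.inf)
    log_p[valid] = grid[valid] + lc_last[a_last[valid]]
    log_p -= gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)

    observed = float(
        sum(lc[a] for lc, a in zip(log_choose, counts[:, 0]))
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    keep = log_p <= observed + _REL_EPS
    return float(min(1.0, np.exp(log_p[keep]).sum()))


def crosstab(categories, groups, row_order=None) -> ContingencyTable:
    """Build an r x 2 table of a categorical covariate vs good/poor groups.

    Samples with a missing category or group are dropped (complete-case).
    """
    cats = np.asarray(categories, dtype=object)
    grps = np.asarray(groups, dtype=object)
    ok = np.array([
        c is not None and g in ("good", "poor") and not (isinstance(c, float) and np.isnan(c))
        for c, g in zip(cats, grps)
    ])
    cats, grps = cats[ok], grps[ok]
    labels = row_order if row_order is not None else sorted(set(map(str, cats)))
    counts = np.zeros((len(labels), 2), dtype=int)
    pos = {str(l): i for i, l in enumerate(labels)}
    for c, g in zip(cats, grps):
        counts[pos[str(c)], 0 if g == "good" else 1] += 1
    return ContingencyTable(tuple(map(str, labels)), ("good", "poor"), counts)


def spearman_assoc(values, ordinal) -> tuple[float, float]:
    """Spearman rank correlation of per-sample values vs an ordinal covariate.

    Ties get mid-ranks; the p-value comes from the t approximation.
    Constant input has no defined correlation and is rejected.
    """
    v = np.asarray(values, dtype=float)
    o = np.asarray(ordinal, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(o)
    v, o = v[ok], o[ok]
    if v.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(v) == 0 or np.ptp(o) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(v, o)
    return float(rho), float(p)


def two_group_t(values, labels) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test between two labeled groups."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 group labels, got {uniq.size}")
    a, b = v[lab == uniq[0]], v[lab == uniq[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
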