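"""Per-cohort survival evaluation of gene-set pairs.

The screen dichotomizes each cohort by the sign of the prognostic index,
then tests the split with a two-group log-rank test and a Cox
proportional-hazards fit (Efron tie handling).  The log-rank and
single-covariate Cox routines are implemented directly on sorted risk-set
arrays so that screening thousands of pairs stays fast; multivariate Cox
models delegate to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import chdtrc, ndtr

from .core import GeneSetPair, IndexVector, compute_index
from .io import ExpressionCohort

__all__ = [
    "Dichotomy",
    "LogrankResult",
    "CoxResult",
    "CohortScreenRecord",
    "dichotomize",
    "logrank_test",
    "cox_univariate",
    "cox_multivariate",
    "screen_cohort",
]

BALANCE_FRACTION = 0.20
_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class Dichotomy:
    n_poor: int
    n_good: int
    balanced: bool
    poor_mask: np.ndarray
    evaluable: np.ndarray


def dichotomize(index: IndexVector, balance_fraction: float = BALANCE_FRACTION) -> Dichotomy:
    """Split evaluable samples by index sign; index > 0 is the poor group.

    ``balanced`` is True when the smaller group holds at least
    ``balance_fraction`` of the evaluable samples (inclusive).
    """
    evaluable = index.evaluable
    total = int(evaluable.sum())
    if total == 0:
        raise ValueError("no evaluable samples to dichotomize")
    n_poor = int(index.poor_mask.sum())
    n_good = total - n_poor
    balanced = min(n_poor, n_good) / total >= balance_fraction
    return Dichotomy(n_poor, n_good, balanced, index.poor_mask.copy(), evaluable.copy())


# ---------------------------------------------------------------------------
# sorted risk-set precomputation shared by log-rank and Cox


class _RiskSet:
    """Time-sorted view of one cohort's outcome, reused across many pairs."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]
        # block starts of tied times
        self.starts = np.flatnonzero(np.r_[True, np.diff(self.time) > 0])
        self.n_risk = self.n - self.starts
        self.d = np.add.reduceat(self.event, self.starts)
        ev = self.d > 0
        self.ev_blocks = np.flatnonzero(ev)
        # flattened (block, j) pairs for Efron tie corrections
        d_ev = self.d[self.ev_blocks].astype(int)
        self.flat_block = np.repeat(np.arange(self.ev_blocks.size), d_ev)
        self.flat_frac = np.concatenate([np.arange(k) / k for k in d_ev]) if d_ev.size else np.empty(0)
        self.n_events = int(self.event.sum())
        self.ev_n_risk = self.n_risk[self.ev_blocks].astype(float)
        self.ev_d = self.d[self.ev_blocks]

    def group_counts(self, group_sorted: np.ndarray):
        """Per event block: at-risk count and event count of the flagged group."""
        g = group_sorted.astype(float)
        n1 = np.cumsum(g[::-1])[::-1][self.starts][self.ev_blocks]
        d1 = np.add.reduceat(self.event * g, self.starts)[self.ev_blocks]
        return n1, d1


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    degenerate: bool


def _logrank_from_counts(rs: _RiskSet, n1: np.ndarray, d1: np.ndarray) -> LogrankResult:
    n_risk = rs.ev_n_risk
    d = rs.ev_d
    frac = n1 / n_risk
    observed_minus_expected = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1.0 - frac) * (n_risk - d) / np.maximum(n_risk - 1.0, 1.0)
    variance = float(np.sum(var_terms))
    if variance <= 0.0:
        return LogrankResult(0.0, 1.0, True)
    stat = observed_minus_expected ** 2 / variance
    return LogrankResult(stat, float(chdtrc(1.0, stat)), False)


def _logrank_sorted(rs: _RiskSet, group_sorted: np.ndarray) -> LogrankResult:
    n1, d1 = rs.group_counts(group_sorted)
    return _logrank_from_counts(rs, n1, d1)


def logrank_test(group: np.ndarray, time: np.ndarray, event: np.ndarray) -> LogrankResult:
    """Two-group log-rank test; ``group`` is a boolean membership vector.

    Returns the chi-square statistic (1 df) and its two-sided p-value.  A
    degenerate comparison (a group with no at-risk contrast, e.g. zero
    events overall) yields statistic 0, p = 1, and ``degenerate=True``.
    """
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("log-rank test requires two non-empty groups")
    rs = _RiskSet(time, event)
    return _logrank_sorted(rs, group[rs.order])


# ---------------------------------------------------------------------------
# single-covariate Cox partial likelihood (Efron ties), Newton in 1-D


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    beta: float
    se: float
    z: float
    p_wald: float
    p_onesided: float
    ci_low: float
    ci_high: float
    separation: bool


def _cox1d_sorted(rs: _RiskSet, x_sorted: np.ndarray) -> CoxResult:
    """Newton--Raphson fit of a one-covariate Cox model on sorted data."""
    x = np.asarray(x_sorted, dtype=float)
    ev_starts = rs.starts[rs.ev_blocks]
    ev_d = rs.d[rs.ev_blocks].astype(int)
    # per-block sum of x over tied events, and total over events
    xe = x * rs.event
    sum_x_events = np.add.reduceat(xe, rs.starts)[rs.ev_blocks]

    def score_hess(beta: float):
        w = np.exp(beta * x)
        xw = x * w
        xxw = x * xw
        S0 = np.cumsum(w[::-1])[::-1][ev_starts]
        S1 = np.cumsum(xw[::-1])[::-1][ev_starts]
        S2 = np.cumsum(xxw[::-1])[::-1][ev_starts]
        ew = rs.event * w
        s0 = np.add.reduceat(ew, rs.starts)[rs.ev_blocks]
        s1 = np.add.reduceat(rs.event * xw, rs.starts)[rs.ev_blocks]
        s2 = np.add.reduceat(rs.event * xxw, rs.starts)[rs.ev_blocks]
        f = rs.flat_frac
        b = rs.flat_block
        phi0 = S0[b] - f * s0[b]
        phi1 = S1[b] - f * s1[b]
        phi2 = S2[b] - f * s2[b]
        r = phi1 / phi0
        loglik = float(beta * np.sum(sum_x_events) - np.sum(np.log(phi0)))
        score = float(np.sum(sum_x_events) - np.sum(r))
        hess = float(-np.sum(phi2 / phi0 - r * r))
        return loglik, score, hess

    if ev_d.size == 0 or np.ptp(x) == 0.0:
        return CoxResult(1.0, 0.0, np.inf, 0.0, 1.0, 0.5, 0.0, np.inf, True)

    return _newton1d(score_hess)


def _cox_binary_from_counts(rs: _RiskSet, n1: np.ndarray, d1: np.ndarray) -> CoxResult:
    """Binary-covariate Cox fit using per-block group counts only.

    For a 0/1 covariate the Efron risk-set sums reduce to
    R = r0 + r1*exp(beta) and D = d0 + d1*exp(beta), so each Newton
    iteration touches only the event blocks.
    """
    r1 = n1
    r0 = rs.ev_n_risk - n1
    d = rs.ev_d
    d0 = d - d1
    sum_d1 = float(d1.sum())
    b = rs.flat_block
    f = rs.flat_frac
    a1 = r1[b] - f * d1[b]   # coefficient of exp(beta) in phi
    a0 = r0[b] - f * d0[b]

    def score_hess(beta: float):
        e = np.exp(beta)
        phi = a0 + a1 * e
        ratio = a1 * e / phi
        loglik = float(beta * sum_d1 - np.sum(np.log(phi)))
        score = float(sum_d1 - np.sum(ratio))
        hess = float(np.sum(ratio * ratio - ratio))
        return loglik, score, hess

    return _newton1d(score_hess)


def _newton1d(score_hess) -> CoxResult:
    beta = 0.0
    loglik, score, hess = score_hess(beta)
    score0, hess0 = score, hess
    converged = False
    for _ in range(40):
        if hess >= -1e-12:
            break
        step = float(np.clip(-score / hess, -2.0, 2.0))
        new_beta = beta + step
        new_ll, new_score, new_hess = score_hess(new_beta)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 10:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_hess = score_hess(new_beta)
            halvings += 1
        beta, loglik, score, hess = new_beta, new_ll, new_score, new_hess
        if abs(step) < 1e-9 or abs(score) < 1e-9:
            converged = True
            break
        if abs(beta) > _SEPARATION_BETA:
            break

    if (not converged and abs(beta) >= _SEPARATION_BETA) or hess >= -1e-12:
        z = score0 / np.sqrt(-hess0) if hess0 < 0 else 0.0
        hr = np.inf if beta > 0 else (0.0 if beta < 0 else 1.0)
        return CoxResult(
            hazard_ratio=hr, beta=beta, se=np.inf, z=float(z),
            p_wald=float(2.0 * ndtr(-abs(z))),
            p_onesided=float(ndtr(-z)),
            ci_low=0.0, ci_high=np.inf, separation=True,
        )

    se = float(np.sqrt(-1.0 / hess))
    z = beta / se
    return CoxResult(
        hazard_ratio=float(np.exp(beta)), beta=float(beta), se=se, z=float(z),
        p_wald=float(2.0 * ndtr(-abs(z))),
        p_onesided=float(ndtr(-z)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        separation=False,
    )


def cox_univariate(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> CoxResult:
    """Cox proportional-hazards fit of a single covariate.

    ``x`` may be a boolean group vector (poor vs good; hazard ratio is then
    poor relative to good) or a continuous covariate such as the raw index.
    Requires at least two events.  Under monotone likelihood (complete
    separation) the hazard ratio is reported as ``inf``/``0`` with the
    p-value taken from the score test and ``separation=True``.
    """
    x = np.asarray(x, dtype=float)
    event = np.asarray(event, dtype=float)
    if event.sum() < 2:
        raise ValueError("Cox regression requires at least 2 events")
    rs = _RiskSet(time, event)
    return _cox1d_sorted(rs, x[rs.order])


def cox_multivariate(covariates: pd.DataFrame, time: np.ndarray, event: np.ndarray):
    """Joint Cox fit of several covariates (complete cases, Efron ties).

    Returns ``(table, model_p)`` where ``table`` is a DataFrame indexed by
    covariate with columns hazard_ratio, p, ci_low, ci_high and ``model_p``
    is the likelihood-ratio test of the whole model.  Rank-deficient
    designs are rejected naming the collinear columns.
    """
    from lifelines import CoxPHFitter

    df = covariates.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=float)
    df = df.dropna()
    X = df.drop(columns=["_time", "_event"]).to_numpy(dtype=float)
    if X.shape[0] == 0:
        raise ValueError("no complete cases")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(X.shape[0]), X]))
    if rank < X.shape[1] + 1:
        # identify offending columns by greedy scan
        bad = []
        kept = [np.ones(X.shape[0])]
        for j, col in enumerate(covariates.columns):
            trial = np.column_stack(kept + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(col)
            else:
                kept.append(X[:, j])
        raise ValueError(f"rank-deficient design; collinear covariates: {bad}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    table = pd.DataFrame({
        "hazard_ratio": np.exp(cph.params_),
        "p": cph.summary["p"],
        "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
    })
    model_p = float(cph.log_likelihood_ratio_test().p_value)
    return table, model_p


# ---------------------------------------------------------------------------
# the screen


@dataclass
class CohortScreenRecord:
    """Survival evaluation of one gene-set pair in one cohort."""

    gsp: GeneSetPair
    cohort_id: str
    n_poor_group: int
    n_good_group: int
    n_unevaluable: int
    hazard_ratio: float
    p_logrank: float
    p_cox_onesided: float
    balanced: bool
    direction_ok: bool
    degenerate: bool


def _outcome_mask(cohort: ExpressionCohort) -> np.ndarray:
    if not cohort.has_outcome():
        raise ValueError(f"cohort {cohort.cohort_id!r} has no survival outcome")
    return ~np.isnan(cohort.time)


def screen_cohort(
    cohort: ExpressionCohort,
    gsps: list[GeneSetPair],
    balance_fraction: float = BALANCE_FRACTION,
    cox_covariate: str = "group",
) -> list[CohortScreenRecord]:
    """Evaluate every gene-set pair against one cohort's survival outcome.

    ``cox_covariate`` selects what enters the Cox model: the dichotomized
    ``"group"`` (default) or the continuous ``"index"``.  Per-pair
    degeneracies (single group, zero events) are recorded as flags and the
    screen continues.  Output order matches the input pair order.
    """
    if not gsps:
        raise ValueError("empty gene-set pair list")
    if cox_covariate not in ("group", "index"):
        raise ValueError("cox_covariate must be 'group' or 'index'")
    outcome_ok = _outcome_mask(cohort)
    full_rs: _RiskSet | None = None
    median_cache: dict[tuple[str, ...], np.ndarray] = {}

    def side_median(genes: tuple[str, ...]) -> np.ndarray | None:
        if genes not in median_cache:
            present = [g for g in genes if g in cohort._gene_index]
            if len(present) < 2:
                median_cache[genes] = None
            else:
                sub = cohort.expression(present)
                if np.isnan(sub).any():
                    ok = np.sum(~np.isnan(sub), axis=0) >= 2
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore", RuntimeWarning)
                        med = np.nanmedian(sub, axis=0)
                    med = np.where(ok, med, np.nan)
                else:
                    med = np.median(sub, axis=0)
                median_cache[genes] = med
        return median_cache[genes]

    records: list[CohortScreenRecord] = []
    n = cohort.n_samples
    for gsp in gsps:
        plus = side_median(gsp.m_plus)
        minus = side_median(gsp.m_minus)
        if plus is None or minus is None:
            records.append(CohortScreenRecord(
                gsp, cohort.cohort_id, 0, 0, n, np.nan, 1.0, 0.5,
                balanced=False, direction_ok=False, degenerate=True,
            ))
            continue
        index = plus - minus
        evaluable = ~np.isnan(index) & outcome_ok
        n_uneval = int(n - evaluable.sum())
        poor = evaluable & (index > 0)
        n_poor = int(poor.sum())
        n_eval = int(evaluable.sum())
        n_good = n_eval - n_poor
        balanced = n_eval > 0 and min(n_poor, n_good) / n_eval >= balance_fraction
        if n_poor == 0 or n_good == 0:
            records.append(CohortScreenRecord(
                gsp, cohort.cohort_id, n_poor, n_good, n_uneval, np.nan, 1.0, 0.5,
                balanced=False, direction_ok=False, degenerate=True,
            ))
            continue
        if evaluable.all() and outcome_ok.all():
            if full_rs is None:
                full_rs = _RiskSet(cohort.time, cohort.event)
            rs = full_rs
            sel = slice(None)
        else:
            rs = _RiskSet(cohort.time[evaluable], cohort.event[evaluable])
            sel = evaluable
        group_sorted = poor[sel][rs.order]
        n1, d1 = rs.group_counts(group_sorted)
        lr = _logrank_from_counts(rs, n1, d1)
        if rs.n_events >= 2:
            if cox_covariate == "group":
                cox = _cox_binary_from_counts(rs, n1, d1)
            else:
                cox = _cox1d_sorted(rs, index[sel][rs.order])
            hr, p1 = cox.hazard_ratio, cox.p_onesided
            degenerate = lr.degenerate or cox.separation
        else:
            hr, p1 = np.nan, 0.5
            degenerate = True
        records.append(CohortScreenRecord(
            gsp, cohort.cohort_id, n_poor, n_good, n_uneval, hr,
            lr.p_value, p1, balanced=balanced,
            direction_ok=bool(hr > 1.0), degenerate=degenerate,
        ))
    return records


def evaluate_gsp(cohort: ExpressionCohort, gsp: GeneSetPair,
                 balance_fraction: float = BALANCE_FRACTION) -> CohortScreenRecord:
    """Single-pair convenience wrapper around :func:`screen_cohort`."""
    return screen_cohort(cohort, [gsp], balance_fraction=balance_fraction)[0]


def km_plot(index: IndexVector, time: np.ndarray, event: np.ndarray, ax=None, title: str = ""):
    """Kaplan-Meier curves of the two index-defined groups (matplotlib axes)."""
    from lifelines import KaplanMeierFitter
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = index.evaluable & ~np.isnan(np.asarray(time, dtype=float))
    poor = index.poor_mask
    for name, sel in (("good", mask & ~poor), ("poor", mask & poor)):
        if sel.any():
            km = KaplanMeierFitter()
            km.fit(np.asarray(time)[sel], np.asarray(event)[sel], label=f"{name} (n={int(sel.sum())})")
            km.plot_survival_function(ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xlabel("years")
    ax.set_ylabel("metastasis-free fraction")
    return ax
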