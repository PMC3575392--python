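"""Synthetic multi-cohort expression and survival data with a planted pair.

The generator emulates the statistical structure the screen assumes: a
latent poor-prognosis subpopulation up-shifts the planted poor-candidate
genes and down-shifts the planted good-candidate genes; survival is
exponential with hazard lambda * exp(beta * 1[Is > 0]) driven by the
planted pair's realized index, with independent exponential censoring
calibrated to a target censoring fraction.  Per-cohort location/scale
shifts imitate platform differences; per-sample offsets exercise the
index's shift invariance.  Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import GeneSetPair
from .io import CandidateSets, ExpressionCohort

__all__ = ["SimulationConfig", "simulate_cohorts", "simulate_clinical"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-cohort generator."""

    n_cohorts: int = 3
    n_samples: int = 300
    n_genes: int = 500          # total measured genes incl. candidates
    n_poor_candidates: int = 8
    n_good_candidates: int = 4
    planted_poor_size: int = 5
    planted_good_size: int = 2
    effect: float = float(np.log(2.5))   # log hazard ratio of 1[Is > 0]
    baseline_hazard: float = 0.08        # events / year
    censoring_rate: float = 0.3
    noise_sd: float = 1.0
    signal_shift: float = 1.2            # expression shift in the latent subpopulation
    activation_prob: float = 1.0         # chance a planted gene responds in a poor sample
    poor_fraction: float = 0.4
    cohort_location_shifts: tuple[float, ...] | None = None
    cohort_scales: tuple[float, ...] | None = None
    sample_offset_sd: float = 0.0        # per-sample constant, invisible to the index
    grade_log_odds: float = 1.5          # latent-poor shift of the ordinal grade
    seed: int = 0

    def __post_init__(self):
        if self.planted_poor_size < 2 or self.planted_good_size < 2:
            raise ValueError("planted set sizes must be >= 2")
        if self.planted_poor_size > self.n_poor_candidates:
            raise ValueError("planted poor set larger than the candidate list")
        if self.planted_good_size > self.n_good_candidates:
            raise ValueError("planted good set larger than the candidate list")
        if self.n_genes < self.n_poor_candidates + self.n_good_candidates:
            raise ValueError("gene universe smaller than the candidate lists")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.noise_sd <= 0:
            raise ValueError("rates and noise must be positive")
        if not 0.0 < self.poor_fraction < 1.0:
            raise ValueError("poor_fraction must lie in (0, 1)")

    @property
    def poor_genes(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_poor_candidates))

    @property
    def good_genes(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_good_candidates))

    def candidate_sets(self) -> CandidateSets:
        return CandidateSets(self.poor_genes, self.good_genes)

    def planted_gsp(self) -> GeneSetPair:
        return GeneSetPair(
            self.poor_genes[: self.planted_poor_size],
            self.good_genes[: self.planted_good_size],
        )

    def gene_universe(self) -> list[str]:
        filler = [f"F{i:04d}" for i in range(self.n_genes - self.n_poor_candidates - self.n_good_candidates)]
        return list(self.poor_genes) + list(self.good_genes) + filler


def _censoring_scale(hazards: np.ndarray, target: float) -> float:
    """Exponential-censoring rate achieving the target expected censoring."""
    if target == 0.0:
        return 0.0
    f = lambda lc: float(np.mean(lc / (lc + hazards))) - target
    lo, hi = 1e-12, 1e12
    if f(hi) < 0:
        raise ValueError(f"censoring target {target} infeasible")
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)


def simulate_cohorts(config: SimulationConfig) -> list[ExpressionCohort]:
    """Generate the configured cohorts with outcome attached.

    Each returned cohort carries a ``latent_poor`` boolean attribute (the
    hidden subpopulation indicator) used by :func:`simulate_clinical` and by
    recovery tests; it is not part of the on-disk formats.
    """
    genes = config.gene_universe()
    gsp = config.planted_gsp()
    planted_poor = set(gsp.m_plus)
    planted_good = set(gsp.m_minus)
    poor_rows = [i for i, g in enumerate(genes) if g in planted_poor]
    good_rows = [i for i, g in enumerate(genes) if g in planted_good]

    children = np.random.SeedSequence((config.seed, 0)).spawn(config.n_cohorts)
    cohorts: list[ExpressionCohort] = []
    for c in range(config.n_cohorts):
        rng = np.random.default_rng(children[c])
        n = config.n_samples
        loc = (config.cohort_location_shifts[c]
               if config.cohort_location_shifts is not None else float(c) * 2.0)
        scale = (config.cohort_scales[c]
                 if config.cohort_scales is not None else 1.0)

        latent = rng.random(n) < config.poor_fraction
        # candidate genes are centred so the planted index is balanced;
        # filler genes get platform-looking per-gene baselines
        mu = rng.normal(0.0, 1.0, size=len(genes))
        mu[: config.n_poor_candidates + config.n_good_candidates] = 0.0
        values = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
        delta = config.signal_shift
        for rows, sign in ((poor_rows, +1.0), (good_rows, -1.0)):
            active = rng.random((len(rows), n)) < config.activation_prob
            values[rows] += sign * delta * (active & latent)
        values = values * scale + loc
        if config.sample_offset_sd > 0:
            values += rng.normal(0.0, config.sample_offset_sd, size=n)[None, :]

        # true index of the planted pair drives the hazard
        index = np.median(values[poor_rows], axis=0) - np.median(values[good_rows], axis=0)
        hazards = config.baseline_hazard * np.exp(config.effect * (index > 0))
        event_times = rng.exponential(1.0 / hazards)
        lam_c = _censoring_scale(hazards, config.censoring_rate)
        if lam_c > 0:
            censor_times = rng.exponential(1.0 / lam_c, size=n)
        else:
            censor_times = np.full(n, np.inf)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)

        cohort = ExpressionCohort(
            cohort_id=f"cohort{c + 1}",
            genes=list(genes),
            samples=[f"c{c + 1}s{i + 1}" for i in range(n)],
            values=values,
            time=time,
            event=event,
        )
        cohort.latent_poor = latent
        cohorts.append(cohort)
    return cohorts


def simulate_clinical(config: SimulationConfig, cohorts: list[ExpressionCohort]) -> list[pd.DataFrame]:
    """Clinical tables (outcome + a 3-level ordinal grade) for each cohort.

    Grade follows a proportional-odds model whose linear predictor shifts
    by ``grade_log_odds`` for latent-poor samples, so the grade/group
    association strength is tunable (0 means independence).  The grade is
    also attached to each cohort's ``covariates``.
    """
    children = np.random.SeedSequence((config.seed, 1)).spawn(len(cohorts))
    cutpoints = np.array([-0.5, 0.9])  # baseline grade mix roughly 38/33/29
    tables = []
    for child, cohort in zip(children, cohorts):
        rng = np.random.default_rng(child)
        latent = getattr(cohort, "latent_poor", None)
        if latent is None:
            raise ValueError(f"cohort {cohort.cohort_id!r} lacks the latent_poor attribute "
                             "(not produced by simulate_cohorts?)")
        eta = config.grade_log_odds * latent.astype(float)
        cum = 1.0 / (1.0 + np.exp(-(cutpoints[None, :] - eta[:, None])))
        u = rng.random(cohort.n_samples)
        grade = 1 + (u[:, None] > cum).sum(axis=1)  # 1..3
        df = pd.DataFrame({
            "sample_id": cohort.samples,
            "time_years": cohort.time,
            "event": cohort.event,
            "grade": grade,
        })
        cohort.covariates = df.set_index("sample_id")[["grade"]]
        tables.append(df)
    return tables
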