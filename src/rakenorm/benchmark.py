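"""Benchmark ("actual") norm scores from the full reference population.

Every raw score / age combination receives an IQ_best value: the reference
population is partitioned into many narrow, equal-sized age groups (365 per
1-year cohort, i.e. one per "birthday"), and within each group the raw
scores are converted to the IQ metric by rank-based inverse normal
transformation.  An exact quadrature oracle computes the same quantity from
the generative model, without simulation, for accuracy checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .irt import ItemBank
from .norming import IQ_MEAN, IQ_SD
from .population import N_COHORTS, ReferenceMoments, ScenarioSpec, cell_mean

__all__ = ["compute_iq_best", "analytic_raw_distribution", "analytic_iq_best",
           "GROUPS_PER_COHORT"]

GROUPS_PER_COHORT = 365


def compute_iq_best(pop: pd.DataFrame, groups_per_cohort: int = GROUPS_PER_COHORT):
    """Assign IQ_best to every person in a reference population with raw scores.

    Within each cohort, rows are ordered by age and split into
    ``groups_per_cohort`` contiguous, (near-)equal-sized groups; within each
    group the mid-rank percentile of each raw value is mapped through
    ``100 + 15 * Phi^-1(p)``.

    Returns ``(pop_with_iq_best, norms)`` where ``norms`` is a tidy table
    with one row per (group, raw value): columns group, cohort, age_min,
    age_max, raw, iq_best, count.  A group containing a single raw value
    gets IQ_best = 100 for all members (flagged in the log by its count).
    """
    if groups_per_cohort < 1:
        raise ValueError("groups_per_cohort must be >= 1")
    pop = pop.copy()
    age = pop["age"].to_numpy()
    cohort = pop["cohort"].to_numpy()
    raw = pop["raw"].to_numpy()

    group = np.empty(len(pop), dtype=np.int64)
    for j in np.unique(cohort):
        idx = np.flatnonzero(cohort == j)
        order = np.argsort(age[idx], kind="stable")
        g = (np.arange(idx.size) * groups_per_cohort) // idx.size
        group[idx[order]] = j * groups_per_cohort + g

    iq = np.empty(len(pop))
    records = []
    order = np.argsort(group, kind="stable")
    gs = group[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    ends = np.r_[starts[1:], gs.size]
    for s, e in zip(starts, ends):
        idx = order[s:e]
        g = gs[s]
        r = raw[idx]
        vals, counts = np.unique(r, return_counts=True)
        below = np.concatenate(([0], np.cumsum(counts)[:-1]))
        p = (below + 0.5 * counts) / idx.size
        iq_vals = IQ_MEAN + IQ_SD * ndtri(p)
        iq[idx] = iq_vals[np.searchsorted(vals, r)]
        a = age[idx]
        for v, cnt, q in zip(vals, counts, iq_vals):
            records.append((g, g // groups_per_cohort, a.min(), a.max(),
                            int(v), q, int(cnt)))
    pop["group"] = group
    pop["iq_best"] = iq
    norms = pd.DataFrame(records, columns=["group", "cohort", "age_min",
                                           "age_max", "raw", "iq_best",
                                           "count"])
    return pop, norms


def _poisson_binomial_pmf(p: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i) by iterative convolution."""
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1:i + 2] = pmf[1:i + 2] * (1 - pi) + pmf[:i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def analytic_raw_distribution(age: float, spec: ScenarioSpec, bank: ItemBank,
                              moments: ReferenceMoments,
                              n_nodes: int = 61) -> np.ndarray:
    """Exact raw-score distribution at one age under the generative model.

    Mixture over the 27 demographic cells of the sum-of-Bernoullis
    distribution, with the latent ability integrated over
    Normal(cell mean, 1) standardized by the reference moments
    (Gauss-Hermite quadrature).
    """
    cohort = min(int(age), N_COHORTS - 1)
    table = spec.tables[cohort]
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    pmf = np.zeros(bank.n_items + 1)
    for e, t, r in itertools.product((1, 2, 3), repeat=3):
        prob = table.props[e - 1, t - 1, r - 1] / 100.0
        if prob == 0.0:
            continue
        mu_cell = cell_mean(age, e, t, r)
        thetas = (mu_cell + nodes - moments.mu) / moments.sigma
        for th, wq in zip(thetas, weights):
            item_p = expit(th - bank.difficulties)
            pmf += prob * wq * _poisson_binomial_pmf(item_p)
    return pmf / pmf.sum()


def analytic_iq_best(raw: int, age: float, spec: ScenarioSpec, bank: ItemBank,
                     moments: ReferenceMoments, n_nodes: int = 61) -> float:
    """Exact IQ_best of a raw score at one age: 100 + 15*Phi^-1(mid-CDF)."""
    pmf = analytic_raw_distribution(age, spec, bank, moments, n_nodes)
    raw = int(raw)
    if not 0 <= raw <= bank.n_items:
        raise ValueError(f"raw score {raw} outside 0..{bank.n_items}")
    p = pmf[:raw].sum() + 0.5 * pmf[raw]
    return float(IQ_MEAN + IQ_SD * ndtri(p))


def theoretical_moments(spec: ScenarioSpec, n_age: int = 601):
    """Quadrature mean and SD of the latent ability under a scenario.

    Integrates the ability surface over the 27 cells and a uniform age
    distribution; the unit within-cell normal deviate adds variance 1.
    Serves as the closed-form counterpart of empirical reference moments.
    """
    ages = np.linspace(0.0, 6.0, n_age)
    mean_acc = 0.0
    sq_acc = 0.0
    for j in range(N_COHORTS):
        table = spec.tables[j]
        in_cohort = (ages >= j) & (ages < j + 1) if j < N_COHORTS - 1 else \
                    (ages >= j) & (ages <= j + 1)
        a = ages[in_cohort]
        for e, t, r in itertools.product((1, 2, 3), repeat=3):
            prob = table.props[e - 1, t - 1, r - 1] / 100.0 / N_COHORTS
            if prob == 0.0:
                continue
            m = cell_mean(a, e, t, r)
            mean_acc += prob * np.mean(m)
            sq_acc += prob * np.mean(m**2)
    var = sq_acc - mean_acc**2 + 1.0
    return ReferenceMoments(mu=float(mean_acc), sigma=float(np.sqrt(var)))
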