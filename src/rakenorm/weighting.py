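"""Normative-sample drawing and raking (iterative proportional fitting).

Raking computes post-stratification weights so that the weighted marginal
distribution of each categorical variable in a sample matches population
targets, adjusting one variable at a time until convergence.  The resulting
weights satisfy the post-stratification identity
``p_k = w_k * n_k / sum_l w_l * n_l`` for every marginal category k.

Weights are standardized by dividing through the smallest weight, which sets
the weight of the most overrepresented group to exactly 1 and preserves all
weight ratios (and hence every weighted proportion and weighted fit).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .irt import ItemBank, simulate_raw_scores
from .population import (
    N_COHORTS,
    REFERENCE_MARGINALS,
    ReferenceMoments,
    ScenarioSpec,
    VARIABLES,
    _draw_cells,
    cell_mean,
    standardize_ability,
)

__all__ = [
    "RakingError",
    "reference_targets",
    "draw_norm_sample",
    "rake_weights",
    "standardize_weights",
]

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 50


class RakingError(ValueError):
    """Raking cannot proceed or did not converge."""


def reference_targets() -> dict:
    """Reference-population marginal targets keyed variable -> code -> prop."""
    return {v: dict(REFERENCE_MARGINALS[v]) for v in VARIABLES}


def draw_norm_sample(spec: ScenarioSpec, moments: ReferenceMoments,
                     bank: ItemBank, n_per_cohort: int = 100,
                     seed=None) -> pd.DataFrame:
    """Draw a stratified normative sample from a scenario's generative model.

    Exactly ``n_per_cohort`` persons per 1-year cohort (default 100, total
    600).  Latent abilities are standardized with the *reference* moments and
    converted to raw test scores through the shared item bank.  All weights
    start at 1.
    """
    if n_per_cohort < 2:
        raise ValueError("n_per_cohort must be >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for j in range(N_COHORTS):
        age = rng.uniform(j, j + 1, size=n_per_cohort)
        edu, eth, reg = _draw_cells(rng, spec.tables[j], n_per_cohort)
        z = rng.standard_normal(n_per_cohort)
        x1 = cell_mean(age, edu, eth, reg) + z
        frames.append(pd.DataFrame({
            "age": age, "cohort": j,
            "education": edu.astype(np.int8),
            "ethnicity": eth.astype(np.int8),
            "region": reg.astype(np.int8),
            "x1": x1,
        }))
    sample = pd.concat(frames, ignore_index=True)
    sample["theta_pop"] = standardize_ability(sample["x1"].to_numpy(), moments)
    sample["raw"] = simulate_raw_scores(sample["theta_pop"].to_numpy(), bank,
                                        seed=rng)
    sample["weight"] = 1.0
    return sample


def _marginal_discrepancy(sample, weights, targets):
    """Max absolute difference between weighted shares and targets."""
    worst = 0.0
    total = weights.sum()
    for var, cats in targets.items():
        col = sample[var].to_numpy()
        for cat, target in cats.items():
            share = weights[col == cat].sum() / total
            worst = max(worst, abs(share - target))
    return worst


def rake_weights(sample: pd.DataFrame, targets: dict,
                 tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER) -> np.ndarray:
    """Iterative proportional fitting of person weights to marginal targets.

    ``targets`` maps variable name -> {category: target proportion}; each
    variable's proportions must sum to 1 and every target category must occur
    in the sample.  Arbitrary categorical variables are accepted (joint
    margins can be raked by recoding a cross-classification into a single
    dummy variable).  Returns strictly positive weights, not standardized.
    """
    if not targets:
        raise RakingError("no raking targets supplied")
    for var, cats in targets.items():
        if var not in sample.columns:
            raise RakingError(f"target variable {var!r} not in sample")
        tsum = sum(cats.values())
        if abs(tsum - 1.0) > 1e-9:
            raise RakingError(f"targets for {var!r} sum to {tsum}, expected 1")
        if any(p <= 0 for p in cats.values()):
            raise RakingError(f"targets for {var!r} must all be positive")
        present = set(sample[var].unique())
        missing = [c for c in cats if c not in present]
        if missing:
            raise RakingError(
                f"category {missing[0]!r} of variable {var!r} has no "
                f"observations in the sample; raking targets are unreachable"
            )

    w = np.ones(len(sample), dtype=float)
    masks = {
        var: {cat: (sample[var].to_numpy() == cat) for cat in cats}
        for var, cats in targets.items()
    }
    for iteration in range(1, max_iter + 1):
        for var, cats in targets.items():
            total = w.sum()
            for cat, target in cats.items():
                m = masks[var][cat]
                share = w[m].sum() / total
                w[m] *= target / share
        disc = _marginal_discrepancy(sample, w, targets)
        if disc <= tol:
            log.debug("raking converged after %d iterations (max marginal "
                      "discrepancy %.2e)", iteration, disc)
            return w
    raise RakingError(
        f"raking did not converge within {max_iter} iterations "
        f"(last max marginal discrepancy {disc:.3e})"
    )


def standardize_weights(weights) -> np.ndarray:
    """Divide weights by their minimum so the smallest weight is exactly 1."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return w / w.min()
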