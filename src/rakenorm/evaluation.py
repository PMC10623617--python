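"""Norm-score error evaluation and the full simulation experiment.

Fitted norm models are scored against the benchmark IQ_best on a fixed set
of reference-distributed evaluees with RMSE (total error) and MSD (signed
bias), overall and within 11 person-location bins of 7.5 IQ points centered
at 62.5 ... 137.5.  ``run_experiment`` orchestrates the whole study: for
each population scenario and replicate it draws a normative sample, fits
the weighted (raked) and unweighted variants of the continuous norming
model, and evaluates both against the shared benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import benchmark, irt, norming, population, weighting

__all__ = [
    "BIN_WIDTH", "BIN_MIDPOINTS", "ExperimentConfig", "EvaluationSet",
    "rmse", "msd", "assign_location_bins", "evaluate_model",
    "run_experiment", "summarize",
]

log = logging.getLogger(__name__)

BIN_WIDTH = 7.5
BIN_MIDPOINTS = 62.5 + BIN_WIDTH * np.arange(11)
_BIN_LO = BIN_MIDPOINTS[0] - BIN_WIDTH / 2     # 58.75
_BIN_HI = BIN_MIDPOINTS[-1] + BIN_WIDTH / 2    # 141.25

#: Norm-score differences below this many IQ points are treated as too small
#: to matter in practice (norm tables round to integer IQs).
PRACTICAL_RELEVANCE_IQ = 1.0


def rmse(predicted, best) -> float:
    """Root mean square difference between predicted and benchmark scores."""
    predicted = np.asarray(predicted, dtype=float)
    best = np.asarray(best, dtype=float)
    if predicted.size == 0 or predicted.shape != best.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((predicted - best) ** 2)))


def msd(predicted, best) -> float:
    """Mean signed difference (predicted - benchmark); >0 = overestimation."""
    predicted = np.asarray(predicted, dtype=float)
    best = np.asarray(best, dtype=float)
    if predicted.size == 0 or predicted.shape != best.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(predicted - best))


def assign_location_bins(values) -> np.ndarray:
    """Bin index 0..10 per value (bins of 7.5 IQ centered 62.5..137.5); -1 outside."""
    v = np.asarray(values, dtype=float)
    idx = np.floor((v - _BIN_LO) / BIN_WIDTH).astype(int)
    idx[(v < _BIN_LO) | (v >= _BIN_HI)] = -1
    return idx


@dataclass(frozen=True)
class EvaluationSet:
    """Reference-distributed evaluees carrying their benchmark norm scores."""

    age: np.ndarray
    raw: np.ndarray
    iq_best: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        for name in ("age", "raw", "iq_best"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.age.size == self.raw.size == self.iq_best.size > 0):
            raise ValueError("evaluation set arrays must align and be non-empty")

    @property
    def bins(self) -> np.ndarray:
        return assign_location_bins(self.iq_best)

    @classmethod
    def from_population(cls, pop: pd.DataFrame, size: int, seed=None):
        """Random subsample of a reference population that has iq_best."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pop), size=min(size, len(pop)), replace=False)
        sub = pop.iloc[idx]
        return cls(sub["age"].to_numpy(), sub["raw"].to_numpy(),
                   sub["iq_best"].to_numpy(),
                   seed if isinstance(seed, int) else None)


def evaluate_model(model: norming.NormModel, evalset: EvaluationSet) -> pd.DataFrame:
    """RMSE and MSD of a fitted model, overall and per location bin.

    Returns a tidy frame with columns bin ("overall" or the bin midpoint),
    rmse, msd, n.  Values outside the 11 bins contribute to "overall" only.
    """
    pred = norming.predict_norm_score(model, evalset.raw, evalset.age)
    pred = np.asarray(pred, dtype=float)
    rows = [("overall", rmse(pred, evalset.iq_best),
             msd(pred, evalset.iq_best), evalset.raw.size)]
    bins = evalset.bins
    for b, mid in enumerate(BIN_MIDPOINTS):
        mask = bins == b
        if not mask.any():
            continue
        rows.append((mid, rmse(pred[mask], evalset.iq_best[mask]),
                     msd(pred[mask], evalset.iq_best[mask]), int(mask.sum())))
    return pd.DataFrame(rows, columns=["bin", "rmse", "msd", "n"])


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a full simulation experiment."""

    scenarios: tuple = (1, 2, 3, 4, 5, 6)
    replicates: int = 100
    n_per_cohort: int = 100
    reference_size: int = 24_000_000       # total persons across 6 cohorts
    evaluation_size: int = 20_000
    n_items: int = irt.DEFAULT_N_ITEMS
    item_bounds: tuple = irt.DEFAULT_BOUNDS
    groups_per_cohort: int = benchmark.GROUPS_PER_COHORT
    k: int = norming.DEFAULT_K
    max_terms: int = norming.DEFAULT_MAX_TERMS
    r2_target: float = norming.DEFAULT_R2_TARGET
    raking_tol: float = weighting.DEFAULT_TOL
    raking_max_iter: int = weighting.DEFAULT_MAX_ITER
    scenario5_c: float = population.S5_DEFAULT_C
    master_seed: int = 0

    def __post_init__(self):
        for name in ("replicates", "n_per_cohort", "reference_size",
                     "evaluation_size", "n_items", "groups_per_cohort",
                     "k", "max_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.master_seed is None:
            raise ValueError("a master seed is required (no silent "
                             "nondeterminism)")
        self.scenarios = tuple(self.scenarios)
        self.item_bounds = tuple(self.item_bounds)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def _child_seeds(master_seed: int):
    """Named, independent random streams derived from the master seed."""
    root = np.random.SeedSequence(master_seed)
    pop_ss, bank_ss, refraw_ss, eval_ss, samples_ss = root.spawn(5)
    return {
        "population": pop_ss,
        "bank": bank_ss,
        "reference_raw": refraw_ss,
        "evaluation": eval_ss,
        "samples": samples_ss,
    }


@dataclass
class ExperimentResult:
    """Tidy error table plus the fitted-model archive and run metadata."""

    errors: pd.DataFrame
    models: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    config: ExperimentConfig | None = None
    bank: irt.ItemBank | None = None
    moments: population.ReferenceMoments | None = None


def prepare_reference(config: ExperimentConfig, seeds=None):
    """Reference population with raw scores and IQ_best, plus shared objects.

    Returns (reference_pop, moments, bank, evalset).
    """
    seeds = seeds or _child_seeds(config.master_seed)
    spec1 = population.scenario_cells(1)
    n_per_cohort = config.reference_size // population.N_COHORTS
    log.info("generating reference population (%d per cohort)", n_per_cohort)
    ref = population.generate_population(spec1, n_per_cohort,
                                         seed=seeds["population"])
    moments = population.reference_moments(ref)
    ref["theta_pop"] = population.standardize_ability(ref["x1"].to_numpy(),
                                                      moments)
    bank = irt.draw_item_bank(config.n_items, *config.item_bounds,
                              seed=seeds["bank"])
    ref["raw"] = irt.simulate_raw_scores(ref["theta_pop"].to_numpy(), bank,
                                         seed=seeds["reference_raw"])
    ref, _ = benchmark.compute_iq_best(ref, config.groups_per_cohort)
    evalset = EvaluationSet.from_population(ref, config.evaluation_size,
                                            seed=seeds["evaluation"])
    return ref, moments, bank, evalset


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full weighted-vs-unweighted norming simulation.

    For every scenario and replicate, a 600-person (by default) stratified
    sample is drawn, raked to the reference marginals for the weighted
    method (WCN) and left unweighted for the comparison method (SCN); both
    norm models are fitted and scored on the shared evaluation set.
    Per-replicate failures are logged and counted, never silently dropped.
    """
    seeds = _child_seeds(config.master_seed)
    _, moments, bank, evalset = prepare_reference(config, seeds)
    targets = weighting.reference_targets()

    sample_root = seeds["samples"]
    rows = []
    models = {}
    failures = []
    for scen in config.scenarios:
        spec = population.scenario_cells(
            scen, c=config.scenario5_c if scen == 5 else None)
        scen_ss = np.random.SeedSequence(
            entropy=sample_root.entropy, spawn_key=(*sample_root.spawn_key, scen))
        rep_seeds = scen_ss.spawn(config.replicates)
        for rep, rep_seed in enumerate(rep_seeds):
            try:
                sample = weighting.draw_norm_sample(
                    spec, moments, bank, config.n_per_cohort, seed=rep_seed)
                raked = weighting.standardize_weights(
                    weighting.rake_weights(sample, targets,
                                           tol=config.raking_tol,
                                           max_iter=config.raking_max_iter))
                for method, w in (("WCN", raked),
                                  ("SCN", np.ones(len(sample)))):
                    s = sample.copy()
                    s["weight"] = w
                    ranked = norming.weighted_percentile_ranks(s)
                    model = norming.fit_norm_model(
                        ranked, k=config.k, max_terms=config.max_terms,
                        r2_target=config.r2_target)
                    models[(scen, rep, method)] = model
                    err = evaluate_model(model, evalset)
                    err.insert(0, "population", scen)
                    err.insert(1, "method", method)
                    err.insert(2, "replicate", rep)
                    rows.append(err)
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                log.warning("scenario %d replicate %d failed: %s",
                            scen, rep, exc)
                failures.append((scen, rep, str(exc)))
        log.info("scenario %d done (%d replicates, %d failures so far)",
                 scen, config.replicates, len(failures))
    if not rows:
        raise RuntimeError(f"every replicate failed; first error: "
                           f"{failures[0][2] if failures else 'none run'}")
    errors = pd.concat(rows, ignore_index=True)
    return ExperimentResult(errors=errors, models=models, failures=failures,
                            config=config, bank=bank, moments=moments)


def summarize(errors: pd.DataFrame, bootstrap: int = 2000,
              seed: int = 0) -> pd.DataFrame:
    """Scenario x method cell means of RMSE and MSD with bootstrap 95% CIs.

    Replicate-level values are the equal-weight mean over the 11 location
    bins (the ANOVA cell-mean analog); CIs resample replicates.
    """
    binned = errors[errors["bin"] != "overall"]
    per_rep = (binned.groupby(["population", "method", "replicate"])
               [["rmse", "msd"]].mean().reset_index())
    rng = np.random.default_rng(seed)
    out = []
    for (pop, meth), g in per_rep.groupby(["population", "method"]):
        vals = g[["rmse", "msd"]].to_numpy()
        n = len(vals)
        means = vals.mean(axis=0)
        idx = rng.integers(0, n, size=(bootstrap, n))
        boots = vals[idx].mean(axis=1)
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
        out.append({
            "population": pop, "method": meth, "replicates": n,
            "rmse": means[0], "rmse_lo": lo[0], "rmse_hi": hi[0],
            "msd": means[1], "msd_lo": lo[1], "msd_hi": hi[1],
        })
    return pd.DataFrame(out)


def grand_means(errors: pd.DataFrame) -> dict:
    """Grand mean RMSE/MSD per method over populations, replicates and bins."""
    binned = errors[errors["bin"] != "overall"]
    per_rep = (binned.groupby(["population", "method", "replicate"])
               [["rmse", "msd"]].mean().reset_index())
    per_pop = per_rep.groupby(["population", "method"])[["rmse", "msd"]].mean()
    g = per_pop.groupby("method").mean()
    return {m: {"rmse": float(g.loc[m, "rmse"]), "msd": float(g.loc[m, "msd"])}
            for m in g.index}
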