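"""Weighted semi-parametric continuous norming.

The pipeline: raw scores are ranked within age groups with a weighted
tie-averaged mid-rank rule, percentiles are mapped to an IQ-metric location
(mean 100, SD 15) through the inverse normal transformation, and a Taylor
polynomial in (location, age) is fitted to the raw scores by weighted least
squares with best-subset term selection.  Inverting the fitted polynomial at
a given age converts raw scores back to norm scores.

With all weights equal the weighted path reduces exactly — bit for bit — to
the unweighted semi-parametric continuous norming procedure, so a single
implementation serves both the weighted (WCN) and unweighted (SCN) methods.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "RankedSample",
    "NormModel",
    "weighted_percentile_ranks",
    "location_from_percentile",
    "build_design_matrix",
    "fit_norm_model",
    "predict_raw",
    "predict_norm_score",
]

log = logging.getLogger(__name__)

IQ_MEAN = 100.0
IQ_SD = 15.0

DEFAULT_K = 4
DEFAULT_MAX_TERMS = 12
DEFAULT_R2_TARGET = 0.99

#: Largest number of same-size candidate subsets searched exhaustively;
#: beyond this a deterministic beam search extends the best smaller subsets.
EXHAUSTIVE_LIMIT = 50_000
BEAM_WIDTH = 40
#: How many top candidates per size are audited for monotonicity.
MONO_CANDIDATES = 10
#: Monotonicity-audit grid: points along location x points along age.
MONO_GRID = (200, 60)

#: Cumulative decrease in predicted raw score below which a profile still
#: counts as monotone (absorbs floating-point wiggle on flat stretches).
_MONO_SLACK = 1e-3


def location_from_percentile(p):
    """Map a percentile in (0, 1) to the IQ metric: 100 + 15 * Phi^-1(p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("percentiles must lie strictly inside (0, 1)")
    out = IQ_MEAN + IQ_SD * ndtri(p)
    return out if out.ndim else float(out)


def _group_percentiles(raw: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted tie-averaged mid-rank percentiles for one group.

    For raw value x: (W_below + 0.5 * W_equal) / W_total.  Reduces to the
    RankIt rule (mean rank - 0.5)/n under unit weights.
    """
    order = np.argsort(raw, kind="stable")
    xs, ws = raw[order], w[order]
    total = ws.sum()
    # run boundaries of tied raw values in sorted order
    new_run = np.empty(xs.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = xs[1:] != xs[:-1]
    run_id = np.cumsum(new_run) - 1
    run_w = np.bincount(run_id, weights=ws)
    below = np.concatenate(([0.0], np.cumsum(run_w)[:-1]))
    p_run = (below + 0.5 * run_w) / total
    p = np.empty(xs.size)
    p[order] = p_run[run_id]
    return p


def weighted_percentile_ranks(sample: pd.DataFrame, group_col: str = "cohort",
                              raw_col: str = "raw", weight_col: str = "weight",
                              age_col: str = "age") -> pd.DataFrame:
    """Attach weighted percentile ranks and IQ-metric locations per group.

    Returns a copy of the sample with columns ``percentile``, ``location``
    and ``group_age`` (the weighted mean age of the person's group, used as
    the age predictor in the continuous model).
    """
    w_all = sample[weight_col].to_numpy(dtype=float)
    if np.any(w_all <= 0):
        raise ValueError("weights must be strictly positive")
    out = sample.copy()
    perc = np.empty(len(out))
    gage = np.empty(len(out))
    raw_all = out[raw_col].to_numpy(dtype=float)
    age_all = out[age_col].to_numpy(dtype=float)
    for _, idx in out.groupby(group_col).indices.items():
        perc[idx] = _group_percentiles(raw_all[idx], w_all[idx])
        gage[idx] = np.average(age_all[idx], weights=w_all[idx])
    out["percentile"] = perc
    out["location"] = location_from_percentile(perc)
    out["group_age"] = gage
    return out


#: Alias used in signatures: a ranked sample is a DataFrame as returned by
#: :func:`weighted_percentile_ranks`.
RankedSample = pd.DataFrame


def polynomial_terms(k: int) -> list:
    """Exponent pairs (i, j) with 0 <= i, j <= k, excluding (0, 0)."""
    return [(i, j) for i in range(k + 1) for j in range(k + 1) if (i, j) != (0, 0)]


def build_design_matrix(loc, age, k: int) -> np.ndarray:
    """Design matrix with columns location^i * age^j over all (i, j) != (0, 0)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    loc = np.asarray(loc, dtype=float)
    age = np.asarray(age, dtype=float)
    lp = np.stack([loc**i for i in range(k + 1)], axis=-1)
    ap = np.stack([age**j for j in range(k + 1)], axis=-1)
    cols = [lp[..., i] * ap[..., j] for i, j in polynomial_terms(k)]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class NormModel:
    """Selected polynomial mapping (norm-score location, age) -> raw score."""

    k: int
    terms: tuple                 # exponent pairs (i, j)
    coef: np.ndarray             # one coefficient per term
    intercept: float
    r2: float
    adj_r2: float
    monotone: bool
    flagged: bool                # True when no candidate met the R^2 target
    loc_range: tuple             # calibration range of the location
    age_range: tuple             # calibration range of the age predictor
    raw_range: tuple             # raw-score range seen during fitting
    n_obs: int

    def __post_init__(self):
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=float))
        if len(self.terms) != self.coef.size:
            raise ValueError("terms and coefficients must align")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "terms": [list(t) for t in self.terms],
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "r2": self.r2, "adj_r2": self.adj_r2,
            "monotone": self.monotone, "flagged": self.flagged,
            "loc_range": list(self.loc_range),
            "age_range": list(self.age_range),
            "raw_range": list(self.raw_range),
            "n_obs": self.n_obs,
        })

    @classmethod
    def from_json(cls, s: str) -> "NormModel":
        d = json.loads(s)
        return cls(d["k"], tuple(tuple(t) for t in d["terms"]),
                   np.array(d["coef"]), d["intercept"], d["r2"], d["adj_r2"],
                   d["monotone"], d["flagged"], tuple(d["loc_range"]),
                   tuple(d["age_range"]), tuple(d["raw_range"]), d["n_obs"])


def predict_raw(model: NormModel, loc, age):
    """Evaluate the fitted polynomial (no clamping)."""
    loc = np.asarray(loc, dtype=float)
    age = np.asarray(age, dtype=float)
    out = np.full(np.broadcast(loc, age).shape, model.intercept, dtype=float)
    for (i, j), b in zip(model.terms, model.coef):
        out += b * loc**i * age**j
    return out if out.ndim else float(out)


def _profile(model: NormModel, grid_loc: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Predicted raw over (n_ages, n_loc) without building the full design."""
    out = np.full((ages.size, grid_loc.size), model.intercept)
    for (i, j), b in zip(model.terms, model.coef):
        out += b * (ages[:, None] ** j) * (grid_loc[None, :] ** i)
    return out


def _is_monotone(model: NormModel, n_loc: int = MONO_GRID[0],
                 n_age: int = MONO_GRID[1]) -> bool:
    """Audit: predicted raw non-decreasing in location at every grid age."""
    lo, hi = model.loc_range
    a0, a1 = model.age_range
    grid_loc = np.linspace(lo, hi, n_loc)
    ages = np.linspace(a0, a1, n_age) if a1 > a0 else np.array([a0])
    p = _profile(model, grid_loc, ages)
    return bool(np.all(np.diff(p, axis=1) >= -_MONO_SLACK / n_loc))


def _batched_rss(G, c, yy, subsets):
    """Weighted RSS for each subset (intercept always included).

    G, c are the Gram matrix / moment vector of the standardized design with
    the intercept at index 0; ``subsets`` holds column indices >= 1.
    """
    idx = np.concatenate(
        [np.zeros((subsets.shape[0], 1), dtype=int), subsets + 1], axis=1)
    Gs = G[idx[:, :, None], idx[:, None, :]]
    cs = c[idx][:, :, None]
    try:
        b = np.linalg.solve(Gs, cs)[:, :, 0]
    except np.linalg.LinAlgError:
        # near-collinear candidate somewhere in the batch: tiny ridge keeps
        # the ranking intact while making every system solvable
        eye = np.eye(idx.shape[1])
        b = np.linalg.solve(Gs + 1e-9 * eye, cs)[:, :, 0]
    cs = cs[:, :, 0]
    rss = yy - np.einsum("bi,bi->b", cs, b)
    return np.maximum(rss, 0.0)


def _finalize(X, y, sw, col_mean, col_scale, subset, terms_all, k,
              loc, age, raw, n):
    """Fit final coefficients for one subset and package a NormModel."""
    Z = (X[:, subset] - col_mean[subset]) / col_scale[subset]
    A = np.column_stack([np.ones(n), Z]) * sw[:, None]
    bz, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    coef = bz[1:] / col_scale[subset]
    intercept = bz[0] - float(np.sum(bz[1:] * col_mean[subset] / col_scale[subset]))

    resid = y - (X[:, subset] @ coef + intercept)
    w = sw**2
    wmean = np.average(y, weights=w)
    tss = float(np.sum(w * (y - wmean) ** 2))
    rss = float(np.sum(w * resid**2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    m = subset.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1) if n > m + 1 else r2

    model = NormModel(
        k=k,
        terms=tuple(terms_all[j] for j in subset),
        coef=coef, intercept=intercept,
        r2=r2, adj_r2=adj, monotone=False, flagged=False,
        loc_range=(float(loc.min()), float(loc.max())),
        age_range=(float(age.min()), float(age.max())),
        raw_range=(float(raw.min()), float(raw.max())),
        n_obs=n,
    )
    return model


def fit_norm_model(ranked: RankedSample, k: int = DEFAULT_K,
                   max_terms: int = DEFAULT_MAX_TERMS,
                   r2_target: float = DEFAULT_R2_TARGET,
                   raw_col: str = "raw", loc_col: str = "location",
                   age_col: str = "group_age",
                   weight_col: str = "weight") -> NormModel:
    """Best-subset weighted polynomial regression of raw score on (location, age).

    For each model size m = 1..max_terms the subset with the lowest weighted
    residual sum of squares is found (exhaustively where the combination
    count allows, by deterministic beam search beyond that); the final model
    is the smallest size whose adjusted R^2 reaches ``r2_target`` and whose
    predicted raw score is non-decreasing in the location over the
    calibration grid.  If no size qualifies, the monotone candidate with the
    highest adjusted R^2 is returned with ``flagged=True``.
    """
    n = len(ranked)
    if n < max_terms + 2:
        raise ValueError(f"need at least {max_terms + 2} rows, got {n}")
    loc = ranked[loc_col].to_numpy(dtype=float)
    age = ranked[age_col].to_numpy(dtype=float)
    y = ranked[raw_col].to_numpy(dtype=float)
    w = ranked[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    terms_all = polynomial_terms(k)
    X = build_design_matrix(loc, age, k)
    P = X.shape[1]
    max_terms = min(max_terms, P)

    col_mean = X.mean(axis=0)
    col_scale = X.std(axis=0)
    usable = col_scale > 1e-12 * np.maximum(1.0, np.abs(col_mean))
    col_scale = np.where(usable, col_scale, 1.0)

    sw = np.sqrt(w)
    Z = (X - col_mean) / col_scale
    A = np.column_stack([np.ones(n), Z]) * sw[:, None]
    yw = y * sw
    G = A.T @ A
    c = A.T @ yw
    yy = float(yw @ yw)

    cand_cols = np.flatnonzero(usable)
    best_flagged = None
    prev_top = None  # best subsets of the previous size (beam seeds)

    for m in range(1, max_terms + 1):
        if comb(cand_cols.size, m) <= EXHAUSTIVE_LIMIT:
            subsets = np.array(list(itertools.combinations(cand_cols, m)),
                               dtype=int)
        else:
            seen = set()
            ext = []
            for s in prev_top:
                base = set(s)
                for col in cand_cols:
                    if col in base:
                        continue
                    key = tuple(sorted((*s, col)))
                    if key not in seen:
                        seen.add(key)
                        ext.append(key)
            subsets = np.array(ext, dtype=int)
        rss = _batched_rss(G, c, yy, subsets)
        order = np.argsort(rss, kind="stable")
        prev_top = [tuple(subsets[i]) for i in order[:BEAM_WIDTH]]

        for rank_i in order[:MONO_CANDIDATES]:
            model = _finalize(X, y, sw, col_mean, col_scale,
                              np.asarray(subsets[rank_i]), terms_all, k,
                              loc, age, y, n)
            if _is_monotone(model):
                model = NormModel(**{**model.__dict__, "monotone": True,
                                     "coef": model.coef})
                if model.adj_r2 >= r2_target:
                    log.debug("accepted %d-term model, adj R^2 = %.5f",
                              m, model.adj_r2)
                    return model
                if best_flagged is None or model.adj_r2 > best_flagged.adj_r2:
                    best_flagged = model
                break  # best monotone model of this size found; grow m

    if best_flagged is None:
        raise ValueError(
            "no monotone polynomial candidate found at any size; "
            "consider a lower k or a larger sample"
        )
    log.debug("no candidate reached adj R^2 >= %.3f; returning flagged "
              "%d-term model (adj R^2 = %.5f)", r2_target,
              best_flagged.n_terms, best_flagged.adj_r2)
    return NormModel(**{**best_flagged.__dict__, "flagged": True,
                        "coef": best_flagged.coef})


def predict_norm_score(model: NormModel, raw, age, lo: float = 40.0,
                       hi: float = 160.0, tol: float = 1e-4,
                       return_flags: bool = False):
    """Invert the fitted polynomial: norm-score location for (raw, age).

    Bisection over the widest location interval containing IQ 100 on which
    the predicted raw score is non-decreasing at the given age (the fitted
    quartic may bend outside the calibration range, so the search is
    restricted to its monotone core).  Raw scores below/above the attainable
    range at that age are clamped to the interval endpoint and flagged.

    Raises if the prediction profile decreases materially inside the
    calibration location range at any requested age.
    """
    raw_a, age_a = np.broadcast_arrays(np.asarray(raw, dtype=float),
                                       np.asarray(age, dtype=float))
    shape = raw_a.shape
    raw_a = raw_a.ravel()
    age_a = age_a.ravel()
    n_grid = 241
    grid = np.linspace(lo, hi, n_grid)
    prof = _profile(model, grid, age_a)          # (n, n_grid)
    drops = np.diff(prof, axis=1)

    # material non-monotonicity within the calibration region is a model
    # error; outside the calibration age range (evaluees younger/older than
    # the group centers) the search is simply restricted to the monotone core
    cal = (grid[:-1] >= model.loc_range[0]) & (grid[1:] <= model.loc_range[1])
    in_cal_age = (age_a >= model.age_range[0]) & (age_a <= model.age_range[1])
    cal_drop = np.clip(drops[:, cal], None, 0.0).sum(axis=1)
    cal_drop = np.where(in_cal_age, cal_drop, 0.0)
    if np.any(cal_drop < -_MONO_SLACK):
        bad_age = age_a[int(np.argmin(cal_drop))]
        raise ValueError(
            f"prediction profile is non-monotone in the location within the "
            f"calibration range at age {bad_age:.3f}"
        )

    ok = drops >= -_MONO_SLACK / n_grid
    center = int(np.argmin(np.abs(grid - IQ_MEAN)))
    seg_idx = np.arange(n_grid - 1)
    # last bad step left of the center bounds the segment from below
    left_bad = np.where(~ok[:, :center], seg_idx[:center] + 1, 0)
    lb = left_bad.max(axis=1) if center > 0 else np.zeros(len(raw_a), dtype=int)
    right_bad = np.where(~ok[:, center:], seg_idx[center:], n_grid - 1)
    rb = right_bad.min(axis=1) if center < n_grid - 1 else np.full(len(raw_a), n_grid - 1)

    a = grid[lb].copy()
    b = grid[rb].copy()
    f_a = np.take_along_axis(prof, lb[:, None], axis=1).ravel()
    f_b = np.take_along_axis(prof, rb[:, None], axis=1).ravel()

    below = raw_a <= f_a
    above = raw_a >= f_b
    clamped = below | above

    n_iter = int(np.ceil(np.log2((hi - lo) / tol))) + 2
    lo_b, hi_b = a.copy(), b.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo_b + hi_b)
        f_mid = predict_raw(model, mid, age_a)
        under = f_mid < raw_a
        lo_b = np.where(under, mid, lo_b)
        hi_b = np.where(under, hi_b, mid)
    scores = 0.5 * (lo_b + hi_b)
    scores[below] = a[below]
    scores[above] = b[above]
    scores = scores.reshape(shape)
    clamped = clamped.reshape(shape)
    if np.any(clamped):
        log.debug("clamped %d of %d norm scores at the search-interval edge",
                  int(clamped.sum()), clamped.size)
    if scores.ndim == 0:
        scores = float(scores)
        clamped = bool(clamped)
    if return_flags:
        return scores, clamped
    return scores
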