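import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rakenorm as rn
from rakenorm import norming


def _one_group(raws, weights):
    df = pd.DataFrame({"cohort": 0, "age": 0.5, "raw": raws,
                       "weight": weights})
    return norming.weighted_percentile_ranks(df)


def test_weighted_midrank_percentiles():
    out = _one_group([10, 10, 20], [1.0, 1.0, 2.0])
    assert np.allclose(out["percentile"], [0.25, 0.25, 0.75])


def test_unit_weights_reduce_to_rankit():
    out = _one_group([5, 7], [1.0, 1.0])
    assert np.allclose(out["percentile"], [0.25, 0.75])
    n = 9
    out = _one_group(np.arange(n), np.ones(n))
    assert np.allclose(np.sort(out["percentile"]),
                       (np.arange(1, n + 1) - 0.5) / n)


def test_single_observation_and_degenerate_group():
    out = _one_group([12], [3.0])
    assert out["percentile"].iloc[0] == 0.5
    assert out["location"].iloc[0] == pytest.approx(100.0)
    tied = _one_group([4, 4, 4], [1.0, 2.0, 3.0])
    assert np.allclose(tied["percentile"], 0.5)


@settings(deadline=None, max_examples=50)
@given(st.data())
def test_percentile_rank_properties(data):
    """Percentiles lie in (0,1), respect raw-score order, honour ties, and
    are invariant to weight rescaling."""
    n = data.draw(st.integers(2, 30))
    raws = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
    weights = data.draw(st.lists(
        st.floats(0.1, 10.0, allow_nan=False), min_size=n, max_size=n))
    out = _one_group(raws, weights)
    p = out["percentile"].to_numpy()
    assert np.all((p > 0) & (p < 1))
    order = np.argsort(raws, kind="stable")
    assert np.all(np.diff(p[order]) >= -1e-12)
    r = np.asarray(raws)
    for v in np.unique(r):
        assert np.allclose(p[r == v], p[r == v][0])
    scaled = _one_group(raws, np.asarray(weights) * 7.25)
    assert np.allclose(scaled["percentile"], p, atol=1e-12)


def test_location_from_percentile():
    assert norming.location_from_percentile(0.5) == 100.0
    assert norming.location_from_percentile(0.841345) == pytest.approx(115.0, abs=0.01)
    assert norming.location_from_percentile(0.158655) == pytest.approx(85.0, abs=0.01)
    for bad in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ValueError):
            norming.location_from_percentile(bad)


def test_design_matrix_shapes():
    loc = np.array([90.0, 100.0, 110.0])
    age = np.array([1.0, 2.0, 3.0])
    assert norming.build_design_matrix(loc, age, 4).shape == (3, 24)
    X1 = norming.build_design_matrix(loc, age, 1)
    assert X1.shape == (3, 3)
    # location 0: only pure-age columns can be non-zero
    X = norming.build_design_matrix(np.array([0.0]), np.array([2.0]), 4)
    terms = norming.polynomial_terms(4)
    nonzero = {terms[j] for j in np.flatnonzero(X[0])}
    assert all(i == 0 for i, _ in nonzero)
    with pytest.raises(ValueError):
        norming.build_design_matrix(loc, age, 0)


def test_noise_free_term_recovery():
    """Best-subset selection recovers the exact generating polynomial."""
    rng = np.random.default_rng(0)
    n = 400
    loc = rng.uniform(60, 140, n)
    age = rng.uniform(0.5, 5.5, n)
    raw = 5.0 + 0.25 * loc + 0.05 * loc * age + 0.8 * age**2
    ranked = pd.DataFrame({"raw": raw, "location": loc, "group_age": age,
                           "weight": 1.0})
    model = norming.fit_norm_model(ranked, k=4)
    assert set(model.terms) == {(1, 0), (1, 1), (0, 2)}
    assert model.r2 > 1 - 1e-10
    assert not model.flagged
    coef = dict(zip(model.terms, model.coef))
    assert coef[(1, 0)] == pytest.approx(0.25, abs=1e-8)
    assert coef[(1, 1)] == pytest.approx(0.05, abs=1e-9)
    assert model.intercept == pytest.approx(5.0, abs=1e-6)


def test_duplicated_rows_equal_doubled_weights(raked_sample):
    ranked = norming.weighted_percentile_ranks(raked_sample)
    doubled = ranked.copy()
    doubled["weight"] = 2.0 * doubled["weight"]
    duplicated = pd.concat([ranked, ranked], ignore_index=True)
    m1 = norming.fit_norm_model(doubled)
    m2 = norming.fit_norm_model(duplicated)
    assert m1.terms == m2.terms
    assert np.allclose(m1.coef, m2.coef, rtol=1e-8, atol=1e-12)
    assert m1.intercept == pytest.approx(m2.intercept, rel=1e-8)


def test_unit_weight_weighted_path_equals_unweighted(sample_scenario3):
    """With all weights equal the weighted pipeline is bit-identical to the
    unweighted one (percentiles, locations, coefficients, norm scores)."""
    ones = sample_scenario3.copy()
    ones["weight"] = 1.0
    equal = sample_scenario3.copy()
    equal["weight"] = 2.0  # equal but not unit: rescaling must not matter
    r_ones = norming.weighted_percentile_ranks(ones)
    r_equal = norming.weighted_percentile_ranks(equal)
    assert np.array_equal(r_ones["percentile"].to_numpy(),
                          r_equal["percentile"].to_numpy())
    assert np.array_equal(r_ones["location"].to_numpy(),
                          r_equal["location"].to_numpy())
    m_ones = norming.fit_norm_model(r_ones)
    m_equal = norming.fit_norm_model(r_equal)
    assert m_ones.terms == m_equal.terms
    assert np.allclose(m_ones.coef, m_equal.coef, rtol=1e-10)
    scores_ones = norming.predict_norm_score(m_ones, np.arange(32), np.full(32, 3.0))
    scores_equal = norming.predict_norm_score(m_equal, np.arange(32), np.full(32, 3.0))
    assert np.allclose(scores_ones, scores_equal, atol=1e-8)


def test_fitted_model_quality(fitted_model):
    assert fitted_model.monotone
    assert not fitted_model.flagged
    assert fitted_model.adj_r2 >= 0.99
    assert 1 <= fitted_model.n_terms <= 12


def test_predict_raw_simple_model():
    model = norming.NormModel(k=1, terms=((1, 0),), coef=[1.0], intercept=0.0,
                              r2=1.0, adj_r2=1.0, monotone=True, flagged=False,
                              loc_range=(40, 160), age_range=(0, 6),
                              raw_range=(40, 160), n_obs=10)
    assert norming.predict_raw(model, 7.0, 3.0) == pytest.approx(7.0)


def test_predict_raw_matches_fit(fitted_model, raked_sample):
    ranked = norming.weighted_percentile_ranks(raked_sample)
    row = ranked.iloc[ranked["location"].sub(100).abs().argmin()]
    pred = norming.predict_raw(fitted_model, row["location"], row["group_age"])
    resid = 1.0 - fitted_model.r2
    assert abs(pred - row["raw"]) < 6 * np.sqrt(resid * ranked["raw"].var() + 1e-12) + 1.5


def test_round_trip_inversion(fitted_model):
    ells = np.linspace(60, 140, 33)
    for age in (0.8, 3.0, 5.2):
        raws = norming.predict_raw(fitted_model, ells, np.full_like(ells, age))
        back = norming.predict_norm_score(fitted_model, raws,
                                          np.full_like(ells, age))
        assert np.allclose(back, ells, atol=1e-3)


def test_inversion_center_and_clamping(fitted_model):
    raw_at_100 = norming.predict_raw(fitted_model, 100.0, 3.0)
    assert norming.predict_norm_score(fitted_model, raw_at_100, 3.0) == pytest.approx(100.0, abs=1e-3)
    score, clamped = norming.predict_norm_score(fitted_model, 1e6, 3.0,
                                                return_flags=True)
    assert clamped and score <= 160.0
    score_lo, clamped_lo = norming.predict_norm_score(fitted_model, -1e6, 3.0,
                                                      return_flags=True)
    assert clamped_lo and score_lo >= 40.0


def test_norm_scores_monotone_in_raw(fitted_model):
    raws = np.arange(32, dtype=float)
    for age in (1.0, 3.5, 5.0):
        scores = norming.predict_norm_score(fitted_model, raws,
                                            np.full(32, age))
        assert np.all(np.diff(scores) >= -1e-6)


def test_model_json_roundtrip(fitted_model):
    back = norming.NormModel.from_json(fitted_model.to_json())
    assert back.terms == fitted_model.terms
    assert np.allclose(back.coef, fitted_model.coef)
    assert back.adj_r2 == fitted_model.adj_r2
    x = norming.predict_raw(back, 95.0, 2.2)
    assert x == pytest.approx(norming.predict_raw(fitted_model, 95.0, 2.2))


def test_fit_rejects_tiny_or_invalid_samples(raked_sample):
    ranked = norming.weighted_percentile_ranks(raked_sample)
    with pytest.raises(ValueError, match="rows"):
        norming.fit_norm_model(ranked.head(5))
    bad = ranked.copy()
    bad.loc[bad.index[0], "weight"] = -1.0
    with pytest.raises(ValueError, match="positive"):
        norming.fit_norm_model(bad)
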