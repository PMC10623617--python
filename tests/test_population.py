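import numpy as np
import pytest

import rakenorm as rn
from rakenorm.benchmark import theoretical_moments
from rakenorm.population import CellTable, REFERENCE_MARGINALS, age_trend


@pytest.mark.parametrize("age,edu,eth,reg,expected", [
    (0, 3, 3, 3, -6.0),
    (6, 1, 1, 1, 3.2696),
    (3, 2, 2, 2, -0.8319),
])
def test_cell_mean_values(age, edu, eth, reg, expected):
    assert rn.cell_mean(age, edu, eth, reg) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("kwargs", [
    dict(age=-0.1, education=1, ethnicity=1, region=1),
    dict(age=6.5, education=1, ethnicity=1, region=1),
    dict(age=3, education=0, ethnicity=1, region=1),
    dict(age=3, education=1, ethnicity=4, region=1),
])
def test_cell_mean_rejects_out_of_range(kwargs):
    with pytest.raises(ValueError):
        rn.cell_mean(**kwargs)


def test_scenario1_is_exact_outer_product(spec1):
    table = spec1.tables[0]
    # (native, south, low) cell: 40% x 30% x 60%
    assert table.props[2, 2, 2] == pytest.approx(7.2, abs=1e-12)
    assert table.props.sum() == pytest.approx(100.0, abs=1e-9)
    m = {v: np.array(list(REFERENCE_MARGINALS[v].values()))
         for v in ("education", "ethnicity", "region")}
    outer = 100 * np.einsum("i,j,k->ijk", m["education"], m["ethnicity"],
                            m["region"])
    assert np.allclose(table.props, outer, atol=1e-12)
    assert all(t is spec1.tables[0] for t in spec1.tables)


@pytest.mark.parametrize("scenario,education", [
    (2, (28.0, 20.0, 52.0)),
    (3, (20.0, 20.0, 60.0)),
    (4, (30.0, 40.0, 30.0)),
])
def test_education_scenarios_change_only_education(scenario, education, spec1):
    spec = rn.scenario_cells(scenario)
    table = spec.tables[0]
    assert np.allclose(table.marginal("education"), education, atol=1e-9)
    for var in ("ethnicity", "region"):
        assert np.allclose(table.marginal(var),
                           spec1.tables[0].marginal(var), atol=1e-12)


def test_scenario5_preserves_marginals_but_not_joints(spec1):
    spec = rn.scenario_cells(5)
    table = spec.tables[0]
    for var in ("education", "ethnicity", "region"):
        assert np.allclose(table.marginal(var),
                           spec1.tables[0].marginal(var), atol=1e-12)
    assert np.abs(table.props - spec1.tables[0].props).max() > 0.1
    with pytest.raises(ValueError, match="below zero"):
        rn.scenario_cells(5, c=0.5)


def test_scenario6_clustered_cohorts(spec1):
    spec = rn.scenario_cells(6)
    ref = spec1.tables[0].props
    active = np.zeros((3, 3, 3))
    for table in spec.tables:
        assert (table.props == 0).sum() == 18
        assert table.props.sum() == pytest.approx(100.0, abs=1e-9)
        active += (table.props > 0)
    # every cell is active in exactly two of the six cohorts
    assert np.all(active == 2)
    # exact tripling is arithmetically impossible (cells are multiples of
    # 0.4 %), so the pooled table matches the reference only approximately
    assert np.allclose(spec.pooled().props, ref, rtol=0.02)


def test_scenario_spec_json_roundtrip():
    spec = rn.scenario_cells(6)
    back = rn.ScenarioSpec.from_json(spec.to_json())
    for a, b in zip(spec.tables, back.tables):
        assert np.allclose(a.props, b.props, atol=1e-12)


def test_generate_population_structure(spec1):
    pop = rn.generate_population(spec1, 100_000, seed=5)
    assert len(pop) == 600_000
    assert pop["age"].between(0, 6, inclusive="left").all()
    assert (pop["cohort"] == np.floor(pop["age"])).all()
    shares = pop["education"].value_counts(normalize=True)
    assert shares[1] == pytest.approx(0.40, abs=0.005)
    assert shares[2] == pytest.approx(0.20, abs=0.005)
    assert shares[3] == pytest.approx(0.40, abs=0.005)
    resid = pop["x1"] - rn.cell_mean(pop["age"], pop["education"],
                                     pop["ethnicity"], pop["region"])
    assert resid.mean() == pytest.approx(0.0, abs=0.01)
    assert resid.std() == pytest.approx(1.0, abs=0.01)


def test_generate_population_reproducible(spec1):
    a = rn.generate_population(spec1, 2000, seed=7)
    b = rn.generate_population(spec1, 2000, seed=7)
    assert a.equals(b)
    c = rn.generate_population(spec1, 2000, seed=8)
    assert not a["x1"].equals(c["x1"])


def test_reference_moments_match_quadrature_oracle(reference_small, spec1):
    _, moments = reference_small
    oracle = theoretical_moments(spec1)
    assert moments.mu == pytest.approx(oracle.mu, abs=0.02)
    assert moments.sigma == pytest.approx(oracle.sigma, abs=0.02)
    # the latent SD of the reference population is ~2.27
    assert 2.2 < moments.sigma < 2.35


def test_reference_moments_degenerate():
    import pandas as pd
    with pytest.raises(ValueError):
        rn.reference_moments(pd.DataFrame({"x1": []}))
    with pytest.raises(ValueError, match="degenerate"):
        rn.reference_moments(pd.DataFrame({"x1": np.ones(10)}))


def test_standardize_ability(moments):
    assert rn.standardize_ability(moments.mu, moments) == pytest.approx(0.0)
    ident = rn.ReferenceMoments(0.0, 1.0)
    x = np.array([-1.3, 0.4, 2.0])
    assert np.array_equal(rn.standardize_ability(x, ident), x)
    with pytest.raises(ValueError):
        rn.ReferenceMoments(0.0, 0.0)


def test_biased_scenario_lowers_standardized_mean(moments):
    """Underrepresenting high education lowers the reference-standardized mean."""
    s2 = rn.scenario_cells(2)
    oracle2 = theoretical_moments(s2)
    assert rn.standardize_ability(oracle2.mu, moments) < -0.05
    pop2 = rn.generate_population(s2, 20_000, seed=9)
    theta = rn.standardize_ability(pop2["x1"].to_numpy(), moments)
    assert theta.mean() < -0.05
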