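"""Demographically structured simulated populations for norming studies.

A latent cognitive ability is modeled as a polynomial growth curve in age plus
additive effects of three categorical demographic variables (education,
ethnicity, region), each with three levels.  Category codes are ordered by
ability direction: code 1 marks the above-average category (high education,
non-native ethnicity, northwest region), code 2 the average one, and code 3
the below-average category (low education, native ethnicity, south region),
so that the negative coefficients of the ability surface lower the mean for
below-average categories.

Six population scenarios are provided: a demographically representative
reference population and five systematic distortions of it (education
under-/overrepresentation, biased joint distributions with intact marginals,
and clustered sampling with empty cross-classification cells per age cohort).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLES",
    "CATEGORY_LABELS",
    "REFERENCE_MARGINALS",
    "CellTable",
    "ScenarioSpec",
    "ReferenceMoments",
    "cell_mean",
    "scenario_cells",
    "generate_population",
    "reference_moments",
    "standardize_ability",
]

#: Demographic variables in fixed order (also the cell-table axis order).
VARIABLES = ("education", "ethnicity", "region")

#: Category label per variable and numeric code (1 = above-average ability,
#: 2 = average, 3 = below-average).
CATEGORY_LABELS = {
    "education": {1: "high", 2: "medium", 3: "low"},
    "ethnicity": {1: "non-native", 2: "mixed", 3: "native"},
    "region": {1: "northwest", 2: "east", 3: "south"},
}

#: Reference-population marginal distributions, keyed by numeric code.
REFERENCE_MARGINALS = {
    "education": {1: 0.40, 2: 0.20, 3: 0.40},
    "ethnicity": {1: 0.30, 2: 0.40, 3: 0.30},
    "region": {1: 0.20, 2: 0.20, 3: 0.60},
}

N_COHORTS = 6
AGE_MAX = 6.0

# Coefficients of the latent-ability surface.
_B_EDU = -1.5
_B_ETH = -0.25
_B_REG = -0.1
_B_ETH_REG = -0.05
_B_AGE1 = 1.2
_B_AGE2 = -0.06
_B_AGE4 = 0.0001


def cell_mean(age, education, ethnicity, region):
    """Mean latent ability for a demographic cell at a given age.

    All arguments may be scalars or broadcastable arrays.  Ages must lie in
    [0, 6] and codes in {1, 2, 3}.
    """
    age = np.asarray(age, dtype=float)
    edu = np.asarray(education)
    eth = np.asarray(ethnicity)
    reg = np.asarray(region)
    if np.any((age < 0.0) | (age > AGE_MAX)):
        raise ValueError(f"age must lie in [0, {AGE_MAX}]")
    for name, codes in (("education", edu), ("ethnicity", eth), ("region", reg)):
        if not np.all(np.isin(codes, (1, 2, 3))):
            raise ValueError(f"{name} codes must be in {{1, 2, 3}}")
    out = (
        _B_EDU * edu
        + _B_ETH * eth
        + _B_REG * reg
        + _B_ETH_REG * eth * reg
        + _B_AGE1 * age
        + _B_AGE2 * age**2
        + _B_AGE4 * age**4
    )
    return out if out.ndim else float(out)


def age_trend(age):
    """The pure-age part of the ability surface (demographic terms at zero)."""
    age = np.asarray(age, dtype=float)
    return _B_AGE1 * age + _B_AGE2 * age**2 + _B_AGE4 * age**4


@dataclass(frozen=True)
class CellTable:
    """27-cell joint demographic distribution (percent of population).

    ``props`` is indexed ``[education-1, ethnicity-1, region-1]`` and sums to
    100.  Zero cells are allowed (clustered-sampling cohorts).
    """

    props: np.ndarray

    def __post_init__(self):
        props = np.asarray(self.props, dtype=float)
        if props.shape != (3, 3, 3):
            raise ValueError("cell table must have shape (3, 3, 3)")
        if np.any(props < 0):
            raise ValueError("cell proportions must be non-negative")
        if abs(props.sum() - 100.0) > 1e-9:
            raise ValueError(f"cell proportions must sum to 100, got {props.sum()!r}")
        object.__setattr__(self, "props", props)

    @classmethod
    def from_marginals(cls, marginals=None) -> "CellTable":
        """Independent (outer-product) joint table from per-variable marginals."""
        marginals = marginals or REFERENCE_MARGINALS
        arrs = []
        for var in VARIABLES:
            m = marginals[var]
            v = np.array([m[1], m[2], m[3]], dtype=float)
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{var} marginal must sum to 1")
            arrs.append(v)
        props = 100.0 * np.einsum("i,j,k->ijk", *arrs)
        return cls(props)

    def marginal(self, variable: str) -> np.ndarray:
        """Marginal percentages (codes 1..3) for one variable."""
        axis = VARIABLES.index(variable)
        other = tuple(i for i in range(3) if i != axis)
        return self.props.sum(axis=other)

    def flat_probs(self) -> np.ndarray:
        """Cell probabilities (sum 1) in C-order over (edu, eth, reg)."""
        return (self.props / 100.0).ravel()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"education": e, "ethnicity": t, "region": r,
             "percent": self.props[e - 1, t - 1, r - 1]}
            for e, t, r in itertools.product((1, 2, 3), repeat=3)
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            f"{e},{t},{r}": float(self.props[e - 1, t - 1, r - 1])
            for e, t, r in itertools.product((1, 2, 3), repeat=3)
        }

    @classmethod
    def from_dict(cls, d) -> "CellTable":
        props = np.zeros((3, 3, 3))
        for key, val in d.items():
            e, t, r = (int(x) for x in key.split(","))
            props[e - 1, t - 1, r - 1] = float(val)
        return cls(props)


@dataclass(frozen=True)
class ScenarioSpec:
    """A population scenario: one joint cell table per age cohort."""

    scenario_id: int
    tables: tuple
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.tables) != N_COHORTS:
            raise ValueError(f"expected {N_COHORTS} cohort tables")
        object.__setattr__(self, "tables", tuple(self.tables))

    def pooled(self) -> CellTable:
        """Mean cell table over the six cohorts."""
        return CellTable(np.mean([t.props for t in self.tables], axis=0))

    def to_json(self) -> str:
        return json.dumps({
            "scenario_id": self.scenario_id,
            "params": self.params,
            "tables": [t.to_dict() for t in self.tables],
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ScenarioSpec":
        d = json.loads(s)
        return cls(d["scenario_id"],
                   tuple(CellTable.from_dict(t) for t in d["tables"]),
                   d.get("params", {}))


# Education marginals of the distorted scenarios, keyed by numeric code
# (1 = high, 2 = medium, 3 = low).
_SCENARIO_EDUCATION = {
    2: {1: 0.28, 2: 0.20, 3: 0.52},
    3: {1: 0.20, 2: 0.20, 3: 0.60},
    4: {1: 0.30, 2: 0.40, 3: 0.30},
}

#: Sign pattern of the scenario-5 joint perturbation; sums to zero over each
#: variable so all marginals are preserved exactly.
_S5_PATTERN = np.array([1.0, -2.0, 1.0])
#: Default scenario-5 perturbation magnitude (percentage points).
S5_DEFAULT_C = 0.15


def scenario_cells(scenario_id: int, *, c: float | None = None) -> ScenarioSpec:
    """Per-cohort joint cell tables for one of the six population scenarios.

    Scenarios 1-5 use the same table in every cohort.  Scenario 5 perturbs
    the joint cells by ``c * f(e) * f(t) * f(r)`` percentage points with
    f = (+1, -2, +1), which leaves all marginals intact while over-
    representing the extreme-ability corner cells.  Scenario 6 activates a
    different third of the 27 cells in each cohort, at triple weight, so the
    pooled table equals the reference table.
    """
    if scenario_id not in range(1, 7):
        raise ValueError("scenario_id must be in 1..6")
    reference = CellTable.from_marginals()

    if scenario_id == 1:
        return ScenarioSpec(1, (reference,) * N_COHORTS)

    if scenario_id in _SCENARIO_EDUCATION:
        marg = dict(REFERENCE_MARGINALS)
        marg["education"] = _SCENARIO_EDUCATION[scenario_id]
        table = CellTable.from_marginals(marg)
        return ScenarioSpec(scenario_id, (table,) * N_COHORTS)

    if scenario_id == 5:
        c = S5_DEFAULT_C if c is None else float(c)
        delta = c * np.einsum("i,j,k->ijk", _S5_PATTERN, _S5_PATTERN, _S5_PATTERN)
        props = reference.props + delta
        if np.any(props < 0):
            raise ValueError(
                f"scenario-5 magnitude c={c} drives a joint cell below zero "
                f"(min cell {props.min():.3f}%)"
            )
        return ScenarioSpec(5, (CellTable(props),) * N_COHORTS, {"c": c})

    # Scenario 6: partition the 27 cells into three blocks of nine by
    # (e + t + r) mod 3; cohort j activates block (j mod 3) at triple weight.
    # No 9-cell block of the reference table can carry exactly one third of
    # the mass (all cells are multiples of 0.4 %), so the tripled cells are
    # renormalized to sum 100 within each cohort; the scale stays within
    # 1.3 % of 3 and the pooled table matches the reference to < 2 %.
    e, t, r = np.meshgrid([1, 2, 3], [1, 2, 3], [1, 2, 3], indexing="ij")
    block = (e + t + r) % 3
    tables = []
    for j in range(N_COHORTS):
        mask = block == (j % 3)
        props = np.where(mask, reference.props, 0.0)
        props *= 100.0 / props.sum()
        tables.append(CellTable(props))
    return ScenarioSpec(6, tuple(tables), {"partition": "(e+t+r) mod 3"})


def _draw_cells(rng: np.random.Generator, table: CellTable, n: int):
    """Draw n demographic cells; returns (edu, eth, reg) code arrays."""
    flat = rng.choice(27, size=n, p=table.flat_probs())
    edu = flat // 9 + 1
    eth = (flat // 3) % 3 + 1
    reg = flat % 3 + 1
    return edu, eth, reg


def generate_population(spec: ScenarioSpec, n_per_cohort: int,
                        seed=None) -> pd.DataFrame:
    """Person-level population table drawn from a scenario.

    For each cohort, ages are Uniform over that year, a demographic cell is
    drawn from the cohort's table, and the latent ability is the cell mean at
    the person's age plus a standard-normal deviate.

    Returns a DataFrame with columns age, cohort, education, ethnicity,
    region, x1.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
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
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ReferenceMoments:
    """Mean and SD of the latent ability in the reference population."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def reference_moments(pop: pd.DataFrame) -> ReferenceMoments:
    """Empirical moments of x1 over a (reference) population table."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    x1 = pop["x1"].to_numpy()
    sigma = float(np.std(x1))
    if sigma <= 0:
        raise ValueError("degenerate population: sd(x1) is zero")
    return ReferenceMoments(mu=float(np.mean(x1)), sigma=sigma)


def standardize_ability(x1, moments: ReferenceMoments):
    """z-standardize latent ability by the *reference* population moments.

    Distorted-scenario populations are standardized with the scenario-1
    moments, not their own, so that the standardized scale carries the bias
    induced by non-representative sampling.
    """
    if not moments.sigma > 0:
        raise ValueError("sigma must be positive")
    return (np.asarray(x1, dtype=float) - moments.mu) / moments.sigma
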