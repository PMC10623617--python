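"""Dichotomous 1-PL (Rasch) test simulation.

A fixed bank of item difficulties, drawn once per experiment, turns
standardized latent abilities into integer raw scores by Bernoulli sampling
of each item response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["ItemBank", "draw_item_bank", "response_probability", "simulate_raw_scores"]

DEFAULT_N_ITEMS = 31
DEFAULT_BOUNDS = (-3.0, 3.0)


@dataclass(frozen=True)
class ItemBank:
    """Item difficulties on the latent-ability scale."""

    difficulties: np.ndarray
    lo: float = DEFAULT_BOUNDS[0]
    hi: float = DEFAULT_BOUNDS[1]
    seed: int | None = None

    def __post_init__(self):
        d = np.atleast_1d(np.asarray(self.difficulties, dtype=float))
        if d.size < 1:
            raise ValueError("item bank must contain at least one item")
        if not self.lo < self.hi:
            raise ValueError("invalid difficulty bounds: lo must be < hi")
        if np.any((d < self.lo) | (d > self.hi)):
            raise ValueError("difficulties fall outside the declared bounds")
        object.__setattr__(self, "difficulties", d)

    @property
    def n_items(self) -> int:
        return self.difficulties.size

    def to_json(self) -> str:
        return json.dumps({
            "difficulties": self.difficulties.tolist(),
            "lo": self.lo, "hi": self.hi, "seed": self.seed,
        })

    @classmethod
    def from_json(cls, s: str) -> "ItemBank":
        d = json.loads(s)
        return cls(np.array(d["difficulties"]), d["lo"], d["hi"], d.get("seed"))


def draw_item_bank(n_items: int = DEFAULT_N_ITEMS,
                   lo: float = DEFAULT_BOUNDS[0],
                   hi: float = DEFAULT_BOUNDS[1],
                   seed=None) -> ItemBank:
    """Draw item difficulties independently from Uniform(lo, hi)."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if not lo < hi:
        raise ValueError("invalid difficulty bounds: lo must be < hi")
    rng = np.random.default_rng(seed)
    d = rng.uniform(lo, hi, size=n_items)
    return ItemBank(d, lo, hi, seed if isinstance(seed, int) else None)


def response_probability(theta, delta):
    """1-PL success probability exp(theta-delta)/(1+exp(theta-delta)).

    Computed via the logistic sigmoid, stable for large |theta - delta|.
    """
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    out = expit(theta - delta)
    return out if out.ndim else float(out)


def simulate_raw_scores(thetas, bank: ItemBank, seed=None,
                        chunk: int = 200_000) -> np.ndarray:
    """Simulate integer raw scores (0..n_items) for each ability value.

    One uniform draw per person-item pair is compared against the 1-PL
    success probability; item scores are summed.  Chunked so that
    million-person populations stay within ordinary memory.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    rng = np.random.default_rng(seed)
    raw = np.empty(thetas.size, dtype=np.int64)
    delta = bank.difficulties[np.newaxis, :]
    for start in range(0, thetas.size, chunk):
        th = thetas[start:start + chunk, np.newaxis]
        p = expit(th - delta)
        u = rng.random(p.shape)
        raw[start:start + th.size] = (p > u).sum(axis=1)
    return raw


def expected_raw_score(theta, bank: ItemBank):
    """E[raw | theta] = sum_i p(theta, delta_i)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    out = expit(theta[:, None] - bank.difficulties[None, :]).sum(axis=1)
    return out if np.asarray(theta).ndim else out
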