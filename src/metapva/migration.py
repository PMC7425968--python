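"""Distance-decaying migration pressure and Poisson immigrant draws.

Patch ``i`` receives immigrants at a yearly rate

    lambda_i = beta * sum_{j != i} N_j * exp(-alpha * d_ij)

(an incidence-function-style "migration pressure"): ``alpha`` is the rate
of the exponential dispersal kernel (the reciprocal of the mean dispersal
distance, 1/m) and ``beta`` a dimensionless calibrator scaling overall
migration intensity.  The realized immigrant count each year is a Poisson
draw with mean lambda_i, independent across patches.  Migrants are added
to the receiving patch; source patches are not decremented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MigrationParams",
    "migration_pressure",
    "migration_pressures",
    "dispersal_kernel",
    "draw_migrants",
]


@dataclass(frozen=True)
class MigrationParams:
    """alpha: inverse mean dispersal distance (1/m); beta: migration calibrator."""

    alpha: float = 0.01
    beta: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def dispersal_kernel(d: np.ndarray, params: MigrationParams) -> np.ndarray:
    """Matrix W with W_ij = beta * exp(-alpha d_ij) off-diagonal, 0 on it.

    ``lambda = W @ N`` gives all migration pressures at once; precompute W
    when iterating years.
    """
    w = params.beta * np.exp(-params.alpha * np.asarray(d, dtype=float))
    np.fill_diagonal(w, 0.0)
    return w


def migration_pressure(
    i: int, n_vector, d_row, params: MigrationParams
) -> float:
    """Expected immigrants/yr into patch i: beta * sum_{j!=i} N_j exp(-alpha d_ij)."""
    n = np.asarray(n_vector, dtype=float)
    d = np.asarray(d_row, dtype=float)
    if n.shape != d.shape:
        raise ValueError("n_vector and d_row must have the same length")
    if np.any(n < 0):
        raise ValueError("population sizes must be >= 0")
    mask = np.arange(n.size) != i
    return float(params.beta * np.sum(n[mask] * np.exp(-params.alpha * d[mask])))


def migration_pressures(n_vector, d, params: MigrationParams) -> np.ndarray:
    """Vector of migration pressures for every patch (self-contribution excluded)."""
    n = np.asarray(n_vector, dtype=float)
    if np.any(n < 0):
        raise ValueError("population sizes must be >= 0")
    return dispersal_kernel(d, params) @ n


def draw_migrants(lambdas, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson(lambda_i) immigrant counts per patch."""
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam < 0):
        raise ValueError("migration pressures must be >= 0")
    return rng.poisson(lam)
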