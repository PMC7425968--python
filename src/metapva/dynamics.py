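"""Within-patch Ricker dynamics with (optionally correlated) environmental noise.

Each patch follows the discrete-time Ricker recursion

    N_{t+1} = N_t * exp(r_d * (1 - N_t / K) + eps)

where ``eps`` is environmental stochasticity: a normal random variable with
mean 0 and variance ``v_r``, drawn once per patch per year.  ``spacecor``
in [0, 1] scales how strongly noise co-varies between nearby patches; at 0
(the default) patches are independent.  A subpopulation that falls below
one individual is locally extinct and set to exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemographyParams",
    "ricker_step",
    "apply_ceiling",
    "apply_extinction",
    "EnvironmentalNoise",
    "draw_noise",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemographyParams:
    """Demographic parameters of the within-patch model.

    r_d : per-capita growth rate at low density (per vole per yr)
    v_r : variance of environmental stochasticity ((vole x yr)^2)
    spacecor : degree to which noise co-varies between adjacent patches,
        0 (independent) to 1 (strongly locally correlated)
    ceiling : post-growth cap on N as a multiple of K (default 1.0), or
        None for the unbounded recursion.  With lognormal noise the raw
        recursion has E[exp(eps)] = exp(v_r/2) > 1, so subpopulation sizes
        would episodically "boom" to orders of magnitude above K; the
        ceiling keeps each subpopulation at the scale its habitat supports
        (subpopulations are assumed to sit at or near carrying capacity).
    """

    r_d: float = 0.01
    v_r: float = 1.0
    spacecor: float = 0.0
    ceiling: float | None = 1.0

    def __post_init__(self) -> None:
        if self.v_r < 0:
            raise ValueError(f"v_r must be >= 0, got {self.v_r}")
        if not 0.0 <= self.spacecor <= 1.0:
            raise ValueError(f"spacecor must be in [0, 1], got {self.spacecor}")
        if self.ceiling is not None and self.ceiling <= 0:
            raise ValueError(f"ceiling must be > 0 or None, got {self.ceiling}")


def ricker_step(n, k, r_d: float, eps):
    """One year of Ricker growth; scalar or elementwise on arrays.

    A patch with K = 0 (no habitat) maps to 0 regardless of N: it cannot
    support a subpopulation, and migrants stranded there die.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(n < 0):
        raise ValueError("population sizes must be >= 0")
    if np.any(k < 0):
        raise ValueError("carrying capacities must be >= 0")
    safe_k = np.where(k > 0, k, 1.0)
    out = n * np.exp(r_d * (1.0 - n / safe_k) + eps)
    out = np.where(k > 0, out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def apply_ceiling(n_vector, k, ceiling: float | None):
    """Cap each subpopulation at ``ceiling * K`` (no-op when ceiling is None)."""
    n = np.asarray(n_vector, dtype=float)
    if ceiling is None:
        return n
    return np.minimum(n, ceiling * np.asarray(k, dtype=float))


def apply_extinction(n_vector):
    """Set every subpopulation below one individual to exactly zero."""
    n = np.asarray(n_vector, dtype=float)
    return np.where(n < 1.0, 0.0, n)


class EnvironmentalNoise:
    """Sampler for the yearly environmental-noise vector.

    Margins are N(0, v_r).  With ``spacecor > 0`` the cross-patch
    correlation is ``spacecor * exp(-d_ij / L)`` with ``L`` the mean
    inter-patch distance, so correlation decays with distance and
    ``spacecor = 0`` recovers independent draws.  The factorization is
    precomputed once, so per-year draws are a single matrix-vector
    product (or a plain iid draw on the fast path).
    """

    def __init__(self, params: DemographyParams, d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("d must be a square distance matrix")
        self.n = d.shape[0]
        self.params = params
        self._factor: np.ndarray | None = None
        if params.v_r == 0 or params.spacecor == 0 or self.n == 1:
            return
        off = ~np.eye(self.n, dtype=bool)
        scale = float(d[off].mean())
        if scale > 0:
            decay = np.exp(-d / scale)
        else:
            decay = np.ones_like(d)
        corr = params.spacecor * decay
        np.fill_diagonal(corr, 1.0)
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-10:
            logger.warning(
                "noise correlation matrix not positive semidefinite "
                "(min eigenvalue %.3e); clipping to nearest PSD",
                w.min(),
            )
        w = np.clip(w, 0.0, None)
        self._factor = np.sqrt(params.v_r) * (v * np.sqrt(w))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.params.v_r == 0:
            return np.zeros(self.n)
        if self._factor is None:
            return rng.normal(0.0, np.sqrt(self.params.v_r), size=self.n)
        z = rng.standard_normal(self.n)
        return self._factor @ z


def draw_noise(
    n_patches: int,
    params: DemographyParams,
    d: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One yearly noise vector for ``n_patches`` patches (see EnvironmentalNoise)."""
    d = np.asarray(d, dtype=float)
    if d.shape != (n_patches, n_patches):
        raise ValueError(f"d must be {n_patches}x{n_patches}, got {d.shape}")
    return EnvironmentalNoise(params, d).draw(rng)
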