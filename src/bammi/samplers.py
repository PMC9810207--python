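"""Constrained random generators used by the Gibbs conditionals.

Two primitives: truncated-normal draws (for the ordered positive singular
values) and von Mises-Fisher draws on the unit sphere, optionally
restricted to the orthogonal complement of a constraint basis (the ones
vector plus the other singular vectors of the same side, which keeps the
sampled vectors centered and mutually orthogonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats


def draw_truncated_normal(mean, sd, lower, upper, rng) -> float:
    """One draw from N(mean, sd^2) restricted to (lower, upper).

    Uses the scipy inverse-CDF implementation, which is stable far into
    the tails.
    """
    if not sd > 0:
        raise ValueError("sd must be positive")
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _uniform_sphere(d: int, rng) -> np.ndarray:
    x = rng.standard_normal(d)
    return x / np.linalg.norm(x)


def _sample_vmf_cos(d: int, kappa: float, rng) -> float:
    """Cosine of the angle to the mean direction (Ulrich/Wood rejection)."""
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1.0) ** 2)) / (d - 1.0)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1.0) * np.log(1.0 - x0**2)
    while True:
        z = rng.beta((d - 1.0) / 2.0, (d - 1.0) / 2.0)
        w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.uniform()
        if kappa * w + (d - 1.0) * np.log(1.0 - x0 * w) - c >= np.log(u):
            return w


def draw_vmf(direction: np.ndarray, kappa: float, rng) -> np.ndarray:
    """Draw from the von Mises-Fisher density ~ exp(kappa * m'x) on S^{d-1}."""
    direction = np.asarray(direction, dtype=float)
    d = len(direction)
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if kappa == 0:
        return _uniform_sphere(d, rng)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("mean direction must be nonzero when kappa > 0")
    m = direction / nrm
    if d == 1:
        # two-point sphere: P(x=+1) proportional to exp(kappa * m)
        p = 1.0 / (1.0 + np.exp(-np.clip(2.0 * kappa * m[0], -700, 700)))
        return np.array([1.0 if rng.uniform() < p else -1.0])
    w = _sample_vmf_cos(d, kappa, rng)
    v = _uniform_sphere(d - 1, rng)
    x = np.concatenate(([w], np.sqrt(max(1.0 - w * w, 0.0)) * v))
    # rotate the north pole onto m via a Householder reflection
    u = np.zeros(d)
    u[0] = 1.0
    u = u - m
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        return x
    u /= nu
    return x - 2.0 * (u @ x) * u


@dataclass
class ConstraintBasis:
    """Orthonormal set spanning the forbidden directions of a subspace draw."""

    vectors: np.ndarray  # (d, m); may have m == 0

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if V.ndim != 2:
            raise ValueError("basis must be a 2-d array (d, m)")
        self.vectors = V
        m = V.shape[1]
        if m and not np.allclose(V.T @ V, np.eye(m), atol=1e-10):
            raise ValueError("constraint basis is not orthonormal")

    @classmethod
    def centering(cls, d: int, extra: np.ndarray | None = None) -> "ConstraintBasis":
        """Basis spanning the ones vector plus optional extra orthonormal columns."""
        ones = np.full((d, 1), 1.0 / np.sqrt(d))
        cols = [ones]
        if extra is not None and extra.size:
            cols.append(np.atleast_2d(extra.astype(float)).reshape(d, -1))
        B = np.hstack(cols)
        # re-orthonormalize defensively (columns are orthonormal in exact arithmetic)
        Q, _ = np.linalg.qr(B)
        return cls(vectors=Q[:, : B.shape[1]])


def complement_basis(basis: ConstraintBasis, d: int) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of span(basis) in R^d."""
    if basis.vectors.size == 0:
        return np.eye(d)
    return linalg.null_space(basis.vectors.T)


def draw_vmf_in_subspace(raw_direction: np.ndarray, kappa_scale: float, basis: ConstraintBasis, rng) -> np.ndarray:
    """vMF draw restricted to the orthogonal complement of a constraint basis.

    ``raw_direction`` is the unnormalized natural parameter (concentration
    and direction fused); it is projected onto the complement, the
    concentration becomes ``kappa_scale * ||projection||``, and the draw is
    taken in complement coordinates then mapped back.  The result has unit
    norm and is orthogonal to every basis vector.  A numerically zero
    projection falls back to a uniform draw in the complement.
    """
    raw_direction = np.asarray(raw_direction, dtype=float)
    d = len(raw_direction)
    N = complement_basis(basis, d)
    if N.shape[1] == 0:
        raise ValueError("constraint basis spans the whole space")
    coords = N.T @ raw_direction
    nrm = np.linalg.norm(coords)
    if kappa_scale < 0:
        raise ValueError("kappa_scale must be nonnegative")
    if nrm < 1e-12 or kappa_scale == 0:
        xc = _uniform_sphere(N.shape[1], rng)
    else:
        xc = draw_vmf(coords / nrm, kappa_scale * nrm, rng)
    out = N @ xc
    return out / np.linalg.norm(out)


def vmf_mean_resultant_length(d: int, kappa: float) -> float:
    """A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa), the vMF mean resultant length.

    Computed with exponentially scaled Bessel functions; used as the
    independent oracle for the sampler tests.
    """
    from scipy.special import ive

    if kappa == 0:
        return 0.0
    return float(ive(d / 2.0, kappa) / ive(d / 2.0 - 1.0, kappa))
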