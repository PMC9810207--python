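"""Synthetic multi-environment trials with a planted interaction structure.

The default generator emulates a randomized-complete-block maize-style
trial: 20 genotypes x 9 environments x 3 replicates.  Genotype main
effects are N(0, 12), environment main effects N(0, 1) (all normal
distributions are parameterized as mean/variance).  The interaction is
built from three genotype subgroups:

* genotypes 1-5: |N(0, 16)| effects, positive in environments 1-4 and
  negative in environments 5-9 (crossover pattern);
* genotypes 6-10: the mirror image (negative then positive);
* genotypes 11-20: N(0, 1) effects everywhere (stable subgroup).

Draws are independent per genotype-environment cell.  The resulting
matrix is double-centered so that it is a pure interaction, block
effects are identically zero, and plot errors are N(0, 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CenteredGEMatrix, TrialData, double_center


@dataclass
class TrueEffects:
    """Generating values behind one simulated trial."""

    g_true: np.ndarray
    e_true: np.ndarray
    ge_true: CenteredGEMatrix
    sigma2_e_true: float
    stable: np.ndarray  # boolean per genotype; True = stable subgroup

    def to_dict(self) -> dict:
        return {
            "g_true": self.g_true.tolist(),
            "e_true": self.e_true.tolist(),
            "ge_true": self.ge_true.values.tolist(),
            "sigma2_e_true": self.sigma2_e_true,
            "stable": self.stable.tolist(),
        }


@dataclass
class TruthSummary:
    """SVD of the planted interaction matrix: the dimension-selection oracle."""

    true_lambdas: np.ndarray
    ss_per_dim: np.ndarray
    ss_total: float

    def to_dict(self) -> dict:
        return {
            "true_lambdas": self.true_lambdas.tolist(),
            "ss_per_dim": self.ss_per_dim.tolist(),
            "ss_total": self.ss_total,
        }


def simulate_trial(
    seed=None,
    g: int = 20,
    e: int = 9,
    r: int = 3,
    var_g: float = 12.0,
    var_e: float = 1.0,
    var_unstable: float = 16.0,
    var_stable: float = 1.0,
    sigma2_e: float = 2.5,
    n_unstable_pos: int = 5,
    n_unstable_neg: int = 5,
    n_env_pos: int = 4,
) -> tuple[TrialData, TrueEffects]:
    """Simulate one randomized-block trial with the planted GEI structure.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  The two
    unstable subgroups take half-normal interaction effects with opposite
    sign blocks split after environment ``n_env_pos``; the remaining
    genotypes form the stable subgroup.  Returns the plot-level records
    (labels G01.., E1.., B1..) and the generating effects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_unstable_pos + n_unstable_neg > g:
        raise ValueError("unstable subgroup sizes exceed the number of genotypes")

    g_true = rng.normal(0.0, np.sqrt(var_g), size=g)
    e_true = rng.normal(0.0, np.sqrt(var_e), size=e)

    ge = np.zeros((g, e))
    sign = np.where(np.arange(e) < n_env_pos, 1.0, -1.0)
    n1, n2 = n_unstable_pos, n_unstable_neg
    if var_unstable > 0:
        ge[:n1] = np.abs(rng.normal(0.0, np.sqrt(var_unstable), size=(n1, e))) * sign
        ge[n1:n1 + n2] = np.abs(rng.normal(0.0, np.sqrt(var_unstable), size=(n2, e))) * -sign
    if var_stable > 0 and g > n1 + n2:
        ge[n1 + n2:] = rng.normal(0.0, np.sqrt(var_stable), size=(g - n1 - n2, e))
    ge = double_center(ge)

    stable = np.ones(g, dtype=bool)
    stable[:n1 + n2] = False

    gl = [f"G{i + 1:02d}" for i in range(g)]
    el = [f"E{j + 1}" for j in range(e)]
    rows = []
    for j in range(e):
        for rep in range(r):
            for i in range(g):
                mean = g_true[i] + e_true[j] + ge[i, j]  # block effects are zero
                rows.append((gl[i], el[j], f"B{rep + 1}", mean))
    frame = pd.DataFrame(rows, columns=["genotype", "environment", "block", "response"])
    frame["response"] += rng.normal(0.0, np.sqrt(sigma2_e), size=len(frame))

    data = TrialData.from_frame(frame)
    effects = TrueEffects(
        g_true=g_true,
        e_true=e_true,
        ge_true=CenteredGEMatrix(values=ge),
        sigma2_e_true=sigma2_e,
        stable=stable,
    )
    return data, effects


def planted_rank_trial(
    seed=None,
    lambdas=(13.0, 8.0),
    g: int = 20,
    e: int = 9,
    r: int = 3,
    var_g: float = 12.0,
    var_e: float = 1.0,
    sigma2_e: float = 2.5,
) -> tuple[TrialData, TrueEffects]:
    """Trial whose interaction has an exact known rank.

    The interaction is built as ``sum_k lambda_k u_k v_k'`` from random
    centered orthonormal singular vectors, so the planted singular values
    are recovered exactly by :func:`svd_truth`.  Everything else follows
    the default trial layout.  Used for parameter- and rank-recovery
    checks where the truth must be exactly low-rank.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    t = len(lambdas)
    if t > min(g, e) - 1:
        raise ValueError("more planted axes than min(g, e) - 1")

    def centered_orthonormal(d, k):
        M = rng.standard_normal((d, k))
        M -= M.mean(axis=0, keepdims=True)
        Q, _ = np.linalg.qr(M)
        return Q[:, :k]

    U = centered_orthonormal(g, t)
    V = centered_orthonormal(e, t)
    ge = (U * lambdas) @ V.T

    g_true = rng.normal(0.0, np.sqrt(var_g), size=g)
    e_true = rng.normal(0.0, np.sqrt(var_e), size=e)
    row_ss = (ge**2).sum(axis=1)
    stable = row_ss < row_ss.mean()  # descriptive only: low-interaction rows

    gl = [f"G{i + 1:02d}" for i in range(g)]
    el = [f"E{j + 1}" for j in range(e)]
    rows = []
    for j in range(e):
        for rep in range(r):
            for i in range(g):
                rows.append((gl[i], el[j], f"B{rep + 1}", g_true[i] + e_true[j] + ge[i, j]))
    frame = pd.DataFrame(rows, columns=["genotype", "environment", "block", "response"])
    frame["response"] += rng.normal(0.0, np.sqrt(sigma2_e), size=len(frame))
    data = TrialData.from_frame(frame)
    effects = TrueEffects(
        g_true=g_true, e_true=e_true, ge_true=CenteredGEMatrix(values=ge),
        sigma2_e_true=sigma2_e, stable=stable,
    )
    return data, effects


def svd_truth(effects: TrueEffects) -> TruthSummary:
    """Singular values of the planted interaction and cumulative sums of squares.

    The sum-of-squares convention is cell-level: SS through dimension k is
    ``sum_{j<=k} lambda_j^2`` of the g x e interaction matrix (no replicate
    factor), matching the convention used for posterior SS(GEI) summaries.
    """
    svals = np.linalg.svd(effects.ge_true.values, compute_uv=False)
    svals = np.sort(svals)[::-1]
    ss = np.cumsum(svals**2)
    return TruthSummary(true_lambdas=svals, ss_per_dim=ss, ss_total=float(ss[-1]) if len(ss) else 0.0)
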