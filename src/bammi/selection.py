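"""Fixed-dimension model comparison: AIC, BIC and AICM.

AIC and BIC plug the posterior means of all parameters into the deviance
and count parameters with Gollob's per-axis degrees of freedom
(g + e - 1 - 2k for axis k).  AICM works directly on the posterior
log-likelihood draws, penalizing their mean by their variance, so it
needs no plug-in point estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DesignMatrices, ModelState, TrialData
from .gibbs import PosteriorDraws, log_likelihood
from .summaries import align_signs, orthonormalize_uv


def gollob_param_count(g: int, e: int, n_cells: int, t: int) -> int:
    """Block cells + genotypes + two variances + Gollob df per bilinear axis."""
    return n_cells + g + 2 + sum(g + e - 1 - 2 * k for k in range(1, t + 1))


def posterior_mean_state(draws: PosteriorDraws, t: int) -> ModelState:
    """Plug-in state at posterior means (axes sign-aligned then re-orthonormalized)."""
    if t:
        aligned = align_signs(draws, t)
        mean_alphas = np.mean([M[:, :t] for M in aligned.alphas], axis=0)
        mean_gammas = np.mean([M[:, :t] for M in aligned.gammas], axis=0)
        alphas, gammas = orthonormalize_uv(mean_alphas, mean_gammas)
        lambdas = np.mean([lam[:t] for lam in draws.lambdas], axis=0)
    else:
        g = draws.gvec.shape[1]
        alphas = np.empty((g, 0))
        gammas = np.empty((0, 0))
        lambdas = np.empty(0)
    return ModelState(
        beta=draws.beta.mean(axis=0),
        gvec=draws.gvec.mean(axis=0),
        lambdas=lambdas,
        alphas=alphas,
        gammas=gammas if t else np.empty((0, 0)),
        sigma2_lambda=np.ones(t),
        sigma2_g=float(draws.sigma2_g.mean()),
        sigma2_e=float(draws.sigma2_e.mean()),
        mu=float(draws.mu.mean()),
    )


def aic_bic(draws: PosteriorDraws, data: TrialData, designs: DesignMatrices, t: int) -> tuple[float, float]:
    """Deviance at posterior means with Gollob parameter counts."""
    state = posterior_mean_state(draws, t)
    dev = -2.0 * log_likelihood(state, data, designs)
    p = gollob_param_count(designs.g, designs.e, designs.n_cells, t)
    return dev + 2.0 * p, dev + p * np.log(designs.n)


def aicm(loglik_draws) -> float:
    """AICM = -2 * (mean - variance) of the posterior log-likelihood draws."""
    ll = np.asarray(loglik_draws, dtype=float)
    if len(ll) < 2:
        raise ValueError("need at least 2 log-likelihood draws")
    return float(-2.0 * (ll.mean() - ll.var(ddof=1)))


def ockham_table(fits: dict[int, PosteriorDraws], data: TrialData, designs: DesignMatrices,
                 hypothesis: str = "") -> pd.DataFrame:
    """One row per fitted dimension: criteria, mean log-likelihood, residual
    variance, posterior-mean singular values and cumulative SS(GEI)."""
    expected = set(range(max(fits, default=0) + 1))
    if set(fits) != expected:
        import warnings

        warnings.warn(f"criteria table is partial: missing dimensions {sorted(expected - set(fits))}")
    rows = []
    for t in sorted(fits):
        draws = fits[t]
        a, b = aic_bic(draws, data, designs, t)
        lam = np.mean([l[:t] for l in draws.lambdas], axis=0) if t else np.empty(0)
        row = {
            "hypothesis": hypothesis,
            "t": t,
            "aic": a,
            "bic": b,
            "aicm": aicm(draws.loglik),
            "mean_loglik": float(draws.loglik.mean()),
            "mean_sigma2_e": float(draws.sigma2_e.mean()),
            "ss_gei": float(np.sum(lam**2)),
        }
        for k, val in enumerate(lam):
            row[f"lambda_{k + 1}"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)
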