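"""Transdimensional sampling of the number of bilinear axes.

The dimension t moves by nested birth/death steps: a birth appends axis
t+1 with parameters proposed from their full conditionals given the
current residuals (so the dimension-matching Jacobian is one), and a
death removes the last (smallest) axis.  Each sweep first refreshes the
within-model parameters by one Gibbs pass, then attempts exactly one
move chosen with probabilities (pa add, pd delete, p0 stay).

The acceptance ratio for a birth is

    a(t, t+1) = [L(y | t+1) / L(y | t)] * [mu / (t+1)] * [pd / pa]

and the death ratio is its mirror image, so the pair satisfies detailed
balance with respect to the truncated-Poisson prior on t: with the
likelihood ratio forced to one, the chain's stationary distribution of t
is exactly the prior (marginalized over the Gamma hyperprior on mu) —
the canonical correctness check for a reversible-jump sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DesignMatrices, ModelState, TrialData
from .gibbs import (
    GibbsConfig,
    PosteriorDraws,
    _DrawBuffer,
    _gibbs_sweep_inplace,
    _interaction_excluding,
    initial_state,
    log_likelihood,
)
from .priors import PriorSpec
from .samplers import ConstraintBasis, draw_truncated_normal, draw_vmf_in_subspace


@dataclass
class MoveOutcome:
    move: str          # "add", "delete" or "stay"
    accepted: bool
    log_ratio: float
    t_before: int
    t_after: int


@dataclass
class AxisCandidate:
    lam: float
    sigma2_lambda: float
    alpha: np.ndarray
    gamma: np.ndarray


def _augment(state: ModelState, cand: AxisCandidate) -> ModelState:
    out = state.copy()
    out.lambdas = np.append(out.lambdas, cand.lam)
    out.alphas = np.column_stack([out.alphas, cand.alpha]) if out.t else cand.alpha[:, None]
    out.gammas = np.column_stack([out.gammas, cand.gamma]) if out.t else cand.gamma[:, None]
    out.sigma2_lambda = np.append(out.sigma2_lambda, cand.sigma2_lambda)
    return out


def _drop_last(state: ModelState) -> ModelState:
    out = state.copy()
    out.lambdas = out.lambdas[:-1]
    out.alphas = out.alphas[:, :-1]
    out.gammas = out.gammas[:, :-1]
    out.sigma2_lambda = out.sigma2_lambda[:-1]
    return out


def propose_add(state: ModelState, data: TrialData, designs: DesignMatrices,
                prior: PriorSpec, rng) -> AxisCandidate | None:
    """Propose axis t+1 from its conditionals given the current residuals.

    The singular vectors are drawn uniformly on the sphere of the correct
    subspace (their conditional at lambda = 0); the singular value comes
    from its data conditional under a flat scale, truncated to
    (0, lambda_t); the scale parameter then follows from the prior family.
    Returns None when t already equals t_max.
    """
    t_max = prior.t_max if prior.t_max is not None else data.t_max
    t = state.t
    if t >= t_max:
        return None
    g, e = designs.g, designs.e
    alpha = draw_vmf_in_subspace(
        np.zeros(g), 0.0, ConstraintBasis.centering(g, state.alphas if t else None), rng
    )
    gamma = draw_vmf_in_subspace(
        np.zeros(e), 0.0, ConstraintBasis.centering(e, state.gammas if t else None), rng
    )
    resid = data.y - state.beta[designs.cell_idx] - state.gvec[designs.geno_idx] - _interaction_excluding(state, designs, None)
    phi = alpha[designs.geno_idx] * gamma[designs.env_idx]
    prec = phi @ phi + state.sigma2_e / prior.bammi_sigma2_lambda
    mean = (phi @ resid) / prec
    sd = np.sqrt(state.sigma2_e / prec)
    upper = state.lambdas[-1] if t else np.inf
    if upper <= 0:
        upper = 1e-10
    lam = draw_truncated_normal(mean, sd, 0.0, upper, rng)
    from .priors import update_sigma2_lambda

    s2l = update_sigma2_lambda(prior, lam, rng)
    return AxisCandidate(lam=lam, sigma2_lambda=s2l, alpha=alpha, gamma=gamma)


def log_accept_add(state: ModelState, candidate: AxisCandidate, data: TrialData,
                   designs: DesignMatrices, prior: PriorSpec) -> float:
    """Log birth acceptance ratio for appending ``candidate`` as axis t+1."""
    t = state.t
    ll_now = log_likelihood(state, data, designs)
    ll_new = log_likelihood(_augment(state, candidate), data, designs)
    return (ll_new - ll_now) + np.log(state.mu / (t + 1)) + np.log(prior.pd / prior.pa)


def log_accept_delete(state: ModelState, data: TrialData,
                      designs: DesignMatrices, prior: PriorSpec) -> float:
    """Log death acceptance ratio for removing the last (smallest) axis."""
    t = state.t
    if t < 1:
        raise ValueError("no axis to delete")
    ll_now = log_likelihood(state, data, designs)
    ll_red = log_likelihood(_drop_last(state), data, designs)
    return (ll_red - ll_now) + np.log(t / state.mu) + np.log(prior.pa / prior.pd)


def rj_sweep(state: ModelState, data: TrialData, designs: DesignMatrices,
             prior: PriorSpec, rng) -> tuple[ModelState, list[MoveOutcome]]:
    """One Gibbs sweep of within-model parameters plus one dimension move."""
    _gibbs_sweep_inplace(state, data.y, designs, prior, rng)
    t_max = prior.t_max if prior.t_max is not None else data.t_max
    u_move = rng.uniform()
    t = state.t
    if u_move < prior.pa:
        cand = propose_add(state, data, designs, prior, rng)
        if cand is None:
            outcome = MoveOutcome("stay", False, -np.inf, t, t)
        else:
            lr = log_accept_add(state, cand, data, designs, prior)
            if np.log(rng.uniform()) < lr:
                state = _augment(state, cand)
                outcome = MoveOutcome("add", True, lr, t, t + 1)
            else:
                outcome = MoveOutcome("add", False, lr, t, t)
    elif u_move < prior.pa + prior.pd:
        if t == 0:
            outcome = MoveOutcome("stay", False, -np.inf, t, t)
        else:
            lr = log_accept_delete(state, data, designs, prior)
            if np.log(rng.uniform()) < lr:
                state = _drop_last(state)
                outcome = MoveOutcome("delete", True, lr, t, t - 1)
            else:
                outcome = MoveOutcome("delete", False, lr, t, t)
    else:
        outcome = MoveOutcome("stay", True, 0.0, t, t)
    return state, [outcome]


def run_rjmcmc(data: TrialData, designs: DesignMatrices, prior: PriorSpec,
               config: GibbsConfig) -> PosteriorDraws:
    """Run the reversible-jump sampler; draws carry a per-iteration dimension."""
    rng = np.random.default_rng(config.seed)
    t0 = min(config.t_fixed, data.t_max)
    state = initial_state(data, designs, t0, prior)
    buf = _DrawBuffer()
    burn, thin = config.burn_in, config.thin
    for it in range(config.iterations):
        state, _ = rj_sweep(state, data, designs, prior, rng)
        if not np.isfinite(state.sigma2_e):
            raise FloatingPointError(f"non-finite state at iteration {it}")
        if config.check_fraction and rng.uniform() < config.check_fraction:
            state.check()
        if it >= burn and (it - burn) % thin == 0:
            buf.append(state, log_likelihood(state, data, designs))
    return buf.finalize()


def prior_dimension_chain(prior: PriorSpec, t_max: int, sweeps: int, rng) -> np.ndarray:
    """Dimension chain with the likelihood switched off (flat-likelihood mode).

    Runs only the t and mu updates; the stationary distribution of t must
    reproduce the truncated-Poisson prior marginalized over its Gamma
    hyperprior.  Used as the prior-recovery correctness check.
    """
    t = 0
    mu = 1.0
    out = np.empty(sweeps, dtype=int)
    log = np.log
    for i in range(sweeps):
        mu = max(rng.gamma(prior.tau + t, 1.0 / (prior.upsilon + 1.0)), 1e-8)
        u_move = rng.uniform()
        if u_move < prior.pa:
            if t < t_max and log(rng.uniform()) < log(mu / (t + 1)) + log(prior.pd / prior.pa):
                t += 1
        elif u_move < prior.pa + prior.pd:
            if t >= 1 and log(rng.uniform()) < log(t / mu) + log(prior.pa / prior.pd):
                t -= 1
        out[i] = t
    return out


def visit_table(draws) -> tuple[dict, int]:
    """Visit counts per dimension and the modal dimension (ties toward smaller t)."""
    ts = draws.t if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if len(ts) == 0:
        raise ValueError("no draws")
    values, counts = np.unique(ts, return_counts=True)
    table = {int(v): int(c) for v, c in zip(values, counts)}
    modal = int(values[np.argmax(counts)])  # np.argmax takes the first max: smaller t wins ties
    return table, modal
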