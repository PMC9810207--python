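"""Fixed-dimension Gibbs sampler for the Bayesian AMMI model.

All full conditionals are conjugate given the incidence structure:

* block and genotype effects are Gaussian (the genotype update carries a
  ridge ``sigma2_e / sigma2_g`` from the hierarchical prior);
* each singular value ``lambda_k`` is a positive truncated normal, with
  upper truncation at ``lambda_{k-1}`` so the descending order constraint
  is maintained (``lambda_0 = +inf``);
* each singular vector is von Mises-Fisher on the subspace orthogonal to
  the ones vector and to the other vectors of its side;
* variance components are scaled-inverse-chi-square;
* the Poisson mean ``mu`` of the dimension prior is Gamma.

Because X1'X1, Z'Z and X2'X2 are diagonal for incidence matrices, every
update is computed with index-array reductions rather than dense solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DesignMatrices, ModelState, TrialData, double_center, theta_vector
from .priors import PriorSpec, update_sigma2_lambda
from .samplers import ConstraintBasis, draw_truncated_normal, draw_vmf_in_subspace


@dataclass
class GibbsConfig:
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 1
    seed: int | None = None
    t_fixed: int = 2
    pilot: bool = False
    check_fraction: float = 0.01

    def __post_init__(self):
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Stored MCMC samples; axis parameters are ragged across the dimension t."""

    beta: np.ndarray          # (m, n_cells)
    gvec: np.ndarray          # (m, g)
    sigma2_g: np.ndarray      # (m,)
    sigma2_e: np.ndarray      # (m,)
    mu: np.ndarray            # (m,)
    loglik: np.ndarray        # (m,)
    t: np.ndarray             # (m,) int
    lambdas: list = field(default_factory=list)   # each (t_i,)
    alphas: list = field(default_factory=list)    # each (g, t_i)
    gammas: list = field(default_factory=list)    # each (e, t_i)

    @property
    def n_draws(self) -> int:
        return len(self.t)

    def select(self, mask: np.ndarray, max_axes: int | None = None) -> "PosteriorDraws":
        """Subset iterations; optionally keep only the first ``max_axes`` axes."""
        idx = np.flatnonzero(mask)
        cut = slice(None) if max_axes is None else slice(None, max_axes)
        return PosteriorDraws(
            beta=self.beta[idx],
            gvec=self.gvec[idx],
            sigma2_g=self.sigma2_g[idx],
            sigma2_e=self.sigma2_e[idx],
            mu=self.mu[idx],
            loglik=self.loglik[idx],
            t=self.t[idx] if max_axes is None else np.minimum(self.t[idx], max_axes),
            lambdas=[self.lambdas[i][cut] for i in idx],
            alphas=[self.alphas[i][:, cut] for i in idx],
            gammas=[self.gammas[i][:, cut] for i in idx],
        )

    def lambda_matrix(self) -> np.ndarray:
        """(m, t) matrix of singular values; only valid when t is constant."""
        ts = np.unique(self.t)
        if len(ts) > 1:
            raise ValueError("draws span several dimensions; split them first")
        return np.vstack([lam for lam in self.lambdas]) if ts[0] else np.empty((self.n_draws, 0))

    def scalar_frame(self):
        """Scalar traces (plus padded singular values) as a DataFrame."""
        import pandas as pd

        t_max = int(self.t.max(initial=0))
        out = {
            "iteration": np.arange(self.n_draws),
            "t": self.t,
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "mu": self.mu,
            "loglik": self.loglik,
        }
        for k in range(t_max):
            out[f"lambda_{k + 1}"] = np.array(
                [lam[k] if len(lam) > k else np.nan for lam in self.lambdas]
            )
        return pd.DataFrame(out)


def log_likelihood(state: ModelState, data: TrialData, designs: DesignMatrices) -> float:
    """Gaussian log likelihood of the record vector at the current state."""
    if state.sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    resid = data.y - theta_vector(state, designs)
    n = designs.n
    return float(-0.5 * n * np.log(2.0 * np.pi * state.sigma2_e) - 0.5 * (resid @ resid) / state.sigma2_e)


def _interaction_excluding(state: ModelState, designs: DesignMatrices, k: int | None) -> np.ndarray:
    """Record-level bilinear contribution, optionally excluding axis k (0-based)."""
    if state.t == 0:
        return np.zeros(designs.n)
    prod = state.alphas[designs.geno_idx, :] * state.gammas[designs.env_idx, :]
    lam = state.lambdas.copy()
    if k is not None:
        lam[k] = 0.0
    return prod @ lam


def sample_block_conditional(state: ModelState, data: TrialData, designs: DesignMatrices, rng) -> ModelState:
    """Draw beta | g, rest: N((X1'X1)^-1 X1'A1, (X1'X1)^-1 sigma2_e); diagonal system."""
    out = state.copy()
    inter = _interaction_excluding(out, designs, None)
    a1 = data.y - out.gvec[designs.geno_idx] - inter
    mean_b = np.bincount(designs.cell_idx, weights=a1, minlength=designs.n_cells) / designs.count_cell
    out.beta = mean_b + rng.standard_normal(designs.n_cells) * np.sqrt(out.sigma2_e / designs.count_cell)
    return out


def sample_genotype_conditional(state: ModelState, data: TrialData, designs: DesignMatrices, rng) -> ModelState:
    """Draw g | beta, rest: ridge conditional N((Z'Z + I sigma2_e/sigma2_g)^-1 Z'A2, ...)."""
    out = state.copy()
    inter = _interaction_excluding(out, designs, None)
    a2 = data.y - out.beta[designs.cell_idx] - inter
    prec = designs.count_geno + out.sigma2_e / out.sigma2_g
    mean_g = np.bincount(designs.geno_idx, weights=a2, minlength=designs.g) / prec
    out.gvec = mean_g + rng.standard_normal(designs.g) * np.sqrt(out.sigma2_e / prec)
    return out


def _sample_linear_inplace(state, y, designs, rng):
    """Exact joint draw of (beta, g) from their joint Gaussian conditional.

    Block and genotype effects share an unidentified level (a constant can
    move between them), pinned only by the genotype prior; updating them
    one at a time random-walks that direction very slowly.  The joint draw
    from the (n_cells + g)-dimensional Gaussian removes the problem and
    leaves the stationary distribution unchanged.
    """
    from scipy.linalg import cho_factor, cho_solve, solve_triangular

    inter = _interaction_excluding(state, designs, None)
    ystar = y - inter
    nc, g = designs.n_cells, designs.g
    A = np.zeros((nc + g, nc + g))
    A[:nc, :nc] = np.diag(designs.count_cell)
    A[:nc, nc:] = designs.cross_cell_geno
    A[nc:, :nc] = designs.cross_cell_geno.T
    A[nc:, nc:] = np.diag(designs.count_geno + state.sigma2_e / state.sigma2_g)
    rhs = np.concatenate([
        np.bincount(designs.cell_idx, weights=ystar, minlength=nc),
        np.bincount(designs.geno_idx, weights=ystar, minlength=g),
    ])
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError as err:
        raise FloatingPointError(f"singular linear-effects system: {err}") from err
    mean = cho_solve((c, low), rhs)
    # draw = mean + sigma_e * R^{-1} z  with A = R'R (upper Cholesky)
    z = rng.standard_normal(nc + g)
    R = np.triu(c) if not low else np.tril(c).T
    draw = mean + np.sqrt(state.sigma2_e) * solve_triangular(R, z, lower=False)
    state.beta = draw[:nc]
    state.gvec = draw[nc:]


def sample_linear_effects(state: ModelState, data: TrialData, designs: DesignMatrices, rng) -> ModelState:
    """Draw the linear effects (beta, g) from their exact joint conditional."""
    out = state.copy()
    _sample_linear_inplace(out, data.y, designs, rng)
    return out


def _axis_basis(vectors: np.ndarray, k: int) -> ConstraintBasis:
    """Ones vector plus every singular vector of the same side except axis k."""
    others = np.delete(vectors, k, axis=1)
    return ConstraintBasis.centering(vectors.shape[0], others)


def _sample_axis_inplace(state, y, designs, prior, k, rng):
    a4 = y - state.beta[designs.cell_idx] - state.gvec[designs.geno_idx] - _interaction_excluding(state, designs, k)
    phi = state.alphas[designs.geno_idx, k] * state.gammas[designs.env_idx, k]
    prec = phi @ phi + state.sigma2_e / state.sigma2_lambda[k]
    mean = (phi @ a4) / prec
    sd = np.sqrt(state.sigma2_e / prec)
    upper = np.inf if k == 0 else state.lambdas[k - 1]
    if upper <= 0:
        upper = 1e-10  # degenerate interval: previous axis collapsed to zero
    state.lambdas[k] = draw_truncated_normal(mean, sd, 0.0, upper, rng)
    state.sigma2_lambda[k] = update_sigma2_lambda(prior, state.lambdas[k], rng)
    kappa_scale = state.lambdas[k] / state.sigma2_e
    c_alpha = np.bincount(designs.geno_idx, weights=state.gammas[designs.env_idx, k] * a4, minlength=designs.g)
    state.alphas[:, k] = draw_vmf_in_subspace(c_alpha, kappa_scale, _axis_basis(state.alphas, k), rng)
    c_gamma = np.bincount(designs.env_idx, weights=state.alphas[designs.geno_idx, k] * a4, minlength=designs.e)
    state.gammas[:, k] = draw_vmf_in_subspace(c_gamma, kappa_scale, _axis_basis(state.gammas, k), rng)


def sample_bilinear_axis(state: ModelState, data: TrialData, designs: DesignMatrices,
                         prior: PriorSpec, k: int, rng) -> ModelState:
    """Draw (lambda_k, sigma2_lambda_k, alpha_k, gamma_k); k is 1-based as in the model."""
    if not 1 <= k <= state.t:
        raise ValueError(f"axis index {k} outside 1..{state.t}")
    out = state.copy()
    _sample_axis_inplace(out, data.y, designs, prior, k - 1, rng)
    return out


def _sample_variances_inplace(state, y, designs, rng):
    rate_g = max(state.gvec @ state.gvec / 2.0, 1e-300)
    state.sigma2_g = float(np.clip(rate_g / rng.gamma(designs.g / 2.0), 1e-12, 1e12))
    resid = y - state.beta[designs.cell_idx] - state.gvec[designs.geno_idx] - _interaction_excluding(state, designs, None)
    rate_e = max(resid @ resid / 2.0, 1e-300)
    state.sigma2_e = float(np.clip(rate_e / rng.gamma(designs.n / 2.0), 1e-12, 1e12))


def sample_variances(state: ModelState, data: TrialData, designs: DesignMatrices, rng) -> ModelState:
    """Draw sigma2_g ~ InvGamma(g/2, g'g/2) and sigma2_e ~ InvGamma(n/2, RSS/2)."""
    out = state.copy()
    _sample_variances_inplace(out, data.y, designs, rng)
    return out


def sample_mu(state: ModelState, prior: PriorSpec, rng) -> ModelState:
    """Conjugate Gamma update of the Poisson-dimension mean (truncation ignored)."""
    out = state.copy()
    out.mu = float(rng.gamma(prior.tau + state.t, 1.0 / (prior.upsilon + 1.0)))
    out.mu = max(out.mu, 1e-8)
    return out


def _gibbs_sweep_inplace(state, y, designs, prior, rng):
    _sample_linear_inplace(state, y, designs, rng)
    for k in range(state.t):
        _sample_axis_inplace(state, y, designs, prior, k, rng)
    _sample_variances_inplace(state, y, designs, rng)
    state.mu = max(float(rng.gamma(prior.tau + state.t, 1.0 / (prior.upsilon + 1.0))), 1e-8)


def initial_state(data: TrialData, designs: DesignMatrices, t: int, prior: PriorSpec) -> ModelState:
    """Least-squares additive fit plus an SVD of the residual interaction."""
    y = data.y
    beta0 = np.bincount(designs.cell_idx, weights=y, minlength=designs.n_cells) / designs.count_cell
    r1 = y - beta0[designs.cell_idx]
    g0 = np.bincount(designs.geno_idx, weights=r1, minlength=designs.g) / designs.count_geno
    resid = r1 - g0[designs.geno_idx]
    # residual cell-mean matrix, double-centered, seeds the bilinear axes
    sums = np.zeros((designs.g, designs.e))
    counts = np.zeros((designs.g, designs.e))
    np.add.at(sums, (designs.geno_idx, designs.env_idx), resid)
    np.add.at(counts, (designs.geno_idx, designs.env_idx), 1.0)
    cellmeans = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    ge = double_center(cellmeans)
    U, s, Vt = np.linalg.svd(ge)
    lambdas = s[:t].copy()
    lambdas[lambdas < 1e-6] = 1e-6
    lambdas = np.sort(lambdas)[::-1]
    alphas = U[:, :t].copy()
    gammas = Vt[:t].T.copy()
    if prior.hypothesis == "bammi":
        s2l = np.full(t, prior.bammi_sigma2_lambda)
    else:
        s2l = lambdas**2 + 1.0
    sigma2_e = max(float(np.var(resid)), 1e-6)
    sigma2_g = max(float(np.var(g0)), 1e-6)
    return ModelState(
        beta=beta0, gvec=g0, lambdas=lambdas, alphas=alphas, gammas=gammas,
        sigma2_lambda=s2l, sigma2_g=sigma2_g, sigma2_e=sigma2_e, mu=1.0,
    )


class _DrawBuffer:
    def __init__(self):
        self.rows = {k: [] for k in ("sigma2_g", "sigma2_e", "mu", "loglik", "t")}
        self.beta, self.gvec = [], []
        self.lambdas, self.alphas, self.gammas = [], [], []

    def append(self, state, ll):
        self.beta.append(state.beta.copy())
        self.gvec.append(state.gvec.copy())
        self.rows["sigma2_g"].append(state.sigma2_g)
        self.rows["sigma2_e"].append(state.sigma2_e)
        self.rows["mu"].append(state.mu)
        self.rows["loglik"].append(ll)
        self.rows["t"].append(state.t)
        self.lambdas.append(state.lambdas.copy())
        self.alphas.append(state.alphas.copy())
        self.gammas.append(state.gammas.copy())

    def finalize(self) -> PosteriorDraws:
        return PosteriorDraws(
            beta=np.array(self.beta),
            gvec=np.array(self.gvec),
            sigma2_g=np.array(self.rows["sigma2_g"]),
            sigma2_e=np.array(self.rows["sigma2_e"]),
            mu=np.array(self.rows["mu"]),
            loglik=np.array(self.rows["loglik"]),
            t=np.array(self.rows["t"], dtype=int),
            lambdas=self.lambdas,
            alphas=self.alphas,
            gammas=self.gammas,
        )


def _pilot_schedule(data, designs, prior, config, rng):
    """Short pilot run feeding Raftery-Lewis to propose burn-in and thinning."""
    from .diagnostics import raftery_lewis

    pilot_cfg = GibbsConfig(iterations=500, burn_in=0, thin=1, t_fixed=config.t_fixed)
    state = initial_state(data, designs, config.t_fixed, prior)
    buf = _DrawBuffer()
    for _ in range(pilot_cfg.iterations):
        _gibbs_sweep_inplace(state, data.y, designs, prior, rng)
        buf.append(state, log_likelihood(state, data, designs))
    draws = buf.finalize()
    burn, thin = config.burn_in, config.thin
    for trace in (draws.loglik, draws.sigma2_e, draws.sigma2_g):
        try:
            M, N, k, I = raftery_lewis(trace)
        except ValueError:
            continue
        burn = max(burn, M)
        thin = max(thin, k)
    return burn, thin


def run_gibbs(data: TrialData, designs: DesignMatrices, prior: PriorSpec, config: GibbsConfig) -> PosteriorDraws:
    """Run the fixed-dimension Gibbs sampler and return thinned post-burn-in draws."""
    t = config.t_fixed
    if t > data.t_max:
        raise ValueError(f"t_fixed={t} exceeds t_max={data.t_max}")
    rng = np.random.default_rng(config.seed)
    burn, thin = config.burn_in, config.thin
    if config.pilot:
        burn, thin = _pilot_schedule(data, designs, prior, config, rng)
        burn = min(burn, config.iterations // 2)
        thin = min(thin, max(1, (config.iterations - burn) // 200))
    state = initial_state(data, designs, t, prior)
    buf = _DrawBuffer()
    for it in range(config.iterations):
        _gibbs_sweep_inplace(state, data.y, designs, prior, rng)
        if not np.isfinite(state.sigma2_e):
            raise FloatingPointError(f"non-finite state at iteration {it}")
        if config.check_fraction and rng.uniform() < config.check_fraction:
            state.check()
        if it >= burn and (it - burn) % thin == 0:
            buf.append(state, log_likelihood(state, data, designs))
    return buf.finalize()
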