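"""MCMC chain diagnostics: Raftery-Lewis run-length control and the
Heidelberger-Welch stationarity/halfwidth tests.

Raftery-Lewis dichotomizes the chain at a target quantile, fits the
two-state Markov chain of the thinned indicator sequence, and converts
its mixing rate into a required burn-in M, run length N, thinning k and
dependence factor I = (M + N) / N_min, where N_min is the i.i.d. run
length for the same precision.  I close to 1 indicates near-independent
sampling; values above ~5 flag strong autocorrelation or a bad start.

Heidelberger-Welch applies a Cramer-von Mises test to the Brownian
bridge of chain partial sums (spectral density at frequency zero
estimated by an AR fit), discarding initial 10% segments until the test
passes or half the chain is gone; the halfwidth test then compares the
asymptotic confidence halfwidth of the retained mean to a relative
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# asymptotic critical values of the Cramer-von Mises statistic
_CVM_CRITICAL = {0.1: 0.347, 0.05: 0.461, 0.025: 0.581, 0.01: 0.743}


@dataclass
class RafteryLewisResult:
    burn_in: int          # M
    total: int            # N
    thin: int             # k
    dependence: float     # I = (M + N) / N_min
    n_min: int


@dataclass
class HeidelbergerWelchResult:
    stationary: bool
    kept_fraction: float
    cvm_statistic: float
    halfwidth_passed: bool
    halfwidth_ratio: float
    mean: float


def _spectrum0_ar(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density of ``x`` at frequency zero via an AIC-selected AR fit."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    v0 = x @ x / n
    if v0 == 0:
        return 0.0
    max_order = max_order or int(min(n - 1, 10 * np.log10(n)))
    # Levinson-Durbin on the sample autocovariance, AIC order selection
    acov = np.array([x[: n - k] @ x[k:] / n for k in range(max_order + 1)])
    best = (n * np.log(v0), 0.0, v0)  # (aic, sum of AR coefficients, innovation var)
    phi_prev = np.zeros(0)
    sigma2 = acov[0]
    for p in range(1, max_order + 1):
        num = acov[p] - (phi_prev @ acov[1:p][::-1] if p > 1 else 0.0)
        k_p = num / sigma2
        phi = np.concatenate([phi_prev - k_p * phi_prev[::-1], [k_p]]) if p > 1 else np.array([k_p])
        sigma2 = sigma2 * (1.0 - k_p**2)
        if sigma2 <= 0:
            break
        aic = n * np.log(sigma2) + 2.0 * p
        if aic < best[0]:
            best = (aic, float(phi.sum()), sigma2)
        phi_prev = phi
    _, phi_sum, innov = best
    denom = (1.0 - phi_sum) ** 2
    if denom <= 1e-12:
        return float(acov[0])
    return float(innov / denom)


def raftery_lewis(chain, q: float = 0.025, r: float = 0.005, s: float = 0.95,
                  eps: float = 0.001) -> tuple[int, int, int, float]:
    """Raftery-Lewis run-length control; returns (M, N, k, I)."""
    chain = np.asarray(chain, dtype=float)
    phi = stats.norm.ppf((s + 1.0) / 2.0)
    n_min = int(np.ceil(q * (1.0 - q) * (phi / r) ** 2))
    if len(chain) < n_min:
        raise ValueError(f"chain too short: need at least {n_min} samples for (q={q}, r={r}, s={s})")
    dichot = (chain <= np.quantile(chain, q)).astype(int)

    kthin = 1
    while True:
        z = dichot[::kthin]
        # compare first-order vs second-order Markov fit by BIC (as in the original method)
        if len(z) < 4:
            break
        trans3 = np.zeros((2, 2, 2))
        for a, b, c in zip(z[:-2], z[1:-1], z[2:]):
            trans3[a, b, c] += 1
        with np.errstate(divide="ignore", invalid="ignore"):
            # G2 for conditional independence of z_t and z_{t-2} given z_{t-1}
            g2 = 0.0
            for b in range(2):
                tab = trans3[:, b, :]
                tot = tab.sum()
                if tot == 0:
                    continue
                exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tot
                nz = tab > 0
                g2 += 2.0 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz]))
        bic = g2 - 2.0 * np.log(len(z) - 2)
        if bic <= 0 or kthin > len(chain) // 50:
            break
        kthin += 1

    z = dichot[::kthin]
    trans = np.zeros((2, 2))
    for a, b in zip(z[:-1], z[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1)
    alpha = trans[0, 1] / row[0] if row[0] else 0.5  # P(0 -> 1)
    beta = trans[1, 0] / row[1] if row[1] else 0.5   # P(1 -> 0)
    alpha = min(max(alpha, 1e-6), 1 - 1e-6)
    beta = min(max(beta, 1e-6), 1 - 1e-6)
    ab = alpha + beta
    lam = abs(1.0 - ab)
    m_star = np.log(eps * ab / max(alpha, beta)) / np.log(lam) if lam > 0 else 1.0
    M = int(np.ceil(m_star)) * kthin
    n_star = ((2.0 - ab) * alpha * beta / ab**3) * (phi / r) ** 2
    N = int(np.ceil(n_star)) * kthin
    I = (M + N) / n_min
    return M, N, kthin, float(I)


def heidelberger_welch(chain, alpha: float = 0.05, eps: float = 0.1) -> HeidelbergerWelchResult:
    """Stationarity (Cramer-von Mises on the partial-sum bridge) and halfwidth tests."""
    chain = np.asarray(chain, dtype=float)
    if len(chain) < 100:
        raise ValueError("need a chain of length >= 100")
    crit = _CVM_CRITICAL.get(alpha)
    if crit is None:
        raise ValueError(f"alpha must be one of {sorted(_CVM_CRITICAL)}")

    n0 = len(chain)
    stat = np.inf
    kept = chain
    stationary = False
    for drop in range(0, 5):  # discard initial 10% increments up to 50%
        kept = chain[int(drop * 0.1 * n0):]
        n = len(kept)
        s0 = _spectrum0_ar(kept[: max(n // 2, 50)])
        if s0 <= 0:
            stat = 0.0
            stationary = True
            break
        csum = np.cumsum(kept)
        tgrid = np.arange(1, n + 1)
        bridge = (csum - tgrid * kept.mean()) / np.sqrt(n * s0)
        stat = float(np.sum(bridge**2) / n)
        if stat < crit:
            stationary = True
            break

    mean = float(kept.mean())
    s0 = _spectrum0_ar(kept)
    halfwidth = 1.96 * np.sqrt(s0 / len(kept))
    ratio = halfwidth / abs(mean) if mean != 0 else 0.0
    return HeidelbergerWelchResult(
        stationary=stationary,
        kept_fraction=len(kept) / n0,
        cvm_statistic=stat,
        halfwidth_passed=bool(ratio < eps),
        halfwidth_ratio=float(ratio),
        mean=mean,
    )


def monitored_traces(draws) -> dict[str, np.ndarray]:
    """Scalar traces monitored by default: variances, mu, log-likelihood,
    singular values (where the dimension allows) and the first genotype effect."""
    out = {
        "sigma2_g": draws.sigma2_g,
        "sigma2_e": draws.sigma2_e,
        "mu": draws.mu,
        "loglik": draws.loglik,
        "g_1": draws.gvec[:, 0],
    }
    t_common = int(draws.t.min()) if len(draws.t) else 0
    for k in range(t_common):
        out[f"lambda_{k + 1}"] = np.array([lam[k] for lam in draws.lambdas])
    return out


def diagnostic_report(draws, q: float = 0.025, r: float = 0.005, s: float = 0.95) -> pd.DataFrame:
    """Raftery-Lewis and Heidelberger-Welch results for every monitored trace."""
    rows = []
    for name, trace in monitored_traces(draws).items():
        row = {"parameter": name}
        try:
            M, N, k, I = raftery_lewis(trace, q=q, r=r, s=s)
            row.update({"rl_burn": M, "rl_total": N, "rl_thin": k, "rl_dependence": I})
        except ValueError as err:
            row.update({"rl_error": str(err)})
        try:
            hw = heidelberger_welch(trace)
            row.update({
                "hw_stationary": hw.stationary,
                "hw_kept_fraction": hw.kept_fraction,
                "hw_halfwidth_passed": hw.halfwidth_passed,
            })
        except ValueError as err:
            row.update({"hw_error": str(err)})
        rows.append(row)
    return pd.DataFrame(rows)
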