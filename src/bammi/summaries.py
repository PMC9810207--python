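"""Posterior summaries: conditional/marginal splits, sign alignment,
orthonormalized biplot scores, HPD intervals, bivariate credibility
regions and stability classification.

Singular vectors are only identified up to a joint sign flip of
(alpha_k, gamma_k); draws must be sign-aligned against a reference before
coordinate-wise averaging.  Biplot point estimates are the orthonormalized
means of the aligned genotypic (U) and environmental (V) score matrices;
per-entity credibility regions are normal-approximation ellipses built
from the posterior moments of the first two score coordinates, and an
entity is called *stable* when its region covers the origin (no credible
contribution to the interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gibbs import PosteriorDraws


@dataclass
class HPDInterval:
    lower: float
    upper: float
    prob: float = 0.95


@dataclass
class BiplotSummary:
    U: np.ndarray                  # (g, 2) orthonormalized genotypic scores
    V: np.ndarray                  # (e, 2) orthonormalized environmental scores
    ellipses: pd.DataFrame         # per entity: center, covariance, level
    origin_inclusion: pd.Series    # boolean per entity ("G:..."/"E:..." index)
    prob: float = 0.95


def split_draws(draws: PosteriorDraws, t_star: int) -> tuple[PosteriorDraws, PosteriorDraws]:
    """Conditional (t == t*) and marginal (t >= t*, first t* axes) draw sets."""
    cond_mask = draws.t == t_star
    if not cond_mask.any():
        raise ValueError(f"no iteration at dimension t={t_star}")
    marg_mask = draws.t >= t_star
    return draws.select(cond_mask), draws.select(marg_mask, max_axes=t_star)


def align_signs(draws: PosteriorDraws, t_star: int, reference: np.ndarray | None = None) -> PosteriorDraws:
    """Joint sign alignment of (alpha_k, gamma_k) pairs against a reference.

    The reference defaults to the first retained iteration's genotypic
    vectors.  Idempotent, and invariant to flipping all input signs.
    """
    if any(len(lam) < t_star for lam in draws.lambdas):
        raise ValueError("draws must carry at least t_star axes; use split_draws first")
    ref = draws.alphas[0][:, :t_star] if reference is None else reference[:, :t_star]
    alphas, gammas = [], []
    for A, G in zip(draws.alphas, draws.gammas):
        A, G = A.copy(), G.copy()
        flips = np.sign(np.einsum("ik,ik->k", A[:, :t_star], ref))
        flips[flips == 0] = 1.0
        A[:, :t_star] *= flips
        G[:, :t_star] *= flips
        alphas.append(A)
        gammas.append(G)
    out = draws.select(np.ones(draws.n_draws, dtype=bool))
    out.alphas = alphas
    out.gammas = gammas
    return out


def orthonormalize_uv(mean_alphas: np.ndarray, mean_gammas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """QR-orthonormalize the posterior-mean score matrices (positive diagonal)."""
    out = []
    for M in (mean_alphas, mean_gammas):
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("mean score matrix is rank deficient")
        Q, R = np.linalg.qr(M)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        out.append(Q * signs)
    return out[0], out[1]


def hpd(samples, prob: float = 0.95) -> HPDInterval:
    """Shortest interval containing ``prob`` posterior mass (Chen-Shao)."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 50:
        raise ValueError("need at least 50 samples for an HPD interval")
    if np.ptp(samples) == 0:
        return HPDInterval(float(samples[0]), float(samples[0]), prob)
    import arviz

    lo, hi = arviz.hdi(samples, hdi_prob=prob)
    return HPDInterval(float(lo), float(hi), prob)


def _score_samples(draws: PosteriorDraws, side: str) -> np.ndarray:
    mats = draws.alphas if side == "alpha" else draws.gammas
    return np.stack([M[:, :2] for M in mats])  # (m, entities, 2)


def biplot_regions(draws: PosteriorDraws, t_star: int, prob: float = 0.95,
                   genotype_labels=None, environment_labels=None) -> BiplotSummary:
    """Bivariate credibility ellipses for the first two interaction axes.

    Each entity's per-iteration score pair yields a sample mean and 2x2
    covariance; the region is the normal-approximation ellipse at the
    chi-square(2) quantile of ``prob``, and the origin is inside it iff
    its squared Mahalanobis distance is below that quantile.
    """
    if t_star < 2:
        raise ValueError("biplot regions need t_star >= 2; use univariate HPD intervals instead")
    aligned = align_signs(draws, t_star)
    g = aligned.alphas[0].shape[0]
    e = aligned.gammas[0].shape[0]
    glabels = list(genotype_labels) if genotype_labels is not None else [f"G{i + 1:02d}" for i in range(g)]
    elabels = list(environment_labels) if environment_labels is not None else [f"E{j + 1}" for j in range(e)]
    q = stats.chi2.ppf(prob, df=2)
    rows, inclusion = [], {}
    for side, labels, prefix in (("alpha", glabels, "G"), ("gamma", elabels, "E")):
        S = _score_samples(aligned, side)
        for idx, lab in enumerate(labels):
            pts = S[:, idx, :]
            center = pts.mean(axis=0)
            cov = np.cov(pts.T)
            cov = cov + 1e-12 * np.eye(2)  # guard against degenerate spread
            d2 = float(center @ np.linalg.solve(cov, center))
            key = f"{prefix}:{lab}"
            inclusion[key] = d2 <= q
            rows.append({
                "entity": key, "kind": "genotype" if prefix == "G" else "environment",
                "c1": center[0], "c2": center[1],
                "v11": cov[0, 0], "v12": cov[0, 1], "v22": cov[1, 1],
                "mahalanobis2": d2, "prob": prob,
            })
    mean_alphas = np.mean([M[:, :2] for M in aligned.alphas], axis=0)
    mean_gammas = np.mean([M[:, :2] for M in aligned.gammas], axis=0)
    try:
        U, V = orthonormalize_uv(mean_alphas, mean_gammas)
    except ValueError:
        # degenerate score matrices (fewer entities than axes): keep raw means
        U, V = mean_alphas, mean_gammas
    return BiplotSummary(
        U=U, V=V,
        ellipses=pd.DataFrame(rows).set_index("entity"),
        origin_inclusion=pd.Series(inclusion),
        prob=prob,
    )


def classify_stability(summary: BiplotSummary) -> pd.DataFrame:
    """Stable iff the credibility region covers the origin."""
    df = summary.ellipses[["kind", "mahalanobis2"]].copy()
    df["stable"] = summary.origin_inclusion
    return df


def genotype_effect_table(draws: PosteriorDraws, labels=None, prob: float = 0.95) -> pd.DataFrame:
    """Posterior mean and HPD bounds for each genotype main effect."""
    g = draws.gvec.shape[1]
    labels = list(labels) if labels is not None else [f"G{i + 1:02d}" for i in range(g)]
    rows = []
    for i, lab in enumerate(labels):
        iv = hpd(draws.gvec[:, i], prob)
        rows.append({"genotype": lab, "mean": draws.gvec[:, i].mean(),
                     "hpd_lower": iv.lower, "hpd_upper": iv.upper})
    return pd.DataFrame(rows)
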