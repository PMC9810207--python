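"""Predictive cross-validation under whole-cell genotype loss.

Folds withhold entire genotype-within-environment cells (all replicates
of a genotype in an environment disappear at once, the realistic loss
pattern in multi-environment trials), at a target fraction of cells per
fold, subject to every genotype and every environment keeping at least
one training record in every fold.  Withheld records are predicted by
the posterior mean of the model response; accuracy is summarized by the
Pearson correlation (Cor) and the mean squared prediction error (PRESS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialData, build_designs
from .gibbs import GibbsConfig, PosteriorDraws, run_gibbs
from .priors import PriorSpec
from .rjmcmc import run_rjmcmc, visit_table
from .summaries import split_draws


@dataclass
class FoldPlan:
    folds: list[list[tuple]]   # per fold: withheld (genotype, environment) label pairs
    fraction: float


@dataclass
class CVResult:
    per_fold: pd.DataFrame     # columns: fold, model, t, cor, press, n_withheld
    skipped: list = field(default_factory=list)

    def mean_cor(self) -> float:
        return float(self.per_fold["cor"].mean())

    def mean_press(self) -> float:
        return float(self.per_fold["press"].mean())


def make_folds(data: TrialData, fraction: float = 0.10, k: int = 10,
               seed=None, max_tries: int = 500) -> FoldPlan:
    """Partition-style fold plan over occupied genotype-environment cells."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = sorted({(g, e) for g, e in zip(data.table["genotype"], data.table["environment"])},
                   key=lambda p: (str(p[0]), str(p[1])))
    per_fold = int(round(fraction * len(cells)))
    if per_fold < 1 or per_fold * k > len(cells):
        raise ValueError("fraction/fold combination leaves no valid partition; use a smaller fraction")
    cell_of_record = list(zip(data.table["genotype"], data.table["environment"]))
    for _ in range(max_tries):
        order = rng.permutation(len(cells))
        folds = [[cells[i] for i in order[f * per_fold:(f + 1) * per_fold]] for f in range(k)]
        ok = True
        for fold in folds:
            withheld = set(fold)
            keep = np.array([c not in withheld for c in cell_of_record])
            kept_g = {data.table["genotype"][i] for i in np.flatnonzero(keep)}
            kept_e = {data.table["environment"][i] for i in np.flatnonzero(keep)}
            if len(kept_g) < data.g or len(kept_e) < data.e:
                ok = False
                break
        if ok:
            return FoldPlan(folds=folds, fraction=fraction)
    raise RuntimeError("could not satisfy the genotype/environment retention constraint; use a smaller fraction")


def predict_cells(draws: PosteriorDraws, train: TrialData, records: pd.DataFrame) -> np.ndarray:
    """Posterior-mean predictions for withheld records.

    ``records`` needs genotype/environment/block columns; genotypes and
    environments must appear in the training data.  A block cell unseen in
    training falls back to the environment's mean block effect.
    """
    gmap = {lab: i for i, lab in enumerate(train.genotypes)}
    emap = {lab: i for i, lab in enumerate(train.environments)}
    cmap = {cell: i for i, cell in enumerate(train.block_cells)}
    try:
        gi = np.array([gmap[x] for x in records["genotype"]])
        ei = np.array([emap[x] for x in records["environment"]])
    except KeyError as err:
        raise ValueError(f"unseen genotype or environment label: {err}") from err

    beta_mean = draws.beta.mean(axis=0)
    env_of_cell = np.array([emap[c[0]] for c in train.block_cells])
    env_beta_mean = np.array([beta_mean[env_of_cell == j].mean() for j in range(train.e)])
    block_term = np.array([
        beta_mean[cmap[(ev, bl)]] if (ev, bl) in cmap else env_beta_mean[emap[ev]]
        for ev, bl in zip(records["environment"], records["block"])
    ])

    g_term = draws.gvec.mean(axis=0)[gi]
    inter = np.zeros(len(records))
    for lam, A, G in zip(draws.lambdas, draws.alphas, draws.gammas):
        if len(lam):
            inter += (A[gi] * G[ei]) @ lam
    inter /= draws.n_draws
    return block_term + g_term + inter


def cv_metrics(observed, predicted) -> tuple[float, float]:
    """Pearson correlation and mean squared prediction error (PRESS with 1/n)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    press = float(np.mean((obs - pred) ** 2))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan"), press
    return float(np.corrcoef(obs, pred)[0, 1]), press


def _withheld_mask(data: TrialData, fold) -> np.ndarray:
    withheld = set(fold)
    return np.array([
        (g, e) in withheld
        for g, e in zip(data.table["genotype"], data.table["environment"])
    ])


def run_cv(data: TrialData, prior: PriorSpec | list[PriorSpec], config: GibbsConfig,
           method: str = "gibbs", t_values=None, k: int = 10, fraction: float = 0.10,
           seed=None) -> CVResult:
    """Per-fold fits and predictive metrics.

    ``method='gibbs'`` fits each dimension in ``t_values`` at fixed t;
    ``method='rj'`` runs the reversible-jump sampler and predicts from the
    marginal response at the modal dimension.  One row per
    (fold, prior, dimension) combination.
    """
    priors = prior if isinstance(prior, list) else [prior]
    if method not in ("gibbs", "rj"):
        raise ValueError("method must be 'gibbs' or 'rj'")
    if method == "gibbs" and not t_values:
        raise ValueError("gibbs cross-validation needs t_values")
    rng = np.random.default_rng(seed)
    plan = make_folds(data, fraction=fraction, k=k, seed=rng)
    rows, skipped = [], []
    for f, fold in enumerate(plan.folds):
        mask = _withheld_mask(data, fold)
        train = data.subset(~mask)
        test = data.table.loc[mask].reset_index(drop=True)
        designs = build_designs(train)
        for spec in priors:
            fits = {}
            try:
                if method == "gibbs":
                    for t in t_values:
                        cfg = GibbsConfig(iterations=config.iterations, burn_in=config.burn_in,
                                          thin=config.thin, t_fixed=t,
                                          seed=int(rng.integers(2**31)))
                        fits[t] = (t, run_gibbs(train, designs, spec, cfg))
                else:
                    cfg = GibbsConfig(iterations=config.iterations, burn_in=config.burn_in,
                                      thin=config.thin, t_fixed=config.t_fixed,
                                      seed=int(rng.integers(2**31)))
                    draws = run_rjmcmc(train, designs, spec, cfg)
                    _, modal = visit_table(draws)
                    if modal > 0:
                        _, marginal = split_draws(draws, modal)
                    else:
                        marginal = draws.select(draws.t == 0, max_axes=0)
                    fits["rj"] = (modal, marginal)
            except (FloatingPointError, np.linalg.LinAlgError) as err:
                skipped.append((f, spec.hypothesis, str(err)))
                continue
            for key, (t, draws) in fits.items():
                pred = predict_cells(draws, train, test)
                cor, press = cv_metrics(test["response"].to_numpy(), pred)
                rows.append({"fold": f, "model": spec.hypothesis, "t": t,
                             "method": method, "cor": cor, "press": press,
                             "n_withheld": len(test)})
    return CVResult(per_fold=pd.DataFrame(rows), skipped=skipped)
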