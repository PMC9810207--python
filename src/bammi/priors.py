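"""Prior specification for the Bayesian AMMI variants.

The three families differ only in the prior on the scale parameter
``sigma2_lambda_k`` of the positive-truncated-normal prior on each
singular value:

* **BAMMI** — fixed large constant (1e8): effectively flat singular values.
* **BAMMIS** — Jeffreys-type shrinkage, p(s) ~ s^(Delta - 1) with
  0 < Delta < 1/2 (default 1/4); conditional InvGamma(1/2 - Delta, lambda^2/2).
* **BAMMIE** — maximum-entropy inverse-gamma with shape a = 1, scale b = 0;
  conjugate conditional InvGamma(a + 1/2, b + lambda^2/2).

The number of bilinear axes t carries a truncated-Poisson(mu) prior on
{0, ..., t_max} with a Gamma(tau, upsilon) hyperprior on mu, and the
reversible-jump move probabilities (add, delete, stay) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

HYPOTHESES = ("bammi", "bammis", "bammie")


@dataclass
class PriorSpec:
    hypothesis: str = "bammi"
    sigma2_beta: float = 1e8
    bammi_sigma2_lambda: float = 1e8
    bammis_delta: float = 0.25
    bammie_a: float = 1.0
    bammie_b: float = 0.0
    tau: float = 1.0
    upsilon: float = 1.0
    pa: float = 1.0 / 3.0
    pd: float = 1.0 / 3.0
    p0: float = 1.0 / 3.0
    t_max: int | None = None

    def __post_init__(self):
        self.hypothesis = self.hypothesis.lower()
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown prior hypothesis {self.hypothesis!r}; expected one of {HYPOTHESES}")
        if not (0.0 < self.bammis_delta < 0.5):
            raise ValueError("bammis_delta must lie in (0, 1/2)")
        if not np.isclose(self.pa + self.pd + self.p0, 1.0):
            raise ValueError("move probabilities pa + pd + p0 must sum to 1")
        if min(self.pa, self.pd, self.p0) <= 0:
            raise ValueError("move probabilities must be positive")
        if self.tau <= 0 or self.upsilon <= 0:
            raise ValueError("Gamma hyperprior parameters must be positive")


def load_prior_config(path) -> PriorSpec:
    """Build a :class:`PriorSpec` from the ``prior:`` block of a YAML/JSON file.

    Recognized keys match the PriorSpec fields (``hypothesis``,
    ``bammis_delta``, ``tau``, ``upsilon``, ``pa``, ``pd``, ``p0``, ...);
    unknown keys raise an error rather than being silently ignored.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    block = doc.get("prior", doc) if isinstance(doc, dict) else None
    if not isinstance(block, dict):
        raise ValueError(f"no usable 'prior' mapping found in {path}")
    valid = set(PriorSpec.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown prior configuration keys: {sorted(unknown)}")
    return PriorSpec(**block)


def update_sigma2_lambda(spec: PriorSpec, lambda_k: float, rng) -> float:
    """Draw sigma2_lambda_k from its full conditional given lambda_k.

    BAMMI returns the fixed constant.  BAMMIS and BAMMIE are inverse-gamma
    conditionals; inverse-gamma(shape, rate-on-inverse-scale) draws are
    taken as rate / Gamma(shape).
    """
    if lambda_k < 0:
        raise ValueError("lambda_k must be nonnegative")
    if spec.hypothesis == "bammi":
        return spec.bammi_sigma2_lambda
    if spec.hypothesis == "bammis":
        shape = 0.5 - spec.bammis_delta
        scale = lambda_k**2 / 2.0
    else:  # bammie
        shape = spec.bammie_a + 0.5
        scale = spec.bammie_b + lambda_k**2 / 2.0
    scale = max(scale, 1e-300)
    draw = scale / rng.gamma(shape)
    return float(np.clip(draw, 1e-12, 1e12))


def log_prior_t(t: int, mu: float, t_max: int) -> float:
    """Log pmf of a Poisson(mu) truncated and renormalized to {0, ..., t_max}."""
    if not 0 <= t <= t_max:
        raise ValueError(f"t={t} outside [0, {t_max}]")
    if mu <= 0:
        raise ValueError("mu must be positive")
    ts = np.arange(t_max + 1)
    logp = ts * np.log(mu) - special.gammaln(ts + 1)
    return float(logp[t] - special.logsumexp(logp))
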