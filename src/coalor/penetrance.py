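"""Penetrance models: mutation count -> disease probability -> phenotype.

Two model families are supported, each mapping an individual's total number
``k`` of causative mutations (summed over loci) to a disease probability:

* multiplicative: ``P(k) = 1 - (1 - gamma)**k`` with ``0 < gamma < 1``.
  Individuals without any mutation are unaffected; risk rises steeply with
  every additional mutation.
* logistic: ``logit P(k) = alpha + beta * k`` with ``beta > 0``.  There is a
  non-zero baseline risk ``1 / (1 + exp(-alpha))`` at ``k = 0`` and tolerance
  against a small number of mutations.

Disease states are drawn as independent Bernoulli(P(k)) per individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PenetranceModel",
    "disease_probability",
    "assign_phenotypes",
    "PRESETS",
]


@dataclass(frozen=True)
class PenetranceModel:
    """Specification of a penetrance function.

    ``kind`` is ``"multiplicative"`` (parameter ``gamma``) or ``"logistic"``
    (parameters ``alpha``, ``beta``).
    """

    kind: str
    gamma: float | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.kind == "multiplicative":
            if self.gamma is None or not 0.0 < self.gamma < 1.0:
                raise ValueError("multiplicative model needs 0 < gamma < 1")
        elif self.kind == "logistic":
            if self.alpha is None or self.beta is None or not self.beta > 0:
                raise ValueError("logistic model needs alpha and beta > 0")
        else:
            raise ValueError("unknown penetrance kind %r" % (self.kind,))

    @classmethod
    def multiplicative(cls, gamma: float) -> "PenetranceModel":
        return cls(kind="multiplicative", gamma=gamma)

    @classmethod
    def logistic(cls, alpha: float, beta: float) -> "PenetranceModel":
        return cls(kind="logistic", alpha=alpha, beta=beta)

    def label(self) -> str:
        if self.kind == "multiplicative":
            return "multiplicative(gamma=%g)" % self.gamma
        return "logistic(alpha=%g, beta=%g)" % (self.alpha, self.beta)


#: Parameter choices inducing a strong or a weak increase of risk with k.
PRESETS = {
    "multiplicative_strong": PenetranceModel.multiplicative(0.3),
    "multiplicative_weak": PenetranceModel.multiplicative(0.1),
    "logistic_strong": PenetranceModel.logistic(-5.0, 1.0),
    "logistic_weak": PenetranceModel.logistic(-5.0, 0.5),
}


def disease_probability(model: PenetranceModel, k_total):
    """Probability of disease given total causative-mutation count ``k``.

    Accepts a scalar or array of non-negative integers; returns probabilities
    in [0, 1], non-decreasing in ``k``.  The logistic branch uses a stable
    sigmoid, saturating to exact 0/1 beyond double precision.
    """
    k = np.asarray(k_total)
    if np.any(k < 0):
        raise ValueError("mutation counts must be non-negative")
    if model.kind == "multiplicative":
        p = -np.expm1(np.log1p(-model.gamma) * k)
    else:
        p = expit(model.alpha + model.beta * k)
    if np.isscalar(k_total) or np.ndim(k_total) == 0:
        return float(p)
    return p


def assign_phenotypes(
    k_per_individual, model: PenetranceModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw a dichotomous disease state per individual.

    Each individual is affected independently with probability
    ``disease_probability(model, k)``; returns an int8 0/1 vector.
    """
    k = np.asarray(k_per_individual)
    p = disease_probability(model, k)
    return (rng.random(k.shape) < p).astype(np.int8)
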