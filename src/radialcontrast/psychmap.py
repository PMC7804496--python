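"""Single-parameter mapping from contrast energy to proportion correct.

Two Gaussians in contrast-energy space share a mean at the target-alone
contrast ``mu_t``:

* ``G_tau`` (width ``sigma_t``) models identification of the target alone.
  Its width is fixed by the calibration that a 10 % change in target
  contrast produces a 1 % identification rate.
* ``G_phi`` (width ``k_phi * sigma_t``) models identification of the target
  among flankers.  Its width is set by ``E_alpha``, the contrast-energy
  value at which flankers first impede identification (the sole
  experiment-derived parameter): ``G_phi(E_alpha) = 0.01`` by construction.

Predicted proportion correct is ``p = G_tau + (1 - G_phi)``, scaled by an
empirical ceiling of 0.85 (observers in the modelled experiments rarely
exceed ~85 % correct even uncrowded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "H",
    "MappingModel",
    "sigma_tau",
    "k_phi_from",
    "build_model",
    "proportion_correct",
]

#: Calibration constant h = 2*ln(0.01) (< 0): a Gaussian drops to 0.01 at
#: sqrt(-h) standard deviations from its mean.
H = 2.0 * math.log(0.01)

#: Fractional contrast change assumed to produce a 1 % identification rate.
CONTRAST_STEP = 0.1

#: Empirical ceiling on proportion correct in the modelled experiments.
DEFAULT_CEILING = 0.85


def sigma_tau(mu_t: float) -> float:
    """Width of the target-alone Gaussian.

    Solves ``exp(-(0.1*mu_t)^2 / (2*sigma^2)) = 0.01`` for sigma, i.e.
    ``sigma = 0.1 * mu_t / sqrt(-h)`` with ``h = 2*ln(0.01)``.
    """
    if mu_t < 0:
        raise ValueError("mu_t must be >= 0")
    return CONTRAST_STEP * mu_t / math.sqrt(-H)


def k_phi_from(e_alpha: float, mu_t: float) -> float:
    """Width ratio ``k_phi = sigma_phi / sigma_tau`` from printed parameters.

    ``sigma_phi = |E_alpha - mu_t| / sqrt(-h)``, so the ratio reduces to
    ``|E_alpha - mu_t| / (0.1 * mu_t)``.  The squared forms make the sign of
    ``E_alpha - mu_t`` irrelevant; ``E_alpha`` may sit on either side of
    ``mu_t``.  A ratio below 1 would let predicted accuracy exceed the
    ceiling and is rejected.
    """
    if not (mu_t > 0):
        raise ValueError("mu_t must be positive")
    k = abs(e_alpha - mu_t) / (CONTRAST_STEP * mu_t)
    if k < 1.0:
        raise ValueError(
            f"|E_alpha - mu_t| = {abs(e_alpha - mu_t):g} is less than "
            f"0.1*mu_t = {CONTRAST_STEP * mu_t:g}: k_phi = {k:g} < 1 breaks "
            "the flanked-wider-than-alone assumption"
        )
    return k


@dataclass(frozen=True)
class MappingModel:
    """Assembled contrast -> behavior mapping parameters."""

    mu_t: float
    sigma_t: float
    e_alpha: float
    k_phi: float
    ceiling: float = DEFAULT_CEILING

    def __post_init__(self) -> None:
        if not (self.mu_t > 0 and self.sigma_t > 0):
            raise ValueError("mu_t and sigma_t must be positive")
        if self.k_phi < 1:
            raise ValueError("k_phi must be >= 1")
        if not (0 < self.ceiling <= 1):
            raise ValueError("ceiling must lie in (0, 1]")

    @property
    def sigma_phi(self) -> float:
        return self.k_phi * self.sigma_t


def build_model(
    mu_t: float, e_alpha: float, ceiling: float = DEFAULT_CEILING
) -> MappingModel:
    """Assemble a MappingModel from the two contrast-energy landmarks."""
    return MappingModel(
        mu_t=mu_t,
        sigma_t=sigma_tau(mu_t),
        e_alpha=e_alpha,
        k_phi=k_phi_from(e_alpha, mu_t),
        ceiling=ceiling,
    )


def proportion_correct(contrast, model: MappingModel):
    """Predicted proportion of correct identifications at a contrast energy.

    ``ceiling * (G_tau(C) + 1 - G_phi(C))``: at ``C = mu_t`` both Gaussians
    equal 1 and the prediction is the ceiling; in the intermediate band
    where ``G_tau`` has collapsed but ``G_phi`` has not, the prediction
    dips — that dip is the predicted crowding regime.  Accepts scalars or
    arrays; the result lies in ``[0, ceiling]`` whenever ``k_phi >= 1``.
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast energy must be >= 0")
    z2 = (c - model.mu_t) ** 2 / (2.0 * model.sigma_t**2)
    g_tau = np.exp(-z2)
    g_phi = np.exp(-z2 / model.k_phi**2)
    p = model.ceiling * (g_tau + 1.0 - g_phi)
    return float(p) if np.isscalar(contrast) else p
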