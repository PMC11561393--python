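"""Dichotomous logistic response functions, derivatives, and information.

The probability that a person with ability θ answers an item correctly is

    P(θ) = g + (1 − g) / (1 + exp(−D·a·(θ − b)))

with discrimination a, difficulty b, lower asymptote g, and scaling
constant D (1.702 aligns the logistic with the normal ogive; the default
here is 1.0 so that the normal-ogive scaling is never imposed silently).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

# Probability floor/ceiling used inside likelihoods to avoid log(0).
P_FLOOR = 1e-12

__all__ = [
    "three_pl_prob",
    "prob_correct",
    "prob_derivs",
    "grad_loglik_item",
    "item_information",
]


def three_pl_prob(theta, a, b, g=0.0, D=1.0):
    """3PL response probability; g=0 gives 2PL, shared a gives 1PL."""
    z = D * a * (np.asarray(theta, dtype=float) - b)
    return g + (1.0 - g) / (1.0 + np.exp(-z))


def _item_params(item) -> tuple[float, float, float, str]:
    a = float(item["par.1"])
    b = float(item["par.2"])
    g = item.get("par.3", np.nan) if hasattr(item, "get") else item["par.3"]
    g = 0.0 if (g is None or np.isnan(g)) else float(g)
    model = str(item["model"])
    return a, b, g, model


def prob_correct(theta, item, D=1.0):
    """Response probability for one metadata row (missing g treated as 0)."""
    a, b, g, _ = _item_params(item)
    return three_pl_prob(theta, a, b, g, D)


def prob_derivs(theta, a, b, g=0.0, D=1.0):
    """Return (P, dP/da, dP/db, dP/dg) at theta; vectorized over theta."""
    theta = np.asarray(theta, dtype=float)
    z = D * a * (theta - b)
    L = 1.0 / (1.0 + np.exp(-z))
    P = g + (1.0 - g) * L
    dLdz = L * (1.0 - L)
    dP_da = (1.0 - g) * dLdz * D * (theta - b)
    dP_db = -(1.0 - g) * dLdz * D * a
    dP_dg = 1.0 - L
    return P, dP_da, dP_db, dP_dg


def grad_loglik_item(theta, item, response, D=1.0):
    """Gradient of the item log-likelihood w.r.t. its free parameters.

    Returns the gradient over (a, b, g) for 3PLM/DRM, over (a, b) for 2PLM,
    and over (a, b) for 1PLM (g has no component for models without it).
    The log-likelihood is ``x·log P + (1−x)·log(1−P)`` for response x.
    """
    if response not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {response!r}")
    a, b, g, model = _item_params(item)
    z = D * a * (np.asarray(theta, dtype=float) - b)
    L = expit(z)
    Lm = expit(-z)  # stable 1 - L, avoids cancellation when z is large
    P = np.clip(g + (1.0 - g) * L, P_FLOOR, None)
    Qm = np.clip((1.0 - g) * Lm, P_FLOOR, None)  # stable 1 - P
    dLdz = L * Lm
    dP_da = (1.0 - g) * dLdz * D * (theta - b)
    dP_db = -(1.0 - g) * dLdz * D * a
    dP_dg = Lm
    # d loglik / dP
    w = response / P - (1 - response) / Qm
    grad = np.array([w * dP_da, w * dP_db, w * dP_dg])
    if model in ("1PLM", "2PLM"):
        return grad[:2]
    return grad


def item_information(theta, item, D=1.0):
    """Fisher information of a dichotomous item at theta.

    I(θ) = D²a² · (Q/P) · ((P − g)/(1 − g))²  with Q = 1 − P, equivalently
    [P′(θ)]² / (P·Q); non-negative everywhere and 0 in the tails for g > 0.
    """
    a, b, g, _ = _item_params(item)
    P = three_pl_prob(theta, a, b, g, D)
    P = np.clip(P, P_FLOOR, 1.0 - P_FLOOR)
    Q = 1.0 - P
    return (D * a) ** 2 * (Q / P) * ((P - g) / (1.0 - g)) ** 2
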