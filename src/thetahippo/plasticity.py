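"""Learning rules: contrastive-Hebbian, CPCA Hebbian, and their blend.

Two signals are combined per synapse.  The error-driven component is
contrastive Hebbian learning (CHL): the difference of sender-receiver
coproducts between a target ("plus") phase and an earlier expectation
("minus") phase.  The Hebbian component is the CPCA rule, which uses only
the plus phase and moves each weight toward the sender's activity
conditional on receiver activity.  The blended update is

    dW = eps * [ lmix * hebb + (1 - lmix) * err ]

with lmix = 1 for a purely Hebbian synapse and a small lmix (0.001 in the
error-driven condition) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LearningParams",
    "PhasePair",
    "chl_delta",
    "cpca_hebb_delta",
    "center_per_receiver",
    "combined_delta",
    "apply_delta",
]

#: lmix values defining the two study conditions.
LMIX_HEBBIAN = 1.0
LMIX_ERROR_DRIVEN = 0.001


@dataclass
class LearningParams:
    """lmix: Hebbian proportion in [0,1]; eps: learning rate;
    soft_bound: exponential approach to [0,1] instead of hard clipping."""

    lmix: float = LMIX_ERROR_DRIVEN
    eps: float = 0.08
    soft_bound: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.lmix <= 1.0):
            raise ValueError(f"lmix must lie in [0, 1], got {self.lmix}")
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")


@dataclass
class PhasePair:
    """Sender/receiver activations for the minus and plus phases.

    ``minus_phase`` records which theta snapshot supplied the minus data:
    "TT" (trough) for monosynaptic-pathway synapses, "TP" (peak) for the
    Schaffer collaterals.
    """

    x_minus: np.ndarray
    y_minus: np.ndarray
    x_plus: np.ndarray
    y_plus: np.ndarray
    minus_phase: str = "TT"

    def __post_init__(self) -> None:
        if self.minus_phase not in ("TT", "TP"):
            raise ValueError(f"minus_phase must be 'TT' or 'TP', got {self.minus_phase!r}")
        if self.x_minus.shape != self.x_plus.shape or self.y_minus.shape != self.y_plus.shape:
            raise ValueError("PhasePair: minus/plus shapes differ")


def chl_delta(pair: PhasePair) -> np.ndarray:
    """CHL error delta: D_ij = x+_i y+_j - x-_i y-_j (outer products)."""
    return np.outer(pair.x_plus, pair.y_plus) - np.outer(pair.x_minus, pair.y_minus)


def cpca_hebb_delta(x_plus: np.ndarray, y_plus: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    """CPCA Hebbian delta: D_ij = y+_j (x+_i - w_ij).

    Repeated application drives w_ij toward the expected sender activity
    conditional on the receiver being active; with y+_j = 0 nothing is
    learned at unit j's synapses.
    """
    x = np.asarray(x_plus, dtype=float)
    y = np.asarray(y_plus, dtype=float)
    if w.shape != (x.shape[0], y.shape[0]):
        raise ValueError(
            f"cpca_hebb_delta: w shape {w.shape} != ({x.shape[0]}, {y.shape[0]})"
        )
    return y[None, :] * (x[:, None] - w)


def center_per_receiver(delta: np.ndarray,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract each receiver's mean delta over its connected synapses.

    Because a unit's drive is the *mean* of its weighted inputs, adding a
    constant to all of a receiver's weights shifts every stimulus's drive
    equally and cannot change any within-layer competition; that uniform
    component only pushes weights toward the [0, 1] bounds, where clipping
    erases the differences that carry information.  Removing it
    (subtractive normalization) leaves the functionally relevant,
    difference-carrying part of the update.
    """
    if mask is None:
        return delta - delta.mean(axis=0, keepdims=True)
    m = mask.astype(float)
    means = (delta * m).sum(axis=0) / m.sum(axis=0)
    return (delta - means[None, :]) * m


def combined_delta(hebb_delta: np.ndarray, err_delta: np.ndarray,
                   params: LearningParams) -> np.ndarray:
    """Blend: eps * [lmix * hebb + (1 - lmix) * err]."""
    if hebb_delta.shape != err_delta.shape:
        raise ValueError("combined_delta: component shapes differ")
    return params.eps * (params.lmix * hebb_delta + (1.0 - params.lmix) * err_delta)


def apply_delta(weights: np.ndarray, delta: np.ndarray,
                params: LearningParams) -> np.ndarray:
    """Apply a weight change, keeping weights in [0, 1].

    Hard clipping by default.  With ``soft_bound`` positive changes are
    scaled by (1 - w) and negative ones by w, so weights approach the
    bounds exponentially and never touch them.
    """
    if weights.shape != delta.shape:
        raise ValueError("apply_delta: weight/delta shapes differ")
    if params.soft_bound:
        scaled = np.where(delta > 0, delta * (1.0 - weights), delta * weights)
        return np.clip(weights + scaled, 0.0, 1.0)
    return np.clip(weights + delta, 0.0, 1.0)
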