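"""Instantaneous imitation reward.

The per-step objective combines a pose-tracking reward with two physics
costs::

    r_t = lambda_joint * r_joint - lambda_ctrl * c_ctrl - lambda_energy * c_energy

where ``r_joint = exp(-alpha_joint * sum_i (q_i - qhat_i)^2)`` rewards
matching the reference joint configuration, ``c_ctrl = sum_j a_j^2``
penalizes action magnitude, and ``c_energy = sum_j |v_j| * |f_j|`` penalizes
the mechanical-power magnitude at each joint. The energy cost takes the
product of absolute values so it is a true cost (non-negative); a signed-sum
variant ``|sum_j v_j f_j|`` is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RewardWeights",
    "RewardTerms",
    "joint_reward",
    "control_cost",
    "energy_cost",
    "total_reward",
    "compute_terms",
]


@dataclass(frozen=True)
class RewardWeights:
    lambda_joint: float = 1.0
    lambda_ctrl: float = 0.0
    lambda_energy: float = 0.0
    alpha_joint: float = 1.0  # rad^-2
    signed_energy: bool = False

    def __post_init__(self) -> None:
        if min(self.lambda_joint, self.lambda_ctrl, self.lambda_energy) < 0:
            raise ValueError("reward weights must be non-negative")
        if self.alpha_joint <= 0:
            raise ValueError("alpha_joint must be positive")


@dataclass(frozen=True)
class RewardTerms:
    r_joint: float
    c_ctrl: float
    c_energy: float
    r_total: float


def joint_reward(q: np.ndarray, qhat: np.ndarray, alpha_joint: float = 1.0):
    """exp(-alpha * sum of squared joint-angle errors); in (0, 1].

    Supports batched input with joints on the last axis.
    """
    q = np.asarray(q, dtype=float)
    qhat = np.asarray(qhat, dtype=float)
    if q.shape[-1] != qhat.shape[-1]:
        raise ValueError(f"joint count mismatch: {q.shape} vs {qhat.shape}")
    return np.exp(-alpha_joint * np.sum((q - qhat) ** 2, axis=-1))


def control_cost(a: np.ndarray):
    """Sum of squared actions."""
    a = np.asarray(a, dtype=float)
    return np.sum(a**2, axis=-1)


def energy_cost(v: np.ndarray, f: np.ndarray, signed: bool = False):
    """Mechanical-power-magnitude cost.

    Default: ``sum_j |v_j| * |f_j|`` (non-negative). With ``signed=True``:
    ``|sum_j v_j * f_j|``, the magnitude of net mechanical power.
    """
    v = np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    if v.shape[-1] != f.shape[-1]:
        raise ValueError(f"length mismatch: {v.shape} vs {f.shape}")
    if signed:
        return np.abs(np.sum(v * f, axis=-1))
    return np.sum(np.abs(v) * np.abs(f), axis=-1)


def total_reward(r_joint, c_ctrl, c_energy, weights: RewardWeights):
    """Exact weighted combination of the three terms."""
    return (
        weights.lambda_joint * r_joint
        - weights.lambda_ctrl * c_ctrl
        - weights.lambda_energy * c_energy
    )


def compute_terms(
    q: np.ndarray,
    qhat: np.ndarray,
    a: np.ndarray,
    v: np.ndarray,
    f_joint: np.ndarray,
    weights: RewardWeights,
) -> RewardTerms:
    """All reward terms for one step; ``f_joint`` is per-joint actuator force."""
    rj = float(joint_reward(q, qhat, weights.alpha_joint))
    cc = float(control_cost(a))
    ce = float(energy_cost(v, f_joint, signed=weights.signed_energy))
    return RewardTerms(rj, cc, ce, float(total_reward(rj, cc, ce, weights)))
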