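"""PCA geometry of the intention bottleneck and decoder hidden layers.

Activation tensors of shape (clips, timesteps, units) are flattened to
(clips x timesteps, units), mean-centered, and projected onto the top
principal components; the projections are reshaped back to
(clips, timesteps, n_components) so temporal and trial structure survive.
The variance explained by the top three components quantifies how
compressed each layer's representation is along the reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .arm import Rollout

__all__ = ["ActivationTensor", "flatten_project", "analyze_policy_layers",
           "collect_activation_tensors"]


@dataclass
class ActivationTensor:
    """Per-layer activations over clips and timesteps."""

    values: np.ndarray  # (clips, timesteps, units)
    layer_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (clips, timesteps, units)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"layer {self.layer_label}: non-finite values")


def flatten_project(
    tensor: ActivationTensor, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled PCA of an activation tensor.

    Returns ``(projected, variance_fractions)`` where ``projected`` has
    shape (clips, timesteps, n_components) in the original (clip,
    timestep) order and ``variance_fractions`` are the explained-variance
    ratios of the retained components (non-increasing).
    """
    vals = tensor.values
    n_clips, n_t, n_units = vals.shape
    if n_components > n_units:
        raise ValueError(
            f"n_components = {n_components} exceeds units = {n_units}"
        )
    flat = vals.reshape(n_clips * n_t, n_units)
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(flat)
    return (
        proj.reshape(n_clips, n_t, n_components),
        pca.explained_variance_ratio_.copy(),
    )


def collect_activation_tensors(
    rollouts: list[Rollout],
) -> dict[str, ActivationTensor]:
    """Stack recorded rollout activations into per-layer tensors.

    Requires rollouts produced with ``record_activations=True``; the
    intention means form the ``intention`` layer and each decoder hidden
    layer contributes one tensor.
    """
    if not rollouts:
        raise ValueError("no rollouts supplied")
    for ro in rollouts:
        if ro.intention_means is None or ro.layer_activations is None:
            raise ValueError(
                f"rollout {ro.clip_id} was recorded without activations"
            )
    layers: dict[str, ActivationTensor] = {
        "intention": ActivationTensor(
            np.stack([ro.intention_means for ro in rollouts]), "intention"
        )
    }
    names = rollouts[0].layer_activations.keys()
    for name in names:
        layers[name] = ActivationTensor(
            np.stack([ro.layer_activations[name] for ro in rollouts]), name
        )
    return layers


def analyze_policy_layers(
    rollouts: list[Rollout],
    n_components: int = 3,
    joint_index: int = 0,
) -> dict:
    """Per-layer PCA report for recorded rollouts.

    Returns a dict with one entry per layer (intention + decoder hidden
    layers), each holding ``variance_fractions`` and ``projection``, plus
    a tidy ``table`` joining the projections with the concurrent joint
    angle (column ``q``) for trajectory visualization.
    """
    layers = collect_activation_tensors(rollouts)
    report: dict = {"layers": {}, "table": None}
    rows = []
    q_all = np.stack([ro.q[:, joint_index] for ro in rollouts])
    for name, tensor in layers.items():
        k = min(n_components, tensor.values.shape[2])
        proj, var = flatten_project(tensor, n_components=k)
        report["layers"][name] = {
            "variance_fractions": var,
            "projection": proj,
        }
        n_clips, n_t, _ = proj.shape
        for ci in range(n_clips):
            for ti in range(n_t):
                row = {"layer": name, "clip": ci, "t": ti,
                       "q": q_all[ci, ti]}
                for pc in range(k):
                    row[f"pc{pc + 1}"] = proj[ci, ti, pc]
                rows.append(row)
    report["table"] = pd.DataFrame(rows)
    return report


def variance_table(report: dict) -> pd.DataFrame:
    """Long-form (layer, pc, variance_fraction) table from a report."""
    rows = []
    for name, entry in report["layers"].items():
        for i, f in enumerate(entry["variance_fractions"]):
            rows.append({"layer": name, "pc": i + 1, "variance_fraction": f})
    return pd.DataFrame(rows)
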