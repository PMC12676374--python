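"""Shared I/O: HDF5 clip/rollout storage, CSV export, time-series ingest.

HDF5 is the canonical container (``/clips/<id>/{qhat, v, actions, forces}``
with ``dt``/``duration``/``seed`` attributes; ``/emg/signal`` with ``fs``
and channel names); CSV is supported everywhere reports or external series
come in, using the long layout ``time, clip_id, <variable columns>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .arm import RawEMGRecording, ReferenceClip, Rollout

__all__ = [
    "write_clips_h5",
    "read_clips_h5",
    "clips_to_csv",
    "write_emg_h5",
    "read_emg_h5",
    "TimeSeriesTable",
    "read_timeseries",
]


def write_clips_h5(path: str | Path, clips: list[ReferenceClip],
                   rollouts: list[Rollout] | None = None,
                   seed: int | None = None) -> None:
    rollouts = rollouts or [None] * len(clips)
    with h5py.File(path, "w") as f:
        grp = f.create_group("clips")
        if seed is not None:
            grp.attrs["seed"] = seed
        for clip, ro in zip(clips, rollouts):
            g = grp.create_group(clip.clip_id)
            g.create_dataset("qhat", data=clip.qhat)
            g.attrs["dt"] = clip.dt
            g.attrs["duration"] = clip.duration
            if clip.true_activations is not None:
                g.create_dataset("true_activations",
                                 data=clip.true_activations)
            if ro is not None:
                g.create_dataset("v", data=ro.v)
                g.create_dataset("actions", data=ro.actions)
                g.create_dataset("forces", data=ro.forces)
                g.attrs["rollout_dt"] = ro.dt


def read_clips_h5(path: str | Path) -> tuple[list[ReferenceClip], list[Rollout | None]]:
    clips, rollouts = [], []
    with h5py.File(path, "r") as f:
        grp = f["clips"]
        for cid in sorted(grp):
            g = grp[cid]
            clips.append(
                ReferenceClip(
                    clip_id=cid,
                    qhat=g["qhat"][()],
                    dt=float(g.attrs["dt"]),
                    duration=float(g.attrs["duration"]),
                    true_activations=(
                        g["true_activations"][()]
                        if "true_activations" in g else None
                    ),
                )
            )
            if "actions" in g:
                rollouts.append(
                    Rollout(
                        clip_id=cid, q=g["qhat"][()], v=g["v"][()],
                        actions=g["actions"][()], forces=g["forces"][()],
                        dt=float(g.attrs.get("rollout_dt", g.attrs["dt"])),
                    )
                )
            else:
                rollouts.append(None)
    return clips, rollouts


def clips_to_csv(path: str | Path, clips: list[ReferenceClip]) -> None:
    """Long-format export: one row per frame, columns q0..qn (+ a0..am)."""
    rows = []
    for clip in clips:
        for t in range(clip.n_frames):
            row = {"clip_id": clip.clip_id, "time": t * clip.dt}
            for j in range(clip.qhat.shape[1]):
                row[f"q{j}"] = clip.qhat[t, j]
            if clip.true_activations is not None:
                for m in range(clip.true_activations.shape[1]):
                    row[f"a{m}"] = clip.true_activations[t, m]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_emg_h5(path: str | Path, rec: RawEMGRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("emg")
        g.create_dataset("signal", data=rec.signal)
        g.create_dataset("trial_onsets", data=rec.trial_onsets)
        g.attrs["fs"] = rec.fs
        g.attrs["channels"] = [c.encode() for c in rec.channels]


def read_emg_h5(path: str | Path) -> RawEMGRecording:
    with h5py.File(path, "r") as f:
        g = f["emg"]
        return RawEMGRecording(
            fs=float(g.attrs["fs"]),
            channels=[
                c.decode() if isinstance(c, bytes) else str(c)
                for c in g.attrs["channels"]
            ],
            signal=g["signal"][()],
            trial_onsets=g["trial_onsets"][()],
        )


@dataclass
class TimeSeriesTable:
    """Uniform clip-structured multichannel series.

    ``values`` is (n_frames_total, n_channels) with rows grouped by clip
    in ``clip_ids``; ``rate`` is the frame rate in Hz.
    """

    values: np.ndarray
    clip_ids: np.ndarray
    channels: list[str]
    rate: float

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]


def read_timeseries(path: str | Path, rate: float | None = None) -> TimeSeriesTable:
    """Ingest a clip-structured series from package HDF5 or long CSV.

    CSV must carry ``time`` and ``clip_id`` columns plus one column per
    variable; the rate is inferred from the time stamps unless given.
    NaN frames are rejected with their locations listed.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        clips, _ = read_clips_h5(path)
        values = np.concatenate([c.qhat for c in clips])
        cids = np.concatenate(
            [np.full(c.n_frames, c.clip_id, dtype=object) for c in clips]
        )
        channels = [f"q{j}" for j in range(values.shape[1])]
        return TimeSeriesTable(values, cids, channels, 1.0 / clips[0].dt)
    df = pd.read_csv(path)
    required = {"time", "clip_id"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"CSV must have columns {sorted(required)}; found "
            f"{list(df.columns)}"
        )
    var_cols = [c for c in df.columns if c not in required]
    bad = df[var_cols].isna()
    if bad.any().any():
        locs = list(zip(*np.nonzero(bad.to_numpy())))[:10]
        raise ValueError(f"NaN values at (row, col) positions {locs}")
    if rate is None:
        by_clip = df.groupby("clip_id", sort=False)["time"]
        diffs = by_clip.diff().dropna()
        if diffs.empty or diffs.min() <= 0:
            raise ValueError(
                "cannot infer frame rate from time stamps; pass rate= "
                "explicitly"
            )
        rate = float(1.0 / diffs.median())
    return TimeSeriesTable(
        values=df[var_cols].to_numpy(dtype=float),
        clip_ids=df["clip_id"].to_numpy(),
        channels=var_cols,
        rate=rate,
    )
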