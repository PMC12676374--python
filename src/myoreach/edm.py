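"""Empirical dynamic modeling: delay embedding and simplex projection.

State-space reconstruction from time series: a scalar (or multivariate)
observable is delay-embedded as ``(x(t), x(t+tau), ..., x(t+(E-1)tau))``
with ``tau`` negative meaning lags into the past; the embedded points
trace a shadow manifold that preserves the topology of the generating
attractor. Simplex projection forecasts a target series ``Tp`` frames
ahead by finding the ``k = E+1`` nearest library neighbors of each query
point and averaging their futures with exponential distance weights
``w_i = exp(-d_i / d_1)``. Forecast skill is the Spearman rank
correlation between predictions and observations ("simplex rho"), which
is invariant to monotone transforms of the target.

Embeddings never span clip boundaries; the default library/query split
assigns even-indexed clips to the library and odd-indexed clips to the
queries, so the two sets are disjoint in time by construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "SimplexResult",
    "EmbeddedPoints",
    "delay_embed",
    "simplex_forecast",
    "cross_decode",
    "grid_search",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding and forecast parameters; neighbors fixed at E+1."""

    E: int = 3
    tau: int = -1
    Tp: int = 1

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if self.tau == 0:
            raise ValueError("tau must be nonzero")
        if self.Tp < 1:
            raise ValueError("Tp must be >= 1")

    @property
    def k(self) -> int:
        return self.E + 1


@dataclass
class SimplexResult:
    """Forecasts, observations, and the Spearman skill of one evaluation."""

    predictions: np.ndarray
    observed: np.ndarray
    rho: float | None
    config: EmbeddingConfig
    n_valid: int


@dataclass
class EmbeddedPoints:
    """Delay-embedded points with their base times and clip labels."""

    coords: np.ndarray    # (N, E * n_vars)
    times: np.ndarray     # (N,) global frame index of x(t)
    clip_ids: np.ndarray  # (N,)


def _as_clip_arrays(
    series: np.ndarray, clip_ids: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if clip_ids is None:
        clip_ids = np.zeros(series.shape[0], dtype=int)
    clip_ids = np.asarray(clip_ids)
    if clip_ids.shape[0] != series.shape[0]:
        raise ValueError("clip_ids length must match series length")
    return series, clip_ids


def delay_embed(
    series: np.ndarray,
    config: EmbeddingConfig,
    clip_ids: np.ndarray | None = None,
) -> EmbeddedPoints:
    """Delay-embed a (possibly multivariate) clip-structured series.

    For each valid time ``t`` the point is the concatenation over
    variables of ``(x(t), x(t+tau), ..., x(t+(E-1)tau))``. A point is
    valid only if every lagged index falls inside the same clip; clips too
    short for the embedding are skipped with a warning, and an error is
    raised only if no clip yields any point.
    """
    series, clip_ids = _as_clip_arrays(series, clip_ids)
    E, tau = config.E, config.tau
    offsets = np.arange(E) * tau
    coords_all, times_all, cids_all = [], [], []
    for cid in pd_unique(clip_ids):
        idx = np.nonzero(clip_ids == cid)[0]
        T = len(idx)
        span = (E - 1) * abs(tau)
        if T < span + 1:
            logger.warning(
                "clip %r too short for E=%d tau=%d (T=%d); skipped",
                cid, E, tau, T,
            )
            continue
        local_t = np.arange(T)
        valid = np.all(
            (local_t[:, None] + offsets[None, :] >= 0)
            & (local_t[:, None] + offsets[None, :] < T),
            axis=1,
        )
        lt = local_t[valid]
        # (n_points, E) lagged local indices -> (n_points, E, n_vars)
        lag_idx = lt[:, None] + offsets[None, :]
        pts = series[idx[lag_idx]]  # (n_points, E, n_vars)
        # concatenate per variable: var-major ordering (v0 lags, v1 lags, ...)
        pts = np.transpose(pts, (0, 2, 1)).reshape(len(lt), -1)
        coords_all.append(pts)
        times_all.append(idx[lt])
        cids_all.append(clip_ids[idx[lt]])
    if not coords_all:
        raise ValueError("every clip is too short for the requested embedding")
    return EmbeddedPoints(
        coords=np.concatenate(coords_all),
        times=np.concatenate(times_all),
        clip_ids=np.concatenate(cids_all),
    )


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in first-appearance order."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


def _future_target_ok(
    times: np.ndarray, clip_ids: np.ndarray, Tp: int,
    target: np.ndarray, all_clip_ids: np.ndarray,
) -> np.ndarray:
    """Mask of points whose time+Tp stays inside the same clip with a
    finite target value."""
    n = len(target)
    fut = times + Tp
    ok = fut < n
    same = np.zeros_like(ok)
    same[ok] = all_clip_ids[fut[ok]] == clip_ids[ok]
    finite = np.zeros_like(ok)
    finite[ok] = np.isfinite(target[fut[ok]])
    return ok & same & finite


def simplex_forecast(
    library: EmbeddedPoints,
    queries: EmbeddedPoints,
    target: np.ndarray,
    config: EmbeddingConfig,
    all_clip_ids: np.ndarray | None = None,
    standardize: bool = False,
) -> SimplexResult:
    """Simplex projection of ``target`` at horizon ``Tp`` from a library.

    For each query, the ``k = E+1`` Euclidean nearest library neighbors
    (restricted to points with a valid future) vote with weights
    ``exp(-d_i/d_1)`` normalized to sum one; if the nearest distance is
    exactly zero, only the zero-distance neighbors' futures are averaged.
    Library and queries must be disjoint in time (enforced).
    """
    target = np.asarray(target, dtype=float).ravel()
    if all_clip_ids is None:
        all_clip_ids = np.zeros(len(target), dtype=int)
    Tp, k = config.Tp, config.k

    if np.intersect1d(library.times, queries.times).size > 0:
        raise ValueError("library and query sets overlap in time")

    lib_ok = _future_target_ok(
        library.times, library.clip_ids, Tp, target, all_clip_ids
    )
    lib_coords = library.coords[lib_ok]
    lib_fut = target[library.times[lib_ok] + Tp]
    if lib_coords.shape[0] < k:
        raise ValueError(
            f"library has {lib_coords.shape[0]} usable points < k = {k}"
        )
    q_ok = _future_target_ok(
        queries.times, queries.clip_ids, Tp, target, all_clip_ids
    )
    q_coords = queries.coords[q_ok]
    observed = target[queries.times[q_ok] + Tp]
    n_valid = q_coords.shape[0]
    if n_valid == 0:
        raise ValueError("no query point has an observable future target")

    scale = None
    if standardize:
        scale = lib_coords.std(axis=0)
        scale[scale == 0] = 1.0
        lib_coords = lib_coords / scale
        q_coords = q_coords / scale

    nn = NearestNeighbors(n_neighbors=k).fit(lib_coords)
    dists, idx = nn.kneighbors(q_coords)
    preds = np.empty(n_valid)
    for i in range(n_valid):
        d, futures = dists[i], lib_fut[idx[i]]
        if d[0] == 0.0:
            zero = d == 0.0
            preds[i] = futures[zero].mean()
        else:
            w = np.exp(-d / d[0])
            w = w / w.sum()
            preds[i] = np.dot(w, futures)

    if np.ptp(observed) == 0.0:
        logger.warning("observed targets have zero variance; rho undefined")
        rho = None
    else:
        rho = float(spearmanr(observed, preds).statistic)
    return SimplexResult(
        predictions=preds, observed=observed, rho=rho,
        config=config, n_valid=n_valid,
    )


def split_clips(
    points: EmbeddedPoints, library_clips: set
) -> tuple[EmbeddedPoints, EmbeddedPoints]:
    """Partition embedded points into library and query sets by clip."""
    in_lib = np.isin(points.clip_ids, list(library_clips))
    lib = EmbeddedPoints(points.coords[in_lib], points.times[in_lib],
                         points.clip_ids[in_lib])
    qry = EmbeddedPoints(points.coords[~in_lib], points.times[~in_lib],
                         points.clip_ids[~in_lib])
    return lib, qry


def cross_decode(
    source: np.ndarray,
    target: np.ndarray,
    config: EmbeddingConfig,
    clip_ids: np.ndarray | None = None,
    library_clips: set | None = None,
    standardize: bool = False,
) -> SimplexResult:
    """Decode ``target`` from a delay embedding of ``source``.

    The source (e.g. joint angles, possibly multivariate) is embedded; the
    simplex forecast then predicts the time-aligned target (e.g. one
    muscle's activation) ``Tp`` frames ahead. ``library_clips`` selects the
    library set; by default even-indexed clips (in appearance order) form
    the library and odd-indexed clips the queries.
    """
    source_arr, cids = _as_clip_arrays(source, clip_ids)
    points = delay_embed(source_arr, config, cids)
    uniq = pd_unique(cids)
    if library_clips is None:
        library_clips = set(uniq[::2].tolist())
    lib, qry = split_clips(points, library_clips)
    if lib.coords.shape[0] == 0 or qry.coords.shape[0] == 0:
        raise ValueError("library or query clip set is empty")
    return simplex_forecast(
        lib, qry, target, config, all_clip_ids=cids, standardize=standardize
    )


def grid_search(
    source: np.ndarray,
    target: np.ndarray,
    E_range: range | list = range(1, 11),
    tau_range: list = (-1, -2, -3, -4),
    Tp_range: range | list = range(1, 11),
    clip_ids: np.ndarray | None = None,
    library_clips: set | None = None,
    standardize: bool = False,
) -> tuple[EmbeddingConfig, np.ndarray]:
    """Exhaustive (E, tau, Tp) search maximizing simplex rho.

    Returns the best config and the full rho surface with shape
    ``(|E_range|, |tau_range|, |Tp_range|)`` (NaN where undefined). Ties
    break toward smaller E, then smaller |tau|, then smaller Tp — the
    iteration order below.
    """
    E_list, tau_list, Tp_list = list(E_range), list(tau_range), list(Tp_range)
    if not (E_list and tau_list and Tp_list):
        raise ValueError("parameter ranges must be non-empty")
    tau_list = sorted(tau_list, key=abs)
    surface = np.full((len(E_list), len(tau_list), len(Tp_list)), np.nan)
    best: tuple[float, EmbeddingConfig] | None = None
    for (i, E), (j, tau), (l, Tp) in itertools.product(
        enumerate(E_list), enumerate(tau_list), enumerate(Tp_list)
    ):
        cfg = EmbeddingConfig(E=E, tau=tau, Tp=Tp)
        try:
            res = cross_decode(
                source, target, cfg, clip_ids=clip_ids,
                library_clips=library_clips, standardize=standardize,
            )
        except ValueError:
            continue
        if res.rho is None:
            continue
        surface[i, j, l] = res.rho
        if best is None or res.rho > best[0]:
            best = (res.rho, cfg)
    if best is None:
        raise ValueError("every grid cell is undefined")
    return best[1], surface
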