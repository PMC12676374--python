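"""Tests for delay embedding and simplex projection.

The brute-force oracle here recomputes simplex forecasts with naive
all-pairs distances and the direct weight formula, independent of the
library implementation (which uses a neighbor index).
"""

import numpy as np
import pytest

from myoreach.edm import (
    EmbeddedPoints,
    EmbeddingConfig,
    cross_decode,
    delay_embed,
    grid_search,
    simplex_forecast,
    split_clips,
)


def naive_simplex(lib_coords, lib_futures, q_coords, k):
    """Independent simplex oracle: all-pairs distances, direct weights."""
    preds = np.empty(len(q_coords))
    for i, q in enumerate(q_coords):
        d = np.sqrt(((lib_coords - q) ** 2).sum(axis=1))
        idx = np.argsort(d, kind="stable")[:k]
        dd = d[idx]
        if dd[0] == 0.0:
            preds[i] = lib_futures[idx][dd == 0.0].mean()
        else:
            w = np.exp(-dd / dd[0])
            preds[i] = (w / w.sum()) @ lib_futures[idx]
    return preds


# -- delay embedding --------------------------------------------------------


def test_delay_embed_definition_example():
    pts = delay_embed(np.array([1.0, 2, 3, 4, 5]),
                      EmbeddingConfig(E=2, tau=-1, Tp=1))
    np.testing.assert_array_equal(
        pts.coords, [[2, 1], [3, 2], [4, 3], [5, 4]]
    )
    np.testing.assert_array_equal(pts.times, [1, 2, 3, 4])


def test_delay_embed_E1_is_raw_series():
    x = np.array([3.0, 1.0, 4.0, 1.0])
    pts = delay_embed(x, EmbeddingConfig(E=1, tau=-1, Tp=1))
    np.testing.assert_array_equal(pts.coords.ravel(), x)


def test_delay_embed_respects_clip_boundaries():
    x = np.arange(20.0)
    cids = np.repeat([0, 1], 10)
    pts = delay_embed(x, EmbeddingConfig(E=3, tau=-1, Tp=1), cids)
    assert pts.coords.shape[0] == 16  # 8 per clip
    for c in (0, 1):
        sel = pts.clip_ids == c
        assert sel.sum() == 8
        # no embedded vector mixes values from the other clip
        lo, hi = (0.0, 9.0) if c == 0 else (10.0, 19.0)
        assert pts.coords[sel].min() >= lo and pts.coords[sel].max() <= hi


def test_delay_embed_removing_a_clip_is_local():
    """Dropping one clip never changes another clip's embedded points."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    cids = np.repeat([0, 1, 2], 10)
    cfg = EmbeddingConfig(E=2, tau=-2, Tp=1)
    full = delay_embed(x, cfg, cids)
    reduced = delay_embed(x[10:], cfg, cids[10:])
    keep = full.clip_ids != 0
    np.testing.assert_array_equal(full.coords[keep], reduced.coords)


def test_delay_embed_short_clips_skipped_then_rejected(caplog):
    x = np.arange(12.0)
    cids = np.repeat([0, 1], [3, 9])
    cfg = EmbeddingConfig(E=4, tau=-1, Tp=1)
    pts = delay_embed(x, cfg, cids)  # clip 0 (T=3) skipped with warning
    assert set(pts.clip_ids) == {1}
    with pytest.raises(ValueError, match="too short"):
        delay_embed(np.arange(3.0), cfg)


def test_positive_tau_embeds_into_future():
    pts = delay_embed(np.array([1.0, 2, 3, 4]),
                      EmbeddingConfig(E=2, tau=1, Tp=1))
    np.testing.assert_array_equal(pts.coords, [[1, 2], [2, 3], [3, 4]])


# -- simplex forecast -------------------------------------------------------


def _embed_split(x, cfg, cids, lib_clips):
    pts = delay_embed(x, cfg, cids)
    return split_clips(pts, lib_clips)


def test_zero_distance_query_returns_neighbor_future():
    """A query identical to a unique library point inherits its future."""
    x = np.array([0.0, 1.0, 2.0, 5.0, 9.0,     # clip 0 (library)
                  0.0, 1.0, 7.0, 3.0, 4.0])    # clip 1 (query)
    cids = np.repeat([0, 1], 5)
    cfg = EmbeddingConfig(E=2, tau=-1, Tp=1)
    lib, qry = _embed_split(x, cfg, cids, {0})
    res = simplex_forecast(lib, qry, x, cfg, all_clip_ids=cids)
    # query point (1, 0) at time 6 coincides with library point at time 1
    i = int(np.nonzero(qry.times[: res.n_valid] == 6)[0][0])
    assert res.predictions[i] == pytest.approx(x[1 + 1])  # its future, 2.0


def test_sine_forecast_high_skill():
    t = np.arange(400) * 0.1
    x = np.sin(t)
    cids = np.where(np.arange(400) < 200, 0, 1)
    res = cross_decode(x, x, EmbeddingConfig(E=2, tau=-1, Tp=1),
                       clip_ids=cids, library_clips={0})
    assert res.rho >= 0.99


def test_logistic_map_skill_decays_with_horizon():
    x = np.empty(500)
    x[0] = 0.4
    for i in range(499):
        x[i + 1] = 3.8 * x[i] * (1 - x[i])
    cids = np.where(np.arange(500) < 250, 0, 1)
    rhos = {
        Tp: cross_decode(x, x, EmbeddingConfig(E=2, tau=-1, Tp=Tp),
                         clip_ids=cids, library_clips={0}).rho
        for Tp in (1, 5)
    }
    assert rhos[1] > rhos[5]


def test_matches_bruteforce_oracle_on_random_series():
    """Library implementation equals the naive oracle within 1e-10 on 50
    random series."""
    rng = np.random.default_rng(42)
    for trial in range(50):
        n = 80
        x = np.cumsum(rng.normal(size=n))
        cids = np.where(np.arange(n) < n // 2, 0, 1)
        E = int(rng.integers(1, 5))
        tau = int(rng.choice([-1, -2]))
        Tp = int(rng.integers(1, 4))
        cfg = EmbeddingConfig(E=E, tau=tau, Tp=Tp)
        lib, qry = _embed_split(x, cfg, cids, {0})
        res = simplex_forecast(lib, qry, x, cfg, all_clip_ids=cids)
        # rebuild the oracle's library/query sets with the same validity rule
        lib_ok = lib.times + Tp < n // 2
        q_ok = qry.times + Tp < n
        expected = naive_simplex(
            lib.coords[lib_ok], x[lib.times[lib_ok] + Tp],
            qry.coords[q_ok], cfg.k,
        )
        np.testing.assert_allclose(res.predictions, expected, atol=1e-10)


def test_weights_sum_to_one_and_nonnegative():
    """Forecasts are convex combinations: bounded by the library futures."""
    rng = np.random.default_rng(1)
    x = np.cumsum(rng.normal(size=100))
    cids = np.where(np.arange(100) < 50, 0, 1)
    cfg = EmbeddingConfig(E=3, tau=-1, Tp=2)
    res = cross_decode(x, x, cfg, clip_ids=cids, library_clips={0})
    assert np.all(res.predictions >= x[:50].min() - 1e-12)
    assert np.all(res.predictions <= x[:50].max() + 1e-12)


def test_rho_is_rank_based():
    """Simplex rho is a rank correlation: monotone transforms (cube, exp)
    of predictions or observations leave it unchanged."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(2)
    src = np.cumsum(rng.normal(size=200))
    tgt = np.sin(np.arange(200) * 0.15) + 0.1 * rng.normal(size=200)
    cids = np.where(np.arange(200) < 100, 0, 1)
    res = cross_decode(src, tgt, EmbeddingConfig(E=2, tau=-1, Tp=1),
                       clip_ids=cids)
    for g in (lambda x: x**3, np.exp):
        assert spearmanr(g(res.observed), res.predictions
                         ).statistic == pytest.approx(res.rho, abs=1e-12)
        assert spearmanr(res.observed, g(res.predictions)
                         ).statistic == pytest.approx(res.rho, abs=1e-12)


def test_overlapping_library_and_query_rejected():
    x = np.arange(20.0)
    cfg = EmbeddingConfig(E=2, tau=-1, Tp=1)
    pts = delay_embed(x, cfg)
    with pytest.raises(ValueError, match="overlap"):
        simplex_forecast(pts, pts, x, cfg)


def test_constant_target_rho_undefined():
    x = np.cumsum(np.random.default_rng(3).normal(size=60))
    cids = np.where(np.arange(60) < 30, 0, 1)
    res = cross_decode(x, np.zeros(60), EmbeddingConfig(E=2, tau=-1, Tp=1),
                       clip_ids=cids)
    assert res.rho is None


def test_white_noise_target_decodes_near_zero():
    """Independent white-noise targets give |rho| <= 0.2 (20 seeds)."""
    rhos = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 600
        src = np.cumsum(rng.normal(size=n))
        tgt = rng.normal(size=n)
        cids = np.where(np.arange(n) < n // 2, 0, 1)
        res = cross_decode(src, tgt, EmbeddingConfig(E=2, tau=-1, Tp=1),
                           clip_ids=cids)
        assert res.n_valid >= 200
        rhos.append(abs(res.rho))
    assert np.mean(rhos) <= 0.2
    assert np.max(rhos) <= 0.3


def test_self_coordinate_target_decodes_well(small_dataset):
    """A target equal to one source coordinate is almost perfectly
    predictable from the embedding (dense noiseless library)."""
    clips, _, _ = small_dataset
    src = np.concatenate([c.qhat for c in clips])
    cids = np.concatenate(
        [np.full(c.n_frames, i) for i, c in enumerate(clips)]
    )
    tgt = src[:, 1]
    res = cross_decode(src, tgt, EmbeddingConfig(E=2, tau=-1, Tp=1),
                       clip_ids=cids)
    assert res.rho >= 0.95


# -- grid search ------------------------------------------------------------


def test_grid_search_single_cell_and_shape():
    rng = np.random.default_rng(4)
    x = np.cumsum(rng.normal(size=120))
    cids = np.where(np.arange(120) < 60, 0, 1)
    best, surface = grid_search(x, x, E_range=[2], tau_range=[-1],
                                Tp_range=[3], clip_ids=cids)
    assert (best.E, best.tau, best.Tp) == (2, -1, 3)
    assert surface.shape == (1, 1, 1)
    _, surf = grid_search(x, x, E_range=range(1, 4), tau_range=[-1, -2],
                          Tp_range=range(1, 3), clip_ids=cids)
    assert surf.shape == (3, 2, 2)


def test_grid_search_tie_breaks_toward_smaller_parameters(monkeypatch):
    """When several cells reach the same maximal rho, the winner is the
    smallest E, then smallest |tau|, then smallest Tp."""
    import myoreach.edm as edm_mod
    from myoreach.edm import SimplexResult

    def fake_decode(source, target, config, **kwargs):
        # every config ties at rho = 1
        return SimplexResult(np.zeros(3), np.zeros(3), 1.0, config, 3)

    monkeypatch.setattr(edm_mod, "cross_decode", fake_decode)
    x = np.arange(40, dtype=float)
    best, surface = grid_search(x, x, E_range=range(1, 4),
                                tau_range=[-2, -1], Tp_range=range(1, 3))
    assert np.all(surface == 1.0)
    assert (best.E, best.tau, best.Tp) == (1, -1, 1)


def test_config_validation():
    with pytest.raises(ValueError, match="tau"):
        EmbeddingConfig(E=2, tau=0, Tp=1)
    assert EmbeddingConfig(E=4, tau=-1, Tp=1).k == 5
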