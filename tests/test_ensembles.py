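"""Graph distances, permutation calibration at small scale, enrichment."""

import numpy as np
import pytest
from itertools import combinations

import wmintermit as wm
from wmintermit import ccg, ensembles
from wmintermit.core import EnsembleGraph


def _graph(n, edges, evaluated=None):
    adj = np.zeros((n, n), bool)
    for j, k in edges:
        adj[j, k] = adj[k, j] = True
    ev = np.ones((n, n), bool) if evaluated is None else evaluated
    np.fill_diagonal(ev, False)
    return EnsembleGraph(1, adj, ev, np.arange(n))


def test_manhattan_identity_and_hand_count():
    g1 = _graph(8, [(1, 2), (3, 4)])
    g2 = _graph(8, [(1, 2), (5, 6)])
    assert ensembles.graph_manhattan_distance(g1, g1) == 0
    assert ensembles.graph_manhattan_distance(g1, g2) == 2


def test_manhattan_equals_upper_triangle_hamming():
    rng = np.random.default_rng(0)
    n = 10
    for _ in range(5):
        e1 = [(i, j) for i in range(n) for j in range(i + 1, n)
              if rng.random() < 0.2]
        e2 = [(i, j) for i in range(n) for j in range(i + 1, n)
              if rng.random() < 0.2]
        g1, g2 = _graph(n, e1), _graph(n, e2)
        brute = sum(1 for i in range(n) for j in range(i + 1, n)
                    if g1.adjacency[i, j] != g2.adjacency[i, j])
        assert ensembles.graph_manhattan_distance(g1, g2) == brute


def test_manhattan_metric_properties():
    rng = np.random.default_rng(1)
    n = 7
    gs = []
    for _ in range(3):
        e = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.3]
        gs.append(_graph(n, e))
    d = ensembles.graph_manhattan_distance
    for a in gs:
        assert d(a, a) == 0
    for a, b in combinations(gs, 2):
        assert d(a, b) == d(b, a) >= 0
    a, b, c = gs
    assert d(a, c) <= d(a, b) + d(b, c)


def test_manhattan_respects_evaluated_mask():
    ev = np.ones((6, 6), bool)
    ev[0, 1] = ev[1, 0] = False
    g1 = _graph(6, [(0, 1), (2, 3)], evaluated=ev)
    g2 = _graph(6, [], evaluated=None)
    # the differing (0,1) edge is not jointly evaluated -> not counted
    assert ensembles.graph_manhattan_distance(g1, g2) == 1


def test_disjoint_node_sets_rejected():
    g1 = _graph(4, [])
    g2 = EnsembleGraph(1, np.zeros((4, 4), bool), np.ones((4, 4), bool),
                       np.arange(10, 14))
    with pytest.raises(ValueError):
        ensembles.graph_manhattan_distance(g1, g2)


def _session_raster(seed, condition_specific, n_units=10, per_cond=8,
                    sync_rate=1.5):
    cfg = wm.SimConfig(n_units=n_units, n_trials_per_condition=per_cond,
                       tuning_gain=0.0, evoked_gain=0.0,
                       ensemble_pairs_per_condition=3,
                       condition_specific_ensembles=condition_specific,
                       sync_rate_hz=sync_rate, delay_range_ms=(1400, 1400),
                       seed=seed)
    spikes, trials, truth = wm.simulate_session(cfg)
    raster = ccg.delay_raster_from_spikes(spikes, trials,
                                          unit_ids=np.arange(n_units))
    return raster, trials, truth


def test_condition_specific_ensembles_detected_by_distance():
    raster, trials, truth = _session_raster(5, condition_specific=True,
                                            per_cond=12)
    pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    res = ensembles.manhattan_null_zscore(
        raster, trials.cue_location.to_numpy(), pairs, n_perm=12, seed=0)
    assert res.z > 1.645


def test_shared_ensembles_distance_at_null_level():
    raster, trials, _ = _session_raster(6, condition_specific=False)
    pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    res = ensembles.manhattan_null_zscore(
        raster, trials.cue_location.to_numpy(), pairs, n_perm=12, seed=0)
    assert abs(res.z) < 2.5


def test_rate_matched_uses_within_group_pairs_only():
    raster, trials, _ = _session_raster(7, condition_specific=True)
    pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    res = ensembles.rate_matched_distance(
        raster, trials.cue_location.to_numpy(), pairs, n_perm=5, seed=0)
    assert len(res.per_condition_pair) == 12
    for c1, c2 in res.per_condition_pair:
        assert (c1 <= 4 and c2 <= 4) or (c1 >= 5 and c2 >= 5)


def test_enrichment_independent_assignment_near_one():
    """Ensembles assigned independently of tuning: conjunction at chance."""
    ratios = []
    for seed in range(4):
        cfg = wm.SimConfig(n_units=12, n_trials_per_condition=10,
                           tuning_gain=1.5, tuning_in_off=True,
                           ensemble_pairs_per_condition=3,
                           ensembles_match_tuning=False, seed=40 + seed)
        spikes, trials, truth = wm.simulate_session(cfg)
        raster = ccg.delay_raster_from_spikes(spikes, trials,
                                              unit_ids=np.arange(12))
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        edge = ccg.ccg_condition_edges(raster, trials.cue_location.to_numpy(),
                                       pairs)
        try:
            enr = ensembles.joint_selectivity_enrichment(
                spikes, trials, pairs, edge, unit_ids=raster.unit_ids)
            ratios.append(enr["ratio"])
        except ValueError:
            continue
    assert ratios, "no session produced a defined enrichment"
    # independence: mean near 1 (broad CI at this scale)
    assert np.mean(ratios) < 3.0


def test_enrichment_matched_assignment_elevated():
    # same-preference pairs fire at elevated rates in their condition, which
    # raises the CCG baseline; sync is set high enough to clear 7 SDs there
    cfg = wm.SimConfig(n_units=16, n_trials_per_condition=24,
                       tuning_gain=2.5, tuning_in_off=True,
                       ensemble_pairs_per_condition=2,
                       ensembles_match_tuning=True, sync_rate_hz=4.0, seed=50)
    spikes, trials, truth = wm.simulate_session(cfg)
    raster = ccg.delay_raster_from_spikes(spikes, trials,
                                          unit_ids=np.arange(16))
    pairs = [(i, j) for i in range(16) for j in range(i + 1, 16)]
    edge = ccg.ccg_condition_edges(raster, trials.cue_location.to_numpy(),
                                   pairs)
    enr = ensembles.joint_selectivity_enrichment(spikes, trials, pairs, edge,
                                                 unit_ids=raster.unit_ids)
    assert enr["ratio"] > 2.0
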