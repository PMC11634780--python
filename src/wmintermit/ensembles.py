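"""Condition-specific ensemble graphs and their comparison across cues.

Significant jitter-corrected CCGs define, per cue condition, a binary graph
over the CCG-eligible units. Graphs for two conditions are compared by the
Manhattan distance: the number of edges whose presence differs, counted over
pairs evaluable in both conditions. The session statistic is the mean
distance over all 28 condition pairs; its null distribution comes from
re-running the entire CCG -> significance -> graph -> distance pipeline with
cue labels permuted among the trials of each condition pair, and the
observed mean is z-scored against that null. A firing-rate-matched control
restricts comparisons to within the rate-homogeneous location groups 1-4 and
5-8, and a joint-selectivity analysis asks whether pairs that respond to the
same cue during the evoked response are functionally connected to that cue
more often than independence predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .ccg import ccg_condition_edges
from .core import BinaryRaster, EnsembleGraph

__all__ = ["EnsembleGraph", "graph_manhattan_distance", "build_graphs",
           "manhattan_null_zscore", "rate_matched_distance",
           "joint_selectivity_enrichment", "DistanceResult"]


@dataclass
class DistanceResult:
    observed: float             # mean Manhattan distance over condition pairs
    null: np.ndarray            # permutation null of the mean distance
    z: float
    per_condition_pair: dict    # (c1, c2) -> observed distance


def graph_manhattan_distance(g1: EnsembleGraph, g2: EnsembleGraph) -> int:
    """Number of edges whose presence differs, over jointly evaluated pairs."""
    if not np.array_equal(g1.unit_ids, g2.unit_ids):
        raise ValueError("graphs must share a node set")
    both = np.triu(g1.evaluated & g2.evaluated, 1)
    return int((g1.adjacency != g2.adjacency)[both].sum())


def build_graphs(edge_result: dict, n_units: int, unit_ids=None):
    """EnsembleGraph per condition from a ``ccg_condition_edges`` result."""
    unit_ids = np.arange(n_units) if unit_ids is None else np.asarray(unit_ids)
    pairs = edge_result["pairs"]
    graphs = {}
    for ci, c in enumerate(edge_result["conditions"]):
        adj = np.zeros((n_units, n_units), dtype=bool)
        ev = np.zeros((n_units, n_units), dtype=bool)
        for (j, k), s, e in zip(pairs, edge_result["significant"][:, ci],
                                edge_result["evaluated"][:, ci]):
            adj[j, k] = adj[k, j] = bool(s)
            ev[j, k] = ev[k, j] = bool(e)
        graphs[int(c)] = EnsembleGraph(int(c), adj, ev, unit_ids)
    return graphs


def _pairwise_distances(edge_result: dict, condition_pairs) -> dict:
    sig = edge_result["significant"]
    ev = edge_result["evaluated"]
    cond_index = {int(c): i for i, c in enumerate(edge_result["conditions"])}
    out = {}
    for c1, c2 in condition_pairs:
        i1, i2 = cond_index[c1], cond_index[c2]
        both = ev[:, i1] & ev[:, i2]
        out[(c1, c2)] = int((sig[both, i1] != sig[both, i2]).sum())
    return out


def manhattan_null_zscore(raster: BinaryRaster, trial_conditions, pairs,
                          n_perm: int = 50, seed: int = 0,
                          condition_pairs=None, window_ms: int = 25,
                          labeled_ms_per_trial=None) -> DistanceResult:
    """Observed vs label-permuted mean Manhattan distance for one session.

    Each permutation shuffles the cue-location labels across all trials at
    once and re-runs the entire CCG -> significance -> graph -> distance
    pipeline, so every null draw carries the same cross-condition-pair
    correlation structure as the observed statistic (the 28 distances share
    graphs). Per-condition-pair independent shuffles would underestimate
    the null variance of the mean and overdisperse the z-score.
    """
    from .ccg import make_fft_cache
    trial_conditions = np.asarray(trial_conditions)
    conditions = np.unique(trial_conditions)
    if condition_pairs is None:
        condition_pairs = list(combinations([int(c) for c in conditions], 2))
    used = sorted({c for cp in condition_pairs for c in cp})

    cache = make_fft_cache(raster)
    obs_edges = ccg_condition_edges(raster, trial_conditions, pairs,
                                    conditions=used, window_ms=window_ms,
                                    labeled_ms_per_trial=labeled_ms_per_trial,
                                    cache=cache)
    obs_d = _pairwise_distances(obs_edges, condition_pairs)
    observed = float(np.mean(list(obs_d.values())))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pool = np.flatnonzero(np.isin(trial_conditions, used))
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(pool)
        subsets, start = {}, 0
        for c in used:
            m = int((trial_conditions == c).sum())
            subsets[c] = perm[start:start + m]
            start += m
        e = ccg_condition_edges(raster, trial_conditions, pairs,
                                conditions=used, window_ms=window_ms,
                                labeled_ms_per_trial=labeled_ms_per_trial,
                                trial_subsets=subsets, cache=cache)
        null[p] = np.mean(list(_pairwise_distances(
            e, condition_pairs).values()))
    sd = null.std(ddof=1)
    z = float((observed - null.mean()) / sd) if sd > 0 else np.nan
    return DistanceResult(observed=observed, null=null, z=z,
                          per_condition_pair=obs_d)


def rate_matched_distance(raster: BinaryRaster, trial_conditions, pairs,
                          groups=((1, 2, 3, 4), (5, 6, 7, 8)),
                          n_perm: int = 50, seed: int = 0,
                          window_ms: int = 25,
                          labeled_ms_per_trial=None) -> DistanceResult:
    """Manhattan statistic confined to within-group condition pairs.

    Groups default to the rate-homogeneous cue-location subsets 1-4 and 5-8
    (6 condition pairs per group, 12 in total); the same permutation null
    machinery applies.
    """
    cps = []
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 conditions")
        cps.extend(combinations(g, 2))
    return manhattan_null_zscore(raster, trial_conditions, pairs,
                                 n_perm=n_perm, seed=seed,
                                 condition_pairs=cps, window_ms=window_ms,
                                 labeled_ms_per_trial=labeled_ms_per_trial)


def joint_selectivity_enrichment(spikes, trials, pairs, edge_result,
                                 unit_ids=None, alpha: float = 0.05,
                                 evoked_window=(0.0, 400.0)):
    """Conjunction of evoked co-selectivity and delay connectivity.

    Per cue location c: P_sel(c) is the fraction of pairs whose two units are
    both cue-selective (one-way ANOVA on [0, 400)-ms evoked rates, P < alpha)
    with preferred location c; P_conn(c) the fraction with a significant CCG
    in c; P_joint(c) the fraction satisfying both. The enrichment ratio is
    mean_c P_joint / mean_c (P_sel * P_conn); 1 under independence.

    Returns dict with the ratio, per-location table and the marginals.
    """
    from .preprocess import _epoch_counts
    all_units, rate_all = _epoch_counts(spikes, trials, *evoked_window)
    if unit_ids is None:  # pairs index this unit ordering
        unit_ids = all_units
    row = {u: i for i, u in enumerate(all_units)}
    rate = np.stack([rate_all[row[u]] if u in row
                     else np.zeros(rate_all.shape[1])
                     for u in np.asarray(unit_ids)])
    cues = trials["cue_location"].to_numpy()
    conds = edge_result["conditions"]
    n_units = len(unit_ids)

    selective = np.zeros(n_units, dtype=bool)
    pref = np.zeros(n_units, dtype=int)
    for i in range(n_units):
        groups = [rate[i, cues == c] for c in conds]
        if any(len(g) < 2 for g in groups) or np.ptp(rate[i]) == 0:
            continue
        p = stats.f_oneway(*groups).pvalue
        if np.isfinite(p) and p < alpha:
            selective[i] = True
            pref[i] = conds[int(np.argmax([g.mean() for g in groups]))]

    pairs = np.asarray(pairs)
    sig = edge_result["significant"]
    p_sel, p_conn, p_joint = [], [], []
    for ci, c in enumerate(conds):
        both_sel = (selective[pairs[:, 0]] & selective[pairs[:, 1]]
                    & (pref[pairs[:, 0]] == c) & (pref[pairs[:, 1]] == c))
        conn = sig[:, ci]
        p_sel.append(both_sel.mean())
        p_conn.append(conn.mean())
        p_joint.append((both_sel & conn).mean())
    p_sel, p_conn, p_joint = map(np.asarray, (p_sel, p_conn, p_joint))
    expected = float(np.mean(p_sel * p_conn))
    if expected == 0:
        raise ValueError("independence expectation is zero; session excluded")
    ratio = float(np.mean(p_joint)) / expected
    with np.errstate(invalid="ignore", divide="ignore"):
        per_loc = np.where(p_sel * p_conn > 0, p_joint / (p_sel * p_conn),
                           np.nan)
    return {"ratio": ratio, "p_sel": p_sel, "p_conn": p_conn,
            "p_joint": p_joint, "per_location_ratio": per_loc,
            "conditions": np.asarray(conds)}
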