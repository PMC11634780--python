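"""Session-level orchestration: simulate/load -> decode -> states -> models.

``run_session`` wires the stages end to end with seeds split from one master
seed; the expensive 50-shuffle decoding ensemble is computed once and shared
by the state labeling. ``run_cohort`` aggregates session summaries with
across-session sign-rank tests. All report entries are plain Python scalars
or lists so reports serialize to JSON directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
from scipy import stats

from . import betamix, ccg, decode, ensembles, preprocess, states, tuning
from .core import DELAY_WINDOW, LABEL_ON, LABEL_OFF
from .synthetic import SimConfig, simulate_session

__all__ = ["run_session", "run_cohort", "config_hash"]


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _seed_ints(master: int, n: int):
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_session(config: SimConfig, n_shuffles: int = 50, n_perm: int = 25,
                include_states: bool = True, include_ccg: bool = True,
                include_betamix: bool = True, include_state_ccg: bool = False,
                include_aux: bool = False, max_ccg_units: int = 24) -> dict:
    """Run the full synthetic-session analysis; returns a JSON-able report.

    ``max_ccg_units`` caps the pair count for the permutation-heavy ensemble
    comparison (units are taken in id order from the CCG-eligible set).
    """
    seeds = _seed_ints(config.seed, 8)
    spikes, trials, truth = simulate_session(config)
    report = {"config_hash": config_hash(config), "seed": config.seed,
              "n_units": config.n_units, "n_trials": len(trials)}

    total_time_s = trials["go_time_ms"].sum() / 1000.0 + 0.4 * len(trials)
    analysis_units, ccg_units = preprocess.filter_units(
        spikes, total_time_s, min_total_spikes=0, min_rate_hz=1.0)

    rates_z = preprocess.smooth_and_zscore_rates(spikes, trials,
                                                 unit_ids=analysis_units)
    rates_hz = preprocess.smooth_and_zscore_rates(spikes, trials,
                                                  unit_ids=analysis_units,
                                                  zscore=False)

    conf = decode.loo_confidence(rates_z, trials, seed=seeds[0])
    report["delay_accuracy"] = conf.delay_mean_accuracy()
    cues = trials.set_index("trial_id").loc[conf.trial_ids,
                                            "cue_location"].to_numpy()
    dmask = (conf.time_ms >= DELAY_WINDOW[0]) & (conf.time_ms < DELAY_WINDOW[1])
    report["per_condition_accuracy"] = {
        int(c): float(np.nanmean(conf.accuracy[cues == c][:, dmask]))
        for c in np.unique(cues)}

    if include_betamix:
        vals, tids, conds = [], [], []
        for i, t in enumerate(conf.trial_ids):
            v = conf.values[i, dmask]
            v = v[np.isfinite(v)]
            vals.append(v)
            tids.append(np.full(v.size, t))
            conds.append(np.full(v.size, cues[i]))
        report["delta_bits_per_trial"] = betamix.cv_model_comparison(
            np.concatenate(vals), np.concatenate(tids), k=4, seed=seeds[1],
            conditions=np.concatenate(conds))

    segments = None
    if include_states:
        null = states.build_null_confidence(rates_z, trials,
                                            n_shuffles=n_shuffles,
                                            seed=seeds[0],
                                            window=states.LABEL_SPAN)
        z = states.zscore_confidence(conf, null)
        segments = states.label_states(z, null)
        summary = states.summarize_states(segments, trials)
        for lab in ("On", "Off", "incorrect"):
            report[f"{lab.lower()}_mean_per_trial"] = summary[lab]["mean_per_trial"]
            report[f"{lab.lower()}_mean_duration_ms"] = summary[lab]["mean_duration_ms"]
        det = segments.timepoint_labels(conf.trial_ids, conf.time_ms)
        tru = truth.state_labels_on_grid(conf.trial_ids, conf.time_ms)
        span = (conf.time_ms >= 0) & (conf.time_ms < 1400)
        report["state_balanced_accuracy"] = states.balanced_state_accuracy(
            det[:, span], tru[:, span])

        pref_cond = tuning.preferred_condition_from_confidence(conf, trials)
        prof = tuning.population_rate_profile(rates_hz, trials, segments,
                                              pref_cond)
        report["population_on_delay_z"] = prof["on_delay_mean_z"]
        report["population_off_delay_z"] = prof["off_delay_mean_z"]

        var = tuning.partition_rate_variance(rates_hz, trials, segments)
        if len(var):
            report["cue_var_on_pct"] = float(var["cue_var_on"].mean() * 100)
            report["cue_var_off_pct"] = float(var["cue_var_off"].mean() * 100)

    if include_ccg:
        use_units = np.asarray(ccg_units)[:max_ccg_units]
        raster = ccg.delay_raster_from_spikes(spikes, trials,
                                              unit_ids=use_units)
        uidx = {u: i for i, u in enumerate(raster.unit_ids)}
        pairs = [(i, j) for i in range(len(use_units))
                 for j in range(i + 1, len(use_units))]
        cond_arr = trials["cue_location"].to_numpy()
        edge_res = ccg.ccg_condition_edges(raster, cond_arr, pairs)
        report["n_significant_ccgs"] = int(edge_res["significant"].sum())
        report["pct_significant_pairs"] = float(
            edge_res["significant"].any(axis=1).mean() * 100)

        true_pairs = {c: [(uidx[j], uidx[k]) for j, k in prs
                          if j in uidx and k in uidx]
                      for c, prs in truth.ensemble_pairs.items()}
        hits = total = 0
        pset = {tuple(p): n for n, p in enumerate(pairs)}
        for c, prs in true_pairs.items():
            ci = int(c) - 1
            for j, k in prs:
                key = (min(j, k), max(j, k))
                if key in pset:
                    total += 1
                    hits += bool(edge_res["significant"][pset[key], ci])
        report["ensemble_detection_rate"] = hits / total if total else np.nan

        dist = ensembles.manhattan_null_zscore(raster, cond_arr, pairs,
                                               n_perm=n_perm, seed=seeds[2])
        report["manhattan_z_full"] = dist.z
        report["manhattan_observed"] = dist.observed

        try:
            enr = ensembles.joint_selectivity_enrichment(
                spikes, trials, pairs, edge_res, unit_ids=raster.unit_ids)
            report["enrichment_ratio"] = enr["ratio"]
        except ValueError as err:  # degenerate session: no conjunction basis
            report["enrichment_ratio"] = float("nan")
            report["enrichment_note"] = str(err)

        if include_state_ccg and segments is not None:
            for which in ("On", "Off"):
                sr = ccg.state_restricted_raster(raster, segments, which)
                lab = segments.timepoint_labels(
                    raster.trial_ids,
                    raster.window[0] + np.arange(raster.n_bins))
                code = LABEL_ON if which == "On" else LABEL_OFF
                per_trial = (lab == code).sum(axis=1).astype(float)
                d = ensembles.manhattan_null_zscore(
                    sr, cond_arr, pairs, n_perm=max(n_perm // 2, 5),
                    seed=seeds[3], labeled_ms_per_trial=per_trial)
                report[f"manhattan_z_{which.lower()}"] = d.z

    if include_aux:
        from . import controls, synthetic
        eyes, ms_truth = synthetic.simulate_eye_traces(
            len(trials), msacc_rate_hz=1.2, seed=seeds[4])
        det = controls.detect_microsaccades(eyes)
        n_true = sum(v.size for v in ms_truth.values())
        hits = sum(1 for tr, tv in ms_truth.items() for t in tv
                   if det[tr].size and np.min(np.abs(det[tr] - t)) < 25)
        report["microsaccade_hit_rate"] = hits / n_true if n_true else np.nan
        rng = np.random.default_rng(seeds[5])
        report["noise_sd_unit_variance"] = preprocess.estimate_noise_sd(
            rng.normal(size=200_000))
        if segments is not None:
            try:
                ph = synthetic.simulate_phases(
                    2, [8.0, 16.0, 32.0], kappa=0.0, seed=seeds[6],
                    n_trials=len(trials))
                z = controls.phase_state_association(ph, segments,
                                                     n_perm=200,
                                                     seed=seeds[6])
                report["phase_state_z_mean"] = float(np.mean(z))
            except ValueError:
                report["phase_state_z_mean"] = np.nan
    return report


def run_cohort(configs, **session_kwargs) -> dict:
    """Run several sessions and aggregate with two-sided sign-rank tests."""
    reports = [run_session(c, **session_kwargs) for c in configs]
    out = {"sessions": reports, "n_sessions": len(reports)}

    def signrank(key):
        vals = np.array([r[key] for r in reports if key in r
                         and np.isfinite(r.get(key, np.nan))])
        if vals.size < 2:
            return {"n": int(vals.size), "p": np.nan,
                    "mean": float(vals.mean()) if vals.size else np.nan}
        stat = stats.wilcoxon(vals, alternative="two-sided")
        return {"n": int(vals.size), "p": float(stat.pvalue),
                "mean": float(vals.mean())}

    for key in ("manhattan_z_full", "manhattan_z_on", "manhattan_z_off"):
        if any(key in r for r in reports):
            out[f"signrank_{key}"] = signrank(key)
    if any("enrichment_ratio" in r for r in reports):
        vals = np.array([r["enrichment_ratio"] - 1.0 for r in reports
                         if np.isfinite(r.get("enrichment_ratio", np.nan))])
        if vals.size >= 2 and np.ptp(vals) > 0:
            out["signrank_enrichment_vs_1"] = {
                "n": int(vals.size),
                "p": float(stats.wilcoxon(vals).pvalue),
                "mean_ratio": float(vals.mean() + 1.0)}
    return out
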