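"""End-to-end orchestration: generate or load data, analyze, report.

A run is fully specified by a config mapping plus a seed; reports embed
both (and the package version) so any output can be regenerated exactly.
Reports are JSON with stable key order; tables are flat CSVs.  Each filter
stage logs how many records it excluded, since silent data loss is the
main reproducibility hazard in this kind of analysis.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from turnbias import __version__
from turnbias import calcium as ca
from turnbias import metrics, null_models
from turnbias import effects
from turnbias import synthetic

__all__ = [
    "run_behavior_pipeline",
    "run_calcium_pipeline",
    "calibrate_behavior_tests",
    "write_report",
]

BEHAVIOR_DEFAULTS = {
    "n_larvae": 60,
    "trials_per_larva": 4,
    "bias_strength": 0.5,
    "lock_prob": 0.814,
    "lock_index": None,        # overrides lock_prob when given
    "n_sims_mc": 10_000,
    "n_sims_permutation": 100_000,
    "tail": 0.10,
    "histogram_bin_width": 4.0,
    "min_turns": 3,
}

CALCIUM_DEFAULTS = {
    "n_neurons": 100,
    "n_trials": 3,
    "frame_rate_hz": 0.96,
    "epoch_plan": [["light", 60.0], ["dark", 60.0], ["light", 60.0]],
    "frac_off": 0.15,
    "frac_on": 0.05,
    "noise_sd": 2.0,
    "average_trials": True,
}


def _merge(defaults: dict, config: dict | None) -> dict:
    cfg = dict(defaults)
    if config:
        unknown = set(config) - set(defaults) - {"turns_csv", "traces_csv", "epochs_csv"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    return cfg


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(obj) else float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, out_dir: str | Path, name: str) -> Path:
    """Serialize a report deterministically (sorted keys, fixed layout)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(_json_safe(report), indent=2, sort_keys=True) + "\n")
    return path


def _load_or_generate_turns(cfg: dict, seed: int):
    if cfg.get("turns_csv"):
        turns = pd.read_csv(cfg["turns_csv"])
        truth = None
    else:
        sconfig = synthetic.CohortConfig(
            n_larvae=cfg["n_larvae"],
            trials_per_larva=cfg["trials_per_larva"],
            bias_strength=cfg["bias_strength"],
            lock_prob=cfg["lock_prob"],
            seed=seed,
        )
        turns, truth = synthetic.generate_turn_cohort(sconfig)
    return turns, truth


def run_behavior_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the behavioral analysis end to end and return the report dict.

    Input is either a turn-event CSV (``turns_csv`` config key) or a
    synthetic cohort generated from the config.  Stages: per-larva bias
    table with inclusion filters -> Monte-Carlo bias test against the
    persistence-matched unbiased null -> one-sample permutation test of the
    mean Match Index against 0.5 -> expected %rightward histogram ->
    effect sizes for the left-vs-right group contrast.
    """
    cfg = _merge(BEHAVIOR_DEFAULTS, config)
    if cfg["lock_index"] is not None:
        cfg["lock_prob"] = null_models.lock_to_prob(cfg["lock_index"])
    turns, truth = _load_or_generate_turns(cfg, seed)

    cohort = metrics.turn_cohort_table(turns, min_turns=cfg["min_turns"])
    included = cohort[cohort["included"]]
    log = {
        "n_larvae_total": int(len(cohort)),
        "n_excluded_min_turns": int((~cohort["included"]).sum()),
        "n_excluded_match_index": int(included["match_index"].isna().sum()),
    }

    report = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "mode": "behavior",
        "exclusions": log,
    }

    if included.empty:
        report["empty"] = True
        report["reason"] = "no larvae passed the minimum-turn filter"
        if out_dir is not None:
            cohort.to_csv(Path(out_dir) / "cohort_bias.csv", index=False)
            write_report(report, out_dir, "behavior_report.json")
        return report

    count_cols = sorted(
        (c for c in cohort.columns if c.startswith("n_turns_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    counts = included[count_cols].to_numpy(dtype=np.int64)
    observed = included["mean_pct_rightward"].to_numpy(dtype=float)

    rng = np.random.SeedSequence(seed).spawn(2)
    mc = null_models.mc_bias_test(
        observed, counts, cfg["lock_prob"],
        n_sims=cfg["n_sims_mc"], tail=cfg["tail"], seed=rng[0],
    )
    mi_table = included.dropna(subset=["match_index"])
    if len(mi_table):
        perm = null_models.permutation_match_test(
            mi_table["match_index"].to_numpy(),
            mi_table["n_valid_followups"].to_numpy(),
            n_sims=cfg["n_sims_permutation"], seed=rng[1],
        )
        perm_dict = perm.to_dict()
        perm_dict["mean_match_index_2dp"] = round(perm.observed_mean, 2)
    else:
        perm_dict = {"empty": True, "reason": "no larva had a defined Match Index"}

    hist = null_models.null_histogram(mc, cfg["histogram_bin_width"])

    # group contrast: mean %rightward of right- vs left-classified larvae
    grp_r = included.loc[included["pct_class"] == "R", "mean_pct_rightward"]
    grp_l = included.loc[included["pct_class"] == "L", "mean_pct_rightward"]
    contrast = {"n_right": int(len(grp_r)), "n_left": int(len(grp_l))}
    if len(grp_r) >= 2 and len(grp_l) >= 2:
        contrast["cohens_d"] = effects.cohens_d(grp_r, grp_l)
        contrast["rank_biserial_r"] = effects.rank_biserial_r(grp_r, grp_l)

    report.update(
        {
            "mc_bias_test": mc.to_dict(),
            "permutation_match_test": perm_dict,
            "lr_contrast": contrast,
            "match_index_denominator_convention": (
                "excluded trials are dropped from the denominator; at least "
                "2 valid follow-up trials required"
            ),
        }
    )
    if truth is not None:
        report["ground_truth_check"] = {
            "max_abs_pct_rightward_error": float(
                (
                    cohort.set_index("larva_id")["mean_pct_rightward"]
                    - truth.set_index("larva_id")["mean_pct_rightward"]
                )
                .abs()
                .max()
            )
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        turns.to_csv(out_dir / "turn_events.csv", index=False)
        cohort.to_csv(out_dir / "cohort_bias.csv", index=False)
        hist.to_csv(out_dir / "expected_histogram.csv", index=False)
        write_report(report, out_dir, "behavior_report.json")
    return report


def run_calcium_pipeline(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the calcium-imaging analysis end to end and return the report.

    Input is either trace+epoch CSVs (``traces_csv``/``epochs_csv`` keys)
    or a synthetic cohort with planted responders.  Stages: dF/F
    normalization on the trial-averaged trace -> 3S/3-frame responder
    classification -> timing metrics -> cohort summary.  When ground truth
    is available the report carries a sensitivity/specificity self-check.
    """
    cfg = _merge(CALCIUM_DEFAULTS, config)
    truth = None
    if cfg.get("traces_csv"):
        traces = pd.read_csv(cfg["traces_csv"])
        if not cfg.get("epochs_csv"):
            raise ValueError("traces_csv requires a matching epochs_csv")
        epochs = pd.read_csv(cfg["epochs_csv"])
    else:
        tconfig = synthetic.TraceConfig(
            n_neurons=cfg["n_neurons"],
            n_trials=cfg["n_trials"],
            frame_rate_hz=cfg["frame_rate_hz"],
            epoch_plan=tuple((lbl, float(d)) for lbl, d in cfg["epoch_plan"]),
            frac_off=cfg["frac_off"],
            frac_on=cfg["frac_on"],
            noise_sd=cfg["noise_sd"],
            seed=seed,
        )
        traces, epochs, truth = synthetic.generate_calcium_cohort(tconfig)

    calls = ca.classify_cohort(
        traces, epochs,
        frame_rate_hz=cfg["frame_rate_hz"],
        average_trials=cfg["average_trials"],
    )
    summary = _summary_from_calls(calls)
    report = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "mode": "calcium",
        "summary": summary,
    }
    if truth is not None:
        merged = calls.merge(truth, on="neuron_id")
        is_resp_true = merged["true_class"].isin(("OFF", "ON"))
        is_resp_called = merged["class"].isin(("OFF", "ON"))
        tp = int((is_resp_true & is_resp_called).sum())
        tn = int((~is_resp_true & ~is_resp_called).sum())
        report["self_check"] = {
            "sensitivity": tp / int(is_resp_true.sum()) if is_resp_true.any() else math.nan,
            "specificity": tn / int((~is_resp_true).sum()) if (~is_resp_true).any() else math.nan,
            "n_class_exact": int((merged["true_class"] == merged["class"]).sum()),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out_dir / "responder_calls.csv", index=False)
        write_report(report, out_dir, "calcium_report.json")
    return report


def _summary_from_calls(calls: pd.DataFrame) -> dict:
    objs = [
        ca.ResponderCall(
            neuron_id=r.neuron_id,
            cls=r["class"],
            onset_frame=int(r.onset_frame),
            time_to_half_max_s=r.time_to_half_max_s,
            returned_within_30s=bool(r.returned_within_30s),
        )
        for _, r in calls.iterrows()
    ]
    return ca.cohort_response_summary(objs)


def calibrate_behavior_tests(
    n_replicates: int = 200,
    n_larvae: int = 39,
    lock_prob: float = 0.566,
    n_sims_mc: int = 1000,
    n_sims_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I-error loop for the two behavioral tests under their nulls.

    Each replicate draws an unbiased cohort (counts from the default
    truncated-Poisson model), runs the Monte-Carlo bias test and the Match
    Index permutation test at reduced replication, and records both
    p-values.  Returns rejection rates at ``alpha`` plus the p-value
    vectors for uniformity checks.
    """
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    p_mc = np.empty(n_replicates)
    p_perm = np.empty(n_replicates)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        counts = synthetic._draw_counts(rng, ("poisson", 8.0), 3, n_larvae * 4)
        counts = counts.reshape(n_larvae, 4)
        observed = null_models.simulate_null_cohort(counts, lock_prob, seed=rng)[0]
        mc = null_models.mc_bias_test(
            observed, counts, lock_prob, n_sims=n_sims_mc, seed=rng
        )
        p_mc[r] = mc.p_value
        k = np.full(n_larvae, 3)
        mis = rng.binomial(k, 0.5) / k
        perm = null_models.permutation_match_test(
            mis, k, n_sims=n_sims_perm, seed=rng
        )
        p_perm[r] = perm.p_value
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "mc_type_i_error": float((p_mc <= alpha).mean()),
        "perm_type_i_error": float((p_perm <= alpha).mean()),
        "p_mc": p_mc,
        "p_perm": p_perm,
    }
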