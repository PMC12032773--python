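"""End-to-end orchestration: cohort generation -> preprocessing -> ERP/TF ->
statistics -> decoding, with a reproducible run manifest.

``run_experiment`` simulates a cohort (default 20 healthy subjects + 10 stroke
patients), derives per-subject slow-wave and ROI measures, runs the
102-comparison statistical plan, evaluates both decoders under the
within-/cross-subject schemes, and writes tables, topographies and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import decoding as dec
from .config import TASKS, AnalysisConfig, ExperimentConfig, PreprocConfig
from .erp_tf import average_erp, roi_power, slow_wave_amplitude, tf_power, topography
from .io_prep import EpochSet, Recording, bandpass, epoch, flip_merge, preprocess, rereference, resample
from .stats import build_comparison_table, format_mean_std
from .synthgen import SubjectProfile, make_subject_profile, simulate_session

logger = logging.getLogger(__name__)

TF_CHANNELS = ["C3", "C4", "FCz"]


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    first = sets[0]
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        time_axis=first.time_axis,
        channel_labels=list(first.channel_labels),
        trials=pd.concat([s.trials for s in sets], ignore_index=True),
        sampling_rate=first.sampling_rate,
        merged_laterality=first.merged_laterality,
        cc_ci_map=dict(first.cc_ci_map),
        n_dropped=sum(s.n_dropped for s in sets),
    )


def _condition_masks(profile: SubjectProfile, trials: pd.DataFrame):
    """(stat_group, mask) pairs: HS pools hands; SP splits affected/unaffected."""
    if profile.group == "HS":
        return [("HS", np.ones(len(trials), dtype=bool))]
    aff = (trials["hand"] == profile.affected_side).to_numpy()
    return [("USP", ~aff), ("ASP", aff)]


def compute_subject_measures(
    profile: SubjectProfile,
    recordings: list[Recording],
    pre_cfg: PreprocConfig,
    an_cfg: AnalysisConfig,
    tf_freqs: np.ndarray | None = None,
) -> tuple[list[dict], dict]:
    """Slow-wave (uV) and six ROI (dB) measures per task and moved-side group.

    Returns the tidy measure rows plus the per-(group, task) baseline-corrected
    ERP mean waveforms (channels x time) for grand averaging.
    """
    rows: dict[tuple[str, str], dict] = {}
    erp_means: dict[tuple[str, str], np.ndarray] = {}
    epoch_ledger: list[dict] = []
    for task in TASKS:
        recs = [r for r in recordings if r.meta.get("task") == task]
        erp_eps = concat_epochs([preprocess(r, pre_cfg.band_erp, pre_cfg) for r in recs])
        tf_eps = concat_epochs([preprocess(r, pre_cfg.band_tf, pre_cfg) for r in recs])
        epoch_ledger.append({
            "subject": profile.subject_id, "task": task,
            "generated": sum(len(r.events) for r in recs),
            "epoched": int(erp_eps.data.shape[0]), "dropped": int(erp_eps.n_dropped),
        })
        for group, mask in _condition_masks(profile, erp_eps.trials):
            sel_erp = erp_eps.select(mask)
            sel_tf = tf_eps.select(mask)
            erp = average_erp(sel_erp, an_cfg)
            erp_means[(group, task)] = erp.mean
            tf = tf_power(sel_tf, an_cfg, channels=TF_CHANNELS, freqs=tf_freqs)
            row = {
                "subject_id": profile.subject_id, "group": group, "task": task,
                "slow_wave_cc": slow_wave_amplitude(erp, "Cc", an_cfg),
                "slow_wave_ci": slow_wave_amplitude(erp, "Ci", an_cfg),
                "theta_me": roi_power(tf, "Theta_ME", task),
                "theta_mo": roi_power(tf, "Theta_MO", task),
            }
            for roi in ("Mu_ME", "Mu_MO", "Beta_ME", "Beta_MO"):
                for role in ("Cc", "Ci"):
                    row[f"{roi.lower()}_{role.lower()}"] = roi_power(
                        tf, roi, task, cc_ci_map=sel_erp.cc_ci_map, channel_role=role
                    )
            rows[(group, task)] = row
    return list(rows.values()), erp_means, epoch_ledger


# ---------------------------------------------------------------------------
# decoding datasets
# ---------------------------------------------------------------------------

def prepare_decoding_epochs(rec: Recording, pre_cfg: PreprocConfig) -> EpochSet:
    """Light chain for decoding: reref -> broadband filter -> resample -> epoch.

    ICA/interpolation are skipped here; hand-uncorrelated artifacts only add
    label-independent noise to the decoders.
    """
    out = rereference(rec, pre_cfg.reference_channels)
    high = min(95.0, rec.sampling_rate / 2 - 5.0)
    out = bandpass(out, 0.01, high, pre_cfg.filter_order)
    out = resample(out, pre_cfg.resample_to)
    return epoch(out, pre_cfg.epoch_window_s)


def decode_labels(profile: SubjectProfile, trials: pd.DataFrame) -> np.ndarray:
    """Class labels: left/right hand for HS, affected/unaffected side for SP."""
    if profile.group == "HS":
        return trials["hand"].to_numpy()
    return np.where(trials["hand"] == profile.affected_side, "affected", "unaffected")


def csp_dataset(epochs: EpochSet, labels: np.ndarray, cfg) -> tuple[np.ndarray, np.ndarray]:
    from scipy import signal

    sos = signal.butter(4, cfg.band, btype="bandpass", fs=epochs.sampling_rate, output="sos")
    filt = signal.sosfiltfilt(sos, epochs.data, axis=2)
    tmp = EpochSet(
        data=filt, time_axis=epochs.time_axis, channel_labels=epochs.channel_labels,
        trials=epochs.trials, sampling_rate=epochs.sampling_rate,
    )
    return dec.extract_window(tmp, cfg.window_s, cfg.channels), labels


def cnn_dataset(epochs: EpochSet, labels: np.ndarray, cfg) -> tuple[np.ndarray, np.ndarray]:
    return dec.extract_window(epochs, cfg.window_s, cfg.channels), labels


def evaluate_decoding(
    datasets: dict[str, dict], cfg: ExperimentConfig, seed: int
) -> list[dict]:
    """All 2 populations x 2 tasks x 2 decoders x 2 schemes cells.

    ``datasets[population][(subject_id, task)] = {"csp": (X, y), "cnn": (X, y)}``
    """
    dcfg = cfg.decoding
    results = []
    for population, subj_data in datasets.items():
        for task in TASKS:
            per_subj = {sid: d for (sid, t), d in subj_data.items() if t == task}
            for name in ("csp", "cnn"):
                def factory(name=name):
                    if name == "csp":
                        return dec.CSPLDADecoder(dcfg.csp)
                    any_X = next(iter(per_subj.values()))[name][0]
                    return dec.make_cnn_decoder(dcfg.cnn, any_X.shape[1], any_X.shape[2],
                                                seed=seed)

                fold_accs = []
                for sid, d in per_subj.items():
                    X, y = d[name]
                    res = dec.within_subject_cv(
                        X, y, factory, k=dcfg.within_folds,
                        test_fraction=dcfg.within_test_fraction, seed=seed,
                        mode=dcfg.within_mode, population=population, task=task,
                        decoder_name=name,
                    )
                    fold_accs.append(res.mean_accuracy)
                results.append({
                    "scheme": "within", "population": population, "task": task,
                    "decoder": name, "accuracy": float(np.mean(fold_accs)),
                    "per_subject": fold_accs, "seed": seed,
                })
                cross_in = {sid: d[name] for sid, d in per_subj.items()}
                res = dec.cross_subject_cv(
                    cross_in, factory, population=population, seed=seed,
                    n_repeats=dcfg.cross_repeats_hs,
                    n_test_subjects=dcfg.cross_test_subjects_hs,
                    task=task, decoder_name=name,
                )
                results.append({
                    "scheme": "cross", "population": population, "task": task,
                    "decoder": name, "accuracy": res.mean_accuracy,
                    "per_fold": res.fold_accuracies, "seed": seed,
                })
    return results


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def _config_hash(cfg: ExperimentConfig) -> str:
    blob = repr(asdict(cfg)).encode()  # effects tables have tuple keys
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(cfg: ExperimentConfig, out_dir: str) -> dict:
    """Run the full synthetic-cohort experiment; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    t_start = time.time()
    manifest: dict = {
        "config_hash": _config_hash(cfg), "seed": cfg.seed,
        "stages": {}, "outputs": [], "trial_ledger": [],
    }
    gen = cfg.generator
    gen.rng_seed = cfg.seed
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_hs + cfg.n_sp) % (2**31)

    measures_rows: list[dict] = []
    truth_frames: list[pd.DataFrame] = []
    datasets: dict[str, dict] = {"HS": {}, "SP": {}}
    erp_sums: dict[tuple[str, str], list] = {}

    t0 = time.time()
    for i in range(cfg.n_hs + cfg.n_sp):
        group = "HS" if i < cfg.n_hs else "SP"
        profile = make_subject_profile(group, gen, int(seeds[i]))
        recs, truth = simulate_session(profile, gen)
        truth_frames.append(truth)
        if cfg.write_brainvision:
            from .brainvision import write_brainvision

            raw_dir = os.path.join(out_dir, "raw", profile.subject_id)
            os.makedirs(raw_dir, exist_ok=True)
            for r in recs:
                write_brainvision(r, os.path.join(raw_dir, f"run{r.meta['run']}"))

        rows, erp_means, epoch_ledger = compute_subject_measures(
            profile, recs, cfg.preprocessing, cfg.analysis
        )
        manifest["trial_ledger"].extend(epoch_ledger)
        measures_rows.extend(rows)
        for key, mean in erp_means.items():
            erp_sums.setdefault(key, []).append(mean)

        if cfg.run_decoding:
            for task in TASKS:
                eps = concat_epochs([
                    prepare_decoding_epochs(r, cfg.preprocessing)
                    for r in recs if r.meta["task"] == task
                ])
                labels = decode_labels(profile, eps.trials)
                datasets[group][(profile.subject_id, task)] = {
                    "csp": csp_dataset(eps, labels, cfg.decoding.csp),
                    "cnn": cnn_dataset(eps, labels, cfg.decoding.cnn),
                }

    manifest["stages"]["simulate+measures_s"] = round(time.time() - t0, 2)

    measures = pd.DataFrame(measures_rows)
    truth = pd.concat(truth_frames, ignore_index=True)
    measures.to_csv(os.path.join(out_dir, "subject_measures.csv"), index=False)
    truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)

    t0 = time.time()
    table = build_comparison_table(measures, alpha=cfg.analysis.alpha)
    table.to_csv(os.path.join(out_dir, "stats_table.csv"), index=False)
    pretty = format_mean_std(table)
    sensorimotor = pretty[pretty["contrast"] != "FCz"]
    theta = pretty[pretty["contrast"] == "FCz"]
    sensorimotor.to_csv(os.path.join(out_dir, "table3_sensorimotor.csv"), index=False)
    theta.to_csv(os.path.join(out_dir, "table4_theta_fcz.csv"), index=False)
    manifest["stages"]["stats_s"] = round(time.time() - t0, 2)

    # topographies of the grand-average slow-wave window
    t0 = time.time()
    topo_rows = []
    for (g, task), arrs in erp_sums.items():
        grand = np.mean(arrs, axis=0)
        eps_labels = list(gen.channels)
        time_axis = np.arange(grand.shape[1]) / cfg.preprocessing.resample_to \
            + cfg.preprocessing.epoch_window_s[0]
        topo = topography(grand, time_axis, eps_labels, cfg.analysis.slow_wave_window)
        for ch, val in topo.items():
            topo_rows.append({"group": g, "task": task, "channel": ch, "value_uv": val})
    pd.DataFrame(topo_rows).to_csv(os.path.join(out_dir, "topography_slow_wave.csv"),
                                   index=False)
    manifest["stages"]["topography_s"] = round(time.time() - t0, 2)

    if cfg.run_decoding:
        t0 = time.time()
        cv = evaluate_decoding(datasets, cfg, seed=cfg.seed)
        with open(os.path.join(out_dir, "cv_results.json"), "w") as fh:
            json.dump(cv, fh, indent=2)
        cells = pd.DataFrame([{k: r[k] for k in ("scheme", "population", "task",
                                                 "decoder", "accuracy")} for r in cv])
        cells.to_csv(os.path.join(out_dir, "table5_decoding.csv"), index=False)
        manifest["stages"]["decoding_s"] = round(time.time() - t0, 2)

    manifest["outputs"] = sorted(
        f for f in os.listdir(out_dir)
        if os.path.isfile(os.path.join(out_dir, f))
    )
    manifest["total_s"] = round(time.time() - t_start, 2)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
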