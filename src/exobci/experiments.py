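"""Cohort-level validation experiments on synthetic data.

These routines drive the full pipeline at configurable problem sizes and are
used both by the test suite and by the reproduction script:

* parameter recovery — does the pipeline recover injected slow-wave and ROI
  effects from a simulated healthy-subject passive-movement cohort?
* null decoding — is decoding at chance when no effects are injected?
* PAS/VOL ordering — with between-subject SDs lower for passive than for
  voluntary movement (the published pattern), is cross-subject decoding
  better for the passive task?
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import decoding as dec
from .config import (
    POPULATION_EFFECTS,
    AnalysisConfig,
    CNNConfig,
    CSPConfig,
    GeneratorParams,
    PreprocConfig,
)
from .erp_tf import average_erp, roi_power, slow_wave_amplitude, tf_power
from .io_prep import preprocess
from .montage import CSP_CHANNELS
from .pipeline import cnn_dataset, csp_dataset, decode_labels, prepare_decoding_epochs
from .synthgen import make_subject_profile, simulate_run

ROI_MEASURES = ("theta_me", "theta_mo", "mu_me_cc", "mu_me_ci", "mu_mo_cc",
                "mu_mo_ci", "beta_me_cc", "beta_me_ci", "beta_mo_cc", "beta_mo_ci")
RECOVERY_MEASURES = ("slow_wave_cc", "slow_wave_ci") + ROI_MEASURES


def measure_one_subject(profile, task: str, run_indices, params: GeneratorParams,
                        pre_cfg: PreprocConfig, an_cfg: AnalysisConfig,
                        tf_freqs: np.ndarray) -> dict[str, float]:
    """Run the analysis pipeline on one subject's runs of one task."""
    from .pipeline import concat_epochs

    recs = [simulate_run(profile, task, i, params) for i in run_indices]
    erp_eps = concat_epochs([preprocess(r, pre_cfg.band_erp, pre_cfg) for r in recs])
    tf_eps = concat_epochs([preprocess(r, pre_cfg.band_tf, pre_cfg) for r in recs])
    erp = average_erp(erp_eps, an_cfg)
    tf = tf_power(tf_eps, an_cfg, channels=["C3", "C4", "FCz"], freqs=tf_freqs)
    out = {
        "slow_wave_cc": slow_wave_amplitude(erp, "Cc", an_cfg),
        "slow_wave_ci": slow_wave_amplitude(erp, "Ci", an_cfg),
        "theta_me": roi_power(tf, "Theta_ME", task),
        "theta_mo": roi_power(tf, "Theta_MO", task),
    }
    for roi in ("Mu_ME", "Mu_MO", "Beta_ME", "Beta_MO"):
        for role in ("Cc", "Ci"):
            out[f"{roi.lower()}_{role.lower()}"] = roi_power(
                tf, roi, task, cc_ci_map=erp_eps.cc_ci_map, channel_role=role
            )
    return out


def recovery_experiment(n_subjects: int = 20, trials_per_run: int = 20,
                        sampling_rate: float = 500.0, seed: int = 0,
                        task: str = "PAS") -> pd.DataFrame:
    """Healthy-cohort recovery of injected effects for one task.

    Returns a frame with per-measure estimated and injected cohort means.
    Estimates come from the full pipeline; injected values are the drawn
    per-subject ground truth (not the population means), so trial-level noise
    is the only error source.
    """
    params = GeneratorParams(sampling_rate=sampling_rate,
                             trials_per_run=trials_per_run, runs_per_task=1,
                             blink_rate_per_min=0.0, rng_seed=seed)
    pre = PreprocConfig(ica_enabled=False)
    an = AnalysisConfig()
    tf_freqs = np.arange(3.0, 28.5, 0.5)
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    est, inj = [], []
    run_index = 0 if task == "VOL" else 1
    for s in seeds:
        profile = make_subject_profile("HS", params, int(s))
        est.append(measure_one_subject(profile, task, [run_index], params, pre, an,
                                       tf_freqs))
        inj.append(profile.effects[(task, "any")])
    est_df, inj_df = pd.DataFrame(est), pd.DataFrame(inj)
    rows = []
    for m in RECOVERY_MEASURES:
        diffs = est_df[m] - inj_df[m]
        rows.append({
            "measure": m,
            "estimated": est_df[m].mean(),
            "injected": inj_df[m].mean(),
            "bias": diffs.mean(),
            "sem": diffs.std(ddof=1) / np.sqrt(len(diffs)),
        })
    return pd.DataFrame(rows)


def _zero_params(**kw) -> GeneratorParams:
    p = GeneratorParams(**kw)
    for key in p.effects:
        p.effects[key] = {name: (0.0, 0.0) for name in p.effects[key]}
    return p


def null_decoding_experiment(n_subjects: int = 2, trials_per_run: int = 24,
                             sampling_rate: float = 500.0, seed: int = 0):
    """CSP within-subject decoding with zero injected effects.

    Returns (n_correct, n_total) pooled over strict k-fold test predictions,
    for a binomial comparison against chance.
    """
    params = _zero_params(sampling_rate=sampling_rate, trials_per_run=trials_per_run,
                          runs_per_task=1, blink_rate_per_min=0.0, rng_seed=seed)
    pre = PreprocConfig(ica_enabled=False)
    csp_cfg = CSPConfig()
    correct = total = 0
    seeds = np.random.SeedSequence(seed + 1).generate_state(n_subjects) % (2**31)
    for s in seeds:
        profile = make_subject_profile("HS", params, int(s))
        rec = simulate_run(profile, "PAS", 1, params)
        eps = prepare_decoding_epochs(rec, pre)
        X, y = csp_dataset(eps, decode_labels(profile, eps.trials), csp_cfg)
        res = dec.within_subject_cv(X, y, lambda: dec.CSPLDADecoder(csp_cfg),
                                    k=4, seed=int(s), mode="kfold")
        n_test = len(y)  # strict k-fold partitions every trial once
        correct += round(np.mean(res.fold_accuracies) / 100.0 * n_test)
        total += n_test
    return correct, total


def ordering_effect_table() -> dict:
    """Controlled population table for the PAS-vs-VOL generalization contrast.

    Both tasks share the same population means (lateralized slow-wave, mu and
    beta effects), while the between-subject SDs are the published ones, which
    are uniformly lower for passive movement. Any cross-subject accuracy
    difference between tasks is then attributable to between-subject
    variability alone.
    """
    shared_means = {
        "slow_wave_cc": -7.29, "slow_wave_ci": -4.33,
        "mu_me_cc": -1.5, "mu_me_ci": -0.4,
        "mu_mo_cc": 0.2, "mu_mo_ci": 0.0,
        "beta_me_cc": -0.6, "beta_me_ci": -0.2,
        "beta_mo_cc": 0.1, "beta_mo_ci": 0.0,
        "theta_me": 1.5, "theta_mo": 0.0,
    }
    table = {}
    for (group, task), eff in POPULATION_EFFECTS.items():
        if group == "HS":
            table[(group, task)] = {
                name: (shared_means[name], eff[name][1]) for name in eff
            }
        else:
            table[(group, task)] = dict(eff)
    return table


def _paired_profiles(subject_seed: int, table: dict) -> dict:
    """Two profiles for one subject, differing only in between-subject SD scale.

    Common random numbers: effect = mean + sd_task * z with the standard-normal
    draw z shared between the two conditions.  Both profiles carry their draws
    under every task key and share the subject id, so simulating the same run
    yields bit-identical noise and trial order — the SD manipulation is the
    only difference between the conditions.
    """
    from .synthgen import SubjectProfile

    rng = np.random.default_rng(np.random.SeedSequence([subject_seed, 0xABCD]))
    names = list(table[("HS", "VOL")])
    z = {name: float(rng.standard_normal()) for name in names}
    out = {}
    for cond in ("VOL", "PAS"):
        drawn = {
            name: table[("HS", cond)][name][0] + table[("HS", cond)][name][1] * z[name]
            for name in names
        }
        out[cond] = SubjectProfile(
            subject_id=f"HS-{subject_seed:04d}", group="HS", affected_side="none",
            effects={("VOL", "any"): dict(drawn), ("PAS", "any"): dict(drawn)},
            seed=subject_seed,
        )
    return out


def pas_vol_ordering_experiment(n_seeds: int = 10, n_subjects: int = 8,
                                trials_per_run: int = 20,
                                sampling_rate: float = 500.0, seed: int = 0,
                                cnn_epochs: int = 15, csp_repeats: int = 3,
                                cnn_repeats: int = 1) -> pd.DataFrame:
    """Cross-subject accuracy per task and decoder, averaged over seeds.

    Paired design: subjects' effect draws are shared across tasks (common
    random numbers) and only the between-subject SDs differ, so the task
    contrast is attributable to the SD manipulation alone.  The CSP branch
    uses more train/test splits per seed than the CNN branch: splits are cheap
    for CSP and its task effect (driven by the modest mu/beta SD contrast) is
    smaller than the CNN's slow-wave-driven effect.
    """
    pre = PreprocConfig(ica_enabled=False)
    csp_cfg = CSPConfig()
    cnn_cfg = CNNConfig(f1=4, depth_multiplier=2, f2=8, temporal_kernel=51,
                        separable_kernel=9, epochs=cnn_epochs,
                        channels=list(CSP_CHANNELS))
    table = ordering_effect_table()
    rows = []
    for k in range(n_seeds):
        params = GeneratorParams(sampling_rate=sampling_rate,
                                 trials_per_run=trials_per_run, runs_per_task=1,
                                 blink_rate_per_min=0.0, rng_seed=seed + 1000 * k)
        params.effects = table
        subj_seeds = np.random.SeedSequence(seed + k).generate_state(n_subjects) % (2**31)
        data = {"VOL": {}, "PAS": {}}
        for s in subj_seeds:
            profiles = _paired_profiles(int(s), table)
            for cond, profile in profiles.items():
                # same (task, run) for both conditions -> identical noise
                rec = simulate_run(profile, "VOL", 0, params)
                eps = prepare_decoding_epochs(rec, pre)
                labels = decode_labels(profile, eps.trials)
                data[cond][profile.subject_id] = {
                    "csp": csp_dataset(eps, labels, csp_cfg),
                    "cnn": cnn_dataset(eps, labels, cnn_cfg),
                }
        for task in ("VOL", "PAS"):
            for name in ("csp", "cnn"):
                def factory(name=name):
                    if name == "csp":
                        return dec.CSPLDADecoder(csp_cfg)
                    any_X = next(iter(data[task].values()))["cnn"][0]
                    return dec.make_cnn_decoder(cnn_cfg, any_X.shape[1],
                                                any_X.shape[2], seed=seed + k)

                res = dec.cross_subject_cv(
                    {sid: d[name] for sid, d in data[task].items()}, factory,
                    population="HS", seed=seed + k,
                    n_repeats=csp_repeats if name == "csp" else cnn_repeats,
                    n_test_subjects=2, task=task, decoder_name=name,
                )
                rows.append({"seed": k, "task": task, "decoder": name,
                             "accuracy": res.mean_accuracy})
    return pd.DataFrame(rows)
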