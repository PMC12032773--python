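"""The 102-comparison statistical plan with Benjamini-Hochberg FDR control.

Each cell of the report tables is a paired change-score test: slow-wave and
ROI measures are per-subject baseline-relative quantities, so the Cc and Ci
columns are one-sample t-tests against zero and the Cc-Ci column is a paired
difference test.  All 102 p-values form a single BH-FDR family; significance
is decided on q < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import GROUPS, TASKS

SENSORIMOTOR_MEASURES = ("SlowWave", "Mu_ME", "Mu_MO", "Beta_ME", "Beta_MO")
THETA_MEASURES = ("Theta_ME", "Theta_MO")
CONTRASTS = ("Cc", "Ci", "Cc-Ci")

#: measure name -> column of the per-subject measures frame
MEASURE_COLUMNS = {
    "SlowWave": "slow_wave", "Mu_ME": "mu_me", "Mu_MO": "mu_mo",
    "Beta_ME": "beta_me", "Beta_MO": "beta_mo",
    "Theta_ME": "theta_me", "Theta_MO": "theta_mo",
}


def comparison_plan() -> list[tuple[str, str, str, str]]:
    """All (group, task, measure, contrast) cells: 3*2*(5*3) + 3*2*2 = 102."""
    plan = []
    for group in GROUPS:
        for task in TASKS:
            for measure in SENSORIMOTOR_MEASURES:
                for contrast in CONTRASTS:
                    plan.append((group, task, measure, contrast))
            for measure in THETA_MEASURES:
                plan.append((group, task, measure, "FCz"))
    return plan


@dataclass
class ContrastResult:
    mean: float
    std: float
    t: float
    p: float
    degenerate: bool = False


def paired_contrast(values: np.ndarray) -> ContrastResult:
    """One-sample t-test of per-subject change scores against zero (two-sided).

    Zero-variance inputs are flagged degenerate and reported as p = 1 rather
    than raising, so null simulations remain runnable.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing/non-finite values")
    mean = float(values.mean())
    std = float(values.std(ddof=1))
    if std == 0.0:
        return ContrastResult(mean=mean, std=0.0, t=0.0, p=1.0, degenerate=True)
    res = sps.ttest_1samp(values, 0.0)
    return ContrastResult(mean=mean, std=std, t=float(res.statistic), p=float(res.pvalue))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    return q


def build_comparison_table(measures: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the full statistical plan on a tidy per-subject measures frame.

    ``measures`` columns: subject_id, group (HS/USP/ASP), task (VOL/PAS), and
    one column per measure suffixed _cc / _ci (theta_me / theta_mo unsuffixed,
    they live at FCz).  Returns one row per comparison with t, p, q and the
    q < alpha significance flag; missing cells raise with the absent combos.
    """
    rows = []
    missing = []
    for group, task, measure, contrast in comparison_plan():
        sub = measures[(measures["group"] == group) & (measures["task"] == task)]
        col = MEASURE_COLUMNS[measure]
        if contrast == "FCz":
            colnames = [col]
        elif contrast == "Cc":
            colnames = [f"{col}_cc"]
        elif contrast == "Ci":
            colnames = [f"{col}_ci"]
        else:
            colnames = [f"{col}_cc", f"{col}_ci"]
        if len(sub) < 2 or any(c not in measures.columns for c in colnames):
            missing.append((group, task, measure, contrast))
            continue
        if contrast == "Cc-Ci":
            vals = (sub[colnames[0]] - sub[colnames[1]]).to_numpy()
        else:
            vals = sub[colnames[0]].to_numpy()
        res = paired_contrast(vals)
        rows.append({
            "group": group, "task": task, "measure": measure, "contrast": contrast,
            "n_subjects": len(sub), "mean": res.mean, "std": res.std,
            "t": res.t, "p": res.p, "degenerate": res.degenerate,
        })
    if missing:
        raise ValueError(f"missing measure cells: {missing}")
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    order = {g: i for i, g in enumerate(GROUPS)}
    torder = {t: i for i, t in enumerate(TASKS)}
    morder = {m: i for i, m in enumerate(SENSORIMOTOR_MEASURES + THETA_MEASURES)}
    corder = {c: i for i, c in enumerate(CONTRASTS + ("FCz",))}
    table = table.sort_values(
        by=["group", "task", "measure", "contrast"],
        key=lambda s: s.map({"group": order, "task": torder,
                             "measure": morder, "contrast": corder}[s.name]),
    ).reset_index(drop=True)
    return table


def format_mean_std(table: pd.DataFrame) -> pd.DataFrame:
    """Report-style view: 'mean +/- std' strings plus q-values."""
    out = table.copy()
    out["mean_std"] = [f"{m:.2f} ± {s:.2f}" for m, s in zip(out["mean"], out["std"])]
    out["q_value"] = [f"{q:.2e}" if q < 0.01 else f"{q:.2f}" for q in out["q"]]
    return out[["group", "task", "measure", "contrast", "mean_std", "q_value", "significant"]]
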