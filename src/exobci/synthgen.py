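"""Synthetic event-locked EEG sessions with injectable, recoverable neural effects.

Each simulated session reproduces the study design: four runs (two voluntary,
two passive), 80 cued hand-movement trials per run (40 left / 40 right), with
a 0.5 s cue lead, 2 s movement and 3 s rest.  Per-subject effect magnitudes
are drawn from group-level normal distributions whose means and SDs default
to the published group summary statistics, and are injected as:

* an additive slow-wave potential at the motor channel contralateral (Cc) and
  ipsilateral (Ci) to the moved hand, plateauing over 0.4-1.9 s;
* a frontal-midline theta power change at FCz around movement onset and offset;
* mu (8-13 Hz) and beta (15-28 Hz) event-related desynchronization during
  movement and rebound synchronization after movement offset, implemented as
  multiplicative envelopes on ongoing narrowband oscillators so that baseline
  power is nonzero (as dB baseline correction requires).

Background activity is 1/f noise plus white sensor noise; optional stereotyped
frontal blinks occur at a Poisson rate.  Spatial mixing uses fixed Gaussian
scalp maps centered on C3/C4/FCz.  Signals are emitted as if recorded against
an FCz reference (the FCz row is zero until re-referencing).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import GeneratorParams
from .io_prep import Event, Recording
from .montage import gaussian_scalp_map

TASK_LIST = ("VOL", "PAS")

# oscillator bands coincide with the ROI frequency windows
OSC_BANDS = {"theta": (3.0, 7.0), "mu": (8.0, 13.0), "beta": (15.0, 28.0)}

# envelope plateaus (seconds relative to movement onset). Plateaus extend a
# margin beyond the analysis ROI windows so wavelet temporal smearing does not
# bias the in-window mean.
THETA_ME_PLATEAU = (-0.20, 0.80)   # ROI #1: 0.1-0.5 s
THETA_MO_PLATEAU = (1.70, 2.80)    # ROI #2: 2.0-2.5 s
MU_ME_PLATEAU = (-0.20, 2.30)      # ROI #3: 0.0-2.0 s
MU_MO_PLATEAU = (3.00, 4.40)       # ROI #4: 3.2-4.2 s
BETA_ME_PLATEAU = (0.42, 2.08)     # ROI #5: 0.5-2.0 s
BETA_MO_PLATEAU = {"VOL": (2.52, 3.68), "PAS": (2.12, 3.28)}  # ROI #6
SLOW_PLATEAU = (0.4, 1.9)
SLOW_RAMP = 0.3
ENV_RAMP = {"theta": 0.15, "mu": 0.15, "beta": 0.04}


@dataclass
class SubjectProfile:
    """One simulated participant with drawn per-subject effect magnitudes.

    ``effects[(task, side_cat)]`` maps effect names (slow_wave_cc, mu_me_ci,
    theta_me, ...) to the drawn values; side_cat is ``"any"`` for healthy
    subjects and ``"affected"``/``"unaffected"`` for stroke patients.
    """

    subject_id: str
    group: str                       # HS | SP
    affected_side: str               # left | right | none
    effects: dict[tuple[str, str], dict[str, float]]
    noise_scale: float = 1.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def side_cat(self, hand: str) -> str:
        if self.group == "HS":
            return "any"
        return "affected" if hand == self.affected_side else "unaffected"

    def stat_group(self, hand: str) -> str:
        """Row group of this moved hand: HS, USP or ASP."""
        if self.group == "HS":
            return "HS"
        return "ASP" if hand == self.affected_side else "USP"


def make_subject_profile(group: str, params: GeneratorParams, seed: int) -> SubjectProfile:
    """Draw one subject's effect magnitudes from the group-level distributions."""
    if group not in ("HS", "SP"):
        raise ValueError(f"unknown group {group!r}; expected 'HS' or 'SP'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    if group == "HS":
        affected = "none"
        cats = {"any": "HS"}
    else:
        affected = str(rng.choice(["left", "right"]))
        cats = {"affected": "ASP", "unaffected": "USP"}

    effects: dict[tuple[str, str], dict[str, float]] = {}
    for task in TASK_LIST:
        for cat, stat_group in cats.items():
            table = params.effects[(stat_group, task)]
            drawn = {name: float(rng.normal(mu, sd)) for name, (mu, sd) in table.items()}
            if not all(np.isfinite(list(drawn.values()))):
                raise ValueError("non-finite drawn effect")
            effects[(task, cat)] = drawn
    noise_scale = float(max(0.2, 1.0 + rng.normal(0.0, params.noise_scale_sd)))
    return SubjectProfile(
        subject_id=f"{group}-{seed:04d}", group=group, affected_side=affected,
        effects=effects, noise_scale=noise_scale, seed=seed,
    )


# ---------------------------------------------------------------------------
# waveform builders
# ---------------------------------------------------------------------------

def _cos_ramp(n: int, g0: float, g1: float) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n, endpoint=False)
    return g0 + (g1 - g0) * 0.5 * (1.0 - np.cos(np.pi * x))


def _write(env: np.ndarray, start: int, seg: np.ndarray) -> None:
    n = env.shape[0]
    lo, hi = max(start, 0), min(start + seg.size, n)
    if hi > lo:
        env[lo:hi] = seg[lo - start:hi - start]


def _apply_plateaus(env: np.ndarray, fs: float, t0: float, plateaus, ramp_s: float,
                    base: float = 1.0) -> None:
    """Write gain plateaus (with cosine ramps) into ``env`` around onset t0.

    ``plateaus`` is a sorted list of (start_s, end_s, gain). Ramps connect
    from/to ``base``, or directly between adjacent plateaus when the gap is
    shorter than the ramp.
    """
    ramp = max(1, int(round(ramp_s * fs)))

    def idx(t):
        return int(round((t0 + t) * fs))

    prev_end_i, prev_gain = None, base
    for k, (s, e, g) in enumerate(plateaus):
        si, ei = idx(s), idx(e)
        rs = ramp if prev_end_i is None else max(1, min(ramp, si - prev_end_i))
        _write(env, si - rs, _cos_ramp(rs, prev_gain, g))
        _write(env, si, np.full(max(ei - si, 0), g))
        nxt_si = idx(plateaus[k + 1][0]) if k + 1 < len(plateaus) else None
        if nxt_si is None or nxt_si - ei > ramp:
            _write(env, ei, _cos_ramp(ramp, g, base))
            prev_gain = base
        else:
            prev_gain = g
        prev_end_i = ei


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, slope: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**slope, unit SD per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-slope / 2.0)
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def narrowband_oscillator(rng: np.random.Generator, n_samples: int, fs: float,
                          band: tuple[float, float]) -> np.ndarray:
    """Ongoing band-limited Gaussian oscillator with unit SD."""
    x = rng.standard_normal(n_samples)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _blink_kernel(fs: float) -> np.ndarray:
    t = np.arange(-0.2, 0.2, 1.0 / fs)
    return np.exp(-(t**2) / (2 * 0.06**2))


def _db_to_amp(db: float) -> float:
    return 10.0 ** (db / 20.0)


# ---------------------------------------------------------------------------
# run / session simulation
# ---------------------------------------------------------------------------

def simulate_run(profile: SubjectProfile, task: str, run_index: int,
                 params: GeneratorParams) -> Recording:
    """One continuous run: 80 randomized cue events with injected effects."""
    if task not in TASK_LIST:
        raise ValueError(f"unknown task {task!r}")
    n_runs = 2 * params.runs_per_task
    if not 0 <= run_index < n_runs:
        raise ValueError(f"run_index {run_index} outside configured range 0..{n_runs - 1}")
    params.validate()

    fs = params.sampling_rate
    labels = list(params.channels)
    n_trials = params.trials_per_run
    period = params.trial_period_s
    dur = params.lead_in_s + n_trials * period + params.tail_s
    n = int(round(dur * fs))

    seed_key = zlib.crc32(profile.subject_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence(
        [params.rng_seed, seed_key, TASK_LIST.index(task), run_index]
    ))

    hands = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials // 2))
    rng.shuffle(hands)
    onsets = params.lead_in_s + np.arange(n_trials) * period
    onset_idx = np.round(onsets * fs).astype(int)

    # envelopes (multiplicative for oscillators, additive for the slow wave)
    env = {
        ("mu", "L"): np.ones(n), ("mu", "R"): np.ones(n),
        ("beta", "L"): np.ones(n), ("beta", "R"): np.ones(n),
        ("theta", None): np.ones(n),
    }
    slow = {"L": np.zeros(n), "R": np.zeros(n)}
    beta_mo = BETA_MO_PLATEAU[task]

    for t0, hand in zip(onsets, hands):
        eff = profile.effects[(task, profile.side_cat(str(hand)))]
        roles = {"L": "cc", "R": "ci"} if hand == "right" else {"L": "ci", "R": "cc"}
        for hemi, role in roles.items():
            _apply_plateaus(
                env[("mu", hemi)], fs, t0,
                [(*MU_ME_PLATEAU, _db_to_amp(eff[f"mu_me_{role}"])),
                 (*MU_MO_PLATEAU, _db_to_amp(eff[f"mu_mo_{role}"]))],
                ENV_RAMP["mu"],
            )
            _apply_plateaus(
                env[("beta", hemi)], fs, t0,
                [(*BETA_ME_PLATEAU, _db_to_amp(eff[f"beta_me_{role}"])),
                 (*beta_mo, _db_to_amp(eff[f"beta_mo_{role}"]))],
                ENV_RAMP["beta"],
            )
            _apply_plateaus(
                slow[hemi], fs, t0,
                [(*SLOW_PLATEAU, eff[f"slow_wave_{role}"])],
                SLOW_RAMP, base=0.0,
            )
        _apply_plateaus(
            env[("theta", None)], fs, t0,
            [(*THETA_ME_PLATEAU, _db_to_amp(eff["theta_me"])),
             (*THETA_MO_PLATEAU, _db_to_amp(eff["theta_mo"]))],
            ENV_RAMP["theta"],
        )

    # sources at their scalp centers
    sources = {
        "C3": params.mu_amp_uv * narrowband_oscillator(rng, n, fs, OSC_BANDS["mu"]) * env[("mu", "L")]
        + params.beta_amp_uv * narrowband_oscillator(rng, n, fs, OSC_BANDS["beta"]) * env[("beta", "L")]
        + slow["L"],
        "C4": params.mu_amp_uv * narrowband_oscillator(rng, n, fs, OSC_BANDS["mu"]) * env[("mu", "R")]
        + params.beta_amp_uv * narrowband_oscillator(rng, n, fs, OSC_BANDS["beta"]) * env[("beta", "R")]
        + slow["R"],
        "FCz": params.theta_amp_uv * narrowband_oscillator(rng, n, fs, OSC_BANDS["theta"])
        * env[("theta", None)],
    }

    v = np.zeros((len(labels), n))
    for center, wave in sources.items():
        w = gaussian_scalp_map(center, labels, params.source_sigma_m)
        v += np.outer(w, wave)

    # blinks: stereotyped frontal transients at a Poisson rate
    if params.blink_rate_per_min > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min * dur / 60.0)
        if n_blinks:
            blink_tc = np.zeros(n)
            kernel = _blink_kernel(fs)
            times = np.sort(rng.uniform(0.5, dur - 0.5, n_blinks))
            for tb in times:
                i = int(round(tb * fs))
                a, b = i - kernel.size // 2, i - kernel.size // 2 + kernel.size
                blink_tc[max(a, 0):min(b, n)] += kernel[max(0, -a):kernel.size - max(0, b - n)]
            w = gaussian_scalp_map("Fp1", labels, 0.05) + gaussian_scalp_map("Fp2", labels, 0.05)
            w /= w.max()
            v += np.outer(w * params.blink_amp_uv, blink_tc)

    v += params.pink_noise_uv * profile.noise_scale * pink_noise(
        rng, len(labels), n, fs, params.pink_slope
    )
    v += params.white_noise_uv * profile.noise_scale * rng.standard_normal((len(labels), n))

    # emit against the FCz reference (copy: avoid aliasing the reference row)
    v = v - v[labels.index("FCz")].copy()[None, :]

    events = [
        Event(sample=int(i), task=task, hand=str(h), run=run_index)
        for i, h in zip(onset_idx, hands)
    ]
    return Recording(
        channel_labels=labels, reference_label="FCz", sampling_rate=fs,
        data=v, events=events, subject_id=profile.subject_id,
        meta={"group": profile.group, "affected_side": profile.affected_side,
              "task": task, "run": run_index},
    )


def ground_truth(profile: SubjectProfile) -> pd.DataFrame:
    """Injected effect values, one row per simulated (task, moved-side) condition."""
    rows = []
    for (task, cat), eff in profile.effects.items():
        group = "HS" if profile.group == "HS" else ("ASP" if cat == "affected" else "USP")
        rows.append({
            "subject_id": profile.subject_id, "group": group, "task": task,
            "side_cat": cat, **eff,
        })
    return pd.DataFrame(rows).sort_values(["task", "side_cat"]).reset_index(drop=True)


def simulate_session(profile: SubjectProfile, params: GeneratorParams):
    """Full session: 2 runs per task (interleaved) plus the injected ground truth."""
    order = [TASK_LIST[i % 2] for i in range(2 * params.runs_per_task)]
    recs = [simulate_run(profile, task, i, params) for i, task in enumerate(order)]
    return recs, ground_truth(profile)
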