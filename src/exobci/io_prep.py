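"""Recording/epoch containers and the preprocessing chain.

Pipeline order is fixed: re-reference -> bad-channel interpolation -> ICA
artifact removal -> band-pass filter -> resample -> epoch -> flip-merge.
All data stay in microvolts throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .config import PreprocConfig
from .montage import channel_positions, mirror_map

logger = logging.getLogger(__name__)

TASK_CODES = {("VOL", "left"): 1, ("VOL", "right"): 2, ("PAS", "left"): 3, ("PAS", "right"): 4}
CODE_TO_EVENT = {v: k for k, v in TASK_CODES.items()}


@dataclass
class Event:
    sample: int
    task: str       # VOL | PAS
    hand: str       # left | right
    run: int


@dataclass
class Recording:
    """Continuous multi-channel EEG in uV with movement-onset events."""

    channel_labels: list[str]
    reference_label: str
    sampling_rate: float
    data: np.ndarray                # (channels, samples), uV
    events: list[Event]
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for ev in self.events:
            if not (0 <= ev.sample < self.data.shape[1]):
                raise ValueError(f"event sample {ev.sample} outside recording")

    def ch_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self, **kw) -> "Recording":
        out = replace(self, **kw)
        if "data" not in kw:
            out.data = self.data.copy()
        if "events" not in kw:
            out.events = [replace(e) for e in self.events]
        return out


@dataclass
class EpochSet:
    """Trials x channels x time, time axis in seconds relative to movement onset."""

    data: np.ndarray                 # (n_trials, n_channels, n_times), uV
    time_axis: np.ndarray            # strictly increasing, uniform
    channel_labels: list[str]
    trials: pd.DataFrame             # columns: task, hand, run (+ side_cat for SP)
    sampling_rate: float
    merged_laterality: bool = False
    cc_ci_map: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self):
        dt = np.diff(self.time_axis)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("time axis must be strictly increasing and uniform")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata length mismatch")

    def ch_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            time_axis=self.time_axis,
            channel_labels=list(self.channel_labels),
            trials=self.trials[mask].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
            merged_laterality=self.merged_laterality,
            cc_ci_map=dict(self.cc_ci_map),
            n_dropped=self.n_dropped,
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_recording(path: str) -> Recording:
    """Read a BrainVision (.vhdr) or EDF recording into uV with decoded events."""
    import mne

    path = str(path)
    if path.endswith(".vhdr"):
        import os

        with open(path) as fh:
            header = fh.read()
        for line in header.splitlines():
            if line.startswith(("MarkerFile=", "DataFile=")):
                dep = os.path.join(os.path.dirname(path), line.split("=", 1)[1].strip())
                if not os.path.exists(dep):
                    raise FileNotFoundError(f"missing BrainVision component: {dep}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.endswith(".edf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path}")

    units = set(raw._orig_units.values()) if getattr(raw, "_orig_units", None) else set()
    if units and not units <= {"µV", "uV", "V"}:
        raise ValueError(f"unknown units in file: {units}")

    data_uv = raw.get_data() * 1e6
    events = []
    run = 0
    subject = ""
    for ann in raw.annotations:
        desc = str(ann["description"])
        if desc.startswith("Comment"):
            for part in desc.replace("Comment/", "").split(";"):
                if part.startswith("run="):
                    run = int(part.split("=")[1])
                if part.startswith("subject="):
                    subject = part.split("=")[1]
            continue
        if "Stimulus" in desc or desc.startswith("S"):
            digits = "".join(c for c in desc if c.isdigit())
            if not digits:
                continue
            code = int(digits)
            if code not in CODE_TO_EVENT:
                raise ValueError(f"unmapped event code {code} in {desc!r}")
            task, hand = CODE_TO_EVENT[code]
            sample = int(round(ann["onset"] * raw.info["sfreq"]))
            events.append(Event(sample=sample, task=task, hand=hand, run=run))

    return Recording(
        channel_labels=list(raw.ch_names),
        reference_label="FCz",
        sampling_rate=float(raw.info["sfreq"]),
        data=data_uv,
        events=events,
        subject_id=subject,
    )


# ---------------------------------------------------------------------------
# Preprocessing stages
# ---------------------------------------------------------------------------

def rereference(rec: Recording, refs=("TP9", "TP10")) -> Recording:
    """Subtract the mean of the reference channels from every channel."""
    idx = [rec.ch_index(r) for r in refs]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    out = rec.copy()
    out.data = rec.data - ref
    out.reference_label = "+".join(refs)
    logger.debug("re-referenced to %s", refs)
    return out


def detect_bad_channels(rec: Recording, flat_uv: float = 1e-3, power_sd: float = 5.0) -> list[str]:
    """Flat channels and channels with outlying broadband power (z > power_sd)."""
    sd = rec.data.std(axis=1)
    bads = [ch for ch, s in zip(rec.channel_labels, sd) if s < flat_uv]
    log_p = np.log(np.maximum(sd, 1e-12))
    good = np.array([ch not in bads for ch in rec.channel_labels])
    if good.sum() > 2:
        mu, sigma = log_p[good].mean(), log_p[good].std()
        if sigma > 0:
            z = (log_p - mu) / sigma
            bads += [ch for ch, zi, g in zip(rec.channel_labels, z, good) if g and abs(zi) > power_sd]
    return bads


def interpolate_bad_channels(rec: Recording, bads: list[str], n_neighbors: int = 4) -> Recording:
    """Replace bad channels by an inverse-distance weighted mean of good neighbors.

    Weights are normalized to sum to 1 per bad channel, so constant fields are
    reproduced exactly.
    """
    if not bads:
        return rec.copy()
    good = [ch for ch in rec.channel_labels if ch not in bads]
    if not good:
        raise ValueError("all channels are bad; cannot interpolate")
    pos = channel_positions(tuple(rec.channel_labels))
    out = rec.copy()
    for ch in bads:
        i = rec.ch_index(ch)
        dists = np.linalg.norm(pos - pos[i], axis=1)
        order = [j for j in np.argsort(dists) if rec.channel_labels[j] in good]
        nbrs = order[:n_neighbors]
        w = 1.0 / np.maximum(dists[nbrs], 1e-6)
        w = w / w.sum()
        out.data[i] = w @ rec.data[nbrs]
    logger.info("interpolated %d bad channels: %s", len(bads), bads)
    return out


def _blink_template(rec: Recording) -> np.ndarray:
    """Frontal-channel average, band-limited to blink frequencies (0.5-8 Hz)."""
    frontal = [ch for ch in ("Fp1", "Fp2", "AF7", "AF8") if ch in rec.channel_labels]
    if not frontal:
        frontal = rec.channel_labels[:2]
    tpl = rec.data[[rec.ch_index(c) for c in frontal]].mean(axis=0)
    sos = signal.butter(2, [0.5, 8.0], btype="bandpass", fs=rec.sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, tpl)


def remove_artifacts(rec: Recording, policy: PreprocConfig | None = None) -> Recording:
    """ICA decomposition; zero components correlating with the frontal blink template.

    Components whose absolute Pearson correlation with the blink template
    exceeds the configured threshold are removed and the signal reconstructed.
    """
    policy = policy or PreprocConfig()
    if not policy.ica_enabled:
        return rec.copy()
    from sklearn.decomposition import FastICA

    X = rec.data.T  # (samples, channels)
    # referencing makes the data rank-deficient; cap components at the rank
    evals = np.linalg.eigvalsh(np.cov(rec.data))
    rank = int(np.sum(evals > evals.max() * 1e-10))
    n_comp = min(policy.ica_n_components or rank, rank)
    ica = FastICA(
        n_components=n_comp, whiten="unit-variance", random_state=policy.ica_seed,
        max_iter=500, tol=1e-4,
    )
    try:
        S = ica.fit_transform(X)  # (samples, comps)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"ICA decomposition failed: {exc}") from exc

    tpl = _blink_template(rec)
    tpl = (tpl - tpl.mean()) / (tpl.std() + 1e-12)
    Sn = (S - S.mean(axis=0)) / (S.std(axis=0) + 1e-12)
    corr = (Sn * tpl[:, None]).mean(axis=0)
    bad = np.where(np.abs(corr) > policy.ica_blink_corr_threshold)[0]
    out = rec.copy()
    if bad.size:
        out.data = (X - S[:, bad] @ ica.mixing_[:, bad].T).T
        logger.info("ICA removed %d blink components (|r|=%s)", bad.size,
                    np.round(np.abs(corr[bad]), 3))
    out.meta = dict(rec.meta, ica_removed=int(bad.size))
    return out


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of the stated design order."""
    nyq = rec.sampling_rate / 2.0
    if high <= low:
        raise ValueError("high cutoff must exceed low cutoff")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, rec.data, axis=1)
    out.meta = dict(rec.meta, band=(low, high), filter_order=order)
    logger.debug("bandpass %.3g-%.3g Hz order %d", low, high, order)
    return out


def resample(rec: Recording, target: float = 200.0) -> Recording:
    """Polyphase anti-aliased resampling; event indices rescaled."""
    if target > rec.sampling_rate:
        raise ValueError("upsampling not supported")
    if target == rec.sampling_rate:
        return rec.copy()
    from fractions import Fraction

    frac = Fraction(target / rec.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = target / rec.sampling_rate
    events = [replace(e, sample=int(round(e.sample * ratio))) for e in rec.events]
    events = [e for e in events if e.sample < data.shape[1]]
    out = rec.copy(data=data, events=events)
    out.sampling_rate = float(target)
    return out


def epoch(rec: Recording, window_s=(-3.0, 6.0)) -> EpochSet:
    """Cut half-open [start, end) windows around each movement-onset event.

    Trials whose window exceeds the recording are dropped (count logged and
    stored on the EpochSet).
    """
    if not rec.events:
        raise ValueError("recording has no events to epoch")
    fs = rec.sampling_rate
    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    n_t = i1 - i0
    rows, segs = [], []
    dropped = 0
    for ev in rec.events:
        a, b = ev.sample + i0, ev.sample + i1
        if a < 0 or b > rec.data.shape[1]:
            dropped += 1
            continue
        segs.append(rec.data[:, a:b])
        row = {"task": ev.task, "hand": ev.hand, "run": ev.run}
        rows.append(row)
    if dropped:
        logger.info("dropped %d/%d trials at recording edges", dropped, len(rec.events))
    if not segs:
        raise ValueError("no complete epochs inside the recording")
    time_axis = (np.arange(n_t) + i0) / fs
    return EpochSet(
        data=np.stack(segs),
        time_axis=time_axis,
        channel_labels=list(rec.channel_labels),
        trials=pd.DataFrame(rows),
        sampling_rate=fs,
        n_dropped=dropped,
    )


def flip_epochs(epochs: EpochSet, mask) -> np.ndarray:
    """Return data with left/right channel pairs swapped for the masked trials."""
    mmap = mirror_map(epochs.channel_labels)
    perm = [epochs.ch_index(mmap[ch]) for ch in epochs.channel_labels]
    data = epochs.data.copy()
    data[mask] = data[mask][:, perm, :]
    return data


def flip_merge(epochs: EpochSet, cc_channel: str = "C3", ci_channel: str = "C4") -> EpochSet:
    """Mirror left-hand trials across the midline and pool with right-hand trials.

    The merged set is expressed in the right-movement frame: the channel
    contralateral to the movement (Cc) is on the left hemisphere (C3 by
    default) and the ipsilateral channel (Ci) on the right (C4).
    """
    left = (epochs.trials["hand"] == "left").to_numpy()
    data = flip_epochs(epochs, left)
    trials = epochs.trials.copy()
    trials["mirrored"] = left
    return EpochSet(
        data=data,
        time_axis=epochs.time_axis,
        channel_labels=list(epochs.channel_labels),
        trials=trials,
        sampling_rate=epochs.sampling_rate,
        merged_laterality=True,
        cc_ci_map={"Cc": cc_channel, "Ci": ci_channel},
        n_dropped=epochs.n_dropped,
    )


def preprocess(
    rec: Recording,
    band: tuple[float, float],
    policy: PreprocConfig | None = None,
    merge: bool = True,
) -> EpochSet:
    """Full chain: reref -> interpolate -> ICA -> filter -> resample -> epoch (-> flip-merge)."""
    policy = policy or PreprocConfig()
    rec = rereference(rec, policy.reference_channels)
    bads = list(policy.bad_channels) or detect_bad_channels(
        rec, policy.auto_bad_flat_uv, policy.auto_bad_power_sd
    )
    bads = [b for b in bads if b not in policy.reference_channels]
    rec = interpolate_bad_channels(rec, bads)
    rec = remove_artifacts(rec, policy)
    rec = bandpass(rec, band[0], band[1], policy.filter_order)
    rec = resample(rec, policy.resample_to)
    eps = epoch(rec, policy.epoch_window_s)
    if merge:
        eps = flip_merge(eps)
    return eps
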