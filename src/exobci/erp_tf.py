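"""Grand-average ERPs, slow-wave amplitudes, and Morlet time-frequency ROI power.

Time-frequency maps use a complex Morlet continuous wavelet transform
(center frequency 1 Hz, bandwidth 1.5).  Single-trial power (|CWT|^2) is
averaged over trials, converted to dB, and baseline-corrected by subtracting
the mean dB in the -2.5 to -0.5 s window per frequency and channel, which is
equivalent to division in linear power space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .config import AnalysisConfig
from .io_prep import EpochSet


@dataclass
class ROISpec:
    roi_id: int
    name: str
    freq_window: tuple[float, float]          # Hz, closed
    time_window: tuple[float, float] | dict   # s, closed; dict when task-dependent
    channel: str                              # "FCz" or a Cc/Ci role

    def window_for(self, task: str) -> tuple[float, float]:
        if isinstance(self.time_window, dict):
            return self.time_window[task]
        return self.time_window


#: the six regions of interest; movement execution (ME) and movement offset (MO)
ROI_TABLE = [
    ROISpec(1, "Theta_ME", (3.0, 7.0), (0.1, 0.5), "FCz"),
    ROISpec(2, "Theta_MO", (3.0, 7.0), (2.0, 2.5), "FCz"),
    ROISpec(3, "Mu_ME", (8.0, 13.0), (0.0, 2.0), "role"),
    ROISpec(4, "Mu_MO", (8.0, 13.0), (3.2, 4.2), "role"),
    ROISpec(5, "Beta_ME", (15.0, 28.0), (0.5, 2.0), "role"),
    ROISpec(6, "Beta_MO", (15.0, 28.0), {"VOL": (2.6, 3.6), "PAS": (2.1, 3.1)}, "role"),
]
ROI_BY_NAME = {r.name: r for r in ROI_TABLE}


@dataclass
class ERPSet:
    """Trial-averaged, baseline-corrected waveforms in uV."""

    mean: np.ndarray                # (channels, times)
    time_axis: np.ndarray
    channel_labels: list[str]
    n_trials: int
    baseline: tuple[float, float]
    cc_ci_map: dict[str, str] = field(default_factory=dict)

    def channel(self, label: str) -> np.ndarray:
        return self.mean[self.channel_labels.index(label)]


@dataclass
class TFMap:
    """Baseline-corrected dB power, (frequencies, times, channels)."""

    power_db: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    channel_labels: list[str]
    baseline: tuple[float, float]
    n_trials: int


def _window_mask(axis: np.ndarray, window: tuple[float, float], closed: bool = True):
    lo, hi = window
    eps = 1e-9
    if closed:
        return (axis >= lo - eps) & (axis <= hi + eps)
    return (axis >= lo - eps) & (axis < hi - eps)


def average_erp(epochs: EpochSet, cfg: AnalysisConfig | None = None) -> ERPSet:
    """Average all trials in the set, then subtract the per-channel baseline mean."""
    cfg = cfg or AnalysisConfig()
    if epochs.data.shape[0] == 0:
        raise ValueError("cannot average a condition with zero trials")
    mean = epochs.data.mean(axis=0)
    bl = _window_mask(epochs.time_axis, cfg.erp_baseline)
    if not bl.any():
        raise ValueError("ERP baseline window outside epoch span")
    mean = mean - mean[:, bl].mean(axis=1, keepdims=True)
    return ERPSet(
        mean=mean, time_axis=epochs.time_axis, channel_labels=list(epochs.channel_labels),
        n_trials=epochs.data.shape[0], baseline=cfg.erp_baseline,
        cc_ci_map=dict(epochs.cc_ci_map),
    )


def slow_wave_amplitude(erp: ERPSet, channel_role: str, cfg: AnalysisConfig | None = None) -> float:
    """Mean amplitude (uV) over the closed slow-wave window at the role-mapped channel."""
    cfg = cfg or AnalysisConfig()
    if channel_role in ("Cc", "Ci"):
        if channel_role not in erp.cc_ci_map:
            raise KeyError(f"role {channel_role!r} missing from cc_ci_map")
        label = erp.cc_ci_map[channel_role]
    else:
        label = channel_role
    win = _window_mask(erp.time_axis, cfg.slow_wave_window)
    if cfg.slow_wave_window[0] < erp.time_axis[0] or cfg.slow_wave_window[1] > erp.time_axis[-1]:
        raise ValueError("slow-wave window outside epoch span")
    return float(erp.channel(label)[win].mean())


def morlet_power(data: np.ndarray, fs: float, freqs: np.ndarray,
                 center_freq: float = 1.0, bandwidth: float = 1.5) -> np.ndarray:
    """|CWT|^2 with a complex Morlet wavelet; scales hit ``freqs`` exactly.

    data: (..., times) -> power (..., n_freqs, times).
    """
    if np.max(freqs) >= fs / 2:
        raise ValueError("frequency grid exceeds Nyquist")
    wavelet = f"cmor{bandwidth}-{center_freq}"
    scales = center_freq * fs / np.asarray(freqs, dtype=float)
    coef, _ = pywt.cwt(data, scales, wavelet, sampling_period=1.0 / fs,
                       method="fft", axis=-1)
    # pywt puts the scale axis first; move it next to time
    coef = np.moveaxis(coef, 0, -2)
    return (coef.real**2 + coef.imag**2)


def tf_power(epochs: EpochSet, cfg: AnalysisConfig | None = None,
             channels: list[str] | None = None,
             freqs: np.ndarray | None = None) -> TFMap:
    """Per-trial Morlet power, trial-averaged, in dB relative to the baseline window."""
    cfg = cfg or AnalysisConfig()
    freqs = cfg.freq_grid() if freqs is None else np.asarray(freqs, float)
    labels = channels or list(epochs.channel_labels)
    idx = [epochs.ch_index(ch) for ch in labels]
    data = epochs.data[:, idx, :]
    power = morlet_power(data, epochs.sampling_rate, freqs,
                         cfg.wavelet_center_freq, cfg.wavelet_bandwidth)
    avg = power.mean(axis=0)                       # (channels, freqs, times)
    db = 10.0 * np.log10(np.maximum(avg, 1e-300))
    bl = _window_mask(epochs.time_axis, cfg.tf_baseline)
    if not bl.any():
        raise ValueError("TF baseline window outside epoch span")
    db = db - db[:, :, bl].mean(axis=2, keepdims=True)
    return TFMap(
        power_db=np.moveaxis(db, 0, -1),           # (freqs, times, channels)
        freq_axis=freqs, time_axis=epochs.time_axis, channel_labels=labels,
        baseline=cfg.tf_baseline, n_trials=epochs.data.shape[0],
    )


def roi_power(tf: TFMap, roi: ROISpec | str, task: str,
              cc_ci_map: dict[str, str] | None = None,
              channel_role: str | None = None) -> float:
    """Mean dB over the ROI's closed frequency x time box at its channel.

    For mu/beta ROIs the channel is the Cc or Ci role (pass ``channel_role``
    and the role map); theta ROIs live at FCz.
    """
    if isinstance(roi, str):
        roi = ROI_BY_NAME[roi]
    if roi.channel == "FCz":
        label = "FCz"
    else:
        if channel_role is None:
            raise ValueError("mu/beta ROI needs channel_role='Cc' or 'Ci'")
        cc_ci_map = cc_ci_map or {}
        if channel_role not in cc_ci_map:
            raise KeyError(f"role {channel_role!r} missing from cc_ci_map")
        label = cc_ci_map[channel_role]
    tw = roi.window_for(task)
    fmask = _window_mask(tf.freq_axis, roi.freq_window)
    tmask = _window_mask(tf.time_axis, tw)
    if not fmask.any() or not tmask.any():
        raise ValueError(f"ROI {roi.name} outside the TF map")
    if tw[0] < tf.time_axis[0] or tw[1] > tf.time_axis[-1]:
        raise ValueError(f"ROI {roi.name} time window outside the TF map")
    ci = tf.channel_labels.index(label)
    box = tf.power_db[np.ix_(fmask, tmask, [ci])]
    return float(box.mean())


def topography(values: np.ndarray, time_axis: np.ndarray, channel_labels: list[str],
               window: tuple[float, float]) -> pd.Series:
    """Per-channel mean over a time window; index = channel labels (for plotting/CSV)."""
    mask = _window_mask(time_axis, window)
    arr = np.asarray(values)
    return pd.Series(arr[:, mask].mean(axis=1), index=list(channel_labels), name="value")
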