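"""Configuration: generator parameters, analysis windows, decoder settings.

All tunables live in small dataclasses that can be overridden from a single
YAML file with sections ``generator:``, ``preprocessing:``, ``analysis:``,
``stats:`` and ``decoding:``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .montage import CHANNELS_64, CSP_CHANNELS

GROUPS = ("HS", "USP", "ASP")
TASKS = ("VOL", "PAS")

# ---------------------------------------------------------------------------
# Population effect structure: per (group, task), mean and between-subject SD
# of each injectable effect. Slow-wave entries are mean amplitudes in uV over
# the 0.4-1.9 s window; mu/beta/theta entries are baseline-relative band power
# changes in dB over their ROI windows. Group "HS" is healthy subjects; "USP"
# and "ASP" are the unaffected/affected moved side of stroke patients.
# ---------------------------------------------------------------------------
EFFECT_NAMES = (
    "slow_wave_cc", "slow_wave_ci",
    "mu_me_cc", "mu_me_ci", "mu_mo_cc", "mu_mo_ci",
    "beta_me_cc", "beta_me_ci", "beta_mo_cc", "beta_mo_ci",
    "theta_me", "theta_mo",
)

POPULATION_EFFECTS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("HS", "VOL"): {
        "slow_wave_cc": (0.87, 11.50), "slow_wave_ci": (2.03, 11.63),
        "mu_me_cc": (-1.22, 1.38), "mu_me_ci": (-1.03, 1.20),
        "mu_mo_cc": (0.29, 0.49), "mu_mo_ci": (0.00, 0.33),
        "beta_me_cc": (-0.32, 0.35), "beta_me_ci": (-0.28, 0.30),
        "beta_mo_cc": (0.14, 0.25), "beta_mo_ci": (0.05, 0.23),
        "theta_me": (1.09, 1.17), "theta_mo": (0.51, 0.81),
    },
    ("HS", "PAS"): {
        "slow_wave_cc": (-7.29, 4.51), "slow_wave_ci": (-4.33, 3.69),
        "mu_me_cc": (-1.14, 0.97), "mu_me_ci": (-1.08, 0.98),
        "mu_mo_cc": (0.15, 0.39), "mu_mo_ci": (-0.01, 0.33),
        "beta_me_cc": (-0.25, 0.27), "beta_me_ci": (-0.24, 0.21),
        "beta_mo_cc": (0.06, 0.21), "beta_mo_ci": (-0.01, 0.14),
        "theta_me": (2.10, 1.68), "theta_mo": (-0.09, 0.65),
    },
    ("USP", "VOL"): {
        "slow_wave_cc": (6.73, 7.78), "slow_wave_ci": (8.72, 8.39),
        "mu_me_cc": (-0.57, 0.94), "mu_me_ci": (-0.42, 0.71),
        "mu_mo_cc": (-0.07, 0.41), "mu_mo_ci": (-0.10, 0.37),
        "beta_me_cc": (-0.47, 0.56), "beta_me_ci": (-0.15, 0.45),
        "beta_mo_cc": (0.07, 0.33), "beta_mo_ci": (0.03, 0.26),
        "theta_me": (1.02, 0.72), "theta_mo": (0.34, 0.49),
    },
    ("USP", "PAS"): {
        "slow_wave_cc": (-9.17, 5.84), "slow_wave_ci": (-1.35, 4.21),
        "mu_me_cc": (-1.20, 1.67), "mu_me_ci": (-0.87, 1.27),
        "mu_mo_cc": (0.10, 0.38), "mu_mo_ci": (0.03, 0.29),
        "beta_me_cc": (-0.51, 0.35), "beta_me_ci": (-0.32, 0.25),
        "beta_mo_cc": (0.09, 0.09), "beta_mo_ci": (0.02, 0.10),
        "theta_me": (1.06, 0.86), "theta_mo": (-0.26, 1.01),
    },
    ("ASP", "VOL"): {
        "slow_wave_cc": (-10.43, 18.00), "slow_wave_ci": (-9.01, 14.35),
        "mu_me_cc": (0.47, 2.34), "mu_me_ci": (0.26, 2.11),
        "mu_mo_cc": (0.12, 0.50), "mu_mo_ci": (-0.06, 0.43),
        "beta_me_cc": (0.48, 1.49), "beta_me_ci": (0.32, 1.52),
        "beta_mo_cc": (0.16, 0.24), "beta_mo_ci": (0.03, 0.19),
        "theta_me": (1.05, 0.78), "theta_mo": (0.51, 0.93),
    },
    ("ASP", "PAS"): {
        "slow_wave_cc": (-6.48, 5.89), "slow_wave_ci": (-3.81, 4.14),
        "mu_me_cc": (-1.11, 1.34), "mu_me_ci": (-1.04, 1.51),
        "mu_mo_cc": (0.04, 0.41), "mu_mo_ci": (0.04, 0.48),
        "beta_me_cc": (-0.37, 0.37), "beta_me_ci": (-0.40, 0.34),
        "beta_mo_cc": (0.04, 0.16), "beta_mo_ci": (0.04, 0.16),
        "theta_me": (1.29, 1.10), "theta_mo": (-0.27, 0.73),
    },
}


@dataclass
class GeneratorParams:
    """Synthetic session generator settings.

    Defaults reproduce the study design: 64 channels referenced to FCz, four
    runs (two per task) of 80 trials (40 per hand), each trial a 0.5 s cue,
    2 s movement, 3 s rest. Effect means/SDs default to the printed group
    summary statistics (POPULATION_EFFECTS).
    """

    sampling_rate: float = 1000.0
    channels: list[str] = field(default_factory=lambda: list(CHANNELS_64))
    cue_lead_s: float = 0.5
    movement_s: float = 2.0
    rest_s: float = 3.0
    runs_per_task: int = 2
    trials_per_run: int = 80
    lead_in_s: float = 4.0     # pre-first-trial padding (epoching needs 3 s)
    tail_s: float = 6.0        # post-last-trial padding
    # noise model
    pink_noise_uv: float = 6.0         # 1/f background, per-channel SD in uV
    pink_slope: float = 1.0            # power ~ 1/f**slope
    white_noise_uv: float = 1.5        # sensor noise SD in uV
    noise_scale_sd: float = 0.10       # between-subject lognormal-ish spread
    # ongoing oscillator source amplitudes (SD in uV at the center channel)
    theta_amp_uv: float = 12.0
    mu_amp_uv: float = 12.0
    beta_amp_uv: float = 12.0
    # blink artifacts
    blink_rate_per_min: float = 4.0
    blink_amp_uv: float = 80.0
    # spatial spread of the Gaussian scalp maps
    source_sigma_m: float = 0.035
    # population effect table, (group, task) -> {effect: (mean, sd)}
    effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in POPULATION_EFFECTS.items()}
    )
    rng_seed: int = 0

    @property
    def trial_period_s(self) -> float:
        return self.cue_lead_s + self.movement_s + self.rest_s

    def validate(self) -> None:
        if self.trials_per_run % 2 != 0:
            raise ValueError("trials_per_run must be even (balanced hands)")
        if self.movement_s + self.rest_s + self.cue_lead_s <= 0:
            raise ValueError("trial timing must be positive")
        for key, table in self.effects.items():
            for name, (mean, sd) in table.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key}/{name}")


@dataclass
class PreprocConfig:
    """Preprocessing chain settings (re-reference ... flip-merge)."""

    reference_channels: tuple[str, str] = ("TP9", "TP10")
    bad_channels: list[str] = field(default_factory=list)
    auto_bad_flat_uv: float = 1e-3      # SD below this -> flat channel
    auto_bad_power_sd: float = 5.0      # broadband power z-score threshold
    ica_enabled: bool = True
    ica_n_components: int | None = None
    ica_blink_corr_threshold: float = 0.8
    ica_seed: int = 97
    band_erp: tuple[float, float] = (0.01, 10.0)
    band_tf: tuple[float, float] = (0.5, 40.0)
    filter_order: int = 4
    resample_to: float = 200.0
    epoch_window_s: tuple[float, float] = (-3.0, 6.0)


@dataclass
class AnalysisConfig:
    """ERP / time-frequency analysis windows (seconds relative to movement onset)."""

    erp_baseline: tuple[float, float] = (-2.0, 0.0)
    slow_wave_window: tuple[float, float] = (0.4, 1.9)
    tf_baseline: tuple[float, float] = (-2.5, -0.5)
    wavelet_center_freq: float = 1.0
    wavelet_bandwidth: float = 1.5
    freq_lo: float = 1.0
    freq_hi: float = 40.0
    freq_step: float = 0.5
    alpha: float = 0.05

    def freq_grid(self):
        import numpy as np

        n = int(round((self.freq_hi - self.freq_lo) / self.freq_step)) + 1
        return np.linspace(self.freq_lo, self.freq_hi, n)


@dataclass
class CSPConfig:
    band: tuple[float, float] = (8.0, 30.0)
    window_s: tuple[float, float] = (0.0, 2.0)
    rate: float = 200.0
    channels: list[str] = field(default_factory=lambda: list(CSP_CHANNELS))
    n_filters: int = 2
    ridge: float = 1e-9


@dataclass
class CNNConfig:
    """Compact convolutional decoder (temporal + depthwise spatial + separable)."""

    window_s: tuple[float, float] = (-0.5, 3.0)
    rate: float = 200.0
    channels: list[str] | None = None   # None -> all montage channels
    f1: int = 8
    depth_multiplier: int = 2
    f2: int = 16
    temporal_kernel: int = 101          # ~0.5 s at 200 Hz (odd for symmetric conv)
    separable_kernel: int = 17
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    max_norm: float = 1.0
    epochs: int = 60
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


@dataclass
class DecodingConfig:
    csp: CSPConfig = field(default_factory=CSPConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    within_folds: int = 10
    within_test_fraction: float = 0.1
    within_mode: str = "shuffle"        # "shuffle" (repeated 90/10) or "kfold"
    cross_repeats_hs: int = 10
    cross_test_subjects_hs: int = 2


@dataclass
class ExperimentConfig:
    """Top-level configuration for a full synthetic-cohort experiment."""

    n_hs: int = 20
    n_sp: int = 10
    seed: int = 0
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    preprocessing: PreprocConfig = field(default_factory=PreprocConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    run_decoding: bool = True
    write_brainvision: bool = False


def _update_dataclass(obj: Any, overrides: dict) -> None:
    for key, val in overrides.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _update_dataclass(cur, val)
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, val)


def load_config(path: str | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Build an ExperimentConfig from YAML (sections mirror the dataclasses)."""
    cfg = ExperimentConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    _update_dataclass(cfg, data)
    cfg.generator.validate()
    return cfg
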