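"""ERP averaging, slow-wave amplitudes, Morlet TF maps and ROI power."""

import numpy as np
import pandas as pd
import pytest

from exobci.config import AnalysisConfig
from exobci.erp_tf import (
    ROI_BY_NAME,
    ROI_TABLE,
    TFMap,
    average_erp,
    morlet_power,
    roi_power,
    slow_wave_amplitude,
    tf_power,
    topography,
)
from exobci.io_prep import EpochSet


def make_epochs(data: np.ndarray, fs: float = 200.0, t0: float = -3.0,
                labels=None, cc_ci=True) -> EpochSet:
    n, c, t = data.shape
    labels = labels or [f"ch{i}" for i in range(c)]
    return EpochSet(
        data=data, time_axis=t0 + np.arange(t) / fs, channel_labels=labels,
        trials=pd.DataFrame({"task": ["PAS"] * n, "hand": ["right"] * n,
                             "run": [0] * n}),
        sampling_rate=fs, merged_laterality=cc_ci,
        cc_ci_map={"Cc": labels[0], "Ci": labels[1]} if cc_ci and c >= 2 else {},
    )


class TestAverageERP:
    def test_identical_trials_recover_waveform_minus_baseline(self):
        fs = 200.0
        t = -3.0 + np.arange(int(9 * fs)) / fs
        wave = np.sin(2 * np.pi * 0.5 * t) + 2.0
        data = np.tile(wave, (5, 3, 1))
        eps = make_epochs(data, fs)
        erp = average_erp(eps)
        bl = (t >= -2.0) & (t <= 0.0)
        expected = wave - wave[bl].mean()
        assert np.allclose(erp.mean[0], expected)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(0)
        eps = make_epochs(rng.standard_normal((7, 4, 1800)))
        erp = average_erp(eps)
        bl = (erp.time_axis >= -2.0) & (erp.time_axis <= 0.0)
        assert np.allclose(erp.mean[:, bl].mean(axis=1), 0.0, atol=1e-12)

    def test_zero_trials_error(self):
        eps = make_epochs(np.zeros((1, 2, 1800)))
        with pytest.raises(ValueError):
            average_erp(eps.select(np.array([False])))


class TestSlowWave:
    def test_constant_erp(self):
        eps = make_epochs(np.zeros((3, 2, 1800)))
        erp = average_erp(eps)
        erp.mean[:] = -5.0
        assert slow_wave_amplitude(erp, "Cc") == pytest.approx(-5.0)

    def test_linear_ramp_mean(self):
        """A 0 -> -10 uV ramp over the 0.4-1.9 s window averages to -5 uV."""
        fs = 200.0
        eps = make_epochs(np.zeros((2, 2, 1800)), fs)
        erp = average_erp(eps)
        t = erp.time_axis
        erp.mean[0] = -10.0 * np.clip((t - 0.4) / 1.5, 0.0, 1.0)
        # closed-window mean of a linear ramp on a symmetric grid = midpoint
        assert slow_wave_amplitude(erp, "Cc") == pytest.approx(-5.0, abs=0.02)

    def test_window_outside_epoch_errors(self):
        eps = make_epochs(np.zeros((2, 2, 100)), t0=-0.5)
        erp = average_erp(eps, AnalysisConfig(erp_baseline=(-0.5, 0.0)))
        with pytest.raises(ValueError):
            slow_wave_amplitude(erp, "Cc")

    def test_missing_role_map(self):
        eps = make_epochs(np.zeros((2, 2, 1800)), cc_ci=False)
        erp = average_erp(eps)
        with pytest.raises(KeyError):
            slow_wave_amplitude(erp, "Cc")


class TestTFPower:
    def test_stationary_noise_is_zero_db(self):
        """Baseline-corrected power of stationary noise ~ 0 dB everywhere."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((100, 2, 1800))
        eps = make_epochs(data)
        tf = tf_power(eps, freqs=np.arange(3.0, 30.0, 3.0))
        inner = (tf.time_axis > -2.0) & (tf.time_axis < 5.0)  # avoid cwt edges
        assert np.abs(tf.power_db[:, inner, :].mean()) < 0.2
        # baseline window itself is ~0 by construction
        bl = (tf.time_axis >= -2.5) & (tf.time_axis <= -0.5)
        assert np.abs(tf.power_db[:, bl, :].mean(axis=1)).max() < 1e-10

    def test_tone_burst_power_ratio(self):
        """Doubling 10 Hz amplitude during 0-2 s gives ~ +6 dB at 10 Hz
        (power ratio 4), and +3 dB for a sqrt(2) amplitude step."""
        fs = 200.0
        n = int(9 * fs)
        t = -3.0 + np.arange(n) / fs
        rng = np.random.default_rng(2)
        trials = []
        for _ in range(20):
            phase = rng.uniform(0, 2 * np.pi)
            amp = np.where((t >= 0.0) & (t <= 2.0), np.sqrt(2.0), 1.0)
            trials.append(amp * np.sin(2 * np.pi * 10.0 * t + phase))
        data = np.stack(trials)[:, None, :]
        eps = make_epochs(data, fs, cc_ci=False)
        tf = tf_power(eps, freqs=np.array([10.0]))
        win = (tf.time_axis >= 0.5) & (tf.time_axis <= 1.5)  # clear of smearing
        assert tf.power_db[0, win, 0].mean() == pytest.approx(3.0, abs=0.3)

    def test_pure_tone_peak_frequency(self):
        """The Morlet scale grid maps a pure 20 Hz tone to the 20 Hz bin."""
        fs = 200.0
        t = np.arange(int(9 * fs)) / fs
        data = np.sin(2 * np.pi * 20.0 * t)[None, None, :]
        power = morlet_power(data, fs, np.arange(5.0, 35.5, 0.5))
        prof = power[0, 0, :, 400:1400].mean(axis=1)
        freqs = np.arange(5.0, 35.5, 0.5)
        # within one grid bin (scale discretization of the wavelet transform)
        assert abs(freqs[np.argmax(prof)] - 20.0) <= 0.5

    def test_grid_beyond_nyquist_rejected(self):
        eps = make_epochs(np.zeros((2, 2, 1800)))
        with pytest.raises(ValueError):
            tf_power(eps, freqs=np.array([150.0]))

    def test_db_correction_equals_linear_division(self):
        """Subtracting baseline dB == 10*log10 of baseline-divided linear power."""
        rng = np.random.default_rng(3)
        power = rng.uniform(0.5, 2.0, size=(5, 1800, 2))
        time_axis = -3.0 + np.arange(1800) / 200.0
        bl = (time_axis >= -2.5) & (time_axis <= -0.5)
        db = 10 * np.log10(power)
        corrected = db - db[:, bl, :].mean(axis=1, keepdims=True)
        gm = np.exp(np.log(power[:, bl, :]).mean(axis=1, keepdims=True))
        divided = 10 * np.log10(power / gm)
        assert np.allclose(corrected, divided, rtol=1e-10, atol=1e-10)


class TestROIPower:
    def _flat_map(self, value=0.0):
        freqs = np.arange(1.0, 40.5, 0.5)
        times = -3.0 + np.arange(1800) / 200.0
        return TFMap(
            power_db=np.full((freqs.size, times.size, 2), float(value)),
            freq_axis=freqs, time_axis=times, channel_labels=["C3", "FCz"],
            baseline=(-2.5, -0.5), n_trials=1,
        )

    def test_constant_map(self):
        tf = self._flat_map(2.5)
        assert roi_power(tf, "Theta_ME", "VOL") == pytest.approx(2.5)

    def test_box_fixture(self):
        """+1 dB inside the Mu_ME box, 0 outside -> ROI mean exactly 1."""
        tf = self._flat_map(0.0)
        roi = ROI_BY_NAME["Mu_ME"]
        f = (tf.freq_axis >= 8.0) & (tf.freq_axis <= 13.0)
        t = (tf.time_axis >= 0.0) & (tf.time_axis <= 2.0)
        tf.power_db[np.ix_(f, t, [0])] = 1.0
        val = roi_power(tf, roi, "VOL", cc_ci_map={"Cc": "C3"}, channel_role="Cc")
        assert val == pytest.approx(1.0)

    def test_beta_mo_task_dependent_window(self):
        """Beta_MO reads 2.6-3.6 s for voluntary and 2.1-3.1 s for passive."""
        tf = self._flat_map(0.0)
        t_vol = (tf.time_axis >= 2.6 - 1e-9) & (tf.time_axis <= 3.6 + 1e-9)
        f = (tf.freq_axis >= 15.0) & (tf.freq_axis <= 28.0)
        tf.power_db[np.ix_(f, t_vol, [0])] = 2.0
        vol = roi_power(tf, "Beta_MO", "VOL", cc_ci_map={"Cc": "C3"}, channel_role="Cc")
        pas = roi_power(tf, "Beta_MO", "PAS", cc_ci_map={"Cc": "C3"}, channel_role="Cc")
        assert vol == pytest.approx(2.0)
        # PAS window 2.1-3.1 s overlaps the energized 2.6-3.6 s box for
        # 0.5 s: 101 of its 201 samples carry the 2 dB
        assert pas == pytest.approx(2.0 * 101 / 201, abs=1e-9)

    def test_roi_table_matches_design(self):
        assert len(ROI_TABLE) == 6
        assert ROI_BY_NAME["Theta_ME"].time_window == (0.1, 0.5)
        assert ROI_BY_NAME["Theta_MO"].time_window == (2.0, 2.5)
        assert ROI_BY_NAME["Mu_MO"].time_window == (3.2, 4.2)

    def test_roi_outside_map(self):
        tf = self._flat_map()
        tf.time_axis = tf.time_axis[:200]
        tf.power_db = tf.power_db[:, :200, :]
        with pytest.raises(ValueError):
            roi_power(tf, "Mu_MO", "VOL", cc_ci_map={"Cc": "C3"}, channel_role="Cc")


class TestTopography:
    def test_constant_data(self):
        vals = np.full((4, 100), 3.0)
        t = np.arange(100) / 100.0
        topo = topography(vals, t, ["a", "b", "c", "d"], (0.2, 0.8))
        assert (topo == 3.0).all()

    def test_mirrored_input_gives_mirrored_map(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((2, 100))
        t = np.arange(100) / 100.0
        topo = topography(vals, t, ["C3", "C4"], (0.0, 1.0))
        flipped = topography(vals[::-1], t, ["C3", "C4"], (0.0, 1.0))
        assert topo["C3"] == flipped["C4"]
        assert topo["C4"] == flipped["C3"]
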