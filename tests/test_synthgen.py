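"""Generator invariants: determinism, trial structure, null model, spectra."""

import numpy as np
import pytest

from exobci.config import POPULATION_EFFECTS
from exobci.io_prep import epoch
from exobci.synthgen import (
    ground_truth,
    make_subject_profile,
    simulate_run,
    simulate_session,
)

from conftest import small_params, zero_effect_params


class TestSubjectProfile:
    def test_deterministic_under_seed(self):
        p = small_params()
        a = make_subject_profile("HS", p, seed=1)
        b = make_subject_profile("HS", p, seed=1)
        assert a.effects == b.effects and a.noise_scale == b.noise_scale

    def test_stroke_profiles_have_unilateral_affected_side(self):
        p = small_params()
        sides = {make_subject_profile("SP", p, seed=k).affected_side for k in range(30)}
        assert sides == {"left", "right"}
        assert make_subject_profile("HS", p, seed=0).affected_side == "none"

    def test_zero_sd_draws_equal_population_means(self):
        p = small_params(noise_scale_sd=0.0)
        for key in p.effects:
            p.effects[key] = {n: (m, 0.0) for n, (m, _) in p.effects[key].items()}
        prof = make_subject_profile("HS", p, seed=5)
        for task in ("VOL", "PAS"):
            expected = {n: m for n, (m, _) in POPULATION_EFFECTS[("HS", task)].items()}
            assert prof.effects[(task, "any")] == pytest.approx(expected)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            make_subject_profile("XX", small_params(), seed=0)


class TestSimulateRun:
    def test_event_count_and_balance(self, hs_profile, small_run):
        hands = [e.hand for e in small_run.events]
        n = small_params().trials_per_run
        assert len(hands) == n
        assert hands.count("left") == hands.count("right") == n // 2

    def test_default_trial_structure_is_80_per_run(self):
        p = small_params(trials_per_run=80)
        rec = simulate_run(make_subject_profile("HS", p, seed=2), "VOL", 0, p)
        hands = [e.hand for e in rec.events]
        assert len(rec.events) == 80
        assert hands.count("left") == hands.count("right") == 40

    def test_bit_identical_under_same_inputs(self, hs_profile):
        p = small_params(trials_per_run=8)
        a = simulate_run(hs_profile, "VOL", 0, p)
        b = simulate_run(hs_profile, "VOL", 0, p)
        assert np.array_equal(a.data, b.data)
        assert [e.sample for e in a.events] == [e.sample for e in b.events]

    def test_run_index_out_of_range(self, hs_profile):
        with pytest.raises(ValueError):
            simulate_run(hs_profile, "VOL", 99, small_params())

    def test_null_injection_has_no_event_locked_mean(self):
        """With zero effects the event-locked average tends to zero (3 SEM)."""
        p = zero_effect_params(trials_per_run=100, noise_scale_sd=0.0)
        prof = make_subject_profile("HS", p, seed=3)
        rec = simulate_run(prof, "PAS", 1, p)
        eps = epoch(rec, (-1.0, 2.0))
        for ch in ("C3", "C4", "FCz"):
            x = eps.data[:, eps.ch_index(ch), :]
            mask = eps.time_axis >= 0.4
            window_means = x[:, mask].mean(axis=1)
            sem = window_means.std(ddof=1) / np.sqrt(len(window_means))
            assert abs(window_means.mean()) < 3 * sem + 1e-9

    def test_laterality_flip_swaps_pattern(self):
        """Mean slow-wave amplitude is larger at the contralateral channel and
        swaps C3<->C4 with the moved hand."""
        p = small_params(trials_per_run=40, noise_scale_sd=0.0, pink_noise_uv=0.5,
                         white_noise_uv=0.1)
        for key in p.effects:
            p.effects[key] = {n: (0.0, 0.0) for n in p.effects[key]}
            p.effects[key]["slow_wave_cc"] = (-10.0, 0.0)
            p.effects[key]["slow_wave_ci"] = (-2.0, 0.0)
        prof = make_subject_profile("HS", p, seed=4)
        rec = simulate_run(prof, "PAS", 1, p)
        eps = epoch(rec, (-0.5, 2.5))
        win = (eps.time_axis >= 0.4) & (eps.time_axis <= 1.9)
        out = {}
        for hand in ("left", "right"):
            mask = (eps.trials["hand"] == hand).to_numpy()
            erp = eps.data[mask].mean(axis=0)
            out[hand] = {ch: erp[eps.ch_index(ch), win].mean() for ch in ("C3", "C4")}
        assert out["right"]["C3"] < out["right"]["C4"] < 0
        assert out["left"]["C4"] < out["left"]["C3"] < 0
        assert out["right"]["C3"] == pytest.approx(out["left"]["C4"], abs=1.0)

    def test_background_spectrum_follows_one_over_f(self):
        """Welch log-log slope of the pure-noise background is ~ -1."""
        from scipy.signal import welch

        p = zero_effect_params(trials_per_run=8, white_noise_uv=0.0,
                               noise_scale_sd=0.0, theta_amp_uv=0.0,
                               mu_amp_uv=0.0, beta_amp_uv=0.0)
        prof = make_subject_profile("HS", p, seed=6)
        rec = simulate_run(prof, "VOL", 0, p)
        f, pxx = welch(rec.data[rec.ch_index("Pz")], fs=p.sampling_rate, nperseg=4096)
        band = (f >= 1.0) & (f <= 40.0)
        slope = np.polyfit(np.log(f[band]), np.log(pxx[band]), 1)[0]
        assert slope == pytest.approx(-p.pink_slope, abs=0.25)


class TestSession:
    def test_session_structure(self, hs_profile):
        p = small_params(trials_per_run=8, runs_per_task=2)
        recs, truth = simulate_session(hs_profile, p)
        assert len(recs) == 4
        assert sum(len(r.events) for r in recs) == 32
        assert sorted({r.meta["task"] for r in recs}) == ["PAS", "VOL"]

    def test_ground_truth_is_bookkeeping_identity(self, hs_profile):
        truth = ground_truth(hs_profile)
        assert len(truth) == 2  # HS: one row per task
        for _, row in truth.iterrows():
            drawn = hs_profile.effects[(row["task"], row["side_cat"])]
            for name, val in drawn.items():
                assert row[name] == val

    def test_sp_ground_truth_covers_both_sides(self):
        prof = make_subject_profile("SP", small_params(), seed=9)
        truth = ground_truth(prof)
        assert len(truth) == 4
        assert set(truth["group"]) == {"USP", "ASP"}
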