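"""Generator contracts: schedules, envelopes, visual drives, EEG, behavior."""

import numpy as np
import pandas as pd
import pytest

from avmsi.inference import dprime
from avmsi.synthetic import (
    make_forward_model,
    make_schedule,
    simulate_behavior,
    simulate_envelope,
    simulate_trial_eeg,
    simulate_visual_signal,
)


class TestSchedule:
    def test_experiment_1_counts(self):
        df = make_schedule(1, seed=0)
        assert len(df) == 60
        assert (df.groupby("modality").size() == 20).all()
        assert set(df.gaze) == {"c"}

    def test_experiment_2_counts(self):
        df = make_schedule(2, seed=0)
        assert len(df) == 84
        assert (df.groupby(["modality", "gaze"]).size() == 14).all()
        assert set(df.gaze) == {"d", "e"}

    def test_side_balance_within_cells(self):
        for exp in (1, 2):
            df = make_schedule(exp, seed=3)
            for _, cell in df.groupby(["modality", "gaze"]):
                sides = cell.attended_side.value_counts()
                assert abs(sides.get("L", 0) - sides.get("R", 0)) <= 1

    def test_determinism_and_seed_sensitivity(self):
        a = make_schedule(2, seed=7)
        b = make_schedule(2, seed=7)
        c = make_schedule(2, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(3, seed=0)

    def test_congruence_follows_modality(self):
        df = make_schedule(1, seed=0)
        assert (df.congruent == (df.modality == "AV")).all()


class TestEnvelope:
    def test_length_and_standardization(self):
        env = simulate_envelope(60.0, 64.0, seed=0)
        assert len(env.values) == 3840
        assert abs(env.values.mean()) < 1e-12
        assert abs(env.values.std() - 1.0) < 1e-12
        assert np.all(env.nonneg >= 0)

    def test_independent_seeds_nearly_uncorrelated(self):
        rs = []
        for s in range(40):
            a = simulate_envelope(60.0, 64.0, seed=2 * s).values
            b = simulate_envelope(60.0, 64.0, seed=2 * s + 1).values
            rs.append(np.corrcoef(a, b)[0, 1])
        assert np.max(np.abs(rs)) < 0.15
        assert abs(np.mean(rs)) < 0.03

    def test_modulation_band_limited(self):
        env = simulate_envelope(60.0, 64.0, seed=1).values
        spec = np.abs(np.fft.rfft(env)) ** 2
        freqs = np.fft.rfftfreq(len(env), 1 / 64.0)
        low = spec[(freqs > 0) & (freqs <= 8)].sum()
        high = spec[freqs > 12].sum()
        assert low > 20 * high

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            simulate_envelope(0.0, 64.0, seed=0)
        with pytest.raises(ValueError):
            simulate_envelope(10.0, -1.0, seed=0)

    def test_determinism(self):
        a = simulate_envelope(10.0, 64.0, seed=5).values
        b = simulate_envelope(10.0, 64.0, seed=5).values
        np.testing.assert_array_equal(a, b)


class TestVisualSignal:
    def test_identity_when_no_transform(self):
        env = simulate_envelope(20.0, 64.0, seed=0)
        v = simulate_visual_signal(env, lead_ms=0.0, smooth_ms=0.0, jitter_sd=0.0)
        np.testing.assert_array_equal(v.values, env.values)

    @pytest.mark.parametrize("lead_ms", [62.5, 120.0, 250.0])
    def test_crosscorrelation_peaks_at_lead(self, lead_ms):
        env = simulate_envelope(60.0, 64.0, seed=2)
        v = simulate_visual_signal(env, lead_ms=lead_ms, smooth_ms=0.0, jitter_sd=0.0)
        # brute-force scan: correlate v delayed by k samples with the source
        best, best_k = -np.inf, None
        for k in range(-40, 41):
            if k >= 0:
                r = np.corrcoef(v.values[: 3840 - k], env.values[k:])[0, 1]
            else:
                r = np.corrcoef(v.values[-k:], env.values[: 3840 + k])[0, 1]
            if r > best:
                best, best_k = r, k
        assert abs(best_k - round(lead_ms * 64 / 1000)) <= 1

    def test_heavy_jitter_decorrelates(self):
        env = simulate_envelope(60.0, 64.0, seed=3)
        v = simulate_visual_signal(env, lead_ms=0.0, smooth_ms=0.0, jitter_sd=20.0, seed=0)
        assert abs(np.corrcoef(v.values, env.values)[0, 1]) < 0.2

    def test_excessive_lead_rejected(self):
        env = simulate_envelope(2.0, 64.0, seed=0)
        with pytest.raises(ValueError):
            simulate_visual_signal(env, lead_ms=3000.0)


class TestTrialEeg:
    def _row(self, modality="AV", gaze="d"):
        return dict(
            trial_index=0, experiment=2, modality=modality, gaze=gaze,
            attended_side="L", congruent=modality == "AV", duration_s=12.0,
        )

    def test_degenerate_config_is_pure_kernel_response(self):
        """kappa=0, no noise, single stream, no visual -> z-scored h_A * s."""
        fm = make_forward_model(
            n_channels=4, seed=0, kappa=0.0, noise_sd=0.0,
            gain_visual_by_gaze={"d": 0.0, "c": 0.0, "e": 0.0},
            gain_att=1.0, gain_unatt=0.5,
        )
        env = simulate_envelope(12.0, 64.0, seed=1)
        trial = simulate_trial_eeg(self._row(), {"s_att": env}, fm, seed=0)
        expected = fm.gain_att * fm.h_A.apply(env.values)
        expected = (expected - expected.mean(axis=1, keepdims=True)) / expected.std(
            axis=1, keepdims=True
        )
        np.testing.assert_allclose(trial.eeg, expected, atol=1e-12)

    def test_additive_component_sum(self):
        """The stored components reconstruct the (pre-z-score) EEG exactly."""
        fm = make_forward_model(n_channels=6, seed=1, kappa=0.0, noise_sd=1.0)
        env_a = simulate_envelope(12.0, 64.0, seed=2)
        env_u = simulate_envelope(12.0, 64.0, seed=3)
        v_a = simulate_visual_signal(env_a, seed=4)
        v_u = simulate_visual_signal(env_u, seed=5)
        streams = {"s_att": env_a, "s_unatt": env_u, "v_att": v_a, "v_unatt": v_u}
        trial, comps = simulate_trial_eeg(self._row(), streams, fm, seed=9, return_components=True)
        assert set(comps) == {"aud_att", "aud_unatt", "vis_att", "vis_unatt", "noise"}
        total = sum(comps.values())
        z = (total - total.mean(axis=1, keepdims=True)) / total.std(axis=1, keepdims=True)
        np.testing.assert_allclose(trial.eeg, z, atol=1e-12)

    def test_interaction_only_on_congruent_trials(self):
        fm = make_forward_model(n_channels=4, seed=0, kappa=0.5, noise_sd=1.0)
        env = simulate_envelope(12.0, 64.0, seed=1)
        v = simulate_visual_signal(env, seed=2)
        streams = {"s_att": env, "v_att": v}
        _, c_av = simulate_trial_eeg(self._row("AV"), streams, fm, seed=3, return_components=True)
        _, c_a = simulate_trial_eeg(self._row("A"), streams, fm, seed=3, return_components=True)
        assert "interaction_att" in c_av
        assert "interaction_att" not in c_a

    def test_kernel_support_exceeding_trial_rejected(self):
        fm = make_forward_model(n_channels=4, seed=0, noise_sd=1.0)
        env = simulate_envelope(0.2, 64.0, seed=1)
        with pytest.raises(ValueError):
            simulate_trial_eeg(self._row(), {"s_att": env}, fm, seed=0)

    def test_determinism_given_seed(self):
        fm = make_forward_model(n_channels=4, seed=0, noise_sd=2.0)
        env = simulate_envelope(12.0, 64.0, seed=1)
        t1 = simulate_trial_eeg(self._row(), {"s_att": env}, fm, seed=7)
        t2 = simulate_trial_eeg(self._row(), {"s_att": env}, fm, seed=7)
        np.testing.assert_array_equal(t1.eeg, t2.eeg)

    def test_gain_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_forward_model(n_channels=4, seed=0, gain_att=0.3, gain_unatt=0.5)
        with pytest.raises(ValueError):
            make_forward_model(
                n_channels=4, seed=0,
                gain_visual_by_gaze={"d": 0.1, "c": 0.5, "e": 0.2},
            )


class TestBehavior:
    def test_roundtrip_recovers_target_dprime(self):
        sched = make_schedule(1, seed=0, trials_per_cell=50)
        sched = sched[sched.modality == "AV"].reset_index(drop=True)
        events = simulate_behavior(sched, dprime_target=2.0, fa_rate=0.1, seed=0)
        res = dprime(events, duration_s=60.0)
        assert res.n_target_windows > 100
        assert res.dprime == pytest.approx(2.0, abs=0.25)

    def test_zero_dprime_means_hit_rate_equals_fa_rate(self):
        sched = make_schedule(1, seed=1, trials_per_cell=60)
        sched = sched[sched.modality == "AV"].reset_index(drop=True)
        events = simulate_behavior(sched, dprime_target=0.0, fa_rate=0.3, seed=1)
        res = dprime(events, duration_s=60.0)
        assert res.hit_rate == pytest.approx(res.fa_rate, abs=0.08)

    def test_targets_per_trial_between_1_and_6(self):
        sched = make_schedule(2, seed=2)
        events = simulate_behavior(sched, seed=2)
        counts = events.targets.groupby("trial_index").size()
        assert counts.between(1, 6).all()
        assert (events.targets.target_time >= 0).all()
        assert (events.targets.target_time < 60).all()

    def test_infeasible_pair_rejected(self):
        sched = make_schedule(1, seed=0, trials_per_cell=2)
        with pytest.raises(ValueError):
            simulate_behavior(sched, dprime_target=2.0, fa_rate=1.5)
        with pytest.raises(ValueError):
            simulate_behavior(sched, dprime_target=50.0, fa_rate=0.5)

    def test_comprehension_at_chance(self):
        sched = make_schedule(1, seed=3)
        events = simulate_behavior(sched, comprehension_p=0.25, seed=3)
        comp = events.comprehension
        # AV and A trials only, two questions each
        assert (comp.n_questions == 2).all()
        assert len(comp) == 40
        p_hat = comp.n_correct.sum() / comp.n_questions.sum()
        assert p_hat == pytest.approx(0.25, abs=0.12)
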