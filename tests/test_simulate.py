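import math

import numpy as np
import pandas as pd
import pytest

from erpseq.cloze import entropy_bits
from erpseq.preprocess import (
    DEFAULT_ROIS,
    baseline_correct,
    read_epochs,
    reject_artifacts,
    roi_window_mean,
    write_epochs,
)
from erpseq.simulate import (
    TruthParams,
    build_design,
    generate_cloze_responses,
    generate_epochs,
    generate_predictors,
    generate_stop_signal_session,
    generate_trial_amplitudes,
    simulate_trial_table,
)


class TestBuildDesign:
    def test_paper_scale_layout(self):
        layout = build_design(4, 224, seed=0)
        per_subject = layout.table.groupby("subject")
        assert all(len(g) == 224 for _, g in per_subject)
        for _, g in per_subject:
            assert g["condition"].value_counts().eq(56).all()
            assert len(g[g["condition"].isin(["b", "d"])]) == 112
        # Latin square: each subject sees each item exactly once
        assert not layout.table.duplicated(["subject", "item"]).any()

    def test_minimal(self):
        layout = build_design(1, 4, seed=1)
        assert sorted(layout.table["condition"]) == ["a", "b", "c", "d"]

    def test_determinism(self):
        a = build_design(3, 8, seed=7).table
        b = build_design(3, 8, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_not_divisible_errors(self):
        with pytest.raises(ValueError):
            build_design(2, 10)

    def test_post_question_half(self):
        layout = build_design(5, 16, seed=3)
        for _, g in layout.table.groupby("subject"):
            assert g["post_question"].sum() == 8


class TestGenerateClozeResponses:
    def test_validation(self):
        with pytest.raises(ValueError):
            generate_cloze_responses("strong", n_respondents=1)
        with pytest.raises(ValueError):
            generate_cloze_responses("strong", vocab_size=1)
        with pytest.raises(ValueError):
            generate_cloze_responses("unknown")

    def test_concentration_zero_limit(self):
        rs = generate_cloze_responses("strong", 40, concentration=1e-8, seed=5)
        assert len(rs.counts) == 1
        assert entropy_bits(rs.probabilities()) == 0.0

    def test_large_concentration_limit(self):
        # symmetric Dirichlet -> uniform over vocab 8 -> entropy -> log2(8)
        rs = generate_cloze_responses(
            "strong", 5000, vocab_size=8, concentration=1e6, seed=5
        )
        assert entropy_bits(rs.probabilities()) == pytest.approx(3.0, abs=0.1)

    def test_strong_profile_calibration(self):
        # Monte-Carlo oracle over 500 items: mean entropy in [0.5, 0.9] bits
        es = [
            entropy_bits(
                generate_cloze_responses("strong", 30, seed=i).probabilities()
            )
            for i in range(500)
        ]
        assert 0.5 <= np.mean(es) <= 0.9

    def test_weak_profile_calibration(self):
        es = [
            entropy_bits(
                generate_cloze_responses("weak", 30, seed=i).probabilities()
            )
            for i in range(500)
        ]
        assert 2.2 <= np.mean(es) <= 2.7

    def test_determinism(self):
        a = generate_cloze_responses("weak", 30, seed=11).responses
        b = generate_cloze_responses("weak", 30, seed=11).responses
        assert a == b


class TestGeneratePredictors:
    def test_condition_profile_means(self):
        table = generate_predictors(40, seed=2)
        by_cond = table.groupby("condition")["entropy_bits"].mean()
        assert by_cond["a"] < 1.2 and by_cond["b"] < 1.2
        assert by_cond["c"] > 1.8 and by_cond["d"] > 1.8
        # condition a targets the modal completion -> high cloze
        assert table[table.condition == "a"]["proportion_target"].mean() > 0.6
        assert table[table.condition == "b"]["proportion_target"].mean() < 0.2


class TestGenerateTrialAmplitudes:
    def _zero_truth(self, **kw):
        base = dict(
            alpha=0.5,
            beta_constraint=0.0,
            beta_predictability=0.0,
            sigma_subject=np.zeros(3),
            sigma_item=0.0,
            sigma_residual=0.0,
        )
        base.update(kw)
        return TruthParams(**base)

    def test_all_zero_gives_alpha(self):
        layout = build_design(2, 8, seed=0)
        predictors = generate_predictors(8, seed=1)
        tab = generate_trial_amplitudes(self._zero_truth(), layout, predictors, seed=2)
        np.testing.assert_allclose(tab["amplitude"], 0.5)

    def test_deterministic_linear_predictor(self):
        layout = build_design(2, 8, seed=0)
        predictors = generate_predictors(8, seed=1)
        truth = self._zero_truth(beta_constraint=-0.26)
        tab = generate_trial_amplitudes(truth, layout, predictors, seed=2)
        d_amp = tab["amplitude"].iloc[5] - tab["amplitude"].iloc[0]
        d_ent = tab["entropy_centered"].iloc[5] - tab["entropy_centered"].iloc[0]
        assert d_amp == pytest.approx(-0.26 * d_ent, abs=1e-12)

    def test_ols_recovery_at_paper_scale(self):
        truth = TruthParams(alpha=0.5, beta_constraint=-0.26, sigma_residual=8.0)
        layout = build_design(64, 112, seed=0)
        predictors = generate_predictors(112, seed=1)
        tab = generate_trial_amplitudes(truth, layout, predictors, seed=2)
        X = np.column_stack(
            [np.ones(len(tab)), tab["entropy_centered"], tab["log2_cloze_centered"]]
        )
        y = tab["amplitude"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        cov = np.linalg.inv(X.T @ X) * resid.var(ddof=3)
        se = np.sqrt(cov[1, 1])
        assert abs(beta[1] - (-0.26)) < 3 * se

    def test_nonpd_rho_errors(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            TruthParams(rho=bad)

    def test_marginal_variance_matches_formula(self):
        # Monte-Carlo oracle over repeated generation at a fixed design row
        truth = TruthParams(
            sigma_subject=np.array([1.0, 0.5, 0.4]),
            sigma_item=0.8,
            sigma_residual=1.2,
        )
        layout = build_design(2, 4, seed=0)
        predictors = generate_predictors(4, seed=1)
        reps = 400
        amps = np.empty(reps)
        for r in range(reps):
            tab = generate_trial_amplitudes(truth, layout, predictors, seed=1000 + r)
            amps[r] = tab["amplitude"].iloc[0]
            if r == 0:
                x = np.array(
                    [1.0, tab["entropy_centered"].iloc[0], tab["log2_cloze_centered"].iloc[0]]
                )
        Sig = np.diag(truth.sigma_subject) @ truth.rho @ np.diag(truth.sigma_subject)
        expected = truth.sigma_item**2 + truth.sigma_residual**2 + x @ Sig @ x
        # variance of a sample variance ~ 2 var^2 / n
        se = expected * math.sqrt(2.0 / reps)
        assert abs(amps.var(ddof=1) - expected) < 3 * se

    def test_bit_reproducible(self):
        truth = TruthParams()
        _, _, t1 = simulate_trial_table(truth, 3, 8, seed=42)
        _, _, t2 = simulate_trial_table(truth, 3, 8, seed=42)
        pd.testing.assert_frame_equal(t1, t2)


class TestGenerateEpochs:
    def test_flat_template_recovered_exactly(self):
        layout = build_design(1, 8, seed=0)
        roi = DEFAULT_ROIS["PNP"]
        comps = [
            {
                "name": "PNP",
                "electrodes": roi.electrodes,
                "window_ms": roi.window_ms,
                "amplitude": 2.0,
            }
        ]
        epochs, info = generate_epochs(layout, comps, seed=0)
        epochs = baseline_correct(epochs)
        amps = roi_window_mean(epochs, roi)
        np.testing.assert_allclose(amps, 2.0, atol=1e-12)

    def test_window_must_cover_analysis_span(self):
        layout = build_design(1, 4, seed=0)
        with pytest.raises(ValueError):
            generate_epochs(layout, [], window_ms=(-100.0, 1200.0))
        with pytest.raises(ValueError):
            generate_epochs(layout, [], window_ms=(-200.0, 900.0))

    def test_injected_step_flagged(self):
        layout = build_design(1, 4, seed=0)
        epochs, info = generate_epochs(
            layout, [], {"step_rate": 1.0, "blink_rate": 0.0}, seed=1
        )
        flagged = reject_artifacts(epochs)
        assert flagged.reject_flags.all()
        assert all("step" in r for r in flagged.reject_reasons)

    def test_artifact_rate_binomial(self):
        layout = build_design(10, 100, seed=0)  # 1000 epochs
        epochs, info = generate_epochs(
            layout, [], {"blink_rate": 0.1, "step_rate": 0.0}, seed=2
        )
        flagged = reject_artifacts(epochs)
        frac = flagged.reject_flags.mean()
        # binomial 99% bounds around 0.10 at n=1000
        bound = 2.58 * math.sqrt(0.1 * 0.9 / 1000)
        assert abs(frac - 0.1) < bound
        # rejection flags exactly reproduce the injected artifacts
        np.testing.assert_array_equal(flagged.reject_flags, info["artifact_trials"])

    def test_container_roundtrip(self, tmp_path):
        layout = build_design(1, 4, seed=0)
        epochs, _ = generate_epochs(layout, [], {"blink_rate": 0.5}, seed=3)
        epochs = reject_artifacts(epochs)
        path = tmp_path / "epochs.h5"
        write_epochs(path, epochs)
        back = read_epochs(path)
        np.testing.assert_array_equal(back.data, epochs.data)
        np.testing.assert_array_equal(back.reject_flags, epochs.reject_flags)
        assert back.channel_labels == epochs.channel_labels
        assert back.srate == epochs.srate and back.time0 == epochs.time0
        assert back.reject_reasons == epochs.reject_reasons


class TestGenerateStopSignal:
    def test_staircase_clamped(self):
        sess = generate_stop_signal_session(0.0, (5000.0, 1.0), n_trials=400, seed=0)
        ssds = [s for s, _, _ in sess.stop_trials]
        assert min(ssds) >= 50 and max(ssds) <= 1000
        # SSRT 0 and go RTs above the max SSD: goRT > SSD + 0 -> inhibited
        assert not any(r for _, r, _ in sess.stop_trials)

    def test_race_rule_fast_go_always_responds(self):
        # tiny go RTs: goRT < SSD + 0 on every stop trial -> always responds
        sess = generate_stop_signal_session(0.0, (10.0, 1.0), n_trials=400, seed=0)
        assert all(r for _, r, _ in sess.stop_trials)

    def test_minimum_trials(self):
        with pytest.raises(ValueError):
            generate_stop_signal_session(200.0, n_trials=4)

    def test_determinism(self):
        a = generate_stop_signal_session(245.0, n_trials=64, seed=9)
        b = generate_stop_signal_session(245.0, n_trials=64, seed=9)
        assert a.go_trials == b.go_trials and a.stop_trials == b.stop_trials
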