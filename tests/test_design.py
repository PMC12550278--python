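"""HRF kernel, convolution, model builders, drift, concatenation, contrasts."""

import dataclasses
import warnings

import numpy as np
import pytest

from midvif.design import (
    Contrast,
    DesignMatrix,
    EmptyRegressorError,
    HRFSpec,
    RegressorSpec,
    build_cuefeedback_design,
    build_saturated_design,
    concatenate_runs,
    convolve_regressor,
    cosine_drift,
    hrf_kernel,
    make_contrasts,
)

HRF = HRFSpec()
DT = HRF.microtime_dt


class TestHRFKernel:
    def test_canonical_shape(self):
        kernel, _ = hrf_kernel(HRF)
        t = np.arange(len(kernel)) * DT
        peak_t = t[np.argmax(kernel)]
        assert 4.0 < peak_t < 7.0
        assert kernel[0] == 0.0
        # undershoot: negative lobe after the peak
        assert kernel[(t > 10) & (t < 20)].min() < 0

    def test_derivative_integrates_to_zero(self):
        _, dkernel = hrf_kernel(HRF)
        assert abs(dkernel.sum() * DT) < 1e-3

    def test_matches_reference_double_gamma(self):
        """Cross-check against the nilearn spm_hrf convention."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        kernel, _ = hrf_kernel(HRF)
        ref = spm_hrf(0.8, oversampling=50)
        n = min(len(kernel), len(ref))
        r = np.corrcoef(kernel[:n], ref[:n])[0, 1]
        assert r > 0.999
        assert kernel.max() == pytest.approx(ref.max(), rel=0.02)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(microtime_dt=0.0)


class TestConvolveRegressor:
    frame_times = np.arange(0, 120, 0.8)

    def test_doubled_duration_roughly_doubles_peak(self):
        """For brief events, BOLD amplitude scales ~linearly with duration."""
        one = convolve_regressor(RegressorSpec("a", (10.0,), (1.0,)), self.frame_times, HRF)
        two = convolve_regressor(RegressorSpec("b", (10.0,), (2.0,)), self.frame_times, HRF)
        assert two[:, 0].max() / one[:, 0].max() == pytest.approx(2.0, rel=0.10)

    def test_impulse_equals_thin_boxcar(self):
        """Impulse and sub-microtime boxcar coincide (brute-force oracle)."""
        imp = convolve_regressor(RegressorSpec("a", (10.0,), (0.0,)), self.frame_times, HRF)
        thin = convolve_regressor(RegressorSpec("b", (10.0,), (0.001,)), self.frame_times, HRF)
        assert np.allclose(imp, thin, rtol=1e-3)
        # independent microtime convolution oracle
        kernel, _ = hrf_kernel(HRF)
        n_hi = int(round(self.frame_times[-1] / DT)) + 1
        neural = np.zeros(n_hi)
        neural[int(round(10.0 / DT))] = 1.0
        oracle = np.convolve(neural, kernel)[:n_hi][
            np.round(self.frame_times / DT).astype(int)
        ]
        assert np.allclose(imp[:, 0], oracle, atol=1e-12)

    def test_matches_nilearn_regressor(self):
        """Boxcar regressor agrees with nilearn's compute_regressor."""
        from nilearn.glm.first_level.hemodynamic_models import compute_regressor

        onsets = (5.0, 40.0, 80.0)
        durations = (1.9, 1.9, 1.9)
        mine = convolve_regressor(
            RegressorSpec("cue", onsets, durations), self.frame_times, HRF
        )[:, 0]
        ref, _ = compute_regressor(
            np.vstack([onsets, durations, np.ones(3)]),
            "spm", self.frame_times, oversampling=50,
        )
        ref = ref[:, 0]
        assert np.corrcoef(mine, ref)[0, 1] > 0.999
        assert np.abs(mine - ref).max() < 0.05 * ref.max()

    def test_empty_and_zero_regressors_rejected(self):
        with pytest.raises(EmptyRegressorError):
            convolve_regressor(RegressorSpec("a", (), ()), self.frame_times, HRF)
        with pytest.raises(EmptyRegressorError):
            convolve_regressor(
                RegressorSpec("a", (10.0,), (1.0,), (0.0,)), self.frame_times, HRF
            )

    def test_linearity_over_disjoint_events(self):
        a = RegressorSpec("a", (5.0,), (2.0,))
        b = RegressorSpec("b", (60.0,), (2.0,))
        both = RegressorSpec("ab", (5.0, 60.0), (2.0, 2.0))
        col_a = convolve_regressor(a, self.frame_times, HRF)[:, 0]
        col_b = convolve_regressor(b, self.frame_times, HRF)[:, 0]
        col_ab = convolve_regressor(both, self.frame_times, HRF)[:, 0]
        assert np.allclose(col_ab, col_a + col_b, atol=1e-10)

    def test_shift_equivariance(self):
        """Delaying onsets by k TRs shifts the sampled column by k frames."""
        k = 5
        base = convolve_regressor(RegressorSpec("a", (8.0,), (1.5,)), self.frame_times, HRF)[:, 0]
        shifted = convolve_regressor(
            RegressorSpec("a", (8.0 + k * 0.8,), (1.5,)), self.frame_times, HRF
        )[:, 0]
        assert np.allclose(shifted[k:], base[:-k], atol=1e-8)


class TestBuilders:
    def test_cuefeedback_has_30_task_columns(self, cf_design):
        assert len(cf_design.task_columns) == 30
        assert "cue_LargeWin_derivative" in cf_design.column_names

    def test_saturated_has_24_task_columns(self, sat_design):
        assert len(sat_design.task_columns) == 24
        for name in ("probe_win", "probe_loss", "probe_neutral", "rt"):
            assert name in sat_design.column_names
        assert not any(n.endswith("_derivative") for n in sat_design.column_names)

    def test_empty_feedback_cell_dropped_with_warning(self, run):
        all_hit = dataclasses.replace(
            run,
            trials=tuple(
                dataclasses.replace(t, outcome="Hit" if t.condition == "LargeWin" else t.outcome)
                for t in run.trials
            ),
        )
        with pytest.warns(UserWarning, match="feedback_LargeWin_Miss"):
            design = build_cuefeedback_design(all_hit)
        assert len(design.task_columns) == 28
        assert "feedback_LargeWin_Miss" in design.dropped

    def test_all_rts_absent_drops_rt_column(self, run):
        no_rt = dataclasses.replace(
            run, trials=tuple(dataclasses.replace(t, rt=None) for t in run.trials)
        )
        with pytest.warns(UserWarning, match="rt"):
            design = build_saturated_design(no_rt)
        assert len(design.task_columns) == 23
        assert "rt" not in design.column_names

    def test_probe_columns_pool_conditions(self, run, sat_design):
        win_onsets = sorted(
            t.probe_onset for t in run.trials if t.condition in ("LargeWin", "SmallWin")
        )
        # the win probe column responds to 20 trials: compare against a
        # directly built regressor over the pooled onsets
        spec = RegressorSpec(
            "probe_win",
            tuple(win_onsets),
            tuple(
                t.probe_duration
                for t in sorted(run.trials, key=lambda t: t.probe_onset)
                if t.condition in ("LargeWin", "SmallWin")
            ),
        )
        expected = convolve_regressor(spec, sat_design.frame_times)[:, 0]
        assert np.allclose(sat_design.column("probe_win"), expected)


class TestCosineDrift:
    def test_column_count_at_cutoff(self):
        frame_times = np.arange(400) * 0.8  # 320 s
        assert cosine_drift(frame_times, cutoff=128.0).shape[1] == 5

    def test_orthogonality(self):
        basis = cosine_drift(np.arange(400) * 0.8, cutoff=128.0)
        gram = basis.T @ basis
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_long_cutoff_gives_single_column(self):
        frame_times = np.arange(100) * 0.8
        assert cosine_drift(frame_times, cutoff=1000.0).shape[1] == 1

    def test_cutoff_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cosine_drift(np.arange(100) * 0.8, cutoff=1.0)


class TestConcatenateRuns:
    def test_frames_add_and_nuisance_blocks(self, run, params):
        from midvif.task import simulate_run

        run2 = simulate_run(params, run_id=1, seed=321)
        d1 = build_saturated_design(run)
        d2 = build_saturated_design(run2)
        cat = concatenate_runs([d1, d2])
        assert cat.n_frames == d1.n_frames + d2.n_frames
        intercepts = [n for n, r in zip(cat.column_names, cat.column_roles)
                      if r == "intercept"]
        assert intercepts == ["run1_intercept", "run2_intercept"]
        # run-1 intercept is zero over run-2 frames
        assert np.all(cat.column("run1_intercept")[d1.n_frames:] == 0)

    def test_run_specific_column_zero_filled(self, run, params):
        from midvif.task import simulate_run

        run2 = simulate_run(params, run_id=1, seed=321)
        no_rt = dataclasses.replace(
            run, trials=tuple(dataclasses.replace(t, rt=None) for t in run.trials)
        )
        with pytest.warns(UserWarning):
            d1 = build_saturated_design(no_rt)
        d2 = build_saturated_design(run2)
        cat = concatenate_runs([d1, d2])
        assert "rt" in cat.column_names
        assert np.all(cat.column("rt")[: d1.n_frames] == 0)
        assert not np.all(cat.column("rt")[d1.n_frames:] == 0)

    def test_mismatched_tr_rejected(self, run):
        d1 = build_saturated_design(run, tr=0.8)
        d2 = build_saturated_design(run, tr=1.0)
        with pytest.raises(ValueError, match="tr"):
            concatenate_runs([d1, d2])


class TestMakeContrasts:
    def test_standard_contrast_weights(self, sat_design):
        contrasts = {c.name: c for c in make_contrasts(sat_design)}
        assert len(contrasts) == 7
        whw = contrasts["FB:WHit-WMiss"].as_dict(sat_design)
        assert whw == {
            "feedback_LargeWin_Hit": 0.5, "feedback_SmallWin_Hit": 0.5,
            "feedback_LargeWin_Miss": -0.5, "feedback_SmallWin_Miss": -0.5,
        }
        lw_base = contrasts["Cue:LW-Base"].as_dict(sat_design)
        assert lw_base == {"cue_LargeWin": 1.0}
        assert contrasts["Cue:LW-Neut"].starred
        assert not contrasts["FB:LWHit-Base"].starred

    def test_nuisance_weights_all_zero(self, sat_design):
        nuis = [sat_design.index(n) for n in sat_design.nuisance_columns]
        for c in make_contrasts(sat_design):
            assert np.all(c.weights[nuis] == 0)

    def test_missing_column_skips_contrast(self, run):
        all_hit = dataclasses.replace(
            run,
            trials=tuple(
                dataclasses.replace(t, outcome="Hit" if t.condition == "LargeWin" else t.outcome)
                for t in run.trials
            ),
        )
        with pytest.warns(UserWarning):
            design = build_cuefeedback_design(all_hit)
        with pytest.warns(UserWarning, match="skipped"):
            names = [c.name for c in make_contrasts(design)]
        assert "FB:WHit-WMiss" not in names
        assert "Cue:LW-Neut" in names


class TestDesignMatrixIO:
    def test_csv_round_trip(self, sat_design, tmp_path):
        csv, sidecar = tmp_path / "design.csv", tmp_path / "design.json"
        sat_design.to_csv(csv, sidecar_path=sidecar)
        back = DesignMatrix.from_csv(csv, sidecar)
        assert back.column_names == sat_design.column_names
        assert back.column_roles == sat_design.column_roles
        assert np.allclose(back.values, sat_design.values)
        assert back.tr == sat_design.tr
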