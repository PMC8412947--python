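"""Synthetic trial/MVC generators and their analytic ground truth."""

import numpy as np
import pandas as pd
import pytest

from mtulab import (
    SyntheticTrialConfig,
    ValidationError,
    compute_ground_truth,
    fit_force_length,
    generate_mvc_dataset,
    generate_trial,
)


class TestTrialGeneration:
    def test_soleus_fascicle_spans_preset_endpoints_exactly(self, soleus_trial):
        f = soleus_trial.traces["fascicle_mm"].values
        L0 = soleus_trial.config.L0_mm
        i, j = soleus_trial.window.touchdown_index, soleus_trial.window.toeoff_index
        assert f[i] == pytest.approx(0.994 * L0, abs=1e-12)
        assert f[j] == pytest.approx(0.752 * L0, abs=1e-12)
        assert np.all(np.diff(f[i : j + 1]) <= 0)  # continuous shortening

    def test_vl_is_near_isometric(self, vl_trial):
        f = vl_trial.traces["fascicle_mm"].values
        L0 = vl_trial.config.L0_mm
        assert np.max(np.abs(f - f.mean())) / L0 < 0.02

    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticTrialConfig.from_preset("soleus_like", seed=7)
        a = generate_trial(cfg).to_dataframe()
        b = generate_trial(cfg).to_dataframe()
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_different_seed_differs(self):
        a = generate_trial(SyntheticTrialConfig.from_preset("soleus_like", seed=1))
        b = generate_trial(SyntheticTrialConfig.from_preset("soleus_like", seed=2))
        assert not np.allclose(a.traces["emg_V"].values, b.traces["emg_V"].values)

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticTrialConfig.from_preset("gastrocnemius_like")

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticTrialConfig.from_preset("soleus_like", stance_duration=0.0)

    def test_traces_share_time_base(self, soleus_trial):
        traces = list(soleus_trial.traces.values())
        assert all(traces[0].same_time_base(t) for t in traces[1:])

    def test_ground_truth_finite(self, soleus_trial, vl_trial):
        for trial in (soleus_trial, vl_trial):
            assert all(np.isfinite(v) for v in trial.ground_truth.values())

    def test_csv_round_trip(self, tmp_path, soleus_trial):
        path = tmp_path / "trial.csv"
        soleus_trial.save(path)
        df = pd.read_csv(path)
        assert list(df.columns)[0] == "time_s"
        assert np.allclose(df["fascicle_mm"], soleus_trial.traces["fascicle_mm"].values)


class TestGroundTruthIndependence:
    @pytest.mark.parametrize("preset", ["soleus_like", "vl_like"])
    def test_ten_times_finer_grid_agrees(self, preset):
        cfg = SyntheticTrialConfig.from_preset(preset, noise_sd=0.0)
        base = compute_ground_truth(cfg, n_grid=2001)
        fine = compute_ground_truth(cfg, n_grid=20001)
        for k, v in base.items():
            ref = fine[k]
            scale = max(abs(ref), 1e-9)
            assert abs(v - ref) / scale < 1e-6, k


class TestMvcGeneration:
    def test_noiseless_fit_recovers_generator_exactly(self):
        df = generate_mvc_dataset(41.3, 2887.0, n_angles=8)
        curve = fit_force_length(df["fascicle_mm"], df["force_N"])
        assert curve.L0_mm == pytest.approx(41.3, rel=1e-9)
        assert curve.Fmax_N == pytest.approx(2887.0, rel=1e-9)

    def test_three_points_interpolate_exactly(self):
        df = generate_mvc_dataset(50.0, 2000.0, n_angles=3, curvature=-2.0)
        curve = fit_force_length(df["fascicle_mm"], df["force_N"])
        assert np.allclose(curve.force(df["fascicle_mm"].to_numpy()), df["force_N"], atol=1e-8)

    def test_monte_carlo_recovery_bias_below_2_percent(self):
        # 200 noisy draws at 50 N noise, 8 angles
        recovered = []
        for seed in range(200):
            df = generate_mvc_dataset(41.3, 2887.0, n_angles=8, noise_sd=50.0, seed=seed)
            recovered.append(fit_force_length(df["fascicle_mm"], df["force_N"]).L0_mm)
        assert abs(np.mean(recovered) - 41.3) / 41.3 < 0.02

    def test_too_few_angles(self):
        with pytest.raises(ValidationError):
            generate_mvc_dataset(41.3, 2887.0, n_angles=2)

    def test_lengths_span_vertex(self):
        df = generate_mvc_dataset(41.3, 2887.0)
        assert df["fascicle_mm"].min() < 41.3 < df["fascicle_mm"].max()
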