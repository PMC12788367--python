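"""Metrics, baseline estimators and the end-to-end runner."""

import json

import numpy as np
import pandas as pd
import pytest

from thermobreath.errors import ConfigurationError
from thermobreath.evaluation import (
    baseline_fft_rr,
    baseline_peak_rr,
    mae_rmse,
    run_benchmark,
    summarize_benchmark,
)
from thermobreath.frame_codec import write_trf
from thermobreath.pipeline import PipelineConfig, process_signal, run_pipeline
from thermobreath.synthetic import (
    BreathTruth,
    SyntheticBreathParams,
    paced_protocol,
    render_synthetic_video,
    simulate_breath_signal,
)

F_CAM = 25.0
T = np.arange(0, 60, 1 / F_CAM)


class TestMaeRmse:
    @pytest.mark.parametrize(
        "est,ref,expected",
        [
            ([10, 20, 30], [10, 20, 30], (0.0, 0.0)),
            ([11, 9], [10, 10], (1.0, 1.0)),
            ([10, 12], [10, 10], (1.0, np.sqrt(2.0))),
        ],
    )
    def test_hand_computed_errors(self, est, ref, expected):
        assert mae_rmse(est, ref) == pytest.approx(expected)

    def test_rmse_never_below_mae(self, rng):
        for _ in range(20):
            est = rng.normal(18, 3, size=15)
            ref = rng.normal(18, 3, size=15)
            mae, rmse = mae_rmse(est, ref)
            assert rmse >= mae >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            mae_rmse([1, 2], [1])


class TestPeakBaseline:
    def test_noiseless_sinusoid_counts_breaths(self):
        rr = baseline_peak_rr(np.sin(2 * np.pi * 0.3 * T), F_CAM)
        assert rr == pytest.approx(18.0, abs=1.0)

    def test_constant_signal_gives_zero_rate(self):
        assert baseline_peak_rr(np.zeros(1500), F_CAM) == 0.0

    def test_too_short_signal_not_ready(self):
        assert baseline_peak_rr(np.zeros(10), F_CAM) is None

    def test_heavy_noise_hurts_peak_counting_more_than_pipeline(self):
        """Paired comparison on identical heavily corrupted inputs: averaged
        over the batch, the adaptive pipeline must beat raw peak counting."""
        errs_pipe, errs_peak = [], []
        rate = 16.7
        for seed in range(8):
            phase = np.random.default_rng(seed).uniform(0, 2 * np.pi)
            params = SyntheticBreathParams(
                f_rr=rate / 60.0, noise_sd=0.9, drift_amp=0.3, phase=phase, seed=seed
            )
            truth = simulate_breath_signal(params)
            result = process_signal(truth.samples, F_CAM)
            rr_peak = baseline_peak_rr(result.trace.filtered, F_CAM)
            errs_pipe.append(abs(result.rr.mean_rr - rate))
            errs_peak.append(abs(rr_peak - rate))
        assert np.mean(errs_pipe) < np.mean(errs_peak)


class TestFftBaseline:
    def test_noiseless_sinusoid_within_one_bin(self):
        rr = baseline_fft_rr(29.0 + 1.5 * np.sin(2 * np.pi * 0.3 * T), F_CAM)
        assert rr == pytest.approx(18.0, abs=1.0)

    def test_two_equal_tones_tie_break_to_lower_frequency(self):
        x = 29.0 + np.sin(2 * np.pi * 0.2 * T) + np.sin(2 * np.pi * 0.4 * T)
        assert baseline_fft_rr(x, F_CAM) == pytest.approx(12.0, abs=1.0)

    def test_pure_subband_drift_yields_sentinel(self):
        x = 29.0 + 0.5 * np.sin(2 * np.pi * 0.02 * T)
        assert baseline_fft_rr(x, F_CAM) is None

    def test_short_record_yields_sentinel(self):
        assert baseline_fft_rr(np.ones(100), F_CAM) is None


class TestBenchmark:
    def test_summary_reports_all_methods(self):
        df = run_benchmark(n_signals=4, seed=5)
        summary = summarize_benchmark(df)
        assert summary["n_signals"] == 4
        for method in ("pipeline", "peak", "fft"):
            assert summary[f"rmse_{method}"] >= summary[f"mae_{method}"] >= 0

    def test_benchmark_deterministic_under_seed(self):
        a = run_benchmark(n_signals=3, seed=9)
        b = run_benchmark(n_signals=3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_grid_mode_generates_n_per_rate(self):
        df = run_benchmark(rates_bpm=[12.0, 18.0], n_per_rate=2, seed=5)
        assert len(df) == 4
        assert sorted(df["rate_bpm"].unique()) == [12.0, 18.0]


class TestPipelineConfig:
    def test_yaml_keys_reach_every_stage(self, tmp_path):
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(
            "filter: {low_hz: 0.1, high_hz: 0.6, order: 4}\n"
            "phase: {velocity_window: 4, mad_window: 19, sensitivity: 0.5,\n"
            "        dwell_s: 0.2, consolidation_s: 0.4, neutral: true}\n"
            "detector: {stride: 3, confidence_min: 0.5}\n"
            "tracker: {q_scale: 2.0, r_scale: 9.0, max_coast_frames: 10}\n"
            "extraction: {percentile: 2.0}\n"
        )
        cfg = PipelineConfig.from_yaml(cfg_path)
        assert cfg.filter.low_hz == 0.1 and cfg.filter.high_hz == 0.6
        assert cfg.phase.velocity_window == 4 and cfg.phase.neutral_enabled
        assert cfg.stride == 3 and cfg.confidence_min == 0.5
        assert cfg.q_scale == 2.0 and cfg.max_coast_frames == 10
        assert cfg.percentile == 2.0
        assert cfg.kalman(25.0).r_scale == 9.0

    def test_snapshot_roundtrips_through_dict(self):
        cfg = PipelineConfig()
        assert PipelineConfig.from_dict(cfg.to_dict()) == cfg


@pytest.fixture(scope="module")
def paced_fixture(tmp_path_factory):
    """Rendered paced-breathing fixture: .trf stream + ground-truth CSV."""
    from thermobreath.synthetic import SceneParams

    out = tmp_path_factory.mktemp("fixture")
    base = SyntheticBreathParams(noise_sd=0.15, drift_amp=0.3, seed=4)
    protocol = paced_protocol([12.0, 18.0, 24.0], 60.0, base)
    scene = SceneParams(height=72, width=96, face_axes=(20.0, 24.0))
    truth = BreathTruth(
        samples=protocol.samples,
        times=protocol.times,
        phase_truth=protocol.phase_truth,
        rr_true=18.0,
        params=base,
    )
    frames, rois = render_synthetic_video(truth, scene)
    write_trf(out / "fixture.trf", frames, base.f_cam)
    pd.DataFrame(
        {
            "frame_index": np.arange(len(frames)),
            "x1": rois[:, 0],
            "y1": rois[:, 1],
            "x2": rois[:, 2],
            "y2": rois[:, 3],
        }
    ).to_csv(out / "truth.csv", index=False)
    return out, protocol


class TestRunPipeline:
    def test_paced_fixture_recovers_each_block_within_clinical_tolerance(
        self, paced_fixture, tmp_path
    ):
        """Every paced block's mean estimated rate must sit within the 2 BPM
        clinical tolerance of its guided rate."""
        fixture_dir, protocol = paced_fixture
        run_pipeline(
            fixture_dir / "fixture.trf",
            tmp_path,
            truth_csv=fixture_dir / "truth.csv",
            seed=2,
            jitter_px=1.0,
            miss_rate=0.05,
        )
        trace = pd.read_csv(tmp_path / "trace.csv")
        rr = trace["rr_final"].to_numpy()
        for i, rate in enumerate(protocol.rates):
            sl = protocol.block_slice(i)
            block_mean = np.nanmean(rr[sl])
            assert abs(block_mean - rate) < 2.0

    def test_detector_calls_follow_stride_schedule(self, paced_fixture, tmp_path):
        fixture_dir, protocol = paced_fixture
        report = run_pipeline(
            fixture_dir / "fixture.trf",
            tmp_path,
            truth_csv=fixture_dir / "truth.csv",
            seed=2,
        )
        n = report["n_frames"]
        assert report["detector_calls"] == -(-n // 2)  # ceil(N/2)

    def test_rerun_same_seed_is_identical(self, paced_fixture, tmp_path):
        fixture_dir, _ = paced_fixture
        outs = []
        for sub in ("a", "b"):
            run_pipeline(
                fixture_dir / "fixture.trf",
                tmp_path / sub,
                truth_csv=fixture_dir / "truth.csv",
                seed=11,
                jitter_px=1.5,
                miss_rate=0.1,
            )
            outs.append(pd.read_csv(tmp_path / sub / "trace.csv"))
        pd.testing.assert_frame_equal(outs[0], outs[1])

    def test_signal_csv_input_bypasses_frame_stages(self, tmp_path):
        from thermobreath.signal_extraction import BreathSignal, Sample

        params = SyntheticBreathParams(f_rr=0.3, noise_sd=0.05, drift_amp=0.0, seed=6)
        truth = simulate_breath_signal(params)
        sig = BreathSignal(f_cam=F_CAM, window_s=70.0)
        for k, v in enumerate(truth.samples):
            sig.push(Sample(k, float(v), (0, 0), 1))
        csv_path = tmp_path / "signal.csv"
        sig.to_csv(csv_path)
        report = run_pipeline(csv_path, tmp_path / "out", seed=0)
        assert report["n_frames"] is None
        assert report["mean_rr_bpm"] == pytest.approx(18.0, abs=0.5)
        assert json.loads((tmp_path / "out" / "report.json").read_text())["seed"] == 0
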