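"""Non-stationary fluctuation analysis: selection, variance, parabola fit."""

import numpy as np
import pytest

from asickin.nsfa import (
    baseline_variance,
    bin_current_variance,
    exclude_artifact_sweeps,
    fit_current_variance,
    pairwise_variance,
    run_nsfa,
    select_stable_stretch,
)
from asickin.sweeps import RecordingMeta, StimulusEpoch, StimulusProtocol
from asickin.synth import (
    EnsembleSpec,
    NoiseModel,
    activation_desensitization_popen,
    generate_nsfa_block,
)

from conftest import make_square_block


def nsfa_block(n_channels=100, i_single=-0.6, p_peak=0.86, n_sweeps=70, seed=1,
               noise_sd=0.3, rundown=0.0, jitter=0.0, dt=1e-4, epoch=0.5):
    protocol = StimulusProtocol(
        epochs=(StimulusEpoch(0.1, epoch, 5.0, "test"),), rest_level=8.0
    )
    t_end = 0.1 + epoch + 0.05
    grid = np.arange(0.0, t_end, dt)
    popen = activation_desensitization_popen(grid, p_peak, 0.003, 0.181, 0.1)
    spec = EnsembleSpec(n_channels=n_channels, single_channel_current=i_single, popen=popen)
    noise = NoiseModel(baseline_sd=noise_sd, rundown_per_sweep=rundown, rundown_jitter_sd=jitter)
    return generate_nsfa_block(spec, protocol, n_sweeps, noise, seed,
                               sample_interval=dt, t_end=t_end)


class TestStableStretch:
    def test_longest_run_wins_over_earlier_shorter_run(self):
        block = make_square_block([-100, -95, -200, -101, -99, -98])
        assert select_stable_stretch(block, tolerance=0.10) == [3, 4, 5]

    def test_identical_peaks_keep_everything(self):
        block = make_square_block([-70] * 6)
        assert select_stable_stretch(block) == list(range(6))

    def test_zero_tolerance_distinct_peaks_errors(self):
        block = make_square_block([-100, -90, -80])
        with pytest.raises(ValueError, match="stable stretch"):
            select_stable_stretch(block, tolerance=0.0)


class TestArtifactExclusion:
    def test_clean_block_keeps_all(self):
        block = make_square_block([-100] * 10, noise_sd=0.5, seed=3)
        assert exclude_artifact_sweeps(block) == list(range(10))

    def test_injected_spike_is_flagged(self):
        block = make_square_block([-100] * 10, noise_sd=0.5, seed=3)
        block.sweeps[4].current[300] += 50.0  # brief electrical artifact
        assert exclude_artifact_sweeps(block) == [i for i in range(10) if i != 4]

    def test_infinite_threshold_disables_filter(self):
        block = make_square_block([-100] * 5, noise_sd=0.5, seed=3)
        block.sweeps[2].current[250] += 500.0
        assert exclude_artifact_sweeps(block, np.inf) == list(range(5))


class TestPairwiseVariance:
    def test_identical_sweeps_zero_variance(self):
        block = make_square_block([-80, -80])
        trace = pairwise_variance(block)
        np.testing.assert_array_equal(trace.ensemble_variance, 0.0)

    def test_two_constant_sweeps_direct_value(self):
        # sweeps at 0 and 2 pA: (2-0)^2/2 = 2 pA^2 everywhere
        from asickin.sweeps import Sweep, SweepBlock

        t = np.arange(100) * 1e-4
        meta = RecordingMeta(sample_interval=1e-4)
        stim = np.full(100, 8.0)
        prot = StimulusProtocol(epochs=(StimulusEpoch(5e-3, 3e-3, 5.0, "test"),), rest_level=8.0)
        block = SweepBlock(
            sweeps=[Sweep(t, np.zeros(100), stim, meta, 0),
                    Sweep(t, np.full(100, 2.0), stim, meta, 1)],
            protocol=prot,
        )
        trace = pairwise_variance(block)
        np.testing.assert_allclose(trace.ensemble_variance, 2.0)
        assert trace.n_pairs == 1

    def test_unbiased_for_stationary_gaussian_noise(self):
        """Mean pairwise variance converges to sigma^2 for i.i.d. sweeps."""
        sigma = 2.0
        block = make_square_block([0.0] * 500, noise_sd=sigma, seed=9,
                                  sample_interval=1e-3, t_end=0.7)
        trace = pairwise_variance(block)
        est = trace.ensemble_variance.mean()
        # variance-of-variance of the pooled estimator, 3 sigma
        n_eff = (500 - 1) * trace.time.size
        tol = 3 * sigma**2 * np.sqrt(2.0 / n_eff) * 3  # pairs share sweeps: inflate
        assert abs(est - sigma**2) < max(tol, 0.05 * sigma**2)

    def test_insensitive_to_linear_rundown(self):
        """Scaling sweep k by (1 + k*eps) perturbs the estimate only at O(eps^2)."""
        base = make_square_block([-100.0] * 30, noise_sd=0.0)
        eps = 0.01
        for k, sw in enumerate(base.sweeps):
            sw.current *= 1.0 + k * eps
        trace = pairwise_variance(base)
        # drift-induced variance: (100*eps)^2/2 = 0.5 pA^2 at peak, O(eps^2)
        assert trace.ensemble_variance.max() <= (100 * eps) ** 2 / 2 + 1e-9


class TestBaselineVariance:
    def test_noiseless_block_zero(self):
        block = make_square_block([-50, -50, -50])
        assert baseline_variance(block) == 0.0

    def test_gaussian_noise_recovers_sigma_squared(self):
        block = make_square_block([0.0] * 200, noise_sd=2.0, seed=5)
        est = baseline_variance(block, window=0.05)
        assert est == pytest.approx(4.0, rel=0.15)

    def test_zero_window_errors(self):
        block = make_square_block([-50, -50])
        with pytest.raises(ValueError, match="positive"):
            baseline_variance(block, window=0.0)

    def test_window_into_stimulation_errors(self):
        block = make_square_block([-50, -50])
        with pytest.raises(ValueError, match="stimulation"):
            baseline_variance(block, window=0.5)


class TestBinning:
    def test_monotone_decay_gives_ordered_bins(self):
        from asickin.nsfa import VarianceTrace

        t = np.arange(1000) * 1e-4
        current = -100 * np.exp(-t / 0.02)
        trace = VarianceTrace(time=t, mean_current=current,
                              ensemble_variance=np.abs(current), n_pairs=10)
        bc, bv = bin_current_variance(trace, (0, 1000), n_bins=5)
        assert len(bc) == 5
        assert np.all(np.diff(np.abs(bc)) > 0) or np.all(np.diff(np.abs(bc)) < 0)

    def test_flat_zero_current_errors(self):
        from asickin.nsfa import VarianceTrace

        trace = VarianceTrace(time=np.arange(100) * 1e-4,
                              mean_current=np.zeros(100),
                              ensemble_variance=np.zeros(100), n_pairs=5)
        with pytest.raises(ValueError, match="dynamic range"):
            bin_current_variance(trace, (0, 100))

    def test_binned_points_lie_on_true_parabola(self):
        """Binomial-generated block: binned (I, sigma^2) follow i*I - I^2/N."""
        n, i = 100, -0.6
        block = nsfa_block(n_channels=n, i_single=i, n_sweeps=200, noise_sd=0.0, seed=21)
        trace = pairwise_variance(block)
        w0, w1 = int(0.1 / 1e-4), int(0.6 / 1e-4)
        bc, bv = bin_current_variance(trace, (w0, w1), n_bins=10)
        expected = i * bc - bc**2 / n
        # 3 sigma of the variance-of-variance per bin (M-1 = 199 pairs)
        tol = 3 * expected * np.sqrt(2.0 / 199) + 0.05
        assert np.all(np.abs(bv - expected) < np.maximum(tol, 0.1 * expected))


class TestParabolaFit:
    def test_exact_points_recovered_to_machine_precision(self):
        i, n = 1.0, 100.0
        I = np.linspace(5, 95, 10)
        V = i * I - I**2 / n
        res = fit_current_variance(I, V, 0.0, RecordingMeta())
        assert res.i_single == pytest.approx(1.0, abs=1e-10)
        assert res.n_channels == pytest.approx(100.0, abs=1e-7)

    def test_vertex_of_fitted_parabola(self):
        i, n, base = -0.5, 200.0, 3.0
        I = np.linspace(-90, -5, 12)
        V = i * I - I**2 / n + base
        res = fit_current_variance(I, V, base, RecordingMeta())
        vertex_current = res.i_single * res.n_channels / 2
        vertex_var = base + res.i_single**2 * res.n_channels / 4
        assert vertex_current == pytest.approx(i * n / 2, rel=1e-9)
        assert vertex_var == pytest.approx(base + i**2 * n / 4, rel=1e-9)

    def test_negative_channel_count_errors(self):
        I = np.linspace(1, 10, 5)
        V = 0.1 * I + I**2  # upward curvature: no finite channel count
        with pytest.raises(ValueError, match="channel count"):
            fit_current_variance(I, V, 0.0, RecordingMeta())

    def test_low_open_probability_sets_low_confidence(self):
        i, n = 1.0, 100.0
        I = np.linspace(1, 30, 8)  # all below the vertex at 50
        V = i * I - I**2 / n
        res = fit_current_variance(I, V, 0.0, RecordingMeta())
        assert res.low_confidence

    def test_conductance_conversion(self):
        I = np.linspace(-50, -5, 8)
        V = -0.6 * I - I**2 / 100
        meta = RecordingMeta(holding_potential=-60.0, reversal_potential=0.0)
        res = fit_current_variance(I, V, 0.0, meta)
        assert res.conductance == pytest.approx(10.0, rel=1e-6)


class TestFullPipeline:
    def test_recovers_generator_truth(self):
        """70-sweep stochastic block at the reference parameters: peak open
        probability within +/-0.05 and conductance within 15%."""
        block = nsfa_block(n_channels=100, i_single=-0.6, p_peak=0.86,
                           n_sweeps=70, seed=42, noise_sd=0.3)
        res = run_nsfa(block)
        assert res.peak_open_probability == pytest.approx(0.86, abs=0.05)
        assert res.conductance == pytest.approx(10.0, rel=0.15)

    def test_parameter_recovery_grid(self):
        """Median recovery error over the (N, p, i) grid stays within bounds."""
        n_errors, p_errors = [], []
        seed = 100
        for n in (50, 100, 500):
            for p in (0.3, 0.6, 0.86):
                for i in (0.5, 1.0):
                    seed += 1
                    block = nsfa_block(n_channels=n, i_single=i, p_peak=p,
                                       n_sweeps=200, seed=seed, noise_sd=0.2,
                                       dt=2e-4)
                    res = run_nsfa(block)
                    n_errors.append(abs(res.n_channels / n - 1))
                    p_errors.append(abs(res.peak_open_probability - p))
        assert np.median(n_errors) <= 0.15
        assert np.median(p_errors) <= 0.05

    def test_pipeline_defeats_rundown(self):
        block = nsfa_block(n_sweeps=120, seed=77, rundown=0.0008, jitter=0.0008)
        res = run_nsfa(block)
        assert res.peak_open_probability == pytest.approx(0.86, abs=0.07)
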