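"""Jitter pooling, Laguerre fitting, peak metrics, regression, ICC."""

import numpy as np
import pytest

from funci.containers import AcquisitionMeta, StimulusSchedule, VoxelGrid
from funci.phantom import default_dynamic_spec, default_schedule, make_dynamic_phantom
from funci.pipeline import PHANTOM_DIFFUSION, estimate_response, phantom_analysis_roi
from funci.recon import ConductivityMap
from funci.response import (
    PooledTimecourse,
    fit_response,
    icc_oneway,
    laguerre_basis,
    pool_jittered,
    select_response_voxels,
    stimulus_response_regression,
)

GRID2 = VoxelGrid((2, 1, 1), (3.0, 3.0, 3.0))


def maps_from_series(values_per_frame, grid=GRID2):
    """Fake conductivity maps: one value array per frame, all voxels valid."""
    out = []
    for v in values_per_frame:
        arr = np.asarray(v, dtype=float).reshape(grid.shape)
        out.append(ConductivityMap(arr, np.isfinite(arr), grid))
    return out


def one_cycle_schedule(onset=2.4, jitter=0.0, duration=0.5):
    return StimulusSchedule([onset], [duration], [jitter], [0.45])


class TestSelection:
    def test_flat_series_selects_nothing(self):
        meta = AcquisitionMeta(dynamic_duration=1.2)
        maps = maps_from_series([[0.5, 0.5]] * 6)
        sel = select_response_voxels(maps, one_cycle_schedule(), np.ones((2, 1, 1), bool), meta)
        assert sel == set()

    def test_riser_selected_faller_not(self):
        meta = AcquisitionMeta(dynamic_duration=1.2)
        # frames at 0.6, 1.8 (pre-onset), 3.0 (first ON), ...
        vals = [[0.5, 0.5], [0.5, 0.5], [0.6, 0.4], [0.5, 0.5]]
        maps = maps_from_series(vals)
        sel = select_response_voxels(maps, one_cycle_schedule(), np.ones((2, 1, 1), bool), meta)
        assert sel == {(0, 0, 0)}

    def test_no_baseline_frames_rejected(self):
        meta = AcquisitionMeta(dynamic_duration=1.2)
        maps = maps_from_series([[0.5, 0.5]] * 4)
        with pytest.raises(ValueError, match="pre-onset"):
            select_response_voxels(
                maps, one_cycle_schedule(onset=0.0), np.ones((2, 1, 1), bool), meta
            )

    def test_phantom_selection_covers_activated_core(self):
        """Selected set contains ≥ 90% of truly activated valid core voxels
        at the default phantom noise (3 seeds)."""
        for seed in range(3):
            spec = default_dynamic_spec(seed=seed, n_frames=35, n_cycles=2)
            series, mag, labels, truth, sched = make_dynamic_phantom(spec)
            roi = phantom_analysis_roi(labels)
            _, _, voxels, maps = estimate_response(series, mag, labels, sched, roi)
            core_valid = roi & maps[0].valid & truth.activation_mask
            covered = sum(1 for v in np.argwhere(core_valid) if tuple(v) in voxels)
            assert covered / core_valid.sum() >= 0.9


class TestPooling:
    def test_halfway_convention_first_frame_at_0p6(self):
        meta = AcquisitionMeta(dynamic_duration=1.2)
        maps = maps_from_series([[1.0, 1.0]] * 4)
        tc = pool_jittered(maps, one_cycle_schedule(onset=0.0), np.ones((2, 1, 1), bool), meta)
        populated = tc.times[tc.counts > 0]
        assert populated[0] == pytest.approx(0.6)

    def test_sixteen_jitters_tile_the_100ms_grid(self):
        """16 jitters (−0.3…1.2, 0.1 steps) with 1.2 s frames populate every
        0.1 s bin inside the covered window."""
        sched = default_schedule(seed=0)
        meta = AcquisitionMeta(dynamic_duration=1.2)
        n_frames = 224
        maps = maps_from_series([[1.0, 1.0]] * n_frames)
        tc = pool_jittered(maps, sched, np.ones((2, 1, 1), bool), meta)
        assert np.allclose(np.diff(tc.times), 0.1)
        window = (tc.times >= 0) & (tc.times <= 10.0)
        assert np.all(tc.counts[window] > 0)

    def test_mapping_matches_brute_force_enumeration(self):
        """Frame-to-bin assignment equals exhaustive enumeration of all
        (cycle, frame) pairs for two cycles with jitters 0 and 0.1."""
        meta = AcquisitionMeta(dynamic_duration=1.2)
        sched = StimulusSchedule([3.6, 20.4], [0.5, 0.5], [0.0, 0.1], [0.45, 0.45])
        n = 30
        per_frame = np.arange(n) * 0.01  # distinct value per frame
        maps = maps_from_series([[v, v] for v in per_frame])
        tc = pool_jittered(maps, sched, np.ones((2, 1, 1), bool), meta, pre_window=1.8)
        # oracle
        frame_times = (np.arange(n) + 0.5) * 1.2
        bounds = [3.6 - 1.8 - 1e-6, 20.4 - 1.8 - 1e-6, 20.4 + 16.8 - 1.8 - 1e-6]
        bins = {}
        for ci, (onset, jit) in enumerate(zip([3.6, 20.4], [0.0, 0.1])):
            for f, tau in enumerate(frame_times):
                if bounds[ci] <= tau < bounds[ci + 1]:
                    t = tau - (onset + jit)
                    b = int(np.ceil(t / 0.1 - 0.5 - 1e-9))
                    bins.setdefault(b, []).append(per_frame[f])
        assert int(tc.counts.sum()) == sum(len(v) for v in bins.values())
        for b, vals in bins.items():
            i = np.nonzero(np.isclose(tc.times, b * 0.1))[0][0]
            assert tc.counts[i] == len(vals)
            assert tc.values[i] == pytest.approx(np.mean(vals))

    def test_count_conservation(self):
        """Σ bin counts equals cycles × frames-in-window."""
        sched = default_schedule(n_cycles=4, seed=1)
        meta = AcquisitionMeta(dynamic_duration=1.2)
        n_frames = 56
        maps = maps_from_series([[1.0, 1.0]] * n_frames)
        tc = pool_jittered(maps, sched, np.ones((2, 1, 1), bool), meta, pre_window=1.8)
        frame_times = (np.arange(n_frames) + 0.5) * 1.2
        in_window = ((frame_times >= 3.6 - 1.8 - 1e-6)
                     & (frame_times < 3.6 + 4 * 16.8 - 1.8 - 1e-6)).sum()
        assert int(tc.counts.sum()) == in_window

    def test_empty_voxel_set_rejected(self):
        meta = AcquisitionMeta(dynamic_duration=1.2)
        maps = maps_from_series([[1.0, 1.0]] * 6)
        with pytest.raises(ValueError, match="voxel"):
            pool_jittered(maps, one_cycle_schedule(), np.zeros((2, 1, 1), bool), meta)


class TestLaguerreBasis:
    def test_first_function_is_normalised_geometric_decay(self):
        t = np.arange(0, 12, 0.1)
        B = laguerre_basis(1, 0.5, t)
        raw = np.sqrt(1 - 0.5) * 0.5 ** (np.arange(t.size) / 2.0)
        raw /= np.linalg.norm(raw)
        assert np.allclose(B[:, 0], raw, atol=1e-12)

    def test_gram_matrix_is_identity(self):
        t = np.arange(0, 12, 0.1)
        for alpha in (0.2, 0.6, 0.9):
            B = laguerre_basis(10, alpha, t)
            gram = B.T @ B  # direct inner products
            assert np.abs(gram - np.eye(10)).max() < 1e-10

    def test_alpha_to_zero_limit_is_impulse(self):
        B = laguerre_basis(3, 1e-9, np.arange(0, 5, 0.1))
        assert B[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(B[1:, 0]).max() < 1e-4

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_alpha_out_of_range_rejected(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            laguerre_basis(10, alpha, np.arange(0, 12, 0.1))


class TestFitResponse:
    def _tc(self, times, values, counts=None):
        counts = np.ones(times.size, int) if counts is None else counts
        return PooledTimecourse(times=times, values=values, counts=counts)

    def test_zero_timecourse_gives_zero_response(self):
        t = np.round(np.arange(-1.0, 10.0, 0.1), 10)
        rf = fit_response(self._tc(t, np.zeros(t.size)), order=10, alpha=0.5)
        assert np.abs(rf.coefficients).max() < 1e-12
        assert rf.peak_amplitude == 0.0

    def test_in_span_recovery_of_basis_function(self):
        """A timecourse equal to 2× the third basis function is recovered
        with coefficient vector (0, 0, 2, 0, …) to 1e-8."""
        t_post = np.round(np.arange(0, 12, 0.1), 10)
        B = laguerre_basis(10, 0.5, t_post)
        t = np.round(np.arange(-1.0, 12.0, 0.1), 10)
        vals = np.concatenate([np.zeros((t < 0).sum()), 2.0 * B[:, 2]])
        rf = fit_response(self._tc(t, vals), order=10, alpha=0.5)
        expect = np.zeros(10)
        expect[2] = 2.0
        assert np.abs(rf.coefficients - expect).max() < 1e-8

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(0)
        t = np.round(np.arange(-1.0, 12.0, 0.1), 10)
        vals = rng.normal(0, 0.1, t.size)
        counts = rng.integers(1, 4, t.size)
        rf = fit_response(self._tc(t, vals, counts), order=10, alpha=0.6)
        post = t >= -1e-9
        resid = (vals[post] - rf.baseline) - rf.fitted
        B = laguerre_basis(10, 0.6, t[post])
        assert np.abs(B.T @ (counts[post] * resid)).max() < 1e-8

    def test_rank_deficiency_rejected(self):
        t = np.round(np.arange(-0.5, 0.5, 0.1), 10)
        with pytest.raises(ValueError, match="rank"):
            fit_response(self._tc(t, np.zeros(t.size)), order=10, alpha=0.5)

    def test_peak_metrics_on_known_curve(self):
        from funci.phantom import ResponseShape

        h = ResponseShape(peak_time=0.7, shape=2.0)
        t = np.round(np.arange(-2.0, 12.0, 0.1), 10)
        vals = 0.4 + 0.1 * h(t)
        rf = fit_response(self._tc(t, vals), order=10)
        assert rf.baseline == pytest.approx(0.4, abs=1e-3)
        assert rf.peak_amplitude == pytest.approx(0.1, abs=0.005)
        assert abs(rf.peak_time - 0.7) <= 0.1
        assert rf.return_to_baseline_time is not None and rf.return_to_baseline_time > 0.7


class TestRegressionAndICC:
    def test_collinear_points_give_r2_of_1(self):
        fit = stimulus_response_regression([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_normal_equations(self):
        fit = stimulus_response_regression([1.0, 2.0, 2.5], [0.1, 0.2, 0.3])
        assert fit.slope == pytest.approx(7.5)
        assert fit.intercept == pytest.approx(1.0 / 3.0)

    def test_duration_design_accepted(self):
        durations = [0.1, 0.2, 0.3, 0.4, 0.5]
        peaks = [0.02, 0.05, 0.06, 0.09, 0.1]
        fit = stimulus_response_regression(peaks, durations)
        assert 0 < fit.r_squared <= 1

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stimulus_response_regression([1, 2, 3], [0.5, 0.5, 0.5])

    def test_icc_identical_repeats_is_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_oneway(x) == pytest.approx(1.0)

    def test_icc_toy_table_matches_hand_anova(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [6.0, 8.0]])
        # MSB = 15.5, MSW = 1 → (15.5 − 1)/(15.5 + 1)
        assert icc_oneway(x) == pytest.approx(14.5 / 16.5, abs=1e-12)

    def test_icc_matches_independent_implementation(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (6, 3)) + rng.normal(0, 2, (6, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "rater": np.tile(np.arange(3), 6),
                "score": x.ravel(),
            }
        )
        out = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = out.loc[out["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert icc_oneway(x) == pytest.approx(float(ref), abs=1e-10)

    def test_icc_null_simulation_centres_on_zero(self):
        rng = np.random.default_rng(2)
        vals = [icc_oneway(rng.normal(0, 1, (8, 3))) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05

    def test_icc_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway(np.array([[1.0, 2.0]]))
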