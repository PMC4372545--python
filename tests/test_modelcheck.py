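import numpy as np
import pytest

from submem.designmat import build_design
from submem.firstlevel import fit_voxelwise
from submem.modelcheck import (
    compare_models,
    extract_sphere_signal,
    posterior_predictive_simulate,
    ppc_discrepancy,
    sphere_voxels,
    timecourse_frame,
    trial_average,
)
from submem.synthdata import simulate_subject

from conftest import EFFECT_VOXEL, make_truth


class TestSphere:
    def test_radius_below_voxel_size_single_voxel(self, small_spec):
        sphere = sphere_voxels((2, 2, 1), 1.0, small_spec.affine,
                               small_spec.grid_shape)
        assert len(sphere.members) == 1
        assert tuple(sphere.members[0]) == (2, 2, 1)

    def test_lattice_count_5mm_on_1p5mm_grid(self):
        # independent brute-force enumeration oracle
        oracle = sum(
            1
            for i in range(-4, 5)
            for j in range(-4, 5)
            for k in range(-4, 5)
            if 1.5 * np.sqrt(i * i + j * j + k * k) <= 5.0 + 1e-9
        )
        affine = np.diag([1.5, 1.5, 1.5, 1.0])
        sphere = sphere_voxels((10, 10, 10), 5.0, affine, (21, 21, 21))
        assert len(sphere.members) == oracle == 171

    def test_uniform_volume_constant_series(self, small_spec):
        bold = np.full((*small_spec.grid_shape, 10), 7.0)
        series = extract_sphere_signal(bold, (2, 2, 1), 5.0, small_spec.affine)
        assert np.allclose(series, 7.0)

    def test_center_outside_grid_raises(self, small_spec):
        with pytest.raises(ValueError, match="outside grid"):
            sphere_voxels((99, 0, 0), 5.0, small_spec.affine, small_spec.grid_shape)

    def test_members_within_radius(self, small_spec):
        sphere = sphere_voxels((3, 3, 2), 4.0, small_spec.affine,
                               small_spec.grid_shape)
        dists = np.linalg.norm(
            (sphere.members - np.array([3, 3, 2])) * small_spec.voxel_size, axis=1
        )
        assert np.all(dists <= 4.0 + 1e-9)


class TestTrialAverage:
    def test_constant_series_zero_curves(self, small_spec, small_subject):
        series = np.full(small_spec.n_volumes, 5.0)
        tc = trial_average(series, small_subject.schedule,
                           small_subject.behavior, small_spec)
        for c in tc.categories:
            assert np.allclose(tc.mean[c], 0.0)

    def test_zscore_mean_zero_sd_one(self, small_spec, small_subject):
        from submem.modelcheck import _zscore

        series = small_subject.bold[2, 2, 1]
        z = _zscore(series)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_single_trial_band_missing(self, small_spec, small_subject):
        beh = small_subject.behavior.trials.copy()
        # force exactly one trial into category "1", the rest into "4"
        # trial 5 sits mid-run, so its epoch survives the -4 s window
        beh["smt_rating"] = "4"
        beh.loc[5, "smt_rating"] = "1"
        series = small_subject.bold[2, 2, 1]
        tc = trial_average(series, small_subject.schedule, beh, small_spec)
        assert tc.n_trials["1"] == 1
        assert np.isnan(tc.band["1"]).all()
        assert np.isfinite(tc.band["4"]).all()

    def test_epochs_dropped_at_run_end(self, small_spec, small_subject):
        tc = trial_average(
            small_subject.bold[2, 2, 1],
            small_subject.schedule,
            small_subject.behavior,
            small_spec,
            window=(-4.0, 24.0),
        )
        total = sum(tc.n_trials.values())
        assert total + tc.n_dropped == 96
        assert tc.n_dropped > 0  # last trials cannot fit a +24 s window

    def test_category_means_ordered_by_strength_at_peak(self, small_spec):
        # strong noiseless decay signal: peak response ordered by code
        truth = make_truth(noise_sd=0.0, gamma0=2.0, gamma1=0.5)
        subj = simulate_subject(small_spec, truth, seed=21)
        tc = trial_average(subj.bold[2, 2, 1], subj.schedule, subj.behavior,
                           small_spec)
        peaks = [tc.mean[c].max() for c in tc.categories]
        assert peaks == sorted(peaks)

    def test_misaligned_inputs_raise(self, small_spec, small_subject):
        with pytest.raises(ValueError, match="align"):
            trial_average(
                [small_subject.bold[2, 2, 1]],
                [small_subject.schedule, small_subject.schedule],
                [small_subject.behavior],
                small_spec,
            )


class TestPosteriorPredictive:
    def test_default_twenty_replicates(self, small_spec, small_subject):
        design = build_design(
            small_subject.schedule, small_subject.behavior.trials,
            small_subject.motion, "decay", small_spec,
        )
        series = small_subject.bold[2, 2, 1][:, None]
        fit = fit_voxelwise(series, design)
        reps = posterior_predictive_simulate(fit, design, seed=0)
        assert reps.shape == (20, small_spec.n_volumes, 1)

    def test_zero_variance_reproduces_fitted_values(self, small_spec):
        truth = make_truth(noise_sd=0.0, motion_loading_sd=0.0)
        subj = simulate_subject(small_spec, truth, seed=22)
        design = build_design(subj.schedule, subj.behavior.trials, subj.motion,
                              "decay", small_spec)
        series = subj.bold[2, 2, 1][:, None]
        fit = fit_voxelwise(series, design)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-12)
        reps = posterior_predictive_simulate(fit, design, n_sim=3, seed=1)
        fitted = design.values @ fit.beta[0]
        for r in range(3):
            assert np.allclose(reps[r, :, 0], fitted, atol=1e-9)

    def test_observed_inside_envelope_under_true_model(self, small_spec,
                                                       small_subject,
                                                       small_subject_fit):
        design, _ = small_subject_fit
        series = small_subject.bold[2, 2, 1]
        fit = fit_voxelwise(series[:, None], design)
        reps = posterior_predictive_simulate(fit, design, n_sim=20, seed=2)
        observed = trial_average(series, small_subject.schedule,
                                 small_subject.behavior, small_spec)
        rep_tcs = [
            trial_average(reps[r, :, 0], small_subject.schedule,
                          small_subject.behavior, small_spec)
            for r in range(20)
        ]
        ppc = ppc_discrepancy(observed, rep_tcs)
        n_points = sum(f.size for f in ppc.flags.values())
        n_flagged = sum(f.sum() for f in ppc.flags.values())
        # min-max envelope of 20 draws: ~2/21 expected outside; loose bound
        assert n_flagged / n_points < 0.3


class TestPpcDiscrepancy:
    def _observed_and_reps(self, small_spec, small_subject, shift=0.0):
        series = small_subject.bold[2, 2, 1]
        obs = trial_average(series, small_subject.schedule,
                            small_subject.behavior, small_spec)
        reps = []
        rng = np.random.default_rng(0)
        for _ in range(10):
            jitter = series + rng.normal(0, 1e-3, series.shape)
            reps.append(
                trial_average(jitter + shift, small_subject.schedule,
                              small_subject.behavior, small_spec)
            )
        return obs, reps

    def test_identical_curves_zero_misfit(self, small_spec, small_subject):
        obs, reps = self._observed_and_reps(small_spec, small_subject)
        ppc = ppc_discrepancy(obs, reps)
        assert ppc.misfit < 5.0  # jitter-scale distances only
        # and exactly-equal replicate means -> zero misfit, no flags
        ppc_exact = ppc_discrepancy(obs, [obs] * 5)
        assert ppc_exact.misfit == pytest.approx(0.0, abs=1e-15)
        assert not any(f.any() for f in ppc_exact.flags.values())

    def test_large_shift_flags_everything(self, small_spec, small_subject):
        series = small_subject.bold[2, 2, 1]
        obs = trial_average(series, small_subject.schedule,
                            small_subject.behavior, small_spec)
        shifted = [
            type(obs)(
                offsets=obs.offsets,
                categories=obs.categories,
                mean={c: obs.mean[c] + 100.0 for c in obs.categories},
                band=obs.band,
                n_trials=obs.n_trials,
            )
            for _ in range(5)
        ]
        ppc = ppc_discrepancy(obs, shifted)
        assert all(f.all() for f in ppc.flags.values())

    def test_grid_mismatch_raises(self, small_spec, small_subject):
        obs, reps = self._observed_and_reps(small_spec, small_subject)
        bad = type(obs)(
            offsets=obs.offsets[:-1],
            categories=obs.categories,
            mean={c: obs.mean[c][:-1] for c in obs.categories},
            band={c: obs.band[c][:-1] for c in obs.categories},
            n_trials=obs.n_trials,
        )
        with pytest.raises(ValueError, match="grid"):
            ppc_discrepancy(obs, [bad])

    def test_central95_envelope_option(self, small_spec, small_subject):
        obs, reps = self._observed_and_reps(small_spec, small_subject)
        ppc = ppc_discrepancy(obs, reps, envelope="central95")
        assert ppc.misfit >= 0


class TestCompareModels:
    def test_single_model_ranking_of_one(self, small_spec, small_subject):
        series = small_subject.bold[2, 2, 1]
        rank = compare_models(
            series, small_subject.schedule, small_subject.behavior.trials,
            small_subject.motion, small_spec, models=["decay"], n_sim=5, seed=0,
        )
        assert len(rank) == 1
        assert rank.iloc[0]["model"] == "decay"

    @pytest.mark.parametrize("gen", ["sample_plus_delay", "decay"])
    def test_generative_model_ranks_first(self, small_spec, gen):
        truth = make_truth(generative_model=gen)
        subj = simulate_subject(small_spec, truth, seed=33)
        series = subj.bold[tuple(np.array(EFFECT_VOXEL))]
        rank = compare_models(
            series, subj.schedule, subj.behavior.trials, subj.motion,
            small_spec, n_sim=20, seed=1,
        )
        assert rank.iloc[0]["model"] == gen

    def test_timecourse_frame_export(self, small_spec, small_subject):
        series = small_subject.bold[2, 2, 1]
        tc = trial_average(series, small_subject.schedule,
                           small_subject.behavior, small_spec)
        frame = timecourse_frame(tc)
        assert {"category", "offset_s", "mean", "band", "n_trials"} <= set(
            frame.columns
        )
        assert len(frame) == sum(len(tc.offsets) for _ in tc.categories)
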