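import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from submem.designmat import (
    DesignMatrix,
    HRFParams,
    assemble,
    build_design,
    double_gamma_hrf,
    encoding_kernel,
    interest_regressors,
    nuisance_regressors,
)
from submem.synthdata import (
    AcquisitionSpec,
    generate_schedule,
    simulate_behavior,
    simulate_motion,
)

from conftest import make_truth


class TestDoubleGammaHrf:
    def test_peak_location_default_params(self):
        kernel = double_gamma_hrf(tr=2.0, oversampling=100)
        t_peak = np.argmax(kernel) * (2.0 / 100)
        assert 4.0 <= t_peak <= 6.0

    def test_peak_normalized(self):
        assert double_gamma_hrf(tr=2.0, oversampling=8).max() == pytest.approx(1.0)

    def test_large_undershoot_ratio_is_single_gamma(self):
        params = HRFParams(undershoot_ratio=1e12)
        kernel = double_gamma_hrf(params, tr=2.0, oversampling=8)
        assert np.all(kernel >= -1e-12)

    @pytest.mark.parametrize("bad", [
        {"peak_delay": -1.0}, {"peak_dispersion": 0.0}, {"kernel_length": -2.0},
    ])
    def test_nonpositive_params_raise(self, bad):
        with pytest.raises(ValueError):
            double_gamma_hrf(HRFParams(**bad), tr=2.0)

    def test_oversampling_below_one_raises(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(tr=2.0, oversampling=0)


class TestEncodingKernel:
    def test_decay_values(self):
        kernel = encoding_kernel("decay", 1, 5)
        assert kernel == pytest.approx(
            [1.0, 0.25, 0.1111, 0.0625, 0.04, 0.02778], abs=1e-4
        )

    def test_sample_only(self):
        assert encoding_kernel("sample_only", 1, 5).tolist() == [1.0]

    def test_sample_plus_delay_boxcar(self):
        assert encoding_kernel("sample_plus_delay", 1, 5).tolist() == [1.0] * 6

    def test_decay_strictly_decreasing(self):
        assert np.all(np.diff(encoding_kernel("decay", 1, 5)) < 0)

    @pytest.mark.parametrize("model", ["sample_only", "sample_plus_delay", "decay"])
    def test_kernels_nonnegative(self, model):
        assert np.all(encoding_kernel(model, 1, 5) >= 0)

    def test_bad_counts_raise(self):
        with pytest.raises(ValueError):
            encoding_kernel("decay", 0, 5)

    def test_unknown_model_raises(self):
        with pytest.raises(ValueError, match="unknown encoding model"):
            encoding_kernel("boxcar", 1, 5)


@pytest.fixture(scope="module")
def sched_beh_motion(default_spec):
    sched = generate_schedule(default_spec, seed=1)
    beh = simulate_behavior(sched, make_truth(), seed=2)
    motion = simulate_motion(default_spec, seed=3)
    return sched, beh, motion


class TestInterestRegressors:
    def test_ten_columns_for_full_category_use(self, default_spec, sched_beh_motion):
        sched, beh, _ = sched_beh_motion
        assert len(beh.categories_used) == 5
        mat, names = interest_regressors(
            sched, beh.trials, "sample_plus_delay", None, default_spec
        )
        assert mat.shape == (1152, 10)
        assert len(names) == 10

    def test_three_categories_gives_six_columns(self, default_spec, sched_beh_motion):
        sched, beh, _ = sched_beh_motion
        trials = beh.trials.copy()
        trials["smt_rating"] = np.where(
            trials["smt_rating"].isin(["1", "2"]), "3", trials["smt_rating"]
        )
        mat, names = interest_regressors(sched, trials, "decay", None, default_spec)
        assert mat.shape[1] == 6

    def test_empty_schedule_zero_columns(self, default_spec):
        empty = pd.DataFrame(
            columns=["run", "trial", "sample_onset", "delay_onset", "test_onset"]
        )
        beh = pd.DataFrame(columns=["smt_rating"])
        mat, names = interest_regressors(empty, beh, "decay", None, default_spec)
        assert mat.shape[1] == 0 and names == []

    def test_onset_outside_run_raises(self, default_spec):
        sched = pd.DataFrame(
            {"run": [0], "trial": [0], "sample_onset": [280.0],
             "delay_onset": [282.0], "test_onset": [292.0]}
        )
        beh = pd.DataFrame({"smt_rating": ["4"]})
        with pytest.raises(ValueError, match="outside run"):
            interest_regressors(sched, beh, "decay", None, default_spec)

    def test_convolution_linearity(self):
        # regressor for two trials equals the sum of single-trial regressors
        spec = AcquisitionSpec(n_runs=1)
        base = {"delay_onset": None, "test_onset": None}
        def mk(onsets):
            return pd.DataFrame(
                {
                    "run": [0] * len(onsets),
                    "trial": range(len(onsets)),
                    "sample_onset": onsets,
                    "delay_onset": [o + 2 for o in onsets],
                    "test_onset": [o + 12 for o in onsets],
                }
            )
        beh1 = pd.DataFrame({"smt_rating": ["4"]})
        beh2 = pd.DataFrame({"smt_rating": ["4", "4"]})
        both, _ = interest_regressors(mk([0.0, 40.0]), beh2, "decay", None, spec)
        a, _ = interest_regressors(mk([0.0]), beh1, "decay", None, spec)
        b, _ = interest_regressors(mk([40.0]), beh1, "decay", None, spec)
        assert np.allclose(both, a + b, atol=1e-12)


class TestNuisanceRegressors:
    def test_80_columns_at_defaults(self, default_spec, sched_beh_motion):
        _, _, motion = sched_beh_motion
        mat, names, dropped = nuisance_regressors(motion, default_spec)
        assert mat.shape == (1152, 80)
        assert dropped == []
        assert sum(n.startswith("run_") for n in names) == 8
        assert sum(n.startswith("motion_") for n in names) == 48
        assert sum(n.startswith("drift") for n in names) == 24

    def test_drift_columns_sum_to_zero(self, default_spec, sched_beh_motion):
        _, _, motion = sched_beh_motion
        mat, names, _ = nuisance_regressors(motion, default_spec)
        for j, name in enumerate(names):
            if name.startswith("drift"):
                assert abs(mat[:, j].sum()) < 1e-8

    def test_zero_motion_columns_flagged(self):
        spec = AcquisitionSpec(n_runs=1)
        motion = np.zeros((144, 6))
        mat, names, dropped = nuisance_regressors(motion, spec)
        assert len(dropped) == 6
        assert all(d.startswith("motion_") for d in dropped)
        assert not any(n.startswith("motion_") for n in names)

    def test_length_mismatch_raises(self, default_spec):
        with pytest.raises(ValueError, match="motion table"):
            nuisance_regressors(np.zeros((100, 6)), default_spec)

    def test_pure_drift_signal_fit_exactly(self, default_spec, sched_beh_motion):
        # nuisance-only regression of a cubic drift leaves ~zero residuals
        _, _, motion = sched_beh_motion
        mat, names, _ = nuisance_regressors(motion, default_spec)
        n = default_spec.volumes_per_run
        lin = np.arange(n) - (n - 1) / 2.0
        signal = np.tile(3.0 + 0.01 * lin - 2e-4 * lin**2 + 1e-6 * lin**3,
                         default_spec.n_runs)
        beta, *_ = np.linalg.lstsq(mat, signal, rcond=None)
        resid = signal - mat @ beta
        assert np.max(np.abs(resid)) < 1e-8


class TestAssemble:
    def test_column_arithmetic(self, default_spec, sched_beh_motion):
        sched, beh, motion = sched_beh_motion
        design = build_design(
            sched, beh.trials, motion, "sample_plus_delay", default_spec
        )
        assert design.n_columns == 90
        assert design.n_rows == 1152
        assert len(design.interest_columns) == 10
        assert len(design.nuisance_columns) == 80

    def test_duplicate_column_raises(self, default_spec, sched_beh_motion):
        sched, beh, motion = sched_beh_motion
        mat, names = interest_regressors(
            sched, beh.trials, "decay", None, default_spec
        )
        dup = np.hstack([mat, mat[:, :1]])
        with pytest.raises(ValueError, match="rank deficient"):
            assemble((dup, names + ["dup"]),
                     nuisance_regressors(motion, default_spec)[:2], default_spec)

    def test_full_rank_at_defaults(self, default_spec, sched_beh_motion):
        sched, beh, motion = sched_beh_motion
        design = build_design(sched, beh.trials, motion, "decay", default_spec)
        assert np.linalg.matrix_rank(design.values) == design.n_columns

    def test_column_accessor(self, default_spec, sched_beh_motion):
        sched, beh, motion = sched_beh_motion
        design = build_design(sched, beh.trials, motion, "decay", default_spec)
        assert design.column("run_0").sum() == pytest.approx(144)
        with pytest.raises(KeyError):
            design.column("nope")

    def test_tsv_round_trip(self, tmp_path, default_spec, sched_beh_motion):
        sched, beh, motion = sched_beh_motion
        design = build_design(sched, beh.trials, motion, "decay", default_spec)
        path = tmp_path / "design.tsv"
        design.write_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == design.column_names
        assert np.allclose(back.to_numpy(), design.values)


@settings(max_examples=20, deadline=None)
@given(
    n_sample=st.integers(min_value=1, max_value=3),
    n_delay=st.integers(min_value=0, max_value=8),
)
def test_decay_kernel_rule_property(n_sample, n_delay):
    kernel = encoding_kernel("decay", n_sample, n_delay)
    n = np.arange(1, n_sample + n_delay + 1)
    assert np.allclose(kernel, 1.0 / n**2)
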