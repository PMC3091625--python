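import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from beadnorm.io import ControlProfile, ProbeProfileTable
from beadnorm.normalize import (
    PipelineError,
    PipelineSpec,
    average_normalize,
    cubic_spline_normalize,
    enumerate_pipelines,
    force_positive,
    log2_transform,
    loess_normalize,
    parse_pipeline_name,
    quantile_normalize,
    rank_invariant_normalize,
    rma_background,
    rsn_normalize,
    run_pipeline,
    subtract_background,
    vsn_normalize,
    vst_transform,
)


def _df(values, columns=None):
    values = np.asarray(values, float)
    return pd.DataFrame(values,
                        index=[f"p{i}" for i in range(values.shape[0])],
                        columns=columns or [f"s{j}" for j in range(values.shape[1])])


def ranks(col):
    return sps.rankdata(col, method="average")


class TestPipelineGrid:
    def test_exactly_25_unique_names(self):
        specs = enumerate_pipelines()
        names = [s.name for s in specs]
        assert len(specs) == 25
        assert len(set(names)) == 25

    def test_contains_every_published_name(self):
        names = {s.name for s in enumerate_pipelines()}
        expected = (
            {f"{b}_noNorm" for b in ("bg", "noBg")}
            | {f"{b}_{n}" for b in ("bg", "noBg")
               for n in ("average", "rankInvariant", "cubicSpline", "vsn")}
            | {f"bg_{p}_log_{n}" for p in ("forcePos", "rma")
               for n in ("loess", "quantile", "rsn")}
            | {f"{b}_vst_{n}" for b in ("bg", "noBg")
               for n in ("loess", "quantile", "rsn")}
            | {f"noBg_log_{n}" for n in ("loess", "quantile", "rsn")}
        )
        assert names == expected

    def test_name_parsing_is_a_bijection(self):
        for spec in enumerate_pipelines():
            assert parse_pipeline_name(spec.name) == spec
        with pytest.raises(ValueError):
            parse_pipeline_name("bg_magic_quantile")

    def test_invalid_combinations_rejected(self):
        # positivity fixes only make sense for background-corrected log data
        with pytest.raises(ValueError):
            PipelineSpec("noBg", "forcePos", "log", "quantile")
        with pytest.raises(ValueError):
            PipelineSpec("bg", "rma", "vst", "quantile")


class TestBackground:
    def test_subtracts_per_sample_control_mean(self):
        prof = ProbeProfileTable(avg_signal=_df([[100.0, 50.0]]))
        ctrl = ControlProfile(_df([[30.0, 10.0], [30.0, 10.0]]))
        out = subtract_background(prof, ctrl)
        np.testing.assert_allclose(out.avg_signal.values, [[70.0, 40.0]])

    def test_negative_results_retained(self):
        prof = ProbeProfileTable(avg_signal=_df([[20.0]], columns=["s0"]))
        ctrl = ControlProfile(_df([[30.0]], columns=["s0"]))
        assert subtract_background(prof, ctrl).avg_signal.iloc[0, 0] == -10.0

    def test_zero_controls_identity(self):
        prof = ProbeProfileTable(avg_signal=_df([[5.0, 7.0]]))
        ctrl = ControlProfile(_df([[0.0, 0.0]]))
        pd.testing.assert_frame_equal(
            subtract_background(prof, ctrl).avg_signal, prof.avg_signal)

    def test_missing_control_sample_named(self):
        prof = ProbeProfileTable(avg_signal=_df([[1.0, 2.0]], columns=["a", "b"]))
        ctrl = ControlProfile(_df([[1.0]], columns=["a"]))
        with pytest.raises(ValueError, match="b"):
            subtract_background(prof, ctrl)


class TestForcePositive:
    def test_shifts_global_minimum_to_one(self):
        m = _df([[-10.0, 5.0], [0.0, 3.0]])
        out = force_positive(m)
        assert out.values.min() == pytest.approx(1.0)

    def test_identity_when_already_positive(self):
        m = _df([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(force_positive(m), m)

    def test_pairwise_differences_preserved(self):
        m = _df([[-3.0, 8.0], [2.5, -1.0]])
        out = force_positive(m)
        np.testing.assert_allclose(out.values - out.values[0, 0],
                                   m.values - m.values[0, 0])


class TestRmaBackground:
    def test_output_strictly_positive_on_simulated_columns(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        sub = subtract_background(profile, ctrl)
        out = rma_background(sub.avg_signal)
        assert (out.values > 0).all()

    def test_parameter_recovery_on_known_mixture(self):
        rng = np.random.default_rng(8)
        mu, sigma, alpha = 100.0, 10.0, 1 / 300.0
        n = 20000
        x = rng.normal(mu, sigma, n) + rng.exponential(1 / alpha, n)
        out = rma_background(_df(x[:, None]))
        # posterior-mean correction keeps bright signals nearly untouched
        # and squeezes background-only values toward small positive values
        bright = x > 1500
        np.testing.assert_allclose(out.values[bright, 0], x[bright] - mu,
                                   rtol=0.15)
        assert out.values[~bright, 0].min() > 0

    def test_constant_column_rejected(self):
        with pytest.raises(Exception, match="constant"):
            rma_background(_df([[1.0], [1.0], [1.0]]))

    def test_monotone_within_column(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 10, 500) + rng.exponential(200, 500)
        out = rma_background(_df(x[:, None]))
        order = np.argsort(x)
        assert (np.diff(out.values[order, 0]) >= -1e-9).all()


class TestLog2:
    def test_values(self):
        out = log2_transform(_df([[8.0, 1.0]]))
        np.testing.assert_allclose(out.values, [[3.0, 0.0]])

    def test_non_positive_entry_named(self):
        with pytest.raises(ValueError, match=r"p1.*s0"):
            log2_transform(_df([[2.0], [-1.0]]))


class TestVst:
    def test_flattens_variance_trend_relative_to_log2(self, medium_experiment):
        from beadnorm.evaluate import residual_sd_trend
        from beadnorm.stats import residual_sd
        profile, _, design, _ = medium_experiment
        v = vst_transform(profile)
        l2 = log2_transform(force_positive(profile.avg_signal))
        fv = residual_sd_trend(residual_sd(v, design))["flatness_mean"]
        fl = residual_sd_trend(residual_sd(l2, design))["flatness_mean"]
        assert fv < fl

    def test_affine_log2_at_high_intensity_without_background(self):
        from beadnorm.simulate import SimulationConfig, simulate_experiment
        cfg = SimulationConfig(n_probes=2000, n_negative_controls=100,
                               bg_mean=0.0, bg_sd=0.0, seed=13)
        profile, _, _, _ = simulate_experiment(cfg)
        v = vst_transform(profile)
        l2 = log2_transform(force_positive(profile.avg_signal))
        col = profile.sample_ids[0]
        hi = profile.avg_signal[col] >= profile.avg_signal[col].quantile(0.9)
        r = np.corrcoef(v.loc[hi, col], l2.loc[hi, col])[0, 1]
        assert r > 0.999

    def test_strictly_increasing_and_handles_negatives(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        sub = subtract_background(profile, ctrl)
        assert sub.avg_signal.values.min() < 0  # premise of the check
        out = vst_transform(sub, sub.avg_signal)
        assert np.isfinite(out.values).all()
        for col in out.columns:
            order = np.argsort(sub.avg_signal[col].values)
            assert (np.diff(out[col].values[order]) > 0).all()

    def test_requires_bead_statistics(self):
        prof = ProbeProfileTable(avg_signal=_df([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="log"):
            vst_transform(prof)


class TestQuantile:
    def test_hand_example(self):
        out = quantile_normalize(_df([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        np.testing.assert_allclose(out.values,
                                   [[1.5, 1.5], [3.0, 3.0], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        m = _df([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_columns_share_sorted_values_and_ranks_kept(self):
        rng = np.random.default_rng(2)
        m = _df(rng.normal(8, 2, (500, 6)) * rng.uniform(0.5, 2, 6))
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(6):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)
            np.testing.assert_allclose(ranks(out.values[:, j]),
                                       ranks(m.values[:, j]))

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = _df(rng.normal(0, 1, (200, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_ties_share_reference_mean(self):
        m = _df([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(m)
        # tied 1.0s occupy reference slots (5.5, 10.5) -> both get 8.0
        assert out.values[0, 0] == out.values[1, 0] == pytest.approx(8.0)


class TestRsn:
    def test_identical_columns_identity(self):
        rng = np.random.default_rng(6)
        col = rng.normal(8, 2, 300)
        m = _df(np.column_stack([col, col]))
        out = rsn_normalize(m)
        assert np.abs(out.values - m.values).max() < 1e-8

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(7)
        col = np.sort(rng.normal(8, 2, 400))
        m = _df(np.column_stack([col, col + 0.7, col - 0.2]))
        out = rsn_normalize(m)
        ref = out.values[:, np.argsort(np.median(m.values, axis=0))[1]]
        for j in range(3):
            np.testing.assert_allclose(out.values[:, j], ref, atol=0.05)

    def test_rank_preservation(self):
        rng = np.random.default_rng(8)
        m = _df(rng.normal(8, 2, (300, 4)) * [1.0, 1.3, 0.8, 1.1])
        out = rsn_normalize(m)
        for j in range(4):
            np.testing.assert_allclose(ranks(out.values[:, j]),
                                       ranks(m.values[:, j]))

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            rsn_normalize(_df([[1.0], [2.0]]))


class TestLoess:
    def test_equal_columns_unchanged(self):
        rng = np.random.default_rng(9)
        col = rng.normal(8, 2, 200)
        m = _df(np.column_stack([col, col, col]))
        out = loess_normalize(m)
        np.testing.assert_allclose(out.values, m.values, atol=1e-6)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(10)
        base = rng.normal(8, 2, 300)
        m = _df(np.column_stack([base + 0.9, base, base]))
        out = loess_normalize(m)
        resid = out.values[:, 0] - out.values[:, 1:].mean(axis=1)
        assert np.abs(np.median(resid)) < 0.05

    def test_global_mean_roughly_preserved(self):
        rng = np.random.default_rng(11)
        m = _df(rng.normal(8, 2, (400, 5)) + rng.uniform(-0.5, 0.5, 5))
        out = loess_normalize(m)
        assert abs(out.values.mean() - m.values.mean()) < 0.05

    def test_too_few_probes(self):
        with pytest.raises(ValueError):
            loess_normalize(_df(np.random.default_rng(0).normal(size=(5, 3))))


class TestVsn:
    def test_identical_columns_identical_output(self):
        rng = np.random.default_rng(12)
        col = rng.lognormal(5, 1, 400)
        m = _df(np.column_stack([col, col, col]))
        out = vsn_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], atol=1e-9)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 2], atol=1e-9)

    def test_log2_like_at_high_intensity(self, medium_experiment):
        profile, _, _, _ = medium_experiment
        out = vsn_normalize(profile.avg_signal)
        col = profile.sample_ids[0]
        l2 = np.log2(profile.avg_signal[col])
        hi = profile.avg_signal[col] >= profile.avg_signal[col].quantile(0.9)
        assert np.corrcoef(out.loc[hi, col], l2[hi])[0, 1] > 0.999
        # the offset becomes constant deep into the bright tail
        tail = profile.avg_signal[col] >= profile.avg_signal[col].quantile(0.99)
        assert (out.loc[tail, col] - l2[tail]).std() < 0.05

    def test_finite_for_negative_inputs(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        sub = subtract_background(profile, ctrl)
        assert sub.avg_signal.values.min() < 0
        out = vsn_normalize(sub.avg_signal)
        assert np.isfinite(out.values).all()

    def test_stabilizes_variance(self, medium_experiment):
        from beadnorm.evaluate import residual_sd_trend
        from beadnorm.stats import residual_sd
        profile, _, design, _ = medium_experiment
        out = vsn_normalize(profile.avg_signal)
        l2 = log2_transform(force_positive(profile.avg_signal))
        fv = residual_sd_trend(residual_sd(out, design))["flatness_mean"]
        fl = residual_sd_trend(residual_sd(l2, design))["flatness_mean"]
        assert fv < fl


class TestBeadStudioNormalizations:
    def test_average_scale_factors(self):
        m = _df(np.column_stack([np.full(4, 10.0), np.full(4, 20.0)]))
        out = average_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], 15.0)
        np.testing.assert_allclose(out.values[:, 1], 15.0)
        np.testing.assert_allclose(out.mean(axis=0), out.values.mean())

    def test_average_identity_for_equal_means(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(1, 100, 50)
        b = rng.permutation(a)
        m = _df(np.column_stack([a, b]))
        pd.testing.assert_frame_equal(average_normalize(m), m)

    def test_average_rejects_non_positive_mean(self):
        with pytest.raises(ValueError):
            average_normalize(_df([[1.0, -2.0], [1.0, -2.0]]))

    def test_rank_invariant_identity_for_identical_columns(self):
        rng = np.random.default_rng(14)
        col = rng.lognormal(5, 1, 500)
        m = _df(np.column_stack([col, col]))
        out = rank_invariant_normalize(m)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-6)

    def test_rank_invariant_undoes_scaling(self):
        rng = np.random.default_rng(15)
        ref = np.sort(rng.lognormal(5, 1, 1000))
        m = _df(np.column_stack([ref, 2.0 * ref]))
        out = rank_invariant_normalize(m)
        mid = (ref > np.quantile(ref, 0.1)) & (ref < np.quantile(ref, 0.9))
        np.testing.assert_allclose(out.values[mid, 1], ref[mid], rtol=0.02)

    def test_rank_invariant_no_rank_inversions(self, small_experiment):
        # the fitted map is weakly monotone (flat smoother segments may tie),
        # so orders are never inverted
        profile, _, _, _ = small_experiment
        out = rank_invariant_normalize(profile.avg_signal)
        for col in out.columns:
            order = np.argsort(profile.avg_signal[col].values, kind="stable")
            assert (np.diff(out[col].values[order]) >= -1e-9).all()

    def test_rank_invariant_small_set_advises(self):
        rng = np.random.default_rng(16)
        a = rng.normal(100, 10, 300)
        b = rng.permutation(a)  # ranks scrambled -> tiny invariant set
        with pytest.raises(ValueError, match="rank_tolerance"):
            rank_invariant_normalize(_df(np.column_stack([a, b])),
                                     rank_tolerance=0.001)

    def test_cubic_spline_identity_for_identical_columns(self):
        rng = np.random.default_rng(17)
        col = rng.lognormal(5, 1, 400)
        m = _df(np.column_stack([col, col]))
        out = cubic_spline_normalize(m)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-6)

    def test_cubic_spline_matches_quantiles_after_scaling(self):
        rng = np.random.default_rng(18)
        col = rng.lognormal(5, 0.8, 1000)
        m = _df(np.column_stack([col, 1.7 * col]))
        out = cubic_spline_normalize(m)
        q = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(np.quantile(out.values[:, 0], q),
                                   np.quantile(out.values[:, 1], q), rtol=0.02)

    def test_cubic_spline_anchor_count_checked(self):
        with pytest.raises(ValueError):
            cubic_spline_normalize(_df(np.ones((5, 2))), n_anchors=100)


class TestRunPipeline:
    def test_noNorm_is_log2_of_raw(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        out = run_pipeline("noBg_noNorm", profile, ctrl)
        expected = log2_transform(force_positive(profile.avg_signal))
        pd.testing.assert_frame_equal(out, expected)

    def test_bg_forcePos_log_quantile_composition(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        out = run_pipeline("bg_forcePos_log_quantile", profile, ctrl)
        manual = quantile_normalize(log2_transform(force_positive(
            subtract_background(profile, ctrl).avg_signal)))
        pd.testing.assert_frame_equal(out, manual)

    def test_beadstudio_normalizes_raw_then_logs(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        out = run_pipeline("noBg_average", profile, ctrl)
        manual = log2_transform(force_positive(
            average_normalize(profile.avg_signal)))
        pd.testing.assert_frame_equal(out, manual)

    def test_bg_requires_controls(self, small_experiment):
        profile, _, _, _ = small_experiment
        with pytest.raises(ValueError, match="control"):
            run_pipeline("bg_noNorm", profile, None)

    def test_all_25_finite_and_shape_preserving(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        for spec in enumerate_pipelines():
            out = run_pipeline(spec, profile, ctrl)
            assert out.shape == profile.shape, spec.name
            assert np.isfinite(out.values).all(), spec.name
            assert list(out.index) == profile.probe_ids
            assert list(out.columns) == profile.sample_ids

    def test_stage_error_names_stage(self, small_experiment):
        profile, ctrl, _, _ = small_experiment
        broken = ProbeProfileTable(avg_signal=profile.avg_signal)  # no bead stats
        with pytest.raises(PipelineError, match="vst"):
            run_pipeline("noBg_vst_quantile", broken, ctrl)


def test_monotone_methods_preserve_ranks(small_experiment):
    """Every monotone stage preserves within-column rank order."""
    profile, ctrl, _, _ = small_experiment
    raw = profile.avg_signal
    candidates = {
        "forcePos": force_positive(raw),
        "log2": log2_transform(raw),
        "quantile": quantile_normalize(raw),
        "rsn": rsn_normalize(raw),
        "average": average_normalize(raw),
        "cubicSpline": cubic_spline_normalize(raw),
        "vsn": vsn_normalize(raw),
        "vst": vst_transform(profile),
    }
    for name, out in candidates.items():
        for col in raw.columns:
            r = sps.spearmanr(ranks(out[col].values),
                              ranks(raw[col].values)).statistic
            assert r > 0.99999, f"{name}/{col}"
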