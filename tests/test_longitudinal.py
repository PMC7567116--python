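"""Normalization, the two-condition quadratic regression, and t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actnet import synthetic_data as synth
from actnet.longitudinal import (
    DynamicFit,
    call_dynamic_features,
    fit_dynamic_model,
    fit_timecourse,
    fits_to_frame,
    frame_to_fits,
    normalize_proteome,
    timepoint_tests,
)
from actnet.synthetic_data import GroundTruth, generate_timecourse


def _series(meta_times, noise_sd, coef_c, coef_t, rng):
    """Simulate one feature: control quadratic + treated offset polynomial."""
    times = np.tile(np.repeat(meta_times, 3), 2)
    cond = np.array(["C"] * (len(times) // 2) + ["T"] * (len(times) // 2))
    d = (cond == "T").astype(float)
    y = (
        coef_c[0] + coef_c[1] * times + coef_c[2] * times**2
        + d * (coef_t[0] + coef_t[1] * times + coef_t[2] * times**2)
        + rng.normal(0, noise_sd, size=len(times))
    )
    return y, cond, times


class TestNormalizeProteome:
    def _meta(self, cols, times):
        return pd.Series(times, index=cols)

    def test_identity_when_medians_match(self):
        idx = [f"p{i}" for i in range(9)]
        base = np.arange(9, dtype=float).reshape(9, 1)
        ctrl = pd.DataFrame(np.hstack([base, base]), index=idx, columns=["c1", "c2"])
        trt = pd.DataFrame(np.hstack([base, base]), index=idx, columns=["t1", "t2"])
        ct = self._meta(["c1", "c2"], [2.0, 2.0])
        tt = self._meta(["t1", "t2"], [2.0, 2.0])
        cn, tn = normalize_proteome(ctrl, trt, ct, tt)
        pd.testing.assert_frame_equal(cn, ctrl)
        pd.testing.assert_frame_equal(tn, trt)

    def test_offset_removed(self):
        idx = [f"p{i}" for i in range(9)]
        base = np.arange(9, dtype=float)
        ctrl = pd.DataFrame({"c1": base, "c2": base}, index=idx)
        trt = pd.DataFrame({"t1": base + 3.0}, index=idx)
        ct = self._meta(["c1", "c2"], [2.0, 2.0])
        tt = self._meta(["t1"], [2.0])
        _, tn = normalize_proteome(ctrl, trt, ct, tt)
        assert np.allclose(tn["t1"].to_numpy(), base, atol=1e-12)

    def test_feature_missing_in_all_controls_retained(self):
        # 3 proteins x (2 controls + 2 treated); p2 absent from every control.
        # Reference medians use p0/p1 only: control medians (1.5, 3.5) ->
        # median of medians 2.5 -> shifts +1.0 / -1.0. Per-time common set is
        # also p0/p1; shifted control medians are both 2.5 -> reference 2.5;
        # treated medians 5.5 and 7.5 -> shifts -3.0 and -5.0, applied to the
        # retained p2 row too.
        ctrl = pd.DataFrame(
            {"c1": [1.0, 2.0, np.nan], "c2": [3.0, 4.0, np.nan]},
            index=["p0", "p1", "p2"],
        )
        trt = pd.DataFrame(
            {"t1": [5.0, 6.0, 9.0], "t2": [7.0, 8.0, 11.0]},
            index=["p0", "p1", "p2"],
        )
        ct = self._meta(["c1", "c2"], [2.0, 2.0])
        tt = self._meta(["t1", "t2"], [2.0, 2.0])
        cn, tn = normalize_proteome(ctrl, trt, ct, tt)
        assert np.allclose(cn["c1"].dropna(), [2.0, 3.0])
        assert np.allclose(cn["c2"].dropna(), [2.0, 3.0])
        assert np.allclose(tn["t1"], [2.0, 3.0, 6.0])
        assert np.allclose(tn["t2"], [2.0, 3.0, 6.0])
        assert tn.loc["p2"].notna().all()  # excluded from reference, kept in output

    def test_empty_common_set_names_time_point(self):
        ctrl = pd.DataFrame({"c1": [1.0, np.nan]}, index=["p0", "p1"])
        trt = pd.DataFrame({"t1": [np.nan, 2.0]}, index=["p0", "p1"])
        with pytest.raises(ValueError, match="8"):
            normalize_proteome(
                ctrl, trt, self._meta(["c1"], [8.0]), self._meta(["t1"], [8.0])
            )


class TestFitDynamicModel:
    def test_recovers_known_coefficients(self):
        """Estimates fall within 3 SE of truth ~>=95% of the time."""
        rng = np.random.default_rng(42)
        truth = (0.0, 0.5 / 336.0, -0.01 / 336.0**2)  # scaled to raw hours
        n_within = 0
        n_rep = 200
        for _ in range(n_rep):
            y, cond, times = _series(
                synth.DEFAULT_TIMES_H, 0.05, (10.0, 0.0, 0.0), truth, rng
            )
            fit = fit_dynamic_model(y, cond, times)
            # SE implied by reported p-values and estimates (t = beta/se)
            within = True
            for est, tru, p in zip(fit.beta_TvsC, truth, fit.p_TvsC):
                tval = stats.t.ppf(1 - p / 2, fit.n_obs - 6)
                se = abs(est) / tval if tval > 0 else np.inf
                if se > 0 and abs(est - tru) > 3 * se:
                    within = False
            n_within += within
        assert n_within / n_rep >= 0.95

    def test_treated_identical_to_control(self):
        times = np.tile(np.repeat(synth.DEFAULT_TIMES_H, 3), 2)
        half = len(times) // 2
        cond = np.array(["C"] * half + ["T"] * half)
        rng = np.random.default_rng(0)
        profile = 5 + 0.01 * times[:half] + rng.normal(0, 0.1, half)
        y = np.concatenate([profile, profile])
        fit = fit_dynamic_model(y, cond, times)
        assert np.allclose(fit.beta_TvsC, 0.0, atol=1e-10)
        assert fit.global_p == pytest.approx(1.0)

    def test_constant_response(self):
        times = np.tile(np.repeat(synth.DEFAULT_TIMES_H, 3), 2)
        cond = np.array(["C"] * 21 + ["T"] * 21)
        fit = fit_dynamic_model(np.full(42, 7.0), cond, times)
        assert fit.r_squared == 0.0
        assert fit.global_p == 1.0
        assert not fit.is_dynamic

    def test_too_few_observations_marks_failed(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        cond = np.array(["C", "C", "T", "T"])
        times = np.array([2.0, 8.0, 2.0, 8.0])
        fit = fit_dynamic_model(y, cond, times)
        assert fit.failed

    def test_affine_invariance(self):
        """Adding a constant changes only the intercept, not p-values."""
        rng = np.random.default_rng(3)
        y, cond, times = _series(
            synth.DEFAULT_TIMES_H, 0.2, (8.0, 0.001, 0.0), (0.3, 0.002, 0.0), rng
        )
        f1 = fit_dynamic_model(y, cond, times)
        f2 = fit_dynamic_model(y + 100.0, cond, times)
        assert f1.p_TvsC[1] == pytest.approx(f2.p_TvsC[1], rel=1e-8)
        assert f1.p_TvsC[2] == pytest.approx(f2.p_TvsC[2], rel=1e-8)
        assert f1.global_p == pytest.approx(f2.global_p, rel=1e-8)

    def test_missing_dropped_listwise(self):
        rng = np.random.default_rng(4)
        y, cond, times = _series(
            synth.DEFAULT_TIMES_H, 0.1, (5.0, 0.0, 0.0), (1.0, 0.0, 0.0), rng
        )
        y[3] = np.nan
        fit = fit_dynamic_model(y, cond, times)
        assert fit.n_obs == 41


class TestCallDynamicFeatures:
    @staticmethod
    def _fit(feature, p, r2=0.9, n=42):
        return DynamicFit(
            feature=feature, beta_C=(0, 0, 0), beta_TvsC=(0, 0, 0),
            p_TvsC=(0.5, 0.5, 0.5), global_p=p, r_squared=r2, n_obs=n,
            residual_sd=0.1,
        )

    def test_bh_stepup_hand_example(self):
        # step-up on (0.001, 0.01, 0.02, 0.04, 0.9):
        # raw q_i = p_i * m / i -> (0.005, 0.025, 0.0333.., 0.05, 0.9),
        # already monotone from the top.
        pvals = [0.001, 0.01, 0.02, 0.04, 0.9]
        fits = {f"f{i}": self._fit(f"f{i}", p) for i, p in enumerate(pvals)}
        call_dynamic_features(fits)
        expected = [0.005, 0.025, 0.1 / 3, 0.05, 0.9]
        got = [fits[f"f{i}"].q_value for i in range(5)]
        assert np.allclose(got, expected)

    def test_all_p_one_gives_empty_set(self):
        fits = {f"f{i}": self._fit(f"f{i}", 1.0) for i in range(5)}
        assert call_dynamic_features(fits) == set()

    def test_r2_threshold_excludes(self):
        fits = {
            "good": self._fit("good", 0.0001, r2=0.95),
            "lowr2": self._fit("lowr2", 0.0001, r2=0.6),
        }
        assert call_dynamic_features(fits) == {"good"}

    def test_min_obs_threshold_excludes(self):
        fits = {"few": self._fit("few", 0.0001, n=8)}
        assert call_dynamic_features(fits) == set()

    def test_q_monotone_in_p_rank(self, small_network, strong_truth):
        tc = synth.generate_timecourse(
            small_network, strong_truth, "DOX", "therapeutic", synth.TRANSCRIPTOME, seed=21
        )
        fits = fit_timecourse(tc)
        call_dynamic_features(fits)
        df = fits_to_frame(fits).sort_values("global_p")
        assert (np.diff(df["q_value"].to_numpy()) >= -1e-12).all()

    def test_strong_effect_recovery(self, small_network, strong_truth, proteome_timecourse):
        """>=90% of planted dynamic features are called in the strong regime."""
        fits = fit_timecourse(proteome_timecourse)
        called = call_dynamic_features(fits)
        planted = small_network.module_nodes(0)
        assert len(called & planted) / len(planted) >= 0.9

    def test_fit_table_roundtrip(self, tmp_path, proteome_timecourse):
        fits = fit_timecourse(proteome_timecourse)
        call_dynamic_features(fits)
        df = fits_to_frame(fits)
        back = fits_to_frame(frame_to_fits(df))
        pd.testing.assert_frame_equal(df, back)


class TestTimepointTests:
    def _tiny_tc(self, treated_by_time, control_by_time):
        cols, conds, ts, reps = {}, [], [], []
        for cond, by_time in (("C", control_by_time), ("T", treated_by_time)):
            for t, vals in by_time.items():
                for r, v in enumerate(vals, 1):
                    sid = f"{cond}_{t}_{r}"
                    cols[sid] = [v]
                    conds.append(cond)
                    ts.append(float(t))
                    reps.append(r)
        values = pd.DataFrame(cols, index=["feat"])
        meta = pd.DataFrame(
            {"condition": conds, "time_h": ts, "replicate": reps},
            index=pd.Index(values.columns, name="sample_id"),
        )
        return synth.OmicsTimeCourse(values, meta, synth.PROTEOME)

    def test_identical_groups(self):
        tc = self._tiny_tc({2: [1.0, 2.0, 3.0]}, {2: [1.0, 2.0, 3.0]})
        out = timepoint_tests(tc, "vs_control")
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_unit_fold_change(self, rng):
        a = 2.0 + rng.normal(0, 1e-6, 3)
        b = 1.0 + rng.normal(0, 1e-6, 3)
        tc = self._tiny_tc({2: list(a)}, {2: list(b)})
        out = timepoint_tests(tc, "vs_control")
        assert out.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-4)

    def test_matches_hand_computed_t_statistic(self):
        # groups (1, 2) vs (4, 6): diff = -3.5, s_p^2 = (0.5 + 2)/2 = 1.25,
        # t = -3.5 / sqrt(1.25 * (1/2 + 1/2)) = -3.1304951..., df = 2
        tc = self._tiny_tc({2: [1.0, 2.0]}, {2: [4.0, 6.0]})
        out = timepoint_tests(tc, "vs_control")
        t_manual = -3.5 / np.sqrt(1.25)
        p_manual = 2 * stats.t.sf(abs(t_manual), 2)
        assert out.loc[0, "p"] == pytest.approx(p_manual, abs=1e-10)
        assert out.loc[0, "log2fc"] == pytest.approx(-3.5)

    def test_vs_baseline_compares_to_earliest(self):
        tc = self._tiny_tc(
            {2: [1.0, 1.1, 0.9], 8: [2.0, 2.1, 1.9], 24: [3.0, 3.1, 2.9]},
            {2: [0.0, 0.0, 0.1], 8: [0.0, 0.1, 0.0], 24: [0.1, 0.0, 0.0]},
        )
        out = timepoint_tests(tc, "vs_baseline")
        assert sorted(out["time_h"]) == [8.0, 24.0]
        fc8 = out.set_index("time_h").loc[8.0, "log2fc"]
        assert fc8 == pytest.approx(1.0, abs=0.2)

    def test_insufficient_replicates_not_testable(self):
        tc = self._tiny_tc({2: [1.0]}, {2: [1.0, 2.0, 3.0]})
        out = timepoint_tests(tc, "vs_control")
        assert not out.loc[0, "testable"]
        assert np.isnan(out.loc[0, "q"])


def test_null_calibration_small():
    """Type-I rate of the global F-test near nominal on 400 null features."""
    rng = np.random.default_rng(9)
    hits = 0
    n_feat = 400
    for _ in range(n_feat):
        y, cond, times = _series(
            synth.DEFAULT_TIMES_H, 0.3, (5.0, 0.001, 0.0), (0.0, 0.0, 0.0), rng
        )
        if fit_dynamic_model(y, cond, times).global_p <= 0.05:
            hits += 1
    assert 0.02 <= hits / n_feat <= 0.08  # wide band at n=400
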