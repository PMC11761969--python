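"""ROI GLM machinery: design construction vs a summation oracle, OLS vs the
normal-equations oracle, factorial ANOVAs vs hand sums of squares, epoching,
LOO peak test, PPI model structure."""

import numpy as np
import pandas as pd
import pytest

from oceanforage import CohortSpec, TaskConfig, generate_cohort
from oceanforage.bold_sim import (
    DEFAULT_TR,
    HrfSpec,
    RoiGroundTruth,
    event_amplitudes,
    hrf_kernel,
    hrf_value,
    synthesize_roi,
)
from oceanforage.neuro_glm import (
    DesignMatrix,
    DesignSpec,
    assign_psych,
    brain_behavior_corr,
    build_design,
    dct_basis,
    epoch_timecourses,
    fit_glm,
    glm_events,
    group_beta_anova,
    loo_peak_test,
    ppi_factorial,
    ppi_group,
    ppi_regression,
)


@pytest.fixture(scope="module")
def one_participant(cfg):
    logs, _ = generate_cohort(CohortSpec(n_agents=1, seed=17), cfg)
    ev = glm_events(logs[0], cfg, phase="pre")
    n_vol = int(np.ceil(cfg.session_duration / DEFAULT_TR))
    return logs[0], ev, n_vol


def plain_design(cols: dict, n: int) -> DesignMatrix:
    X = pd.DataFrame(cols)
    return DesignMatrix(
        X, {c: False for c in X.columns}, np.zeros((n, 0)), DEFAULT_TR, DesignSpec()
    )


class TestBuildDesign:
    def test_single_event_column_is_sampled_hrf(self):
        ev = pd.DataFrame(
            {"t_abs": [20.0], "glm_class": ["check_switch"], "z_threat": [0.0],
             "z_reward_rate": [0.0]}
        )
        spec = DesignSpec(
            event_classes=("check_switch",), modulated={}, highpass_cutoff=None,
            include_confounds=False, drift=False, oversample=16,
        )
        X = build_design(ev, DEFAULT_TR, 40, spec)
        tv = np.arange(40) * DEFAULT_TR
        # snapped to the oversampled grid: within one fine step of the
        # continuous-time kernel
        expect = hrf_value(HrfSpec(), tv - 20.0)
        assert np.max(np.abs(X.X["check_switch"].to_numpy() - expect)) < 0.05

    def test_constant_modulator_column_omitted(self):
        ev = pd.DataFrame(
            {
                "t_abs": [10.0, 30.0, 50.0],
                "glm_class": ["check_switch"] * 3,
                "z_threat": [0.4, 0.4, 0.4],
                "z_reward_rate": [0.0, 0.1, -0.1],
            }
        )
        spec = DesignSpec(
            event_classes=("check_switch",),
            modulated={"check_switch": ("z_threat", "z_reward_rate")},
            include_confounds=False,
            drift=False,
        )
        X = build_design(ev, DEFAULT_TR, 60, spec)
        assert "check_switch_x_z_threat" in X.omitted_classes
        assert "check_switch_x_z_reward_rate" in X.names

    def test_zero_event_class_recorded(self, one_participant):
        _, ev, n_vol = one_participant
        spec = DesignSpec(event_classes=("check_switch", "nonexistent_class"))
        X = build_design(ev, DEFAULT_TR, n_vol, spec)
        assert "nonexistent_class" in X.omitted_classes

    def test_matches_convolution_by_summation_oracle(self, one_participant, rng):
        _, ev, n_vol = one_participant
        spec = DesignSpec(highpass_cutoff=None, include_confounds=False, drift=False)
        X = build_design(ev, DEFAULT_TR, n_vol, spec)
        os = spec.oversample
        dt = DEFAULT_TR / os
        kernel = hrf_kernel(spec.hrf, dt)
        n_fine = n_vol * os
        for cls in ("check_switch", "forage_switch"):
            sub = ev[ev["glm_class"] == cls]
            # independent route: add a kernel copy per event on the fine grid
            fine = np.zeros(n_fine + len(kernel))
            for t0 in sub["t_abs"]:
                i = int(round(t0 / dt))
                if i < n_fine:
                    fine[i : i + len(kernel)] += kernel
            oracle = fine[:n_fine][::os]
            assert np.max(np.abs(X.X[cls].to_numpy() - oracle)) < 1e-10


class TestHighpass:
    def test_drift_energy_removed_event_columns_preserved(self, one_participant):
        _, ev, n_vol = one_participant
        basis = dct_basis(n_vol, DEFAULT_TR, 100.0)
        tv = np.arange(n_vol) * DEFAULT_TR
        drift = tv - tv.mean()
        filtered = drift - basis @ (basis.T @ drift)
        assert np.sum(filtered**2) < 0.05 * np.sum(drift**2)
        spec = DesignSpec(include_confounds=False, drift=False)
        X_f = build_design(ev, DEFAULT_TR, n_vol, spec)
        spec_n = DesignSpec(
            include_confounds=False, drift=False, highpass_cutoff=None
        )
        X_n = build_design(ev, DEFAULT_TR, n_vol, spec_n)
        col = "check_switch"
        r = np.corrcoef(X_f.X[col], X_n.X[col])[0, 1]
        assert r >= 0.95


class TestFitGlm:
    def test_exact_recovery_without_noise(self, rng):
        n = 120
        cols = {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
            "const": np.ones(n),
        }
        X = plain_design(cols, n)
        b_true = np.array([1.5, -2.0, 0.3])
        y = X.X.to_numpy() @ b_true
        fit = fit_glm(y, X)
        assert fit.betas.to_numpy() == pytest.approx(b_true, abs=1e-10)
        # residual orthogonality invariant
        assert np.max(np.abs(X.X.to_numpy().T @ fit.residuals)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            n, k = 60, 5
            M = rng.standard_normal((n, k))
            y = rng.standard_normal(n)
            X = plain_design({f"c{i}": M[:, i] for i in range(k)}, n)
            fit = fit_glm(y, X)
            oracle = np.linalg.solve(M.T @ M, M.T @ y)
            assert fit.betas.to_numpy() == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_duplicated_column_named_in_error(self, rng):
        n = 50
        col = rng.standard_normal(n)
        X = plain_design({"first": col, "second": col.copy(), "const": np.ones(n)}, n)
        with pytest.raises(ValueError, match="first.*second|second.*first"):
            fit_glm(rng.standard_normal(n), X)

    def test_prewhitening_reports_ar1(self, rng):
        n = 400
        X = plain_design({"x": rng.standard_normal(n), "const": np.ones(n)}, n)
        from scipy import signal as sps

        y = sps.lfilter([1], [1, -0.5], rng.standard_normal(n))
        fit = fit_glm(y, X, prewhiten=True)
        assert fit.ar1 == pytest.approx(0.5, abs=0.1)


def anova3_hand_oracle(df):
    """Balanced three-way fixed-effects ANOVA by explicit sums of squares."""
    factors = ["roi", "switch_type", "feature"]
    grand = df["beta"].mean()
    n = len(df)
    ss = {}
    # main effects
    for f in factors:
        means = df.groupby(f)["beta"].mean()
        counts = df.groupby(f)["beta"].count()
        ss[f] = float((counts * (means - grand) ** 2).sum())
    # two-way interactions
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = factors[i], factors[j]
            cell = df.groupby([a, b])["beta"].agg(["mean", "count"])
            ss_ab = float(
                (cell["count"] * (cell["mean"] - grand) ** 2).sum()
            ) - ss[a] - ss[b]
            ss[f"{a}:{b}"] = ss_ab
    cell3 = df.groupby(factors)["beta"].agg(["mean", "count"])
    ss_cells = float((cell3["count"] * (cell3["mean"] - grand) ** 2).sum())
    ss["three_way"] = ss_cells - sum(
        ss[k] for k in list(ss) if k != "three_way"
    )
    ss_resid = float(((df["beta"] - df.groupby(factors)["beta"].transform("mean")) ** 2).sum())
    df_resid = n - cell3.shape[0]
    out = {}
    levels = {f: df[f].nunique() for f in factors}
    for f in factors:
        out[f] = (ss[f] / (levels[f] - 1)) / (ss_resid / df_resid)
    return out, df_resid


class TestGroupBetaAnova:
    def make_table(self, rng, n_sub=3):
        rows = []
        for pid in range(n_sub):
            for roi in ("Hb", "DRN", "VTA", "SN"):
                for sw in ("check", "forage"):
                    for feat in ("threat", "reward"):
                        rows.append(
                            {
                                "participant_id": pid,
                                "roi": roi,
                                "switch_type": sw,
                                "feature": feat,
                                "beta": rng.standard_normal(),
                            }
                        )
        return pd.DataFrame(rows)

    def test_equal_betas_leave_no_effect_variance(self, rng):
        df = self.make_table(rng)
        df["beta"] = 1.0
        table = group_beta_anova(df)
        effects = table.drop(index="Residual")
        assert (effects["sum_sq"].abs() < 1e-12).all()

    def test_matches_hand_sums_of_squares(self, rng):
        df = self.make_table(rng, n_sub=3)
        table = group_beta_anova(df)
        oracle, df_resid = anova3_hand_oracle(df)
        assert table.loc["C(roi)", "F"] == pytest.approx(oracle["roi"], rel=1e-8)
        assert table.loc["C(switch_type)", "F"] == pytest.approx(
            oracle["switch_type"], rel=1e-8
        )
        assert table.loc["Residual", "df"] == df_resid

    def test_missing_cells_rejected(self, rng):
        df = self.make_table(rng)
        df = df[~((df["roi"] == "Hb") & (df["switch_type"] == "check"))]
        with pytest.raises(ValueError, match="missing cells"):
            group_beta_anova(df)

    def test_additive_effects_show_no_interaction(self, rng):
        df = self.make_table(rng, n_sub=2)
        roi_eff = {"Hb": 0.0, "DRN": 1.0, "VTA": 2.0, "SN": 3.0}
        sw_eff = {"check": 0.5, "forage": -0.5}
        df["beta"] = df["roi"].map(roi_eff) + df["switch_type"].map(sw_eff)
        table = group_beta_anova(df)
        assert table.loc["C(roi)", "sum_sq"] > 1.0
        assert table.loc["C(switch_type)", "sum_sq"] > 1.0
        assert table.loc["C(roi):C(switch_type)", "sum_sq"] < 1e-12


class TestBrainBehaviorCorr:
    def test_collinear_vectors(self):
        x = np.arange(10.0)
        out = brain_behavior_corr(x, 2 * x + 1)
        assert out["r"] == pytest.approx(1.0)
        assert out["p"] < 1e-10

    def test_bonferroni_multiplies_before_cap(self, rng):
        x, y = rng.standard_normal(23), rng.standard_normal(23)
        a = brain_behavior_corr(x, y, n_tests=1)
        b = brain_behavior_corr(x, y, n_tests=4)
        assert b["p_bonferroni"] == pytest.approx(min(1.0, a["p"] * 4))

    def test_zero_variance_flagged(self):
        out = brain_behavior_corr(np.ones(10), np.arange(10.0))
        assert out["undefined"] and np.isnan(out["r"])

    def test_critical_r_calibration(self, rng):
        # |r| exceeds the two-tailed .05 critical value (df=21) in ~5% of
        # independent draws
        count = 0
        reps = 2000
        for _ in range(reps):
            r = np.corrcoef(rng.standard_normal(23), rng.standard_normal(23))[0, 1]
            count += abs(r) > 0.413
        assert 0.03 < count / reps < 0.07


class TestEpochs:
    def test_constant_series_baselines_to_zero(self):
        y = np.full(200, 3.7)
        es = epoch_timecourses(y, [100.0, 200.0], tr=DEFAULT_TR)
        assert es.data == pytest.approx(np.zeros_like(es.data))

    def test_evoked_peak_at_hrf_argmax(self):
        tr = DEFAULT_TR
        n = 300
        onsets = [120.0, 250.0, 380.0]
        tv = np.arange(n) * tr
        y = np.zeros(n)
        for t0 in onsets:
            y += hrf_value(HrfSpec(), tv - t0)
        es = epoch_timecourses(y, onsets, tr=tr, upsample=4)
        peak_t = es.times[np.argmax(es.mean())]
        assert abs(peak_t - 5.0) <= tr / 4 + 0.3

    def test_partial_window_dropped_and_counted(self):
        y = np.zeros(50)
        es = epoch_timecourses(y, [40.0, 95.0], tr=DEFAULT_TR)
        assert es.n_dropped == 1 and len(es.data) == 1

    def test_no_complete_window_rejected(self):
        with pytest.raises(ValueError):
            epoch_timecourses(np.zeros(4), [3.0], tr=DEFAULT_TR)


class TestLooPeak:
    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            loo_peak_test(np.zeros((1, 10)), np.arange(10.0))
        with pytest.raises(ValueError):
            loo_peak_test(np.random.default_rng(0).normal(size=(5, 10)), np.arange(10.0))

    def test_injected_evoked_response_detected(self, rng):
        times = np.arange(-2, 12.01, DEFAULT_TR / 4)
        evoked = hrf_value(HrfSpec(), times)
        detected = 0
        for _ in range(50):
            traces = evoked + rng.standard_normal((23, 24, len(times))).mean(1) * 2.0
            res = loo_peak_test(traces, times, direction="max")
            detected += res["p"] < 0.05
        assert detected >= 45  # >= 90 % power
        assert abs(res["mean_peak_latency"] - 5.0) < 2.0

    def test_marginal_unbiasedness_of_loo_values(self, rng):
        # each participant's value at a latency chosen without their data is
        # mean-zero under the null (the group-level dependence is a separate,
        # documented property)
        means = []
        for _ in range(300):
            traces = rng.standard_normal((8, 30))
            res = loo_peak_test(traces, np.arange(30.0), direction="max")
            means.append(res["values"])
        grand = np.concatenate(means).mean()
        # tested values are positively dependent within a replicate, so the
        # Monte-Carlo error of the grand mean is wider than the iid rate
        assert abs(grand) < 0.1


@pytest.fixture(scope="module")
def ppi_setup(one_participant):
    log, ev, n_vol = one_participant
    truth = RoiGroundTruth(
        "x",
        {"check_switch": 1.0, "forage_switch": -0.5, "check_repeat": 0.4,
         "forage_repeat": 0.2, "discovery": 0.8, "hide": 0.3},
        {("check_switch", "tp"): 0.5},
        snr=0.5,
    )
    amp = assign_psych(event_amplitudes(ev, truth))
    X = build_design(amp, DEFAULT_TR, n_vol, DesignSpec())
    tgt = synthesize_roi(amp, truth, HrfSpec(), n_vol, np.random.default_rng(0))
    seed = synthesize_roi(amp, truth, HrfSpec(), n_vol, np.random.default_rng(1))
    return amp, X, tgt, seed


class TestPpiRegression:
    def _unused(self, one_participant):
        pass

    def test_term_set_and_dropped_psych_main(self, ppi_setup):
        amp, X, tgt, seed = ppi_setup
        out = ppi_regression(tgt, seed, amp, X_base=X)
        terms = set(out["term"])
        for t in ("seed", "seed_x_psych", "seed_x_modulator", "seed_x_psych_x_modulator"):
            assert t in terms
        # psych main is an exact combination of the per-class regressors
        assert "psych" in out.attrs.get("dropped_mains", [])

    def test_constant_psych_rejected(self, ppi_setup):
        amp, X, tgt, seed = ppi_setup
        bad = amp.copy()
        bad["psych"] = np.where(bad["psych"] != 0, 1.0, 0.0)
        with pytest.raises(ValueError, match="constant|collinear"):
            ppi_regression(tgt, seed, bad, X_base=X)

    def test_seed_equals_target_rejected(self, ppi_setup):
        amp, X, tgt, _ = ppi_setup
        with pytest.raises(ValueError, match="identical"):
            ppi_regression(tgt, tgt, amp, X_base=X)

    def test_group_z_from_t(self, ppi_setup, rng):
        fits = []
        for _ in range(8):
            f = pd.DataFrame(
                {"term": ["seed_x_psych_x_modulator"], "estimate": [rng.normal(0.5, 0.1)]}
            )
            fits.append(f)
        g = ppi_group(fits, "seed_x_psych_x_modulator")
        from scipy import stats

        assert g["z"] == pytest.approx(
            np.sign(g["t"]) * stats.norm.isf(g["p"] / 2), rel=1e-9
        )


class TestPpiFactorial:
    def make_peaks(self, rng, shift=None):
        rows = []
        for pid in range(10):
            for c in ("ACC", "AI"):
                for s in ("Hb", "DRN"):
                    val = rng.standard_normal() * 0.01
                    if shift and (c, s) == shift[0]:
                        val += shift[1]
                    rows.append(
                        {"participant_id": pid, "cortical": c, "subcortical": s, "peak": val}
                    )
        return pd.DataFrame(rows)

    def test_identical_cells_show_no_effects_or_rejections(self, rng):
        peaks = self.make_peaks(rng)
        peaks["peak"] = 2.0
        out = ppi_factorial(peaks)
        effects = out["anova"].drop(index="Residual")
        assert (effects["sum_sq"].abs() < 1e-12).all()
        assert not out["tukey_cortical"]["reject"].astype(bool).any()
        assert (out["tukey_cortical"]["meandiff"].astype(float).abs() < 1e-12).all()

    def test_single_shifted_cell_detected(self, rng):
        peaks = self.make_peaks(rng, shift=(("ACC", "Hb"), 5.0))
        out = ppi_factorial(peaks)
        a = out["anova"]
        assert a.loc["C(cortical)", "PR(>F)"] < 0.001
        assert a.loc["C(cortical):C(subcortical)", "PR(>F)"] < 0.001

    def test_two_way_f_matches_hand_oracle(self, rng):
        peaks = self.make_peaks(rng)
        out = ppi_factorial(peaks)["anova"]
        df = peaks
        grand = df["peak"].mean()
        ss_c = sum(
            len(g) * (g["peak"].mean() - grand) ** 2
            for _, g in df.groupby("cortical")
        )
        cell = df.groupby(["cortical", "subcortical"])["peak"].transform("mean")
        ss_resid = ((df["peak"] - cell) ** 2).sum()
        df_resid = len(df) - 4
        f_hand = (ss_c / 1) / (ss_resid / df_resid)
        assert out.loc["C(cortical)", "F"] == pytest.approx(f_hand, rel=1e-8)

    def test_missing_cell_rejected(self, rng):
        peaks = self.make_peaks(rng)
        peaks = peaks[~((peaks["cortical"] == "AI") & (peaks["subcortical"] == "DRN"))]
        with pytest.raises(ValueError, match="incomplete"):
            ppi_factorial(peaks)
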