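"""Step-3 interaction models, backward selection, joint test and permutation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import logicgei as lg
from logicgei.gei import (
    PermutationSummary,
    SingularDesignError,
    Step3Data,
    Term,
    all_candidate_terms,
    backward_select_subpathway,
    build_design,
    fit_risk_model,
    fit_survival_model,
    joint_final_model,
    permutation_test,
    run_step3,
)
from logicgei.io_encoding import EXPOSURE_LEVELS


def make_exposures(n, rng):
    return pd.DataFrame({
        name: pd.Categorical.from_codes(
            rng.integers(0, len(levels), n), categories=list(levels)
        )
        for name, levels in EXPOSURE_LEVELS.items()
    })


def make_covariates(n, rng):
    return pd.DataFrame({
        "age": rng.normal(60, 10, n).round(1),
        "sex": rng.choice(["male", "female"], n),
        "race": rng.choice(["white", "hispanic", "african_american"], n, p=[0.8, 0.1, 0.1]),
        "center": rng.choice(["utah", "northern_california"], n),
    })


@pytest.fixture
def risk_setup():
    rng = np.random.default_rng(0)
    n = 1500
    gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(3)}
    expo = make_exposures(n, rng)
    cova = make_covariates(n, rng)
    term = Term("G0", "smoking", "ge20py")
    inter = gst_cols["G0"] * (expo["smoking"] == "ge20py").to_numpy()
    eta = -0.4 + 0.3 * gst_cols["G0"] + np.log(2.2) * inter
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return gst_cols, expo, cova, y, term


class TestRiskModel:
    def test_exposure_only_2x2_reproduces_cross_product(self):
        # printed alcohol counts: cases 556 non-mod / 191 heavy,
        # controls 759 / 197 -> crude OR 1.3235
        y = np.array([1.0] * 747 + [0.0] * 956)
        alcohol = pd.Categorical(
            ["non_moderate"] * 556 + ["heavy"] * 191
            + ["non_moderate"] * 759 + ["heavy"] * 197,
            categories=["non_moderate", "heavy"],
        )
        n = len(y)
        expo = pd.DataFrame({
            "smoking": pd.Categorical(["never"] * n, categories=list(EXPOSURE_LEVELS["smoking"])),
            "alcohol": alcohol,
            "protein": pd.Categorical(["low"] * n, categories=["low", "high"]),
        })
        gst = {"G0": np.zeros(n)}
        # constant gst and single-level exposures drop to an exposure-only fit:
        # build design manually to keep only intercept + heavy indicator
        design = pd.DataFrame({
            "intercept": np.ones(n),
            "alcohol=heavy": (alcohol == "heavy").astype(float),
        })
        from logicgei.glm import fit_logistic

        fit = fit_logistic(design.to_numpy(), y)
        assert np.exp(fit.beta[1]) == pytest.approx((191 * 759) / (556 * 197), rel=1e-6)
        assert np.exp(fit.beta[1]) == pytest.approx(1.3235, abs=5e-5)

    def test_matches_statsmodels(self, risk_setup):
        # dual route: same design fitted by the independent statsmodels MLE
        gst_cols, expo, cova, y, term = risk_setup
        fit = fit_risk_model(list(gst_cols), gst_cols, expo, cova, None, y, [term])
        design = build_design(list(gst_cols), gst_cols, expo, cova, None, [term])
        ref = sm.Logit(y, design.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, rtol=1e-5)

    def test_recovers_planted_interaction(self, risk_setup):
        gst_cols, expo, cova, y, term = risk_setup
        fit = fit_risk_model(list(gst_cols), gst_cols, expo, cova, None, y, [term])
        gt = fit.terms[term]
        lo, hi = gt.ci95
        assert lo < 2.2 < hi
        assert gt.p < 0.05

    def test_stratum_gene_or_consistency(self, risk_setup):
        # exp(b_GST + b_INT) equals the reported stratum gene OR identity
        gst_cols, expo, cova, y, term = risk_setup
        fit = fit_risk_model(list(gst_cols), gst_cols, expo, cova, None, y, [term])
        expected = np.exp(fit.params["gst_G0"] + fit.params[term.name])
        assert fit.stratum_gene_ratio(term) == pytest.approx(expected, rel=1e-12)

    def test_zero_interaction_gives_equal_stratum_ors(self):
        rng = np.random.default_rng(1)
        n = 3000
        gst = {"G0": rng.integers(0, 2, n).astype(float)}
        expo = make_exposures(n, rng)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 0.5 * gst["G0"])))).astype(float)
        term = Term("G0", "protein", "high")
        fit = fit_risk_model(["G0"], gst, expo, None, None, y, [term])
        # interaction is null: stratum OR ratio ~ 1, i.e. OR_INT CI covers 1
        lo, hi = fit.terms[term].ci95
        assert lo < 1.0 < hi if not fit.terms[term].flipped else True

    def test_hierarchy_always_present(self, risk_setup):
        gst_cols, expo, cova, y, term = risk_setup
        fit = fit_risk_model(list(gst_cols), gst_cols, expo, cova, None, y, [term])
        assert f"gst_{term.gene}" in fit.params.index
        assert f"{term.exposure}={term.level}" in fit.params.index

    def test_singular_design_names_columns(self, risk_setup):
        gst_cols, expo, cova, y, term = risk_setup
        gst_cols = dict(gst_cols)
        gst_cols["G9"] = gst_cols["G0"].copy()  # duplicate column
        with pytest.raises(SingularDesignError, match="gst_G9"):
            fit_risk_model(list(gst_cols), gst_cols, expo, cova, None, y, [term])

    def test_flipped_orientation_reports_ratio_above_one(self):
        rng = np.random.default_rng(2)
        n = 2500
        gst = {"G0": rng.integers(0, 2, n).astype(float)}
        expo = make_exposures(n, rng)
        inter = gst["G0"] * (expo["alcohol"] == "heavy").to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 - np.log(2.0) * inter)))).astype(float)
        term = Term("G0", "alcohol", "heavy")
        fit = fit_risk_model(["G0"], gst, expo, None, None, y, [term])
        gt = fit.terms[term]
        assert gt.flipped and gt.ratio > 1
        # the complement orientation inverts the estimate, not the p-value
        assert gt.ratio == pytest.approx(np.exp(-gt.estimate), rel=1e-12)


class TestSurvivalModel:
    def _survival_data(self, n, rng, hr_int=2.0):
        gst = {"G0": rng.integers(0, 2, n).astype(float)}
        expo = make_exposures(n, rng)
        inter = gst["G0"] * (expo["protein"] == "high").to_numpy()
        stage = pd.Series(rng.choice(["local", "regional", "distant"], n, p=[0.5, 0.35, 0.15]))
        lam0 = pd.Series({"local": 0.004, "regional": 0.01, "distant": 0.04})
        rate = lam0[stage].to_numpy() * np.exp(np.log(hr_int) * inter)
        t_event = rng.exponential(1 / rate)
        time = np.minimum(t_event, 120.0)
        event = (t_event <= 120.0).astype(int)
        return gst, expo, stage, time, event

    def test_two_group_exponential_hr(self):
        rng = np.random.default_rng(3)
        gst, expo, stage, time, event = self._survival_data(5000, rng)
        term = Term("G0", "protein", "high")
        fit = fit_survival_model(["G0"], gst, expo, None, None, time, event,
                                 stage, [term])
        gt = fit.terms[term]
        assert gt.ratio == pytest.approx(2.0, abs=0.25)
        lo, hi = gt.ci95
        assert lo < 2.0 < hi

    def test_eventless_stratum_does_not_change_estimates(self):
        rng = np.random.default_rng(4)
        gst, expo, stage, time, event = self._survival_data(800, rng)
        term = Term("G0", "protein", "high")
        fit1 = fit_survival_model(["G0"], gst, expo, None, None, time, event,
                                  stage, [term])
        # append an all-censored stratum
        n_extra = 50
        gst2 = {"G0": np.concatenate([gst["G0"], rng.integers(0, 2, n_extra).astype(float)])}
        expo2 = pd.concat([expo, make_exposures(n_extra, rng)], ignore_index=True)
        stage2 = pd.concat([stage, pd.Series(["in_situ"] * n_extra)], ignore_index=True)
        time2 = np.concatenate([time, np.full(n_extra, 120.0)])
        event2 = np.concatenate([event, np.zeros(n_extra, dtype=int)])
        fit2 = fit_survival_model(["G0"], gst2, expo2, None, None, time2, event2,
                                  stage2, [term])
        assert fit2.terms[term].estimate == pytest.approx(fit1.terms[term].estimate, rel=1e-6)

    def test_no_events_rejected(self):
        rng = np.random.default_rng(5)
        gst, expo, stage, time, event = self._survival_data(100, rng)
        with pytest.raises(ValueError, match="no events"):
            fit_survival_model(["G0"], gst, expo, None, None, time,
                               np.zeros_like(event), stage, [Term("G0", "protein", "high")])


class TestBackwardSelection:
    def _fit_fn(self, gst_cols, expo, cova, y):
        genes = list(gst_cols)
        return lambda terms: fit_risk_model(genes, gst_cols, expo, cova, None, y, terms)

    def test_all_significant_nothing_removed(self):
        rng = np.random.default_rng(6)
        n = 4000
        gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(2)}
        expo = make_exposures(n, rng)
        terms = [Term("G0", "protein", "high"), Term("G1", "alcohol", "heavy")]
        eta = -0.3
        for t in terms:
            inter = gst_cols[t.gene] * (expo[t.exposure] == t.level).to_numpy()
            eta = eta + np.log(2.5) * inter
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        retained, fit = backward_select_subpathway(
            self._fit_fn(gst_cols, expo, None, y), terms
        )
        assert sorted(retained) == sorted(terms)
        # idempotence: re-running selection on the survivors changes nothing
        retained2, _ = backward_select_subpathway(
            self._fit_fn(gst_cols, expo, None, y), retained
        )
        assert retained2 == retained

    def test_empty_candidates_empty_return(self):
        retained, fit = backward_select_subpathway(lambda t: None, [])
        assert retained == [] and fit is None

    def test_planted_term_survives_noise_terms(self):
        kept = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(700 + rep)
            n = 1703
            gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(3)}
            expo = make_exposures(n, rng)
            planted = Term("G0", "smoking", "ge20py")
            inter = gst_cols["G0"] * (expo["smoking"] == "ge20py").to_numpy()
            y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + np.log(2.0) * inter)))).astype(float)
            candidates = [planted] + [
                Term("G1", "alcohol", "heavy"), Term("G1", "protein", "high"),
                Term("G2", "smoking", "lt20py"), Term("G2", "protein", "high"),
                Term("G2", "alcohol", "heavy"),
            ]
            retained, _ = backward_select_subpathway(
                self._fit_fn(gst_cols, expo, None, y), candidates
            )
            kept += planted in retained
        assert kept >= 0.8 * reps

    def test_terminates_within_term_count_iterations(self):
        rng = np.random.default_rng(8)
        n = 600
        gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(2)}
        expo = make_exposures(n, rng)
        y = rng.integers(0, 2, n).astype(float)  # pure noise
        candidates = all_candidate_terms(list(gst_cols))
        calls = 0
        inner = self._fit_fn(gst_cols, expo, None, y)

        def counting(terms):
            nonlocal calls
            calls += 1
            return inner(terms)

        retained, _ = backward_select_subpathway(counting, candidates)
        assert calls <= len(candidates) + 1


class TestJointModel:
    def test_no_survivors_gives_zero_count(self):
        fit, sig = joint_final_model(lambda t: None, [])
        assert fit is None and sig == []

    def test_single_subpathway_survivors_equal_subpathway_fit(self):
        rng = np.random.default_rng(9)
        n = 2000
        gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(2)}
        expo = make_exposures(n, rng)
        inter = gst_cols["G0"] * (expo["protein"] == "high").to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-(np.log(2.5) * inter - 0.4)))).astype(float)
        term = Term("G0", "protein", "high")
        fit_fn = lambda terms: fit_risk_model(
            list(gst_cols), gst_cols, expo, None, None, y, terms
        )
        sub_fit = fit_fn([term])
        joint_fit, sig = joint_final_model(fit_fn, [term])
        assert joint_fit.params.equals(sub_fit.params)


class TestPermutation:
    def _null_data(self, seed, n=800, n_genes=4):
        rng = np.random.default_rng(seed)
        gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(n_genes)}
        expo = make_exposures(n, rng)
        y = rng.integers(0, 2, n).astype(float)
        return Step3Data(
            gst_cols=gst_cols, exposures=expo, covariates=None, pathway_cols=None,
            subpathways={"sp1": [f"G{i}" for i in range(n_genes // 2)],
                         "sp2": [f"G{i}" for i in range(n_genes // 2, n_genes)]},
            y=y,
        )

    def test_observed_zero_gives_p_one(self):
        data = self._null_data(10)
        summary = permutation_test(data, "risk", 10, np.random.default_rng(0),
                                   observed_count=0)
        assert summary.empirical_p == 1.0

    def test_permutation_preserves_prevalences(self):
        data = self._null_data(11)
        n = len(data.exposures)
        rng = np.random.default_rng(1)
        perm = rng.permutation(n)
        for g, col in data.gst_cols.items():
            assert col[perm].sum() == col.sum()
        for name in EXPOSURE_LEVELS:
            before = data.exposures[name].value_counts().to_dict()
            after = pd.Series(
                np.asarray(data.exposures[name].astype(str))[perm]
            ).value_counts().to_dict()
            assert {k: v for k, v in before.items() if v} == after

    def test_requires_at_least_one_run(self):
        data = self._null_data(12)
        with pytest.raises(ValueError):
            permutation_test(data, "risk", 0, np.random.default_rng(0), observed_count=1)

    def test_null_counts_distribution_matches_observed_distribution(self):
        # exchangeability: under the global null the observed count is a
        # draw from the permutation-count distribution
        observed_counts = [run_step3(self._null_data(900 + k), "risk").count
                           for k in range(12)]
        data = self._null_data(950)
        summary = permutation_test(data, "risk", 40, np.random.default_rng(2))
        from scipy.stats import mannwhitneyu

        stat, p = mannwhitneyu(observed_counts, summary.counts)
        assert p > 0.01

    def test_empirical_p_convention(self):
        s = PermutationSummary(5, 2, [0, 1, 2, 3, 2])
        assert s.empirical_p == pytest.approx(3 / 5)


def test_run_step3_recovers_planted_interaction():
    rng = np.random.default_rng(13)
    n = 1703
    gst_cols = {f"G{i}": rng.integers(0, 2, n).astype(float) for i in range(4)}
    expo = make_exposures(n, rng)
    planted = Term("G1", "smoking", "ge20py")
    inter = gst_cols["G1"] * (expo["smoking"] == "ge20py").to_numpy()
    y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + np.log(2.2) * inter)))).astype(float)
    data = Step3Data(
        gst_cols=gst_cols, exposures=expo, covariates=make_covariates(n, rng),
        pathway_cols=None,
        subpathways={"sp1": ["G0", "G1"], "sp2": ["G2", "G3"]}, y=y,
    )
    result = run_step3(data, "risk")
    assert planted in result.significant
    gt = result.joint_fit.terms[planted]
    lo, hi = gt.ci95
    assert lo < 2.2 < hi
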