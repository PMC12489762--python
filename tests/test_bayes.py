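"""Gaussian Bayes posterior, both topologies, fitting and invariances."""

import math

import numpy as np
import pytest
from scipy import stats

import parkdx as px
from parkdx.bayes import REST, SD_FLOOR_FRACTION
from parkdx.biomarkers import MSA, PD, PSP


def random_model(rng, features=("mrpi", "mrpi2", "swi_put")):
    params = {(c, f): (float(rng.normal(0, 2)), float(rng.uniform(0.5, 2)))
              for c in px.CLASS_ORDER for f in features}
    priors = rng.dirichlet(np.ones(3))
    return px.model_from_marginals(
        params, features, priors={c: float(p)
                                  for c, p in zip(px.CLASS_ORDER, priors)})


def random_panel(rng, features, pid="p", missing_rate=0.2):
    values = {f: float(rng.normal(0, 2)) for f in features
              if rng.random() > missing_rate}
    for f in values:
        if f in px.RATIO_BIOMARKERS:
            values[f] = abs(values[f]) + 0.1
    return px.BiomarkerPanel(pid, values=values)


def brute_force_posterior(model, panel):
    """Direct density product + normalisation with scipy.stats.norm."""
    present = [f for f in model.features if f in panel.values]
    weights = {}
    for c in model.classes:
        w = model.priors[c]
        for f in present:
            mean, sd = model.params[(c, f)]
            w *= stats.norm.pdf(panel.values[f], loc=mean, scale=sd)
        weights[c] = w
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


class TestPosterior:
    def test_identical_classes_split_evenly(self):
        params = {(c, "mrpi"): (140.0, 30.0) for c in (PD, MSA)}
        model = px.model_from_marginals(params, ("mrpi",), classes=(PD, MSA))
        r = px.posterior(model, px.BiomarkerPanel("p", values={"mrpi": 150.0}))
        assert r.probabilities[PD] == pytest.approx(0.5, abs=1e-12)
        assert r.predicted == PD  # tie breaks to first in canonical order

    def test_dominance_at_well_separated_class_mean(self):
        params = {(PD, "mrpi"): (100.0, 10.0), (MSA, "mrpi"): (160.0, 10.0),
                  (PSP, "mrpi"): (220.0, 10.0)}
        model = px.model_from_marginals(params, ("mrpi",))
        r = px.posterior(model, px.BiomarkerPanel("p", values={"mrpi": 220.0}))
        assert r.probabilities[PSP] > 0.99
        assert r.predicted == PSP

    def test_matches_bruteforce_normalisation_oracle(self, rng):
        features = ("mrpi", "mrpi2", "swi_put")
        for i in range(100):
            model = random_model(rng, features)
            panel = random_panel(rng, features, pid=f"p{i}")
            if not any(f in panel.values for f in features):
                continue
            got = px.posterior(model, panel).probabilities
            want = brute_force_posterior(model, panel)
            for c in px.CLASS_ORDER:
                assert got[c] == pytest.approx(want[c], abs=1e-10)

    def test_matches_sklearn_gaussian_nb(self, rng):
        """Independent cross-check against sklearn's Gaussian naive Bayes."""
        from sklearn.naive_bayes import GaussianNB

        X = np.abs(rng.normal(size=(90, 3))) + np.repeat(
            [[1], [2], [3]], 30, axis=0)  # positive: usable as FA values
        y = np.repeat([0, 1, 2], 30)
        gnb = GaussianNB(priors=[1 / 3] * 3).fit(X, y)
        features = ("fa_scp", "fa_cb", "fa_mcp")
        params = {(c, f): (float(gnb.theta_[i, j]),
                           float(np.sqrt(gnb.var_[i, j])))
                  for i, c in enumerate(px.CLASS_ORDER)
                  for j, f in enumerate(features)}
        model = px.model_from_marginals(params, features)
        for row, sk in zip(X[:20], gnb.predict_proba(X[:20])):
            panel = px.BiomarkerPanel(
                "q", values=dict(zip(features, map(float, row))))
            got = px.posterior(model, panel).probabilities
            for i, c in enumerate(px.CLASS_ORDER):
                assert got[c] == pytest.approx(sk[i], abs=1e-8)

    def test_missing_features_are_marginalised(self):
        params = {(c, f): (m, 1.0)
                  for f in ("mrpi", "swi_put")
                  for c, m in zip(px.CLASS_ORDER, (1.0, 2.0, 3.0))}
        model = px.model_from_marginals(params, ("mrpi", "swi_put"))
        full = px.posterior(model, px.BiomarkerPanel("p", values={"mrpi": 1.0}))
        single_params = {(c, "mrpi"): params[(c, "mrpi")] for c in px.CLASS_ORDER}
        single = px.posterior(
            px.model_from_marginals(single_params, ("mrpi",)),
            px.BiomarkerPanel("p", values={"mrpi": 1.0}))
        for c in px.CLASS_ORDER:
            assert full.probabilities[c] == pytest.approx(
                single.probabilities[c], abs=1e-12)

    def test_no_overlapping_features_raises(self, rng):
        model = random_model(rng)
        with pytest.raises(px.InferenceError):
            px.posterior(model, px.BiomarkerPanel("p", values={"fa_put": 400.0}))

    def test_affine_invariance(self, rng):
        """Rescaling one feature in both data and params leaves posteriors fixed."""
        features = ("mrpi", "swi_put")
        model = random_model(rng, features)
        panel = px.BiomarkerPanel("p", values={"mrpi": 1.5, "swi_put": 0.9})
        base = px.posterior(model, panel).probabilities
        a, b = 3.0, 7.0
        params2 = {(c, f): ((a * m + b, a * s) if f == "mrpi" else (m, s))
                   for (c, f), (m, s) in model.params.items()}
        model2 = px.model_from_marginals(params2, features, priors=model.priors)
        panel2 = px.BiomarkerPanel(
            "p", values={"mrpi": a * 1.5 + b, "swi_put": 0.9})
        got = px.posterior(model2, panel2).probabilities
        for c in px.CLASS_ORDER:
            assert got[c] == pytest.approx(base[c], abs=1e-9)


class TestFitting:
    def test_fitted_moments_and_empirical_priors(self, cohort73):
        model = px.fit_class_conditionals(cohort73, prior_mode="empirical")
        assert model.priors == {PD: 38 / 73, MSA: 25 / 73, PSP: 10 / 73}
        vals = np.array([p.values["mrpi"] for p in cohort73
                         if p.diagnosis == PSP])
        mean, sd = model.params[(PSP, "mrpi")]
        assert mean == pytest.approx(vals.mean(), rel=1e-12)
        assert sd == pytest.approx(vals.std(ddof=1), rel=1e-12)

    def test_degenerate_column_hits_sd_floor(self):
        panels = []
        for i in range(3):
            panels.append(px.BiomarkerPanel(f"psp{i}", PSP,
                                            values={"mrpi": 210.761}))
        for i, v in enumerate((140.0, 150.0, 160.0)):
            panels.append(px.BiomarkerPanel(f"pd{i}", PD, values={"mrpi": v}))
        for i, v in enumerate((130.0, 145.0, 155.0)):
            panels.append(px.BiomarkerPanel(f"msa{i}", MSA, values={"mrpi": v}))
        model = px.fit_class_conditionals(px.Cohort(panels), features=("mrpi",))
        mean, sd = model.params[(PSP, "mrpi")]
        assert mean == pytest.approx(210.761)
        assert 0 < sd < 1e-3  # floored at 1e-6 x pooled SD, not zero

    def test_too_few_values_raises_naming_class_and_feature(self):
        panels = [px.BiomarkerPanel("a", PD, values={"mrpi": 1.0}),
                  px.BiomarkerPanel("b", MSA, values={"mrpi": 1.5}),
                  px.BiomarkerPanel("c", MSA, values={"mrpi": 2.0}),
                  px.BiomarkerPanel("d", PSP, values={"mrpi": 2.5}),
                  px.BiomarkerPanel("e", PSP, values={"mrpi": 3.0})]
        with pytest.raises(px.FittingError, match="PD.*mrpi"):
            px.fit_class_conditionals(px.Cohort(panels), features=("mrpi",))

    def test_consistency_on_generator_output(self):
        n = 20_000
        spec = px.SyntheticCohortSpec(group_sizes={PD: n, MSA: n, PSP: n})
        cohort = px.simulate_cohort(spec, seed=2)
        model = px.fit_class_conditionals(cohort)
        for (c, f), (mean, sd) in model.params.items():
            true_mean, true_sd = px.PUBLISHED_MARGINALS[(c, f)]
            assert abs(mean - true_mean) < 4 * true_sd / math.sqrt(n), (c, f)


class TestModel1:
    def test_published_psp_mean_vector_classifies_as_psp(self):
        model = px.model_from_marginals(px.PUBLISHED_MARGINALS,
                                        px.DEFAULT_FEATURES)
        panel = px.BiomarkerPanel("p", values={
            f: px.PUBLISHED_MARGINALS[(PSP, f)][0] for f in px.DEFAULT_FEATURES})
        r = px.classify_model1(model, panel)
        assert r.predicted == PSP and r.model_id == "I"
        # independent check: brute-force densities at the same point
        want = brute_force_posterior(model, panel)
        assert max(want, key=want.get) == PSP

    def test_single_swi_put_feature_favors_pd(self):
        model = px.model_from_marginals(px.PUBLISHED_MARGINALS,
                                        px.DEFAULT_FEATURES)
        r = px.classify_model1(
            model, px.BiomarkerPanel("p", values={"swi_put": 0.925}))
        assert r.predicted == PD
        # density ratio at the PD class mean favours PD over MSA and PSP
        dens = {c: stats.norm.pdf(0.925, *px.PUBLISHED_MARGINALS[(c, "swi_put")])
                for c in px.CLASS_ORDER}
        assert max(dens, key=dens.get) == PD

    def test_equidistant_pd_msa_with_remote_psp(self):
        params = {(PD, "mrpi"): (100.0, 10.0), (MSA, "mrpi"): (120.0, 10.0),
                  (PSP, "mrpi"): (220.0, 10.0)}
        model = px.model_from_marginals(params, ("mrpi",))
        r = px.classify_model1(
            model, px.BiomarkerPanel("p", values={"mrpi": 110.0}))
        assert r.probabilities[PD] == pytest.approx(r.probabilities[MSA],
                                                    rel=1e-9)
        assert r.probabilities[PSP] < 1e-6


class TestModel2:
    @staticmethod
    def stage_models(rng=None, identical=False):
        if identical:
            p1 = {(c, "mrpi"): (150.0, 30.0) for c in (PSP, REST)}
            p2 = {(c, "swi_put"): (0.85, 0.1) for c in (MSA, PD)}
        else:
            rng = rng or np.random.default_rng(0)
            p1 = {(c, "mrpi"): (float(rng.uniform(100, 220)),
                                float(rng.uniform(10, 60)))
                  for c in (PSP, REST)}
            p2 = {(c, "swi_put"): (float(rng.uniform(0.6, 1.0)),
                                   float(rng.uniform(0.05, 0.3)))
                  for c in (MSA, PD)}
        s1 = px.model_from_marginals(p1, ("mrpi",), classes=(PSP, REST))
        s2 = px.model_from_marginals(p2, ("swi_put",), classes=(MSA, PD))
        return s1, s2

    def test_half_half_chains_to_quarter_quarter_half(self):
        s1, s2 = self.stage_models(identical=True)
        panel = px.BiomarkerPanel("p", values={"mrpi": 150.0, "swi_put": 0.85})
        r = px.classify_model2(s1, s2, panel)
        assert r.probabilities == pytest.approx(
            {PD: 0.25, MSA: 0.25, PSP: 0.5}, abs=1e-12)
        assert r.predicted == PSP and r.model_id == "II"

    def test_chain_rule_oracle_on_random_panels(self, rng):
        for i in range(100):
            s1, s2 = self.stage_models(rng)
            panel = px.BiomarkerPanel(
                f"p{i}", values={"mrpi": float(rng.uniform(80, 260)),
                                 "swi_put": float(rng.uniform(0.4, 1.2))})
            r = px.classify_model2(s1, s2, panel)
            assert sum(r.probabilities.values()) == pytest.approx(1.0,
                                                                  abs=1e-12)
            p1 = px.posterior(s1, panel).probabilities[PSP]
            p2 = px.posterior(s2, panel).probabilities[MSA]
            assert r.probabilities[PSP] == pytest.approx(p1, abs=1e-12)
            assert r.probabilities[MSA] == pytest.approx((1 - p1) * p2,
                                                         abs=1e-12)
            assert r.probabilities[PD] == pytest.approx((1 - p1) * (1 - p2),
                                                        abs=1e-12)

    def test_agrees_with_generic_posterior_on_single_stage_problem(self):
        """When stage 1 assigns PSP probability ~0, model II reduces to the
        MSA-vs-PD posterior of stage 2."""
        p1 = {(PSP, "mrpi"): (1000.0, 1.0), (REST, "mrpi"): (150.0, 1.0)}
        s1 = px.model_from_marginals(p1, ("mrpi",), classes=(PSP, REST))
        _, s2 = self.stage_models()
        panel = px.BiomarkerPanel("p", values={"mrpi": 150.0, "swi_put": 0.8})
        r = px.classify_model2(s1, s2, panel)
        direct = px.posterior(s2, panel).probabilities
        assert r.probabilities[MSA] == pytest.approx(direct[MSA], abs=1e-9)
        assert r.probabilities[PD] == pytest.approx(direct[PD], abs=1e-9)

    def test_fit_stages_from_cohort(self, cohort73):
        s1, s2 = px.fit_model2_stages(cohort73)
        assert set(s1.classes) == {PSP, REST}
        assert s1.features == px.ATROPHY_FEATURES
        assert set(s2.classes) == {MSA, PD}
        assert s2.features == px.DEFAULT_FEATURES
        r = px.classify_model2(s1, s2, cohort73.panels[0])
        assert sum(r.probabilities.values()) == pytest.approx(1.0, abs=1e-12)


class TestErrorRateClosedForm:
    def test_two_class_error_matches_normal_cdf(self, rng):
        """1-D equal-variance two-class error rate ~ Phi(-delta/(2 sigma))."""
        delta, sigma, n = 1.0, 1.0, 50_000
        params = {(PD, "fa_scp"): (0.0, sigma), (MSA, "fa_scp"): (delta, sigma)}
        model = px.model_from_marginals(params, ("fa_scp",), classes=(PD, MSA))
        # decision boundary at delta/2; error per class = Phi(-delta/(2 sigma))
        x_pd = rng.normal(0.0, sigma, n)
        x_msa = rng.normal(delta, sigma, n)
        errors = int((x_pd > delta / 2).sum() + (x_msa <= delta / 2).sum())
        # verify the package classifier implements that boundary
        for x in (delta / 2 - 0.1, delta / 2 + 0.1):
            r = px.posterior(model, px.BiomarkerPanel(
                "p", values={"fa_scp": float(x)}))
            assert r.predicted == (PD if x < delta / 2 else MSA)
        p = stats.norm.cdf(-delta / (2 * sigma))
        se = math.sqrt(p * (1 - p) / (2 * n))
        assert abs(errors / (2 * n) - p) < 3 * se


class TestClassifyCohort:
    def test_resubstitution_table_layout(self, cohort73):
        df = px.classify_cohort(cohort73, model_id="I")
        assert list(df.columns) == ["patient_id", "true", "MSA (%)", "PD (%)",
                                    "PSP (%)", "predicted", "model", "correct"]
        assert len(df) == 73
        assert (df["model"] == "I").all()
        pct = df[["MSA (%)", "PD (%)", "PSP (%)"]].to_numpy()
        assert np.allclose(pct.sum(axis=1), 100.0, atol=0.02)

    def test_leave_one_out_runs(self, cohort73):
        loo = px.classify_cohort(cohort73, model_id="I",
                                 protocol="leave_one_out")
        assert len(loo) == 73
        pct = loo[["MSA (%)", "PD (%)", "PSP (%)"]].to_numpy()
        assert np.allclose(pct.sum(axis=1), 100.0, atol=0.02)
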