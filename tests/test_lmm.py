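import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mpoct.stats.lmm import (ModelSpec, ModelSpecError, SingularDesignError,
                             design_matrix, fit_lmm)


def make_table(n_patients=10, n_per=8, seed=0, beta=(20.0, -3.5, 0.5),
               sd_re=1.5, sd_eps=2.0):
    """Direct linear-model data: intercept + device + ez covariate."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        u = rng.normal(0, sd_re)
        for j in range(n_per):
            dev = "MAIA" if j % 2 else "MP3"
            ez = rng.uniform(20, 40)
            y = (beta[0] + beta[1] * (dev == "MAIA") + beta[2] * ez
                 + u + rng.normal(0, sd_eps))
            rows.append(dict(patient_id=f"P{i}", device=dev, run=1 + j % 2,
                             point_id=j, eccentricity_deg=1.0, age=70.0,
                             ez_um=ez, onl_um=60.0, drusen_nl=0.0, sdd_nl=0.0,
                             hrf_nl=0.0, pws_db=y, included=True))
    return pd.DataFrame(rows)


def loglik_oracle(y, X, groups, reml=False):
    """Direct numerical maximization of the marginal Gaussian likelihood."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    labels, inv = np.unique(groups, return_inverse=True)
    Z = np.eye(len(labels))[inv]
    n, p = X.shape

    def nll(theta):
        s2_re, s2 = np.exp(theta)
        V = s2 * np.eye(n) + s2_re * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        beta = np.linalg.solve(XtVi @ X, XtVi @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + r @ Vi @ r)
        if reml:
            sign2, logdet2 = np.linalg.slogdet(XtVi @ X)
            ll += -0.5 * logdet2 + 0.5 * p * np.log(2 * np.pi)
        return -ll

    best = None
    for t0 in ([0.0, 0.0], [1.0, 0.5], [-1.0, 1.0]):
        res = minimize(nll, t0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


class TestFitLMM:
    def test_balanced_design_matches_ols(self):
        """Balanced within-patient design: GLS fixed effects equal OLS."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            u = rng.normal(0, 2.0)
            for x in (0.0, 0.0, 1.0, 1.0):  # identical design per patient
                rows.append(dict(patient_id=f"P{i}", device="MAIA" if x else "MP3",
                                 run=1, point_id=0, eccentricity_deg=0.0,
                                 age=70.0, ez_um=30.0, onl_um=60.0,
                                 drusen_nl=0.0, sdd_nl=0.0, hrf_nl=0.0,
                                 pws_db=20 - 3 * x + u + rng.normal(0, 1.5),
                                 included=True))
        t = pd.DataFrame(rows)
        spec = ModelSpec(mains=("device",), interactions=())
        fit = fit_lmm(t, spec)
        X = np.column_stack([np.ones(len(t)), (t.device == "MAIA").astype(float)])
        ols = np.linalg.lstsq(X, t.pws_db.to_numpy(), rcond=None)[0]
        assert fit.params["intercept"] == pytest.approx(ols[0], abs=1e-6)
        assert fit.params["device"] == pytest.approx(ols[1], abs=1e-6)

    def test_ml_loglik_matches_numerical_oracle(self):
        t = make_table(n_patients=8, n_per=6, seed=11)  # 48 records
        spec = ModelSpec(mains=("device", "ez"), interactions=())
        fit = fit_lmm(t, spec)
        X = design_matrix(t, spec)
        oracle = loglik_oracle(t.pws_db, X, t.patient_id, reml=False)
        assert fit.llf == pytest.approx(oracle, abs=1e-4)

    def test_reml_loglik_matches_numerical_oracle(self):
        t = make_table(n_patients=7, n_per=7, seed=13)
        spec = ModelSpec(mains=("device", "ez"), interactions=(), reml=True)
        fit = fit_lmm(t, spec)
        X = design_matrix(t, spec)
        oracle = loglik_oracle(t.pws_db, X, t.patient_id, reml=True)
        assert fit.llf == pytest.approx(oracle, abs=1e-3)

    def test_parameter_recovery(self):
        t = make_table(n_patients=40, n_per=40, seed=5)
        fit = fit_lmm(t, ModelSpec(mains=("device", "ez"), interactions=()))
        assert fit.params["device"] == pytest.approx(-3.5, abs=0.3)
        assert fit.params["ez"] == pytest.approx(0.5, abs=0.05)
        assert np.sqrt(fit.var_random) == pytest.approx(1.5, abs=0.6)
        assert np.sqrt(fit.var_resid) == pytest.approx(2.0, abs=0.2)

    def test_bic_definition(self):
        t = make_table()
        fit = fit_lmm(t, ModelSpec(mains=("device", "ez"), interactions=()))
        k = len(fit.params) + 2
        assert fit.bic == pytest.approx(-2 * fit.llf + k * np.log(fit.n_obs),
                                        abs=1e-9)
        assert fit.k_params == k

    def test_constant_covariate_is_singular(self):
        t = make_table()
        with pytest.raises(SingularDesignError):
            fit_lmm(t, ModelSpec(mains=("drusen",), interactions=()))

    def test_needs_two_patients(self):
        t = make_table(n_patients=1)
        with pytest.raises(ValueError):
            fit_lmm(t, ModelSpec(mains=("device",), interactions=()))

    def test_excluded_records_ignored(self):
        t = make_table()
        t2 = pd.concat([t, t.assign(included=False, pws_db=999.0)],
                       ignore_index=True)
        f1 = fit_lmm(t, ModelSpec(mains=("device",), interactions=()))
        f2 = fit_lmm(t2, ModelSpec(mains=("device",), interactions=()))
        assert f1.params["device"] == pytest.approx(f2.params["device"],
                                                    abs=1e-10)

    def test_wald_ci_width(self):
        t = make_table()
        fit = fit_lmm(t, ModelSpec(mains=("device", "ez"), interactions=()))
        half = 1.959963984540054 * fit.bse["device"]
        assert fit.conf_int.loc["device", "lower"] == pytest.approx(
            fit.params["device"] - half)
        assert fit.conf_int.loc["device", "upper"] == pytest.approx(
            fit.params["device"] + half)


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(mains=("onl",), interactions=(("eccentricity", "onl"),))

    def test_nonmarginal_allowed_with_flag(self):
        spec = ModelSpec(mains=("onl",),
                         interactions=(("eccentricity", "onl"),),
                         allow_nonmarginal=True)
        assert spec.term_names == ("onl", "eccentricity:onl")

    def test_unknown_terms_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(mains=("banana",), interactions=())
        with pytest.raises(ModelSpecError):
            ModelSpec(mains=("device", "run"), interactions=(("device", "run"),))

    def test_final_model_terms(self):
        spec = ModelSpec.final_model()
        assert set(spec.mains) == {"device", "onl", "ez", "drusen", "hrf"}
        assert set(spec.interactions) == {("eccentricity", "ez"),
                                          ("eccentricity", "onl")}

    def test_interaction_order_canonical(self):
        a = ModelSpec(mains=("eccentricity", "onl"),
                      interactions=(("onl", "eccentricity"),))
        assert a.interactions == (("eccentricity", "onl"),)


class TestReparameterization:
    def test_eccentricity_main_is_null_when_absent_from_truth(self, table20):
        """Adding the eccentricity main effect leaves the thickness
        interaction slopes essentially unchanged (the generator has no
        eccentricity main effect)."""
        f0 = fit_lmm(table20, ModelSpec.final_model(reml=True))
        f1 = fit_lmm(table20,
                     ModelSpec.final_model(reml=True, eccentricity_main=True))
        for term in ("eccentricity:onl", "eccentricity:ez"):
            assert f1.params[term] == pytest.approx(f0.params[term], abs=0.02)
        z = abs(f1.params["eccentricity"] / f1.bse["eccentricity"])
        assert z < 4.0


class TestCoverage:
    def test_wald_ci_coverage_over_replicates(self):
        """95% Wald CI coverage of every generating fixed effect stays in
        [88%, 100%] over 60 seeded direct-mode cohorts."""
        from mpoct.quantify.table import assemble_table
        from mpoct.synthgen.cohort import simulate_cohort
        truth = {"device": -3.553, "drusen": -0.632, "hrf": -9.535,
                 "onl": 0.016, "ez": 0.148,
                 "eccentricity:onl": 0.008, "eccentricity:ez": -0.025}
        cover = {k: 0 for k in truth}
        n_rep = 60
        for seed in range(500, 500 + n_rep):
            table = assemble_table(simulate_cohort(20, seed=seed))
            fit = fit_lmm(table, ModelSpec.final_model(reml=True))
            for k, v in truth.items():
                lo = fit.conf_int.loc[k, "lower"]
                hi = fit.conf_int.loc[k, "upper"]
                cover[k] += lo <= v <= hi
        for k, c in cover.items():
            assert 0.88 <= c / n_rep <= 1.0, (k, c / n_rep)
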