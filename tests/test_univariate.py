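"""EMS denominator logic, exact balanced ANOVA, Cochran's C."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from estubenthos.core_data import SurveyDesign, density_per_sample
from estubenthos.published import (
    MACROFAUNA_ANOVA_MS,
    MACROFAUNA_DENSITY_F,
    MACROFAUNA_DF,
    PERMANOVA_MS,
    PERMANOVA_PSEUDO_F,
    SEDIMENT_ANOVA_MS,
    SEDIMENT_GRAIN_F,
)
from estubenthos.simulate import simulate_survey, null_config, SimulationConfig, TaxonProfile
from estubenthos.univariate import (
    Factor,
    ModelSpec,
    UnbalancedDesignError,
    cochran_c,
    core_model_spec,
    effect_projectors,
    ems_denominators,
    expected_mean_squares,
    f_ratios_from_mean_squares,
    nested_anova,
    variance_components,
)


class TestEmsDenominators:
    def test_core_design_map(self, design):
        assert ems_denominators(core_model_spec(design)) == {
            "H": "H × E",
            "E": "S(E)",
            "H × E": "H × S(E)",
            "S(E)": "P(S(E))",
            "H × S(E)": "H × P(S(E))",
            "P(S(E))": "Residual",
            "H × P(S(E))": "Residual",
        }

    def test_plot_design_map(self, design):
        from estubenthos.univariate import plot_model_spec

        assert ems_denominators(plot_model_spec(design)) == {
            "H": "H × E",
            "E": "S(E)",
            "H × E": "H × S(E)",
            "S(E)": "Residual",
            "H × S(E)": "Residual",
        }

    def test_one_way_fixed_limit(self):
        spec = ModelSpec(factors=(Factor("treat", 4, random=False),), n_replicates=5)
        assert ems_denominators(spec) == {"treat": "Residual"}

    def test_published_density_f_reproduced_to_printed_precision(self, design):
        got = f_ratios_from_mean_squares(
            MACROFAUNA_ANOVA_MS["density"], core_model_spec(design)
        )
        for term, F in zip(got["term"], got["F"]):
            assert F == pytest.approx(MACROFAUNA_DENSITY_F[term], abs=5e-4), term

    def test_published_sediment_grain_f_reproduced(self, design):
        from estubenthos.univariate import plot_model_spec

        got = f_ratios_from_mean_squares(
            SEDIMENT_ANOVA_MS["grain_phi"], plot_model_spec(design)
        )
        for term, F in zip(got["term"], got["F"]):
            # the published sediment table rounds MS to 2 decimals, so
            # ratios are only reproducible to ~1% (e.g. 1.47/0.24)
            assert F == pytest.approx(SEDIMENT_GRAIN_F[term], rel=0.02), term

    def test_published_pseudo_f_reproduced(self, design):
        got = f_ratios_from_mean_squares(PERMANOVA_MS, core_model_spec(design))
        for term, F in zip(got["term"], got["F"]):
            # the published MS carry 5 significant digits, so the ratios
            # are reproducible to ~1e-3 on top of the printed 3 decimals
            assert F == pytest.approx(PERMANOVA_PSEUDO_F[term], abs=1.5e-3), term

    def test_ems_of_term_contains_own_component_with_full_coefficient(self, design):
        spec = core_model_spec(design)
        ems = expected_mean_squares(spec)
        assert ems["E"]["E"] == 36          # h*s*p*r
        assert ems["S(E)"]["S(E)"] == 18    # h*p*r
        assert ems["Residual"] == {"Residual": 1}


def _survey_response(design, seed, sd_site=0.0, sd_plot=0.0, mean=50.0):
    config = SimulationConfig(
        design=design,
        taxa=(TaxonProfile("Taxon01", mean, mean),),
        seed=seed,
        sd_site=sd_site,
        sd_plot=sd_plot,
    )
    faunal, _, truth = simulate_survey(config)
    dens = density_per_sample(faunal, design)
    dens["y"] = np.log1p(dens["density"])
    return dens, truth


class TestNestedAnova:
    def test_ss_decomposition_and_df_bookkeeping(self, design):
        data, _ = _survey_response(design, seed=11, sd_site=0.4, sd_plot=0.3)
        res = nested_anova(data, core_model_spec(design, response="y"))
        tab = res.table
        assert dict(zip(tab["term"], tab["df"])) == MACROFAUNA_DF
        assert tab["df"].sum() == design.n_cores - 1
        total_ss = ((data["y"] - data["y"].mean()) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(total_ss, rel=1e-10)
        assert (tab["SS"] >= -1e-12).all()

    def test_projectors_are_orthogonal_idempotent(self, small_design):
        data, _ = _survey_response(small_design, seed=3)
        projs = effect_projectors(data, core_model_spec(small_design, response="y"))
        names = list(projs)
        for i, a in enumerate(names):
            P = projs[a][0]
            assert np.allclose(P @ P, P, atol=1e-10)
            for b in names[i + 1:]:
                assert np.allclose(P @ projs[b][0], 0, atol=1e-10)

    def test_matches_first_principles_oracle_on_small_design(self, small_design):
        """Classical closed-form nested/crossed mean formulas, written
        independently of the projector engine, give identical SS."""
        rng = np.random.default_rng(42)
        data = small_design.sample_keys()
        data["y"] = rng.normal(size=len(data))
        res = nested_anova(data, core_model_spec(small_design, response="y"))
        ss = dict(zip(res.table["term"], res.table["SS"]))

        g = data["y"].mean()
        m = {}
        for cols in (["habitat"], ["estuary"], ["estuary", "site"],
                     ["habitat", "estuary"], ["habitat", "estuary", "site"],
                     ["estuary", "site", "plot"],
                     ["habitat", "estuary", "site", "plot"]):
            m[tuple(cols)] = data.groupby(cols, observed=True)["y"].mean()

        def dev2(means):
            return (means ** 2).sum()

        n = len(data)
        h, e, s, p, r = 2, 2, 2, 2, 2
        ss_H = e * s * p * r * ((m[("habitat",)] - g) ** 2).sum()
        ss_E = h * s * p * r * ((m[("estuary",)] - g) ** 2).sum()
        ss_S = h * p * r * ((m[("estuary", "site")]
                             - m[("estuary",)]) ** 2).sum()
        he = m[("habitat", "estuary")].copy()
        for (hh, ee), v in he.items():
            he.loc[(hh, ee)] = v - m[("habitat",)][hh] - m[("estuary",)][ee] + g
        ss_HE = s * p * r * dev2(he)
        hes = m[("habitat", "estuary", "site")].copy()
        for (hh, ee, ssx), v in hes.items():
            hes.loc[(hh, ee, ssx)] = (
                v - m[("estuary", "site")][(ee, ssx)]
                - m[("habitat", "estuary")][(hh, ee)] + m[("estuary",)][ee]
            )
        ss_HS = p * r * dev2(hes)
        esp = m[("estuary", "site", "plot")].copy()
        for (ee, ssx, pp), v in esp.items():
            esp.loc[(ee, ssx, pp)] = v - m[("estuary", "site")][(ee, ssx)]
        ss_P = h * r * dev2(esp)
        hesp = m[("habitat", "estuary", "site", "plot")].copy()
        for (hh, ee, ssx, pp), v in hesp.items():
            hesp.loc[(hh, ee, ssx, pp)] = (
                v - m[("estuary", "site", "plot")][(ee, ssx, pp)]
                - m[("habitat", "estuary", "site")][(hh, ee, ssx)]
                + m[("estuary", "site")][(ee, ssx)]
            )
        ss_HP = r * dev2(hesp)

        assert ss["H"] == pytest.approx(ss_H, rel=1e-9)
        assert ss["E"] == pytest.approx(ss_E, rel=1e-9)
        assert ss["S(E)"] == pytest.approx(ss_S, rel=1e-9)
        assert ss["H × E"] == pytest.approx(ss_HE, rel=1e-9)
        assert ss["H × S(E)"] == pytest.approx(ss_HS, rel=1e-9)
        assert ss["P(S(E))"] == pytest.approx(ss_P, rel=1e-9)
        assert ss["H × P(S(E))"] == pytest.approx(ss_HP, rel=1e-9)

    def test_constant_response_reports_missing_f(self, small_design):
        data = small_design.sample_keys()
        data["y"] = 7.0
        res = nested_anova(data, core_model_spec(small_design, response="y"))
        assert np.allclose(res.table["SS"], 0, atol=1e-18)
        assert res.table["F"].isna().all()

    def test_unbalanced_input_rejected(self, small_design):
        data = small_design.sample_keys().iloc[:-1].copy()
        data["y"] = 1.0
        with pytest.raises(UnbalancedDesignError, match="validate_design"):
            nested_anova(data, core_model_spec(small_design, response="y"))

    def test_type_i_error_calibrated_on_null_normals(self, design):
        """Independent standard-normal responses: each term rejects at
        about the nominal 5% (vectorized over 2000 replicate surveys)."""
        spec = core_model_spec(design, response="y")
        data = design.sample_keys()
        data["y"] = 0.0
        projs = effect_projectors(data, spec)
        denom = ems_denominators(spec)
        rng = np.random.default_rng(2024)
        B = 2000
        Y = rng.normal(size=(B, design.n_cores))
        ss = {t: np.einsum("bi,ij,bj->b", Y, P, Y) for t, (P, _) in projs.items()}
        df = {t: d for t, (_, d) in projs.items()}
        band = 3 * np.sqrt(0.05 * 0.95 / B)
        for term, d_name in denom.items():
            F = (ss[term] / df[term]) / (ss[d_name] / df[d_name])
            crit = stats.f.isf(0.05, df[term], df[d_name])
            rate = np.mean(F > crit)
            assert abs(rate - 0.05) < band, (term, rate)

    def test_variance_components_recovered_from_ground_truth(self, design):
        """EMS method-of-moments estimates of the site and plot log-scale
        variance components are unbiased over repeated surveys."""
        sd_site, sd_plot = 0.4, 0.3
        spec = core_model_spec(design, response="y")
        keys = design.sample_keys()
        projs = effect_projectors(keys.assign(y=0.0), spec)
        n_sims = 120
        est_site, est_plot = [], []
        for i in range(n_sims):
            data, _ = _survey_response(
                design, seed=10_000 + i, sd_site=sd_site, sd_plot=sd_plot, mean=400.0
            )
            res = nested_anova(data, spec)
            vc = variance_components(res).set_index("term")["component"]
            est_site.append(vc["S(E)"])
            est_plot.append(vc["P(S(E))"])
        for est, truth in [(est_site, sd_site ** 2), (est_plot, sd_plot ** 2)]:
            mean = np.mean(est)
            se = np.std(est, ddof=1) / np.sqrt(n_sims)
            assert abs(mean - truth) < 3.5 * se + 0.02 * truth, (mean, truth, se)


class TestCochran:
    def test_equal_variances_give_1_over_k(self):
        groups = [[0.0, 1.0, 2.0], [5.0, 6.0, 7.0], [1.0, 2.0, 3.0], [9.0, 10.0, 11.0]]
        res = cochran_c(groups)
        assert res.C == pytest.approx(0.25)
        assert not res.heterogeneous

    def test_all_variance_in_one_group_gives_1(self):
        res = cochran_c([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 5.0, 10.0]])
        assert res.C == pytest.approx(1.0)
        assert res.heterogeneous

    def test_unequal_replication_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            cochran_c([[1.0, 2.0], [1.0, 2.0, 3.0]])

    def test_null_rejection_rate_near_alpha(self):
        """k = 4 groups of n = 3 equal-variance normals: the Beta
        union-bound p-value rejects at ~5% over 10,000 trials."""
        from scipy.optimize import brentq
        from scipy.stats import beta

        k, nu = 4, 2
        crit = brentq(lambda c: k * beta.sf(c, nu / 2, (k - 1) * nu / 2) - 0.05,
                      1 / k + 1e-9, 1 - 1e-9)
        rng = np.random.default_rng(7)
        trials = 10_000
        variances = rng.chisquare(nu, size=(trials, k)) / nu
        C = variances.max(axis=1) / variances.sum(axis=1)
        rate = np.mean(C > crit)
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / trials)
        # and the vectorized critical region agrees with cochran_c itself
        sample = rng.normal(size=(200, k, 3))
        direct = np.array(
            [cochran_c(list(s)).heterogeneous for s in sample]
        )
        cvals = np.array([cochran_c(list(s)).C for s in sample])
        assert np.array_equal(direct, cvals > crit)
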