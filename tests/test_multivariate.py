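"""Bray-Curtis, PERMANOVA, nMDS, SIMPER, CCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from estubenthos.core_data import community_matrix
from estubenthos.multivariate import (
    bray_curtis,
    cca,
    gower_center,
    nmds,
    permanova,
    simper,
    top_taxa,
    _smacof_nonmetric,
)
from estubenthos.simulate import null_dataset, field_survey_preset, simulate_survey
from estubenthos.univariate import core_model_spec, ems_denominators, nested_anova


class TestBrayCurtis:
    def test_hand_computed_example(self):
        m = pd.DataFrame([[4.0, 0.0], [1.0, 1.0]], columns=["a", "b"])
        d = bray_curtis(m, transform="sqrt")
        # sqrt rows (2,0) and (1,1): 1 - 2*min_sum/total = 0.5
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint_rows(self):
        m = pd.DataFrame([[3.0, 2.0], [3.0, 2.0], [0.0, 5.0], [4.0, 0.0]])
        d = bray_curtis(m, transform="none")
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[2, 3] == 1.0

    def test_bounds_symmetry_zero_diagonal_and_zero_taxon_invariance(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        d = bray_curtis(cm)
        a = d.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 0)
        assert (a >= 0).all() and (a <= 1 + 1e-12).all()
        padded = cm.copy()
        padded["Ghost taxon"] = 0.0
        assert np.allclose(bray_curtis(padded).to_numpy(), a)

    def test_all_zero_rows_dropped_with_warning(self):
        m = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(m)
        assert d.shape == (2, 2)
        assert d.attrs["dropped_rows"] == [1]


class TestPermanova:
    def test_euclidean_pseudo_f_equals_anova_f_on_every_term(self, small_design):
        rng = np.random.default_rng(5)
        data = small_design.sample_keys()
        data["y"] = rng.normal(size=len(data))
        spec = core_model_spec(small_design, response="y")
        uni = nested_anova(data, spec)
        D = pd.DataFrame(squareform(pdist(data[["y"]].to_numpy())))
        perm = permanova(D, data, spec, n_perm=0)
        f_uni = dict(zip(uni.table["term"], uni.table["F"]))
        for term, F in zip(perm.table["term"], perm.table["pseudo_F"]):
            if term == "Residual":
                continue
            assert F == pytest.approx(f_uni[term], rel=1e-9), term

    def test_ss_partition_sums_to_total(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        d = bray_curtis(cm)
        res = permanova(d, config.design.sample_keys(), core_model_spec(config.design),
                        n_perm=0)
        total = np.trace(gower_center(d.to_numpy()))
        assert res.table["SS"].sum() == pytest.approx(total, rel=1e-10)

    def test_seed_required_and_deterministic(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        d = bray_curtis(cm)
        spec = core_model_spec(config.design)
        keys = config.design.sample_keys()
        with pytest.raises(ValueError, match="seed"):
            permanova(d, keys, spec, n_perm=9)
        a = permanova(d, keys, spec, n_perm=49, seed=3).table
        b = permanova(d, keys, spec, n_perm=49, seed=3).table
        pd.testing.assert_frame_equal(a, b)

    def test_type_i_error_calibrated_under_null(self, small_design):
        """Structureless communities: permutation p-values reject at about
        the nominal rate for spatial terms and habitat."""
        trials, n_perm = 250, 99
        hits = {"H": 0, "E": 0, "S(E)": 0, "P(S(E))": 0}
        spec = core_model_spec(small_design)
        keys = small_design.sample_keys()
        for i in range(trials):
            faunal, _, _ = null_dataset(small_design, seed=40_000 + i)
            cm = community_matrix(faunal, small_design)
            d = bray_curtis(cm)
            res = permanova(d, keys, spec, n_perm=n_perm, seed=i)
            p = dict(zip(res.table["term"], res.table["p_perm"]))
            for term in hits:
                hits[term] += p[term] <= 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / trials)
        for term, h in hits.items():
            assert abs(h / trials - 0.05) <= band, (term, h / trials)


class TestNmds:
    def test_three_equidistant_points_embed_perfectly(self):
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        res = nmds(d, n_starts=3, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-8)
        dist = pdist(res.coordinates.to_numpy())
        assert np.allclose(dist, dist[0], rtol=1e-4)

    def test_exact_2d_euclidean_distances_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        d = pd.DataFrame(squareform(pdist(X)))
        res = nmds(d, n_starts=4, seed=2)
        assert res.stress < 1e-3
        assert res.converged

    def test_stress_non_increasing_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.normal(size=(12, 4))
            delta = pdist(X)
            start = rng.normal(size=(12, 2))
            _, _, _, history = _smacof_nonmetric(delta, start, max_iter=200, tol=0.0)
            diffs = np.diff(history)
            assert (diffs <= 1e-9).all()

    def test_coordinates_centred_and_seed_reproducible(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        d = bray_curtis(cm)
        a = nmds(d, n_starts=2, seed=11)
        b = nmds(d, n_starts=2, seed=11)
        assert np.allclose(a.coordinates.mean(axis=0), 0, atol=1e-9)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)


class TestSimper:
    def test_contributions_sum_to_average_between_group_dissimilarity(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        grouping = [idx[2] for idx in cm.index]   # habitat
        tab = simper(cm, grouping)
        for (_, _), sub in tab.groupby(["group_a", "group_b"], observed=True):
            assert sub["contribution"].sum() == pytest.approx(
                sub["average_dissimilarity"].iloc[0], rel=1e-10
            )
            assert (sub["contribution"] >= 0).all()
            assert sub["cum_pct"].iloc[-1] == pytest.approx(100.0)

    def test_single_taxon_contributes_100_percent(self):
        m = pd.DataFrame({"only": [5.0, 9.0, 1.0, 2.0]})
        tab = simper(m, ["a", "a", "b", "b"])
        assert tab["contribution_pct"].iloc[0] == pytest.approx(100.0)

    def test_matches_pair_by_pair_brute_force(self):
        m = pd.DataFrame(
            [[4.0, 0.0, 1.0], [2.0, 2.0, 0.0], [0.0, 3.0, 3.0], [1.0, 1.0, 4.0]],
            columns=["t1", "t2", "t3"],
        )
        groups = ["g1", "g1", "g2", "g2"]
        tab = simper(m, groups, transform="none").set_index("taxon")
        X = m.to_numpy()
        expected = np.zeros(3)
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        for i, j in pairs:
            denom = (X[i] + X[j]).sum()
            expected += np.abs(X[i] - X[j]) / denom
        expected /= len(pairs)
        for k, name in enumerate(m.columns):
            assert tab.loc[name, "contribution"] == pytest.approx(expected[k], rel=1e-12)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            simper(pd.DataFrame({"a": [1.0, 2.0]}), ["x", "x"])


def _plot_level_data(preset_survey):
    config, faunal, sediment, _ = preset_survey
    cm = community_matrix(faunal, config.design, level="plot")
    Z = sediment.set_index(["estuary", "site", "habitat", "plot"])[
        ["tom_pct", "chla", "mud_pct", "plant_biomass"]
    ].reindex(cm.index)
    return cm, Z


class TestCca:
    def test_single_covariate_yields_single_axis(self, preset_survey):
        cm, Z = _plot_level_data(preset_survey)
        res = cca(cm[top_taxa(cm, 5)], Z[["tom_pct"]])
        assert len(res.eigenvalues) == 1

    def test_inertia_conservation_against_chi_square(self, preset_survey):
        """Total inertia = chi-square statistic / grand total, and the
        constrained part never exceeds it; with as many independent
        covariates as rank, constrained equals total."""
        from scipy.stats import chi2_contingency

        cm, Z = _plot_level_data(preset_survey)
        Y = cm[top_taxa(cm, 5)]
        res = cca(Y, Z)
        chi2 = chi2_contingency(Y.to_numpy())[0]
        assert res.total_inertia == pytest.approx(chi2 / Y.to_numpy().sum(), rel=1e-10)
        assert res.constrained_inertia <= res.total_inertia + 1e-12
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.proportion_total.sum() <= 1 + 1e-12
        assert np.allclose(res.proportion_constrained.sum(), 1.0)

    def test_eigenvalues_match_reference_implementation(self, preset_survey):
        """Cross-check against the independent CCA in scikit-bio."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        cm, Z = _plot_level_data(preset_survey)
        Y = cm[top_taxa(cm, 5)]
        Y2 = Y.copy()
        Y2.index = ["-".join(i) for i in Y2.index]
        Z2 = Z.copy()
        Z2.index = Y2.index
        ref = skbio_ord.cca(Y2, Z2)
        k = len((res := cca(Y, Z)).eigenvalues)
        assert np.allclose(res.eigenvalues, ref.eigvals.to_numpy()[:k], rtol=1e-6)

    def test_collinear_covariate_dropped_with_warning(self, preset_survey):
        cm, Z = _plot_level_data(preset_survey)
        Z2 = Z.copy()
        Z2["tom_twice"] = 2.0 * Z2["tom_pct"]
        with pytest.warns(UserWarning, match="collinear"):
            res = cca(cm[top_taxa(cm, 5)], Z2)
        assert res.dropped_covariates == ["tom_twice"]

    def test_unrelated_covariates_explain_about_the_permutation_null(self, preset_survey):
        """Covariates orthogonal to community structure: the constrained
        inertia fraction sits inside the row-permutation null distribution."""
        cm, Z = _plot_level_data(preset_survey)
        Y = cm[top_taxa(cm, 5)]
        rng = np.random.default_rng(17)
        noise = pd.DataFrame(
            rng.normal(size=(len(Y), 3)), index=Y.index, columns=["n1", "n2", "n3"]
        )
        frac = cca(Y, noise).constrained_inertia / cca(Y, noise).total_inertia
        null = []
        for _ in range(200):
            perm = noise.sample(frac=1.0, random_state=rng.integers(2**31)).to_numpy()
            shuffled = pd.DataFrame(perm, index=Y.index, columns=noise.columns)
            r = cca(Y, shuffled)
            null.append(r.constrained_inertia / r.total_inertia)
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= frac <= hi

    def test_top_taxa_selection_by_summed_density(self, preset_survey):
        config, faunal, _, _ = preset_survey
        cm = community_matrix(faunal, config.design)
        taxa = top_taxa(cm, 5)
        totals = cm.sum(axis=0).sort_values(ascending=False)
        assert set(taxa) == set(totals.index[:5])
        # the dominant five comprise over 90% of total density here
        assert totals[taxa].sum() / totals.sum() > 0.9
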