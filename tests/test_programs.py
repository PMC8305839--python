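import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabotype.containers import AnnotationTable
from metabotype.preprocess import run_preprocess
from metabotype.programs import (
    CorrelationNetwork,
    adjacency,
    detect_modules,
    eigen_metabolite,
    fit_programs,
    hub_metabolites,
    kme,
    merge_modules,
    module_enrichment,
    module_trait_cor,
    pick_power,
    scale_free_fit,
    significant_modules,
    tom,
)
from metabotype.synth import CohortConfig, generate_cohort


def block_data(rng, n_samples=120, blocks=((10, 1.0), (8, 1.0)), noise=0.4):
    """Samples x metabolites with independent latent factors per block."""
    cols = {}
    idx = 0
    for size, scale in blocks:
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            cols[f"m{idx}"] = scale * f + noise * rng.standard_normal(n_samples)
            idx += 1
    X = pd.DataFrame(cols)
    return (X - X.mean()) / X.std(ddof=1)


def net_from_matrix(A):
    ids = [f"m{i}" for i in range(A.shape[0])]
    return CorrelationNetwork(pd.DataFrame(A, index=ids, columns=ids), beta=1.0, fit_r2=0.0)


class TestAdjacency:
    def test_signed_endpoints(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x, "c": -x})
        net = adjacency(X, beta=3)
        A = net.adjacency
        assert A.loc["a", "b"] == pytest.approx(1.0)
        assert A.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(A), 0.0)

    def test_uncorrelated_midpoint_at_beta_one(self, rng):
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        net = adjacency(pd.DataFrame({"a": x, "b": y}), beta=1)
        assert net.adjacency.loc["a", "b"] == pytest.approx(0.5, abs=0.05)

    def test_symmetry_and_range_on_random_data(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 15)))
        for signed in (True, False):
            A = adjacency(X, beta=6, signed=signed).adjacency.to_numpy()
            assert np.allclose(A, A.T)
            assert A.min() >= 0 and A.max() <= 1

    def test_beta_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame(rng.standard_normal((30, 4))), beta=0.5)


class TestPickPower:
    def test_zero_target_accepts_first_power(self, rng):
        X = block_data(rng)
        beta, r2 = pick_power(X, target_r2=0.0)
        assert beta == 1
        assert r2 >= 0.0

    def test_returned_fit_matches_recomputation(self, rng):
        X = block_data(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, r2 = pick_power(X, target_r2=0.5)
        net = adjacency(X, beta)
        k = net.adjacency.sum(axis=0).to_numpy()
        assert r2 == pytest.approx(scale_free_fit(k), abs=1e-12)

    def test_constant_data_rejected(self):
        X = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        with pytest.raises(ValueError):
            pick_power(X)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pick_power(pd.DataFrame(rng.standard_normal((10, 5))))


class TestTOM:
    def test_complete_graph_gives_all_ones(self):
        A = np.ones((5, 5))
        np.fill_diagonal(A, 0.0)
        T = tom(net_from_matrix(A)).to_numpy()
        assert np.allclose(T, 1.0)

    def test_empty_graph_gives_zero_overlap(self):
        T = tom(net_from_matrix(np.zeros((4, 4)))).to_numpy()
        assert np.allclose(T - np.eye(4), 0.0)

    def test_four_node_hand_example(self):
        A = np.array(
            [
                [0.0, 0.8, 0.3, 0.0],
                [0.8, 0.0, 0.5, 0.2],
                [0.3, 0.5, 0.0, 0.6],
                [0.0, 0.2, 0.6, 0.0],
            ]
        )
        T = tom(net_from_matrix(A)).to_numpy()
        k = A.sum(axis=0)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(4))
                expected = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_range(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        T = tom(net_from_matrix(A)).to_numpy()
        assert np.allclose(T, T.T)
        assert T.min() >= 0 and T.max() <= 1


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X = block_data(rng, blocks=((10, 1.0), (8, 1.0)))
        T = tom(adjacency(X, 12))
        modules = detect_modules(T)
        truth = [1] * 10 + [2] * 8
        assert len(modules.module_ids()) == 2
        assert adjusted_rand_score(truth, modules.assignment) >= 0.8

    def test_min_size_larger_than_panel_sends_all_grey(self, rng):
        X = block_data(rng, blocks=((6, 1.0),))
        T = tom(adjacency(X, 6))
        with pytest.warns(UserWarning, match="grey"):
            modules = detect_modules(T, min_size=10)
        assert (modules.assignment == 0).all()

    def test_isolated_metabolites_fall_into_grey(self, rng):
        X = block_data(rng, blocks=((8, 1.0),))
        for i in range(3):
            X[f"iso{i}"] = rng.standard_normal(len(X))
        T = tom(adjacency(X, 12))
        modules = detect_modules(T, min_size=5)
        assert set(modules.assignment[[f"iso{i}" for i in range(3)]]) == {0}


class TestEigenAndKME:
    def test_identical_profiles_yield_that_profile(self, rng):
        x = rng.standard_normal(80)
        z = (x - x.mean()) / x.std(ddof=1)
        X = pd.DataFrame({"a": z, "b": z, "c": z})
        assignment = pd.Series({"a": 1, "b": 1, "c": 1})
        eig = eigen_metabolite(X, assignment)
        assert np.allclose(np.abs(np.corrcoef(eig[1], z)[0, 1]), 1.0)
        assert np.corrcoef(eig[1], z)[0, 1] > 0  # sign-oriented

    def test_pc1_explains_at_least_any_single_member(self, rng):
        X = block_data(rng, blocks=((6, 1.0),), noise=0.8)
        assignment = pd.Series(1, index=X.columns)
        eig = eigen_metabolite(X, assignment)
        K = kme(X, eig)
        # mean squared correlation with PC1 >= with any single member
        pc1_r2 = (K[1] ** 2).mean()
        for m in X.columns:
            member_r2 = np.mean(
                [np.corrcoef(X[m], X[o])[0, 1] ** 2 for o in X.columns]
            )
            assert pc1_r2 >= member_r2 - 1e-9

    def test_mean_kme_of_members_nonnegative(self, rng):
        X = block_data(rng, blocks=((7, 1.0), (5, 1.0)))
        assignment = pd.Series([1] * 7 + [2] * 5, index=X.columns)
        eig = eigen_metabolite(X, assignment)
        K = kme(X, eig)
        for mod in (1, 2):
            members = assignment.index[assignment == mod]
            assert K.loc[members, mod].mean() >= 0

    def test_kme_of_eigen_with_itself_is_one(self, rng):
        X = block_data(rng, blocks=((5, 1.0),))
        assignment = pd.Series(1, index=X.columns)
        eig = eigen_metabolite(X, assignment)
        Xe = X.copy()
        Xe["eig"] = eig[1]
        K = kme(Xe, eig)
        assert K.loc["eig", 1] == pytest.approx(1.0, abs=1e-12)
        assert K.to_numpy().min() >= -1 and K.to_numpy().max() <= 1

    def test_single_metabolite_module(self, rng):
        X = block_data(rng, blocks=((4, 1.0),))
        X["solo"] = rng.standard_normal(len(X))
        assignment = pd.Series([1] * 4 + [2], index=X.columns)
        eig = eigen_metabolite(X, assignment)
        r = np.corrcoef(eig[2], X["solo"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


class TestMerge:
    def _two_correlated_modules(self, rng, mix=0.95):
        n = 150
        f = rng.standard_normal(n)
        g = mix * f + math.sqrt(max(1 - mix**2, 0)) * rng.standard_normal(n)
        cols = {}
        for i in range(6):
            cols[f"a{i}"] = f + 0.3 * rng.standard_normal(n)
        for i in range(6):
            cols[f"b{i}"] = g + 0.3 * rng.standard_normal(n)
        X = pd.DataFrame(cols)
        X = (X - X.mean()) / X.std(ddof=1)
        assignment = pd.Series([1] * 6 + [2] * 6, index=X.columns)
        from metabotype.programs import ModuleSet

        return X, ModuleSet(assignment=assignment)

    def test_highly_correlated_eigens_merge(self, rng):
        X, modules = self._two_correlated_modules(rng, mix=0.95)
        merged = merge_modules(modules, X)
        assert len(merged.module_ids()) == 1
        assert merged.merged_from[1] == (1, 2)

    def test_weakly_correlated_eigens_stay_separate(self, rng):
        X, modules = self._two_correlated_modules(rng, mix=0.3)
        merged = merge_modules(modules, X)
        assert len(merged.module_ids()) == 2

    def test_merge_idempotent(self, rng):
        X, modules = self._two_correlated_modules(rng, mix=0.95)
        once = merge_modules(modules, X)
        twice = merge_modules(once, X)
        assert (once.assignment == twice.assignment).all()

    def test_seven_planted_blocks_give_seven_programs(self):
        cfg = CohortConfig(n_blocks=7, effect_size=0.0, seed=3).scaled(200)
        coh = generate_cohort(cfg)
        X = run_preprocess(coh.study, coh.calibrant_concentrations).patient_values()
        modules, _ = fit_programs(X)
        assert len(modules.module_ids()) == 7


class TestTraitCorrelation:
    def test_indicator_eigen_correlates_perfectly(self):
        labels = pd.Series([1] * 10 + [2] * 20, index=[f"s{i}" for i in range(30)])
        ind = (labels == 1).astype(float)
        eigen = pd.DataFrame({1: (ind - ind.mean()) / ind.std(ddof=1)})
        tc = module_trait_cor(eigen, labels)
        assert tc.r.loc[1, 1] == pytest.approx(1.0)
        assert tc.p.loc[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_pearsonr_closed_form(self, rng):
        labels = pd.Series(rng.integers(1, 4, size=60), index=[f"s{i}" for i in range(60)])
        eigen = pd.DataFrame({1: rng.standard_normal(60)}, index=labels.index)
        tc = module_trait_cor(eigen, labels)
        for s in sorted(labels.unique()):
            r_ref, p_ref = stats.pearsonr(eigen[1], (labels == s).astype(float))
            assert tc.r.loc[1, s] == pytest.approx(r_ref, abs=1e-12)
            assert tc.p.loc[1, s] == pytest.approx(p_ref, abs=1e-12)

    def test_planted_subtypes_have_correlated_program(self, planted_cohort):
        """Every subtype associates significantly with some program; the
        sphingolipid-coherent subtypes (2: gain, 3: loss) associate
        strongly.  Subtype 1's mixed TAG-up/CER-down signature only
        guarantees significance, not a large |r|, once TAG co-varies with
        the sphingolipid program."""
        coh = planted_cohort
        X = run_preprocess(coh.study, coh.calibrant_concentrations).patient_values()
        labels = coh.truth_labels.loc[X.index]
        modules, _ = fit_programs(X, labels=labels)
        tc = modules.trait_cor
        for s in (1, 2, 3):
            assert (tc.p[s] < 0.05).any()
        for s in (2, 3):
            assert ((tc.r[s].abs() > 0.5) & (tc.p[s] < 0.05)).any()


class TestHubs:
    def test_top_hub_is_max_kme_by_scan(self, rng):
        X = block_data(rng, blocks=((8, 1.0),))
        assignment = pd.Series(1, index=X.columns)
        eig = eigen_metabolite(X, assignment)
        K = kme(X, eig)
        hubs = hub_metabolites(K, assignment, n=1)
        assert hubs[1] == [K[1].idxmax()]

    def test_small_module_returns_all_members_in_order(self, rng):
        X = block_data(rng, blocks=((4, 1.0),))
        assignment = pd.Series(1, index=X.columns)
        eig = eigen_metabolite(X, assignment)
        K = kme(X, eig)
        hubs = hub_metabolites(K, assignment, n=10)
        assert hubs[1] == list(K[1].sort_values(ascending=False).index)


class TestEnrichment:
    def _annotation(self, pathways_by_met):
        mets = list(pathways_by_met)
        table = pd.DataFrame(
            {
                "class": ["complex lipids and fatty acids"] * len(mets),
                "subclass": ["TAG"] * len(mets),
                "pathways": [tuple(pathways_by_met[m]) for m in mets],
            },
            index=pd.Index(mets, name="metabolite_id"),
        )
        return AnnotationTable(table)

    def test_pure_module_matches_hypergeometric_enumeration(self):
        mets = [f"m{i}" for i in range(100)]
        paths = {m: ["target" if i < 10 else "background"] for i, m in enumerate(mets)}
        assignment = pd.Series(
            [1] * 10 + [2] * 90, index=pd.Index(mets, name="metabolite_id")
        )
        out = module_enrichment(assignment, self._annotation(paths))
        row = out[(out["module"] == 1) & (out["pathway"] == "target")].iloc[0]
        # exact tail by explicit enumeration: P(overlap >= 10) drawing 10 of 100
        def c(n, k):
            return math.comb(n, k)

        expected = sum(
            c(10, x) * c(90, 10 - x) for x in range(10, 11)
        ) / c(100, 10)
        assert row["p"] == pytest.approx(expected, abs=1e-12)
        assert row["overlap"] == 10

    def test_empty_module_produces_no_rows(self):
        mets = ["m0", "m1"]
        assignment = pd.Series([0, 0], index=pd.Index(mets, name="metabolite_id"))
        out = module_enrichment(assignment, self._annotation({m: ["p"] for m in mets}))
        assert out.empty

    def test_random_assignment_rarely_significant(self, rng):
        mets = [f"m{i}" for i in range(60)]
        paths = {m: [f"p{i % 5}"] for i, m in enumerate(mets)}
        ann = self._annotation(paths)
        frac_sig = []
        for _ in range(20):
            assignment = pd.Series(
                rng.integers(1, 5, size=60), index=pd.Index(mets, name="metabolite_id")
            )
            out = module_enrichment(assignment, ann)
            frac_sig.append((out["fdr"] < 0.05).mean())
        assert np.mean(frac_sig) <= 0.07

    def test_significant_modules_need_both_conditions(self):
        enrichment = pd.DataFrame(
            {"module": [1, 2], "pathway": ["a", "b"], "p": [0.001, 0.5], "fdr": [0.01, 0.6]}
        )
        from metabotype.programs import TraitCorrelation

        tc = TraitCorrelation(
            r=pd.DataFrame({1: [0.9, 0.9]}, index=[1, 2]),
            p=pd.DataFrame({1: [0.001, 0.001]}, index=[1, 2]),
        )
        assert significant_modules(enrichment, tc) == [1]


class TestPermutationNull:
    def test_trait_pvalues_uniform_under_permutation(self, rng):
        """Permuting labels breaks the module-subtype link: the correlation
        p-values should be uniform (KS test not rejecting)."""
        n = 80
        eigen = pd.DataFrame({1: rng.standard_normal(n)}, index=[f"s{i}" for i in range(n)])
        base = pd.Series(np.repeat([1, 2, 3], [20, 25, 35]), index=eigen.index)
        pvals = []
        for _ in range(200):
            perm = pd.Series(rng.permutation(base.to_numpy()), index=eigen.index)
            tc = module_trait_cor(eigen, perm)
            pvals.append(tc.p.loc[1, 1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
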