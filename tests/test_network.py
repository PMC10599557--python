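import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from gscoex.network import (
    GREY,
    NetworkParams,
    adjacency,
    build_network,
    compute_kme,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    tom_similarity,
)

from conftest import make_expression


def _tom_oracle(adj):
    """Brute-force double-loop topological overlap."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
            out[i, j] = num / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_identical_profiles_give_unit_adjacency(self, rng):
        x = rng.normal(size=30)
        expr = make_expression(np.vstack([x, 2 * x + 1]))
        adj = adjacency(expr, 1, "unsigned")
        assert adj[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_profiles_give_zero_adjacency(self):
        n = 64
        t = np.arange(n)
        expr = make_expression(np.vstack([np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n)]))
        adj = adjacency(expr, 1, "unsigned")
        assert abs(adj[0, 1]) < 1e-10

    def test_closed_form_power_six(self, rng):
        # exact correlation 0.5 from zero-mean orthonormal vectors
        M = rng.normal(size=(40, 2))
        q, _ = np.linalg.qr(M - M.mean(axis=0))
        v1, v2 = q[:, 0], q[:, 1]
        expr = make_expression(np.vstack([v1, 0.5 * v1 + np.sqrt(0.75) * v2]))
        adj = adjacency(expr, 6, "unsigned")
        assert adj[0, 1] == pytest.approx(0.5**6, abs=1e-12)

    def test_signed_formula(self, rng):
        M = rng.normal(size=(40, 2))
        q, _ = np.linalg.qr(M - M.mean(axis=0))
        expr = make_expression(np.vstack([q[:, 0], -q[:, 0] * 0.5 + np.sqrt(0.75) * q[:, 1]]))
        adj = adjacency(expr, 2, "signed")
        assert adj[0, 1] == pytest.approx(((1 - 0.5) / 2) ** 2, abs=1e-12)

    def test_zero_variance_gene_rejected(self, rng):
        expr = make_expression(np.vstack([np.ones(20), rng.normal(size=20)]))
        with pytest.raises(ValueError, match="g0"):
            adjacency(expr, 6)


class TestTOM:
    def test_clique_saturates_to_one(self):
        a = np.ones((3, 3))
        tom = tom_similarity(a)
        assert np.allclose(tom, 1.0)

    def test_empty_graph_has_zero_overlap(self):
        tom = tom_similarity(np.eye(5))
        off = tom[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.abs(tom_similarity(a) - _tom_oracle(a)).max() < 1e-12

    def test_entries_bounded_and_symmetric(self, rng):
        a = rng.random((15, 15)) * 0.5
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)


class TestSoftThreshold:
    def test_vacuous_criterion_returns_smallest_power(self, rng):
        expr = make_expression(rng.normal(size=(50, 30)))
        res = pick_soft_threshold(expr, (3, 5, 9), r2_target=0.0)
        assert res.power == 3

    def test_single_candidate_forced_choice_flagged(self, rng):
        expr = make_expression(rng.normal(size=(50, 30)))
        with pytest.warns(UserWarning):
            res = pick_soft_threshold(expr, (7,), r2_target=0.99)
        assert res.power == 7

    def test_modular_data_with_hubs_reaches_scale_free_fit(self, rng):
        n, p = 100, 600
        f = rng.normal(size=(3, n))
        assign = rng.integers(0, 3, p)
        lam = rng.uniform(0.3, 0.95, p)
        X = lam[:, None] * f[assign] + np.sqrt(1 - lam**2)[:, None] * rng.normal(
            size=(p, n)
        )
        res = pick_soft_threshold(make_expression(X))
        assert res.satisfied
        assert res.power <= 12
        row = res.table[res.table.power == res.power].iloc[0]
        assert row.r_squared >= 0.8


class TestDetectModules:
    def test_planted_two_blocks_recovered_exactly(self, planted_two_blocks):
        expr, truth = planted_two_blocks
        tom = tom_similarity(adjacency(expr, 6))
        _, merged, _, mes = detect_modules(tom, expr, min_module_size=20)
        assert set(merged) == {"M1", "M2"}
        assert adjusted_rand_score(truth, merged) == 1.0
        assert mes.shape[1] == 2

    def test_zero_merge_height_keeps_labels(self, planted_two_blocks):
        expr, _ = planted_two_blocks
        tom = tom_similarity(adjacency(expr, 6))
        labels, merged, _, _ = detect_modules(
            tom, expr, min_module_size=20, merge_cut_height=0.0
        )
        assert (labels == merged).all()

    def test_identical_eigengene_blocks_merge(self, rng):
        n = 100
        f = rng.normal(size=n)
        X = np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(size=(100, n))
        expr = make_expression(X)
        tom = tom_similarity(adjacency(expr, 6))
        _, merged, _, _ = detect_modules(
            tom, expr, min_module_size=20, merge_cut_height=0.25
        )
        assert len(set(merged) - {GREY}) == 1

    def test_too_few_genes_all_grey_with_warning(self, rng):
        expr = make_expression(rng.normal(size=(10, 30)))
        tom = tom_similarity(adjacency(expr, 6))
        with pytest.warns(UserWarning, match="grey"):
            _, merged, _, _ = detect_modules(tom, expr, min_module_size=30)
        assert (merged == GREY).all()

    def test_gene_permutation_invariance(self, planted_two_blocks):
        expr, _ = planted_two_blocks
        perm = np.random.default_rng(5).permutation(len(expr))
        expr_p = expr.iloc[perm]
        tom = tom_similarity(adjacency(expr, 6))
        tom_p = tom_similarity(adjacency(expr_p, 6))
        _, merged, _, _ = detect_modules(tom, expr, min_module_size=20)
        _, merged_p, _, _ = detect_modules(tom_p, expr_p, min_module_size=20)
        aligned = merged_p.loc[expr.index]
        assert adjusted_rand_score(merged, aligned) == 1.0

    def test_deterministic_rebuild(self, small_adjusted, small_network_params):
        pres, _ = small_adjusted
        a = build_network(pres.data, small_network_params)
        b = build_network(pres.data, small_network_params)
        assert (a.merged_labels == b.merged_labels).all()
        pd.testing.assert_frame_equal(a.mes, b.mes)


class TestEigengenes:
    def test_rank_one_module_recovers_common_profile(self, rng):
        v = rng.normal(size=50)
        X = np.outer(np.linspace(0.5, 2.0, 20), v)
        expr = make_expression(X)
        labels = pd.Series(["M1"] * 20, index=expr.index)
        mes, varexp = module_eigengenes(expr, labels)
        assert np.corrcoef(mes["M1"], v)[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert varexp["M1"] == pytest.approx(1.0, abs=1e-12)

    def test_variance_explained_in_unit_interval(self, small_adjusted):
        pres, _ = small_adjusted
        labels = pd.Series(
            ["M1"] * 40 + ["M2"] * 40 + [GREY] * (len(pres.data) - 80),
            index=pres.data.index,
        )
        _, varexp = module_eigengenes(pres.data, labels)
        assert ((varexp > 0) & (varexp <= 1)).all()

    def test_unit_variance_and_sign_orientation(self, rng):
        f = rng.normal(size=60)
        X = np.sqrt(0.7) * f + np.sqrt(0.3) * rng.normal(size=(30, 60))
        expr = make_expression(X)
        labels = pd.Series(["M1"] * 30, index=expr.index)
        mes, _ = module_eigengenes(expr, labels)
        assert mes["M1"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        # oriented toward the module's average profile
        assert np.corrcoef(mes["M1"], X.mean(axis=0))[0, 1] > 0

    def test_flipped_gene_barely_perturbs_eigengene(self, rng):
        f = rng.normal(size=80)
        X = np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(size=(40, 80))
        expr = make_expression(X)
        labels = pd.Series(["M1"] * 40, index=expr.index)
        mes_before, _ = module_eigengenes(expr, labels)
        X2 = np.vstack([X, -f + 0.3 * rng.normal(size=80)])
        expr2 = make_expression(X2)
        labels2 = pd.Series(["M1"] * 41, index=expr2.index)
        mes_after, _ = module_eigengenes(expr2, labels2)
        r = np.corrcoef(mes_before["M1"], mes_after["M1"])[0, 1]
        assert r > 0.99

    def test_single_gene_module_is_standardized_profile(self, rng):
        x = rng.normal(size=40)
        expr = make_expression(x[None, :])
        labels = pd.Series(["M1"], index=expr.index)
        with pytest.warns(UserWarning, match="single gene"):
            mes, _ = module_eigengenes(expr, labels)
        assert np.corrcoef(mes["M1"], x)[0, 1] == pytest.approx(1.0, abs=1e-12)


class TestKME:
    def test_gene_equal_to_eigengene_has_unit_kme(self, rng):
        f = rng.normal(size=60)
        X = np.vstack([f, np.sqrt(0.8) * f + np.sqrt(0.2) * rng.normal(size=(25, 60))])
        expr = make_expression(X)
        mes = pd.DataFrame({"M1": f}, index=expr.columns)
        kme = compute_kme(expr, mes)
        assert kme.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_noise_gene_has_near_zero_kme(self, rng):
        f = rng.normal(size=600)
        X = np.vstack([rng.normal(size=600)])
        expr = make_expression(X)
        mes = pd.DataFrame({"M1": f}, index=expr.columns)
        kme = compute_kme(expr, mes)
        assert abs(kme.iloc[0, 0]) < 0.15

    def test_own_module_kme_dominates_in_planted_modules(self, planted_two_blocks):
        expr, truth = planted_two_blocks
        tom = tom_similarity(adjacency(expr, 6))
        _, merged, _, mes = detect_modules(tom, expr, min_module_size=20)
        kme = compute_kme(expr, mes)
        own_wins = 0
        assigned = merged[merged != GREY]
        for g, m in assigned.items():
            own_wins += kme.loc[g, m] >= kme.loc[g].max() - 1e-12
        assert own_wins >= 0.95 * len(assigned)
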