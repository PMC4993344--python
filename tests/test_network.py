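import numpy as np
import pandas as pd
import pytest

from comethage.association import bicor_matrix
from comethage.core_io import ValidationError
from comethage.ewas import p_to_signed_z, stouffer_meta
from comethage.network import (
    NetworkConfig,
    calibrate_toms,
    consensus_dissimilarity,
    consensus_hub_z,
    cut_modules,
    fisher_z_statistic,
    membership_table,
    module_eigenvector,
    module_membership,
    module_trait_meta,
    quantile_normalize_columns,
    signed_hybrid_adjacency,
    tom,
)


def brute_force_tom(A):
    """Triple-loop oracle for the topological overlap measure."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def _random_adjacency(rng, n=8):
    C = rng.uniform(-1, 1, (n, n))
    C = (C + C.T) / 2
    A = np.maximum(C, 0) ** 6
    np.fill_diagonal(A, 0.0)
    return A


class TestSignedHybridAdjacency:
    def test_negative_correlation_zeroed(self, rng):
        x = rng.normal(size=30)
        X = np.vstack([x, -x + rng.normal(0, 0.01, 30), x + rng.normal(0, 0.01, 30)])
        A = signed_hybrid_adjacency(X)
        assert A[0, 1] == 0.0
        assert A[0, 2] > 0.5

    def test_formula_matches_bicor(self, rng):
        X = rng.normal(size=(6, 40))
        cfg = NetworkConfig(soft_power=6)
        A = signed_hybrid_adjacency(X, cfg)
        C = bicor_matrix(X, cfg.max_p_outliers)
        expected = np.maximum(C, 0) ** 6
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(A, expected, atol=1e-12)

    def test_power_on_half(self):
        assert 0.5**6 == pytest.approx(0.015625)

    def test_range_and_symmetry(self, rng):
        A = signed_hybrid_adjacency(rng.normal(size=(10, 25)))
        assert np.all((A >= 0) & (A <= 1))
        np.testing.assert_allclose(A, A.T)

    def test_too_few_samples(self, rng):
        with pytest.raises(ValidationError):
            signed_hybrid_adjacency(rng.normal(size=(4, 2)))


class TestTom:
    def test_disconnected_pair(self):
        A = np.zeros((4, 4))
        A[2, 3] = A[3, 2] = 0.5
        T = tom(A)
        assert T[0, 1] == 0.0

    def test_complete_graph(self):
        A = 1.0 - np.eye(4)
        T = tom(A)
        off = T[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_brute_force_oracle(self, rng):
        A = _random_adjacency(rng, 8)
        np.testing.assert_allclose(tom(A), brute_force_tom(A), atol=1e-12)

    def test_range_symmetry(self, rng):
        T = tom(_random_adjacency(rng, 12))
        assert np.all((T >= 0) & (T <= 1))
        np.testing.assert_allclose(T, T.T)

    def test_negative_entry_error(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = -0.1
        with pytest.raises(ValidationError):
            tom(A)


class TestCalibration:
    def test_identical_inputs_unchanged(self, rng):
        T = tom(_random_adjacency(rng, 10))
        out = calibrate_toms({"a": T, "b": T.copy()})
        np.testing.assert_allclose(out["a"], T, atol=1e-12)
        np.testing.assert_allclose(out["b"], T, atol=1e-12)

    def test_scaled_lobe_sorted_equal(self, rng):
        T1 = tom(_random_adjacency(rng, 10))
        T2 = np.clip(2 * T1, 0, 1)
        np.fill_diagonal(T2, 1.0)
        out = calibrate_toms({"a": T1, "b": T2})
        tril = np.tril_indices(10, -1)
        np.testing.assert_allclose(np.sort(out["a"][tril]), np.sort(out["b"][tril]), atol=1e-12)

    def test_quantiles_equal_after_calibration(self, rng):
        toms = {l: tom(_random_adjacency(rng, 15)) for l in ("a", "b", "c")}
        out = calibrate_toms(toms)
        tril = np.tril_indices(15, -1)
        for q in (0.25, 0.5, 0.75):
            vals = [np.quantile(out[l][tril], q) for l in out]
            assert max(vals) - min(vals) < 1e-10

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            calibrate_toms({"a": np.eye(4), "b": np.eye(5)})

    def test_quantile_normalize_reference(self):
        M = np.array([[1.0, 2.0], [3.0, 6.0], [2.0, 4.0]])
        out = quantile_normalize_columns(M)
        # sorted reference = mean of per-rank sorted values = [1.5, 3, 4.5]
        np.testing.assert_allclose(np.sort(out[:, 0]), [1.5, 3.0, 4.5])
        np.testing.assert_allclose(np.sort(out[:, 1]), [1.5, 3.0, 4.5])

    def test_quantile_normalize_ties_averaged(self):
        M = np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]])
        out = quantile_normalize_columns(M)
        ref = np.sort(M, axis=0).mean(axis=1)  # [3, 3.5, 4.5]
        assert out[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)


class TestConsensus:
    def test_minimum(self):
        ctoms = {l: np.full((2, 2), v) for l, v in zip("abc", (0.2, 0.5, 0.9))}
        D = consensus_dissimilarity(ctoms, 0.0)
        assert D[0, 0] == pytest.approx(0.8)

    def test_median(self):
        ctoms = {l: np.full((2, 2), v) for l, v in zip("abc", (0.1, 0.2, 0.3))}
        D = consensus_dissimilarity(ctoms, 0.5)
        assert D[0, 0] == pytest.approx(0.8)

    def test_identical_lobes_idempotent(self, rng):
        T = tom(_random_adjacency(rng, 8))
        for q in (0.0, 0.5, 1.0):
            D = consensus_dissimilarity({"a": T, "b": T.copy(), "c": T.copy()}, q)
            np.testing.assert_allclose(D, 1 - T, atol=1e-12)

    def test_bad_quantile(self, rng):
        with pytest.raises(ValidationError):
            consensus_dissimilarity({"a": np.eye(3), "b": np.eye(3)}, 1.5)


def _block_dissimilarity(rng, sizes=(50, 30), background=20, within=0.1, between=0.9):
    n = sum(sizes) + background
    D = np.full((n, n), between)
    start = 0
    for s in sizes:
        D[start : start + s, start : start + s] = within
        start += s
    D += rng.uniform(0, 0.02, (n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestCutModules:
    def test_two_planted_blocks(self, rng):
        D = _block_dissimilarity(rng)
        ms = cut_modules(D, [f"cg{i}" for i in range(D.shape[0])],
                         NetworkConfig(min_module_size=25, cut_height=0.5))
        assert ms.module_ids == [1, 2]
        labels = ms.labels
        assert set(labels[:50]) == {1}
        assert set(labels[50:80]) == {2}

    def test_min_size_too_large(self, rng):
        D = _block_dissimilarity(rng)
        with pytest.warns(UserWarning, match="min_module_size"):
            ms = cut_modules(D, [f"cg{i}" for i in range(D.shape[0])],
                             NetworkConfig(min_module_size=1000, cut_height=0.5))
        assert np.all(ms.labels == 0)

    def test_size_ordering(self, rng):
        D = _block_dissimilarity(rng, sizes=(30, 50))
        ms = cut_modules(D, [f"cg{i}" for i in range(D.shape[0])],
                         NetworkConfig(min_module_size=25, cut_height=0.5))
        sizes = [np.sum(ms.labels == m) for m in ms.module_ids]
        assert sizes == sorted(sizes, reverse=True)

    def test_permutation_equivariance(self, rng):
        D = _block_dissimilarity(rng)
        n = D.shape[0]
        ids = [f"cg{i}" for i in range(n)]
        cfg = NetworkConfig(min_module_size=25, cut_height=0.5)
        ms = cut_modules(D, ids, cfg)
        perm = rng.permutation(n)
        ms_p = cut_modules(D[np.ix_(perm, perm)], [ids[i] for i in perm], cfg)
        lab = dict(zip(ms.cpg_ids, ms.labels))
        lab_p = dict(zip(ms_p.cpg_ids, ms_p.labels))
        # same partition: co-membership must agree for every pair
        import itertools

        for a, b in itertools.islice(itertools.combinations(ids, 2), 2000):
            assert (lab[a] == lab[b] and lab[a] != 0) == (lab_p[a] == lab_p[b] and lab_p[a] != 0)


class TestEigenvector:
    def _residuals(self, X):
        return pd.DataFrame(X, index=[f"cg{i}" for i in range(X.shape[0])],
                            columns=[f"s{j}" for j in range(X.shape[1])])

    def test_identical_profiles(self, rng):
        x = rng.normal(size=20)
        res = self._residuals(np.vstack([x, x, x]))
        e, ve = module_eigenvector(res, ["cg0", "cg1", "cg2"])
        assert abs(np.corrcoef(e, x)[0, 1]) == pytest.approx(1.0)
        assert ve == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(5, 30)) + rng.normal(size=30)
        res = self._residuals(X)
        e, _ = module_eigenvector(res, list(res.index))
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        assert np.corrcoef(e, Z.mean(axis=0))[0, 1] > 0

    def test_unit_norm(self, rng):
        res = self._residuals(rng.normal(size=(6, 25)))
        e, _ = module_eigenvector(res, list(res.index))
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_covariance_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(5, 18))
        res = self._residuals(X)
        e, ve = module_eigenvector(res, list(res.index))
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        w, V = np.linalg.eigh(Z.T @ Z)
        top = V[:, np.argmax(w)]
        assert abs(abs(e @ top) - 1.0) < 1e-10
        assert ve == pytest.approx(np.max(w) / w.sum())

    def test_constant_cpg_dropped(self, rng):
        X = rng.normal(size=(3, 15))
        X[1] = 0.5
        res = self._residuals(X)
        with pytest.warns(UserWarning, match="constant"):
            e, _ = module_eigenvector(res, list(res.index))
        assert np.all(np.isfinite(e))

    def test_too_small_module(self, rng):
        res = self._residuals(rng.normal(size=(3, 10)))
        with pytest.raises(ValidationError):
            module_eigenvector(res, ["cg0"])


class TestMembership:
    def test_proportional(self, rng):
        e = rng.normal(size=20)
        assert module_membership(3 * e + 1, pd.Series(e)) == pytest.approx(1.0)

    def test_negated(self, rng):
        e = rng.normal(size=20)
        assert module_membership(-e, pd.Series(e)) == pytest.approx(-1.0)

    def test_constant_profile_nan(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            mm = module_membership(np.full(10, 0.3), rng.normal(size=10))
        assert np.isnan(mm)

    def test_hub_has_top_membership(self, small_cohort):
        betas, sheet, truth = small_cohort
        from comethage.ewas import adjust_age_sex

        res = adjust_age_sex(betas["frontal"], sheet)
        members = list(truth.module_label[truth.module_label == 1].index)
        e, _ = module_eigenvector(res, members)
        mms = {c: module_membership(res.loc[c], e) for c in members}
        # all planted members share one latent: memberships should be high
        assert np.median(list(mms.values())) > 0.5


class TestConsensusHubZ:
    def test_high_mm_large_z(self):
        z = consensus_hub_z({"a": 0.99, "b": 0.99, "c": 0.99}, {"a": 50, "b": 50, "c": 50})
        assert z > 10

    def test_zero_mm(self):
        z = consensus_hub_z({"a": 0.0, "b": 0.0}, {"a": 50, "b": 50})
        assert z == pytest.approx(0.0)

    def test_ranking_matches_fisher_average_equal_n(self, rng):
        n = {"a": 40, "b": 40, "c": 40}
        mms = [dict(zip("abc", rng.uniform(-0.9, 0.9, 3))) for _ in range(20)]
        zs = [consensus_hub_z(m, n) for m in mms]
        avg_fisher = [np.mean([np.arctanh(v) for v in m.values()]) for m in mms]
        assert np.all(np.argsort(zs) == np.argsort(avg_fisher))

    def test_membership_table_consistency(self, small_cohort):
        betas, sheet, truth = small_cohort
        from comethage.ewas import adjust_age_sex

        res = {l: adjust_age_sex(b, sheet) for l, b in betas.items()}
        members = list(truth.module_label[truth.module_label == 1].index)
        eig = {l: {1: module_eigenvector(res[l], members)[0]} for l in res}
        table = membership_table(res, eig)
        row = table[(table["cpg_id"] == members[0]) & (table["module"] == 1)].iloc[0]
        zs = [fisher_z_statistic(row[f"mm_{l}"], res[l].shape[1]) for l in res]
        assert row["z_meta"] == pytest.approx(float(stouffer_meta(zs)[0]), abs=1e-9)


class TestModuleTraitMeta:
    def test_trait_equals_eigenvector(self, rng):
        e = pd.Series(rng.normal(size=30))
        eig = {l: {1: e} for l in ("a", "b")}
        traits = {l: e.to_numpy() for l in ("a", "b")}
        out = module_trait_meta(eig, traits)
        assert out["r_a"].iloc[0] == pytest.approx(1.0)
        assert out["z_meta"].iloc[0] > 10

    def test_constant_trait_skipped(self, rng):
        e = pd.Series(rng.normal(size=30))
        eig = {l: {1: e} for l in ("a", "b", "c")}
        traits = {"a": e.to_numpy(), "b": e.to_numpy(), "c": np.zeros(30)}
        with pytest.warns(UserWarning, match="constant trait"):
            out = module_trait_meta(eig, traits)
        assert out["n_sets"].iloc[0] == 2
        assert np.isnan(out["p_c"].iloc[0])


class TestEndToEndNetwork:
    def test_planted_modules_recovered(self, small_cohort):
        betas, sheet, truth = small_cohort
        from comethage.ewas import adjust_age_sex, variance_filter

        kept, _ = variance_filter(betas)
        res = {l: adjust_age_sex(b.subset_cpgs(kept), sheet) for l, b in betas.items()}
        cfg = NetworkConfig(min_module_size=15)
        toms = {l: tom(signed_hybrid_adjacency(r, cfg)) for l, r in res.items()}
        D = consensus_dissimilarity(calibrate_toms(toms), 0.0)
        ms = cut_modules(D, kept, cfg)
        truth_labels = truth.module_label[kept].to_numpy()
        planted = truth_labels > 0
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth_labels[planted], ms.labels[planted])
        assert ari >= 0.8

    def test_matrices_stay_valid(self, small_cohort):
        betas, sheet, truth = small_cohort
        from comethage.ewas import adjust_age_sex

        res = adjust_age_sex(betas["frontal"], sheet)
        A = signed_hybrid_adjacency(res.iloc[:100])
        T = tom(A)
        for M in (A, T):
            assert np.all((M >= 0) & (M <= 1))
            np.testing.assert_allclose(M, M.T, atol=1e-12)
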