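"""Co-expression network construction and module detection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from berrynet.datatypes import NetworkParams, ValidationError
from berrynet.netmodules import (
    adjacency_tom,
    detect_modules,
    find_modules,
    merge_close_modules,
    module_eigengene,
    select_soft_power,
    tom_from_adjacency,
)


def block_profiles(rng, sizes, n_obs=30, within_r=0.9, prefix="g"):
    """Features in blocks sharing one latent factor (within-block corr ~r)."""
    rows, ids = [], []
    lam = np.sqrt(within_r)
    i = 0
    for b, size in enumerate(sizes):
        base = rng.normal(size=n_obs)
        for _ in range(size):
            rows.append(lam * base + np.sqrt(1 - lam**2) * rng.normal(size=n_obs))
            ids.append(f"{prefix}{i:03d}")
            i += 1
    return pd.DataFrame(rows, index=ids)


class TestSoftPower:
    def test_single_candidate_returned_with_warning(self):
        rng = np.random.default_rng(0)
        prof = block_profiles(rng, [30])
        with pytest.warns(UserWarning):
            sel = select_soft_power(prof, candidate_powers=(6,), target_r2=0.99)
        assert sel.power == 6.0

    def test_degenerate_all_correlated_falls_back_to_smallest(self):
        base = np.arange(10.0)
        prof = pd.DataFrame(
            [2.0 * base + i for i in range(25)],
            index=[f"g{i}" for i in range(25)],
        )
        with pytest.warns(UserWarning, match="degenerate|smallest"):
            sel = select_soft_power(prof, candidate_powers=(2, 4, 8))
        assert sel.power == 2.0

    def test_three_block_data_selects_at_least_four(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = block_profiles(rng, [50, 50, 50])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_soft_power(prof)
            hits += sel.power >= 4
        assert hits > 10  # majority of seeds


class TestTOM:
    def test_perfectly_correlated_pair(self):
        prof = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [2.0, 4, 6, 8, 10]], index=["a", "b"]
        )
        tom = adjacency_tom(prof, NetworkParams(power=6.0))
        assert tom.loc["a", "b"] == pytest.approx(1.0)
        assert tom.loc["a", "a"] == 1.0

    def test_uncorrelated_pair_no_shared_neighbors(self):
        # two exactly orthogonal profiles, no third feature
        prof = pd.DataFrame(
            [[1.0, -1, 1, -1], [1.0, 1, -1, -1]], index=["a", "b"]
        )
        tom = adjacency_tom(prof, NetworkParams(power=6.0))
        assert tom.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_formula(self):
        a = np.array(
            [
                [0.0, 0.5, 0.2, 0.0],
                [0.5, 0.0, 0.4, 0.1],
                [0.2, 0.4, 0.0, 0.3],
                [0.0, 0.1, 0.3, 0.0],
            ]
        )
        tom = tom_from_adjacency(a)
        k = a.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(4))
                expected = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry_random(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(40, 8)),
                            index=[f"g{i}" for i in range(40)])
        tom = adjacency_tom(prof, NetworkParams(power=6.0)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)

    def test_unsigned_adjacency_monotone_in_power(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(10, 6)),
                            index=[f"g{i}" for i in range(10)])
        corr = np.corrcoef(prof.to_numpy())
        lo = np.abs(corr) ** 4
        hi = np.abs(corr) ** 8
        off = ~np.eye(10, dtype=bool)
        assert (hi[off] <= lo[off] + 1e-15).all()

    def test_zero_variance_feature_rejected(self):
        prof = pd.DataFrame(
            [[1.0, 2, 3], [5.0, 5, 5]], index=["ok", "flat"]
        )
        with pytest.raises(ValidationError, match="flat"):
            adjacency_tom(prof, NetworkParams())


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(3)
        prof = block_profiles(rng, [50, 50], within_r=0.9)
        params = NetworkParams(power=6.0, min_module_size=10)
        tom = adjacency_tom(prof, params)
        asg = detect_modules(tom, params, prof)
        truth = ["A"] * 50 + ["B"] * 50
        assert len(asg.module_ids) == 2
        assert adjusted_rand_score(truth, asg.labels.loc[prof.index]) == 1.0

    def test_identical_features_form_one_module(self):
        base = np.array([0.0, 1, 2, 1, 3])
        prof = pd.DataFrame(
            [base + 0.0 for _ in range(12)], index=[f"g{i}" for i in range(12)]
        )
        params = NetworkParams(power=6.0, min_module_size=5)
        tom = adjacency_tom(prof, params)
        asg = detect_modules(tom, params, prof)
        assert len(asg.module_ids) == 1
        assert (asg.labels == asg.module_ids[0]).all()

    def test_independent_features_all_unassigned(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            prof = pd.DataFrame(rng.normal(size=(10, 30)),
                                index=[f"g{i}" for i in range(10)])
            params = NetworkParams(power=6.0, min_module_size=5)
            tom = adjacency_tom(prof, params)
            asg = detect_modules(tom, params, prof)
            hits += (asg.labels == "unassigned").all()
        assert hits >= 18

    def test_labels_ordered_by_descending_size(self):
        rng = np.random.default_rng(5)
        prof = block_profiles(rng, [20, 40], within_r=0.95)
        params = NetworkParams(power=6.0, min_module_size=10)
        tom = adjacency_tom(prof, params)
        asg = detect_modules(tom, params, prof, prefix="WD")
        sizes = asg.sizes()
        assert list(sizes.index) == ["WD1", "WD2"]
        assert sizes["WD1"] >= sizes["WD2"]


class TestEigengene:
    def test_identical_members_explain_everything(self):
        base = np.array([0.0, 1, 2, 3, 4])
        data = pd.DataFrame([base, base, base], index=["a", "b", "c"])
        eig, ve = module_eigengene(data)
        assert ve == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented with the mean member profile

    def test_two_orthogonal_members_split_variance(self):
        data = pd.DataFrame(
            [[1.0, -1, 1, -1], [1.0, 1, -1, -1]], index=["a", "b"]
        )
        _, ve = module_eigengene(data)
        assert ve == pytest.approx(0.5)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(20, 5)),
                            index=[f"g{i}" for i in range(20)])
        eig, ve = module_eigengene(data)
        arr = data.to_numpy()
        z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(
            axis=1, keepdims=True
        )
        evals, evecs = np.linalg.eigh(z.T @ z)
        v1 = evecs[:, -1]
        assert min(
            np.abs(eig.to_numpy() - v1).max(),
            np.abs(eig.to_numpy() + v1).max(),
        ) < 1e-10
        assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)

    def test_unit_norm(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(5, 7)))
        eig, _ = module_eigengene(data)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_singleton_module_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            module_eigengene(pd.DataFrame([[1.0, 2, 3]]))


class TestMerge:
    def _split_assignment(self, prof, params):
        tom = adjacency_tom(prof, params)
        return detect_modules(tom, params, prof)

    def test_same_pattern_modules_merge(self):
        rng = np.random.default_rng(8)
        # two "modules" carved from one latent pattern
        prof = block_profiles(rng, [60], within_r=0.95)
        labels = pd.Series(
            ["A"] * 30 + ["B"] * 30, index=prof.index
        )
        from berrynet.datatypes import ModuleAssignment
        from berrynet.netmodules import module_eigengene as me

        eg = {m: me(prof.loc[labels == m])[0] for m in ("A", "B")}
        asg = ModuleAssignment(
            labels, pd.DataFrame(eg).T, pd.Series({"A": 0.9, "B": 0.9})
        )
        merged = merge_close_modules(asg, prof, merge_cut=0.25)
        assert len(merged.module_ids) == 1

    def test_merge_cut_zero_is_identity(self):
        rng = np.random.default_rng(9)
        prof = block_profiles(rng, [25, 25], within_r=0.9)
        params = NetworkParams(power=6.0, min_module_size=10)
        asg = self._split_assignment(prof, params)
        merged = merge_close_modules(asg, prof, merge_cut=0.0)
        pd.testing.assert_series_equal(merged.labels, asg.labels)

    def test_orthogonal_modules_unchanged(self):
        rng = np.random.default_rng(10)
        prof = block_profiles(rng, [20, 20, 20], within_r=0.95)
        params = NetworkParams(power=6.0, min_module_size=10)
        asg = self._split_assignment(prof, params)
        n_before = len(asg.module_ids)
        merged = merge_close_modules(asg, prof, merge_cut=0.25)
        assert len(merged.module_ids) == n_before


class TestFindModules:
    def test_zero_variance_features_excluded_and_reported(self):
        rng = np.random.default_rng(11)
        prof = block_profiles(rng, [30], within_r=0.9)
        prof.loc["flat1"] = 3.0
        prof.loc["flat2"] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = find_modules(prof, NetworkParams(min_module_size=10))
        assert set(res.excluded) == {"flat1", "flat2"}
        assert "flat1" not in res.assignment.labels.index
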