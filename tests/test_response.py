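"""Stage-wise response computations: log2FC, ANOVA, clustering, PCA, overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from berrynet.datatypes import (
    DETable,
    ExpressionMatrix,
    MetaboliteTable,
    ResponseProfiles,
    ValidationError,
)
from berrynet.response import (
    cluster_response_profiles,
    de_overlap,
    log2_fold_change,
    pca_scores,
    stagewise_anova,
)


def one_stage_matrix(ct, wd, mode="counts"):
    """A single-feature, single-stage ExpressionMatrix from replicate lists."""
    samples = [f"CT_1_r{i}" for i in range(1, len(ct) + 1)] + [
        f"WD_1_r{i}" for i in range(1, len(wd) + 1)
    ]
    meta = pd.DataFrame(
        {
            "stage_daa": [1] * len(samples),
            "treatment": ["CT"] * len(ct) + ["WD"] * len(wd),
            "replicate": list(range(1, len(ct) + 1)) + list(range(1, len(wd) + 1)),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    values = pd.DataFrame([list(ct) + list(wd)], index=["f1"], columns=samples)
    return ExpressionMatrix(values, meta, mode=mode)


def metab_table(ct, wd):
    em = one_stage_matrix(ct, wd, mode="vst")
    return MetaboliteTable(em.values.clip(lower=0), em.sample_meta)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "ct, wd, pc, expected",
        [
            ((2, 2, 2), (8, 8, 8), 0.0, 2.0),
            ((5, 5, 5), (5, 5, 5), 0.0, 0.0),
            ((0, 0, 0), (3, 3, 3), 1.0, 2.0),
        ],
    )
    def test_known_values(self, ct, wd, pc, expected):
        em = one_stage_matrix(ct, wd)
        out = log2_fold_change(em, pseudocount=pc)
        assert out.log2fc.loc["f1", 1] == pytest.approx(expected)

    def test_antisymmetric_under_label_swap(self, demo_study):
        em = demo_study.counts
        swapped_meta = em.sample_meta.copy()
        swapped_meta["treatment"] = swapped_meta["treatment"].map(
            {"CT": "WD", "WD": "CT"}
        )
        swapped = ExpressionMatrix(em.values, swapped_meta, mode="counts")
        a = log2_fold_change(em, pseudocount=1.0).log2fc
        b = log2_fold_change(swapped, pseudocount=1.0).log2fc
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_missing_treatment_cell_errors(self):
        em = one_stage_matrix((1, 2), (3, 4))
        trimmed = ExpressionMatrix(
            em.values[["CT_1_r1", "CT_1_r2"]],
            em.sample_meta.loc[["CT_1_r1", "CT_1_r2"]],
            mode="counts",
        )
        with pytest.raises(ValidationError, match="no replicates"):
            log2_fold_change(trimmed, pseudocount=1.0)


class TestStagewiseAnova:
    def test_identical_groups(self):
        p = stagewise_anova(metab_table((1, 2, 3), (1, 2, 3)))
        assert p.loc["f1", 1] == pytest.approx(1.0)

    def test_separated_groups_f150(self):
        # MSbetween/MSwithin = 150 with df (1, 4)
        p = stagewise_anova(metab_table((1, 2, 3), (11, 12, 13)))
        assert p.loc["f1", 1] == pytest.approx(float(sps.f.sf(150, 1, 4)),
                                               rel=1e-9)
        assert p.loc["f1", 1] < 0.001

    def test_degenerate_zero_variance(self):
        assert stagewise_anova(metab_table((5, 5), (5, 5))).loc["f1", 1] == 1.0
        assert stagewise_anova(metab_table((5, 5), (6, 6))).loc["f1", 1] == 0.0

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        ct, wd = rng.normal(5, 1, 4), rng.normal(5.5, 1, 4)
        p_anova = stagewise_anova(metab_table(ct, wd)).loc["f1", 1]
        t, p_t = sps.ttest_ind(ct, wd, equal_var=True)
        assert p_anova == pytest.approx(p_t, rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [
            stagewise_anova(
                metab_table(rng.normal(5, 1, 3), rng.normal(5, 1, 3))
            ).loc["f1", 1]
            for _ in range(1000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


def brute_force_complete_linkage(dist: np.ndarray):
    """Exhaustive agglomeration: at each step merge the pair of current
    clusters with minimal complete-linkage distance; returns merge order
    as frozensets with heights."""
    clusters = {i: frozenset([i]) for i in range(dist.shape[0])}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        key = min(merged)
        clusters[key] = merged
        merges.append((merged, d))
    return merges


class TestClustering:
    def _profiles(self, rows: dict):
        return ResponseProfiles(pd.DataFrame(rows).T)

    def test_identical_profiles_merge_first(self):
        prof = self._profiles(
            {
                "a": [0, 1, 2, 3, 4],
                "b": [0, 1, 2, 3, 4],
                "c": [4, 1, 0, 2, 1],
            }
        )
        res = cluster_response_profiles(prof)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {res.clustered_ids[int(res.linkage[0, 0])],
                 res.clustered_ids[int(res.linkage[0, 1])]}
        assert first == {"a", "b"}

    def test_anticorrelated_profiles_merge_last(self):
        x = np.array([0.0, 1, 2, 3, 4])
        z = 0.9 * x + np.array([0.3, -0.2, 0.1, -0.3, 0.2])
        prof = self._profiles({"x": x, "minus_x": -x, "z": z})
        res = cluster_response_profiles(prof)
        assert res.linkage[-1, 2] == pytest.approx(2.0, abs=0.2)
        assert res.linkage[-1, 2] > res.linkage[0, 2]

    def test_merge_tree_matches_brute_force(self):
        rows = {
            "p1": [0.0, 1.0, 2.0, 3.0],
            "p2": [0.1, 1.2, 1.8, 3.2],
            "p3": [3.0, 1.0, 2.0, 0.0],
            "p4": [1.0, -1.0, 1.5, -1.2],
        }
        prof = self._profiles(rows)
        res = cluster_response_profiles(prof)
        ids = res.clustered_ids
        corr = np.corrcoef(pd.DataFrame(rows).T.loc[ids].to_numpy())
        dist = 1 - corr
        np.fill_diagonal(dist, 0)
        oracle = brute_force_complete_linkage(dist)
        # compare merge heights (the sequence characterizes the tree here)
        for (members, d), height in zip(oracle, res.linkage[:, 2]):
            assert height == pytest.approx(d, abs=1e-10)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(8, 5)),
                          index=[f"f{i}" for i in range(8)])
        a = cluster_response_profiles(ResponseProfiles(df))
        b = cluster_response_profiles(ResponseProfiles(df.iloc[::-1]))
        assert a.leaf_order == b.leaf_order

    def test_zero_variance_set_aside(self):
        prof = self._profiles(
            {"a": [0, 1, 2, 3, 4], "b": [1, 0, 2, 4, 3], "flat": [2, 2, 2, 2, 2]}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_response_profiles(prof)
        assert res.leaf_order[-1] == "flat"

    def test_all_flat_errors(self):
        prof = self._profiles({"a": [1, 1, 1], "b": [2, 2, 2]})
        with pytest.raises(ValidationError, match="zero variance"):
            cluster_response_profiles(prof)


class TestPCA:
    def test_collinear_points_pc1_explains_all(self):
        x = pd.DataFrame({"f1": [0, 1, 2, 3.0], "f2": [0, 2, 4, 6.0]})
        res = pca_scores(x, center=True, scale=False)
        assert res.variance_explained_pct[0] == pytest.approx(100.0)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["f1", "f2"])
        res = pca_scores(x, center=True, scale=False)
        assert res.variance_explained_pct[0] == pytest.approx(50.0, abs=3.0)
        assert res.variance_explained_pct[1] == pytest.approx(50.0, abs=3.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(5, 4)),
                         columns=[f"f{i}" for i in range(4)])
        res = pca_scores(x, center=True, scale=False)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        oracle_scores = centered @ evecs
        for j in range(4):
            got = res.scores.iloc[:, j].to_numpy()
            want = oracle_scores[:, j]
            assert np.allclose(got, want, atol=1e-10) or np.allclose(
                got, -want, atol=1e-10
            )
        np.testing.assert_allclose(
            res.variance_explained_pct, 100 * evals / evals.sum(), atol=1e-9
        )

    def test_zero_variance_feature_dropped_when_scaling(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"f1": rng.normal(size=6), "f2": rng.normal(size=6),
                          "flat": np.ones(6)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_scores(x, center=True, scale=True)
        assert "flat" not in res.loadings.index

    def test_too_few_features(self):
        x = pd.DataFrame({"f1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="2 usable features"):
            pca_scores(x, center=True, scale=False)


def make_de_table(stage_sets: dict[int, dict[str, str]]):
    rows = []
    for stage, genes in stage_sets.items():
        for gid, direction in genes.items():
            rows.append(
                {
                    "gene_id": gid,
                    "stage_daa": stage,
                    "log2fc": 1.0 if direction == "up" else -1.0,
                    "padj": 0.01,
                    "direction": direction,
                }
            )
    return DETable(pd.DataFrame(rows))


class TestDEOverlap:
    def test_two_stage_example(self):
        de = make_de_table(
            {1: {"g1": "up", "g2": "up"}, 2: {"g2": "down"}}
        )
        res = de_overlap(de)
        assert res.regions[(1,)] == 1  # unique to stage 1
        assert res.regions[(2,)] == 0
        assert res.regions[(1, 2)] == 1
        assert res.per_stage.loc[1, "total"] == 2

    def test_up_down_totals(self):
        genes = {f"g{i}": "up" for i in range(175)}
        genes.update({f"h{i}": "down" for i in range(39)})
        res = de_overlap(make_de_table({26: genes}))
        row = res.per_stage.loc[26]
        assert row["total"] == row["up"] + row["down"] == 214

    def test_region_cardinalities_sum_to_union(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(300)]
        stage_sets = {
            s: {g: "up" for g in rng.choice(universe, size=100, replace=False)}
            for s in range(1, 6)
        }
        res = de_overlap(make_de_table(stage_sets))
        exclusive_total = sum(res.regions.values())
        union = set().union(*(set(v) for v in stage_sets.values()))
        assert exclusive_total == len(union) == res.union_size
        assert len(res.regions) == 31  # 2^5 - 1 regions
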