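import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import benthonet as bn
from benthonet.module_env import apply_transform, eigengenes_frame


def power_iteration_first_right_singular(z, n_iter=2000):
    """Independent SVD oracle: power iteration on z^T z."""
    a = z.T @ z
    v = np.ones(a.shape[0]) / np.sqrt(a.shape[0])
    for _ in range(n_iter):
        v = a @ v
        v /= np.linalg.norm(v)
    return v


def permanova_groups_oracle(d, groups):
    """Single categorical term R2 by explicit sums of squared distances."""
    d = np.asarray(d)
    n = d.shape[0]
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in set(groups):
        idx = [i for i, x in enumerate(groups) if x == g]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    return (ss_total - ss_within) / ss_total


class TestEigengene:
    def test_identical_profiles_rank_one(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, 8).astype(float)
        df = pd.DataFrame([base, base, base], index=list("abc"),
                          columns=[f"s{j}" for j in range(8)])
        eg = bn.eigengene(df)
        assert eg.variance_explained == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eg.scores.to_numpy(), expected, atol=1e-12)

    def test_two_orthogonal_groups_half_variance(self):
        n = 40
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        a, b = np.sin(t), np.cos(t)  # orthogonal, equal norm
        df = pd.DataFrame([a, a, b, b], index=list("wxyz"),
                          columns=[f"s{j}" for j in range(n)])
        eg = bn.eigengene(df)
        assert eg.variance_explained == pytest.approx(0.5, abs=0.01)

    def test_matches_power_iteration_oracle(self, small_dataset):
        table, truth = small_dataset["table"], small_dataset["truth"]
        members = truth.module_members(1)
        sub = table.subset_otus(members)
        eg = bn.eigengene(sub)
        x = sub.data.to_numpy(dtype=float)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        oracle = power_iteration_first_right_singular(z)
        assert abs(np.dot(eg.scores.to_numpy(), oracle)) > 0.999

    def test_unit_norm_and_orientation(self, small_dataset):
        table, truth = small_dataset["table"], small_dataset["truth"]
        for mod in (1, 2):
            eg = bn.eigengene(table.subset_otus(truth.module_members(mod)), mod)
            assert np.linalg.norm(eg.scores) == pytest.approx(1.0)
            x = table.subset_otus(truth.module_members(mod)).data.to_numpy(float)
            z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
            assert np.dot(eg.scores, z.mean(axis=0)) >= 0

    def test_invariant_to_otu_order_and_scale(self, small_dataset):
        table, truth = small_dataset["table"], small_dataset["truth"]
        members = truth.module_members(1)
        sub = table.subset_otus(members).data
        eg1 = bn.eigengene(sub)
        scaled = sub.iloc[::-1] * 7  # reversed rows, rescaled profiles
        eg2 = bn.eigengene(scaled.astype(float))
        assert abs(np.dot(eg1.scores, eg2.scores)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_rows_dropped_and_small_module_errors(self):
        df = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4], [5, 5, 5, 5]],
                          index=list("abc"), columns=list("wxyz"))
        with pytest.raises(ValueError, match="non-constant"):
            bn.eigengene(df)


class TestCorrelateEnv:
    def test_eigengene_equal_to_variable_r_one(self):
        scores = pd.Series(np.linspace(-0.5, 0.5, 10),
                           index=[f"s{j}" for j in range(10)])
        scores /= np.linalg.norm(scores)
        eg = bn.Eigengene(module=1, scores=scores, variance_explained=1.0,
                          orientation_sign=1)
        meta = pd.DataFrame({"salinity": scores * 3 + 35}, index=scores.index)
        out = bn.correlate_env([eg], meta, variables=["salinity"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_transforms_applied(self):
        vals = pd.Series([1.0, 10.0, 100.0])
        assert apply_transform(vals, "log10").tolist() == pytest.approx([0, 1, 2])
        assert apply_transform(pd.Series([3.0]), "square").tolist() == [9.0]
        assert np.isnan(apply_transform(pd.Series([0.0]), "log")).all()

    def test_shuffled_metadata_p_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            scores = rng.normal(size=20)
            scores /= np.linalg.norm(scores)
            eg = bn.Eigengene(1, pd.Series(scores,
                                           index=[f"s{j}" for j in range(20)]),
                              1.0, 1)
            meta = pd.DataFrame({"v": rng.normal(size=20)}, index=eg.scores.index)
            ps.append(bn.correlate_env([eg], meta, variables=["v"]).iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pah_sensitive_module_negative_with_fluoranthene(self):
        from benthonet.synthetic_community import reduced_design

        hits = 0
        n_rep = 10
        for s in range(n_rep):
            design = reduced_design()
            table, meta, _, truth = bn.simulate_dataset(design, seed=1500 + s)
            members = truth.module_members(design.pah_sensitive_module)
            eg = bn.eigengene(table.subset_otus(members),
                              design.pah_sensitive_module)
            out = bn.correlate_env([eg], meta, variables=["fluoranthene"],
                                   transforms={"fluoranthene": "log"})
            hits += (out.iloc[0]["r"] < 0) and (out.iloc[0]["p"] < 0.05)
        assert hits >= 0.9 * n_rep

    def test_constant_variable_nan(self):
        scores = pd.Series(np.linspace(0, 1, 6), index=[f"s{j}" for j in range(6)])
        eg = bn.Eigengene(1, scores / np.linalg.norm(scores), 1.0, 1)
        meta = pd.DataFrame({"c": np.ones(6)}, index=scores.index)
        out = bn.correlate_env([eg], meta, variables=["c"])
        assert np.isnan(out.iloc[0]["r"])

    def test_eigengenes_frame_shape(self, small_dataset):
        table, truth = small_dataset["table"], small_dataset["truth"]
        egs = bn.module_eigengenes(table, truth.modules)
        frame = eigengenes_frame(egs)
        assert frame.shape == (2, table.n_samples)


class TestPermanova:
    def _clustered(self, gap=10.0, n=8, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n // 2, 3)),
                         rng.normal(gap, 1, (n // 2, 3))])
        d = squareform(pdist(pts))
        ids = [f"s{j}" for j in range(n)]
        meta = pd.DataFrame({"grp": ["a"] * (n // 2) + ["b"] * (n // 2)}, index=ids)
        return pd.DataFrame(d, index=ids, columns=ids), meta

    def test_single_term_r2_matches_group_ss_oracle(self):
        d, meta = self._clustered(gap=3.0, n=8, seed=4)
        res = bn.permanova(d, ["grp"], meta, n_perm=99, seed=0)
        oracle = permanova_groups_oracle(d.to_numpy(), meta["grp"].tolist())
        assert res.r2("grp") == pytest.approx(oracle, abs=1e-9)

    def test_r2_fractions_sum_to_one(self, small_dataset):
        table, meta = small_dataset["table"], small_dataset["meta"]
        res = bn.permanova_bray_curtis(table, meta,
                                       ["salinity", "fluoranthene"],
                                       n_perm=49, seed=1)
        assert res.table["r2"].drop("Total").sum() == pytest.approx(1.0)

    def test_separated_clusters_minimal_p(self):
        d, meta = self._clustered(gap=50.0, n=12, seed=1)
        res = bn.permanova(d, ["grp"], meta, n_perm=199, seed=2)
        assert res.p("grp") == pytest.approx(1 / 200)

    def test_equal_distances_r2_near_zero(self):
        n = 10
        d = np.ones((n, n)) - np.eye(n)
        ids = [f"s{j}" for j in range(n)]
        meta = pd.DataFrame({"grp": ["a", "b"] * (n // 2)}, index=ids)
        res = bn.permanova(pd.DataFrame(d, index=ids, columns=ids),
                           ["grp"], meta, n_perm=99, seed=0)
        assert abs(res.r2("grp")) < 0.15

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        meta = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            bn.permanova(d, ["x"], meta.set_index(pd.Index(["a", "b"])))

    def test_constant_term_dropped_with_warning(self):
        d, meta = self._clustered(n=8)
        meta["const"] = 1.0
        res = bn.permanova(d, ["const", "grp"], meta, n_perm=49, seed=0)
        assert "const" not in res.table.index

    def test_complete_cases_only(self):
        d, meta = self._clustered(gap=30.0, n=10, seed=3)
        meta["x"] = np.arange(10, dtype=float)
        meta.loc[meta.index[0], "x"] = np.nan
        res = bn.permanova(d, ["x"], meta, n_perm=49, seed=0)
        assert res.n_samples == 9

    def test_core_salinity_r2_exceeds_satellite(self):
        # environmental filtering acts on the core community; satellites
        # are randomly dispersed
        from benthonet.synthetic_community import reduced_design
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            table, meta, _, truth = bn.simulate_dataset(reduced_design(),
                                                        seed=700 + s)
            core = list(truth.otu_class.index[truth.otu_class == "core"])
            sat = list(truth.otu_class.index[truth.otu_class == "satellite"])
            r2_core = bn.permanova_bray_curtis(
                table.subset_otus(core), meta, ["salinity"],
                n_perm=29, seed=s).r2("salinity")
            r2_sat = bn.permanova_bray_curtis(
                table.subset_otus(sat), meta, ["salinity"],
                n_perm=29, seed=s).r2("salinity")
            hits += r2_core > r2_sat
        assert hits >= 0.9 * n_rep
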