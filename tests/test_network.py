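"""Correlation matrix, module extraction, collectives, stratification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import cytonet as cn
from cytonet.data import FrequencyMatrix


def _freq_df(x, prefix="k"):
    return pd.DataFrame(
        x, index=[f"s{i}" for i in range(len(x))],
        columns=[f"{prefix}{j}" for j in range(x.shape[1])])


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.arange(10.0)
        df = _freq_df(np.column_stack([x, 2 * x + 3, -x]))
        rho = cn.spearman_matrix(df).to_numpy()
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_rank_formula_example(self):
        """x=(1..5) vs y=(2,1,4,3,5): 1 - 6*4/(5*24) = 0.8 by the
        classical d-squared formula."""
        df = _freq_df(np.column_stack([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5],
                                       [1, 3, 2, 4, 5]]))
        rho = cn.spearman_matrix(df)
        assert rho.iloc[0, 1] == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_equals_rank_then_pearson_oracle(self):
        """Spearman equals ranking followed by Pearson to 1e-12 on
        random matrices."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 100, (10, 8))
            rho = cn.spearman_matrix(_freq_df(x)).to_numpy()
            ranks = np.apply_along_axis(stats.rankdata, 0, x)
            oracle = np.corrcoef(ranks, rowvar=False)
            np.testing.assert_allclose(rho, oracle, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        x = np.column_stack([np.ones(8), np.arange(8.0), np.arange(8.0) ** 2])
        with pytest.warns(UserWarning, match="constant"):
            rho = cn.spearman_matrix(_freq_df(x))
        assert rho.iloc[0, 1] == 0.0
        assert rho.iloc[0, 0] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 5"):
            cn.spearman_matrix(_freq_df(np.ones((4, 3))))


def _block_rho(sizes, within, between=0.0):
    n = sum(sizes)
    r = np.full((n, n), between)
    start = 0
    for s, w in zip(sizes, within):
        r[start:start + s, start:start + s] = w
        start += s
    np.fill_diagonal(r, 1.0)
    names = [f"k{i}" for i in range(n)]
    return pd.DataFrame(r, index=names, columns=names)


class TestExtractModules:
    def test_two_perfect_blocks(self):
        rho = _block_rho([5, 5], [1.0, 1.0])
        mods = cn.extract_modules(rho, m_min=4, rho_min=0.3)
        assert len(mods.qualified()) == 2
        assert sorted(mods.qualified()["size"]) == [5, 5]

    def test_identity_matrix_nothing_qualifies(self):
        rho = _block_rho([10], [0.0])
        mods = cn.extract_modules(rho, m_min=2, rho_min=0.3)
        assert len(mods.qualified()) == 0

    def test_qualification_monotone_in_rho_min(self):
        """Raising rho_min never qualifies a previously unqualified
        module (the cut and partition are rho_min-independent)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (60, 4))
        f = rng.normal(0, 1, 60)
        x[:, :2] += 0.8 * f[:, None]
        rho = cn.spearman_matrix(_freq_df(x))
        qualified = []
        for rho_min in (0.1, 0.3, 0.5, 0.9):
            mods = cn.extract_modules(rho, m_min=2, rho_min=rho_min)
            qualified.append(set(mods.qualified()["module"].index))
        sizes = [len(q) for q in qualified]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_blocks_recovered_exactly(self):
        """Planted within-block rho >= 0.5, between <= 0.1, n=100
        samples: recovered partition matches the plan (ARI = 1) in at
        least 19 of 20 seeds."""
        hits = 0
        planted = np.repeat([0, 1, 2], [6, 5, 4])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            factors = rng.normal(0, 1, (100, 3))
            x = 0.75 * factors[:, planted] + rng.normal(0, 0.55, (100, 15))
            mods = cn.extract_modules(cn.spearman_matrix(_freq_df(x)),
                                      m_min=4, rho_min=0.3)
            labels = mods.assignment.to_numpy()
            hits += adjusted_rand_score(planted, labels) == 1.0
        assert hits >= 19

    def test_default_study_three_qualified_networks(
            self, gut_freq_true, primary_study):
        """The default synthetic study yields exactly 3 qualified
        networks plus an unqualified residual cluster."""
        rho = cn.spearman_matrix(gut_freq_true)
        mods = cn.extract_modules(rho)
        q = mods.qualified()
        assert len(q) == 3
        assert len(mods.module_info) == 4
        residual = mods.module_info[~mods.module_info["is_network"]]
        assert residual["size"].iloc[0] == 3

    def test_network_naming_by_da_direction(self, gut_freq_true, primary_study):
        groups = cn.inflamed_contrast(primary_study.metadata).loc[
            gut_freq_true.samples]
        da = cn.ttest_inflamed_vs_rest(gut_freq_true, groups)
        rho = cn.spearman_matrix(gut_freq_true)
        mods = cn.extract_modules(rho, da_table=da)
        truth_mod = primary_study.truth.subset_info.set_index(
            "subset_id")["module"]
        # the depleted module is named network1, the enriched network2
        n1 = set(mods.members("network1"))
        n2 = set(mods.members("network2"))
        assert n1 == set(truth_mod[truth_mod == "network1"].index)
        assert n2 == set(truth_mod[truth_mod == "network2"].index)

    def test_too_few_subsets(self):
        with pytest.raises(ValueError, match="3 subsets"):
            cn.extract_modules(_block_rho([2], [1.0]))


class TestCollectives:
    def test_single_member_module(self):
        rho = _block_rho([4, 4], [1.0, 1.0])
        mods = cn.extract_modules(rho, m_min=4, rho_min=0.3)
        x = np.abs(np.random.default_rng(0).uniform(0, 10, (6, 8)))
        values = _freq_df(x)
        freq = FrequencyMatrix(values=values, mode="total_CD45")
        coll = cn.collective_frequencies(freq, mods)
        for module in coll.columns:
            members = mods.members(module)
            np.testing.assert_allclose(
                coll[module], values[members].sum(axis=1))

    def test_modules_covering_all_subsets_sum_to_100(self):
        rho = _block_rho([4, 4], [1.0, 1.0])
        mods = cn.extract_modules(rho, m_min=4, rho_min=0.3)
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(8), size=6) * 100
        freq = FrequencyMatrix(values=_freq_df(x), mode="total_CD45")
        coll = cn.collective_frequencies(freq, mods)
        np.testing.assert_allclose(coll.sum(axis=1), 100.0)

    def test_requires_total_cd45_mode(self):
        rho = _block_rho([4], [1.0])
        mods = cn.extract_modules(rho, m_min=2, rho_min=0.3, k_range=range(2, 4))
        freq = FrequencyMatrix(values=_freq_df(np.ones((5, 4))),
                               mode="lineage")
        with pytest.raises(ValueError, match="total_CD45"):
            cn.collective_frequencies(freq, mods)

    def test_inflamed_enrichment_of_network2(self, gut_freq_true,
                                             primary_study):
        groups = cn.inflamed_contrast(primary_study.metadata).loc[
            gut_freq_true.samples]
        da = cn.ttest_inflamed_vs_rest(gut_freq_true, groups)
        mods = cn.extract_modules(cn.spearman_matrix(gut_freq_true),
                                  da_table=da)
        coll = cn.collective_frequencies(gut_freq_true, mods)
        infl = coll.loc[groups == "inflamed", "network2"]
        rest = coll.loc[groups == "rest", "network2"]
        assert infl.median() > rest.median()
        assert coll.loc[groups == "inflamed", "network1"].median() < \
            coll.loc[groups == "rest", "network1"].median()


class TestStratify:
    @staticmethod
    def _meta(collectives, inflamed, diagnosis="CD"):
        return pd.DataFrame({
            "sample_id": collectives.index,
            "subject_id": [f"p{i // 2}" for i in range(len(collectives))],
            "status": np.where(inflamed, "inflamed", "noninflamed"),
            "diagnosis": diagnosis,
        })

    def test_all_zero_collectives_none_flagged(self):
        coll = pd.DataFrame({"network2": np.zeros(6)},
                            index=[f"s{i}" for i in range(6)])
        meta = self._meta(coll, inflamed=np.tile([True, False], 3))
        out = cn.stratify_patients(coll, meta)
        assert out["flagged"].sum() == 0

    def test_tiny_cutoff_flags_every_inflamed_patient(self):
        coll = pd.DataFrame({"network2": np.full(6, 5.0)},
                            index=[f"s{i}" for i in range(6)])
        meta = self._meta(coll, inflamed=np.tile([True, False], 3))
        out = cn.stratify_patients(coll, meta, cutoff_percent=1e-9)
        assert out["flagged"].all()

    def test_patient_without_inflamed_sample_unflagged(self):
        coll = pd.DataFrame({"network2": np.full(4, 99.0)},
                            index=[f"s{i}" for i in range(4)])
        meta = self._meta(coll, inflamed=np.array([True, False, False, False]))
        out = cn.stratify_patients(coll, meta)
        assert out.set_index("subject_id").loc["p0", "flagged"]
        assert not out.set_index("subject_id").loc["p1", "flagged"]
        assert np.isnan(
            out.set_index("subject_id").loc["p1", "max_inflamed_collective"])

    def test_designated_subgroup_recovered(self, primary_config, subset_ids):
        """A generator run with a designated high-network2 subgroup and
        quiet latent factors flags exactly that subgroup at the 50%
        cutoff."""
        cfg = dataclasses.replace(
            primary_config, n_high_n2=6, high_n2_boost=4.0, delta=0.3,
            sigma_mod=0.2, sigma_res=0.2, sigma_subj=0.1, sigma_noise=0.15,
            cells_per_sample={"ileum": 800, "colon": 500, "blood": 300},
        )
        study = cn.simulate_study(cfg, seed=3)
        cells = study.cells_for(study.intestinal_mask())
        freq = cn.compute_frequencies(
            cells.label, cells.sample_id, metadata=study.metadata,
            mode="total_CD45", all_subsets=subset_ids)
        info = study.truth.subset_info.set_index("subset_id")
        coll = pd.DataFrame({
            "network2": freq.values[
                info[info["module"] == "network2"].index].sum(axis=1)})
        out = cn.stratify_patients(coll, study.metadata)
        flagged = set(out.loc[out["flagged"], "subject_id"])
        assert flagged == set(study.truth.high_network2_subjects)


def test_edge_list_threshold():
    rho = _block_rho([3, 3], [0.9, 0.9], between=0.1)
    edges = cn.edge_list(rho, threshold=0.4)
    assert len(edges) == 6  # within-block pairs only
    assert (edges["rho"] >= 0.4).all()
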