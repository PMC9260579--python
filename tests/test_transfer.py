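"""LDA label transfer: fit, posteriors, rejection, concordance."""

import numpy as np
import pandas as pd
import pytest

import cytonet as cn
from cytonet.data import REJECTED, CellTable
from cytonet.transfer import EPS_NUM, _log_posteriors


def _cells(x, markers=None, samples=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    markers = markers or [f"m{i}" for i in range(x.shape[1])]
    samples = samples if samples is not None else np.repeat("s", len(x))
    return CellTable(values=x, markers=markers, sample_id=np.asarray(samples))


def _two_class_1d(n=400, mu=(0.0, 4.0), seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(mu[0], 1, n), rng.normal(mu[1], 1, n)])
    labels = np.repeat(["a", "b"], n)
    return _cells(x[:, None]), labels


class TestFitLDA:
    def test_point_mass_classes_recover_means(self):
        x = np.vstack([np.tile([1.0, 2.0], (40, 1)),
                       np.tile([5.0, 6.0], (40, 1))])
        labels = np.repeat(["a", "b"], 40)
        model = cn.fit_lda(_cells(x), labels)
        np.testing.assert_allclose(model.means[0], [1.0, 2.0])
        np.testing.assert_allclose(model.means[1], [5.0, 6.0])
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_permutation_invariance(self):
        cells, labels = _two_class_1d()
        model1 = cn.fit_lda(cells, labels)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cells.n_cells)
        model2 = cn.fit_lda(cells.subset(perm), labels[perm])
        np.testing.assert_allclose(model1.means, model2.means)
        np.testing.assert_allclose(model1.covariance, model2.covariance)

    def test_mean_consistency_on_gaussian_classes(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = np.vstack([rng.normal([0, 0, 0], 1.0, (n, 3)),
                       rng.normal([3, 3, 3], 1.0, (n, 3))])
        labels = np.repeat(["a", "b"], n)
        model = cn.fit_lda(_cells(x), labels)
        assert np.all(np.abs(model.means[0] - 0) < 3 / np.sqrt(n))
        assert np.all(np.abs(model.means[1] - 3) < 3 / np.sqrt(n))

    def test_small_class_rejected(self):
        x = np.vstack([np.zeros((2, 3)), np.ones((50, 3))])
        labels = np.array(["a"] * 2 + ["b"] * 50)
        with pytest.raises(ValueError, match="cells"):
            cn.fit_lda(_cells(x), labels)

    def test_json_round_trip(self, tmp_path):
        cells, labels = _two_class_1d()
        model = cn.fit_lda(cells, labels)
        model.to_json(tmp_path / "lda.json")
        back = cn.LDAModel.from_json(tmp_path / "lda.json")
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.covariance, model.covariance)
        assert back.classes == model.classes


class TestPredictWithRejection:
    def _unit_model(self, mus=(0.0, 4.0)):
        return cn.LDAModel(
            classes=["a", "b"],
            means=np.array([[mus[0]], [mus[1]]]),
            covariance=np.array([[1.0]]),
            priors=np.array([0.5, 0.5]),
            markers=["m0"],
        )

    def test_closed_form_logistic_posterior_1d(self):
        """Equal-prior N(0,1) vs N(4,1): posterior of class a at x=0 is
        1/(1+exp(-8)); assigned at tau=0.95, rejected at tau=1."""
        model = self._unit_model()
        cells = _cells([[0.0]])
        post = cn.posterior_matrix(model, cells)[0]
        expected = 1.0 / (1.0 + np.exp(-8.0))
        assert post[0] == pytest.approx(expected, abs=1e-12)
        r95 = cn.predict_with_rejection(model, cells, tau=0.95)
        assert r95.labels[0] == "a"
        r100 = cn.predict_with_rejection(model, cells, tau=1.0)
        assert r100.labels[0] == REJECTED

    def test_equidistant_cell_rejected(self):
        model = self._unit_model()
        res = cn.predict_with_rejection(model, _cells([[2.0]]), tau=0.95)
        assert res.labels[0] == REJECTED
        assert res.max_posterior[0] == pytest.approx(0.5)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(0)
        cells, labels = _two_class_1d()
        model = cn.fit_lda(cells, labels)
        probe = _cells(rng.normal(2, 3, (100, 1)))
        post = cn.posterior_matrix(model, probe)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_tau_to_zero_equals_plain_argmax_bruteforce(self):
        """At tau -> 0+ the classifier is plain LDA argmax; checked
        against a direct quadratic-form implementation on 5-marker toys."""
        rng = np.random.default_rng(3)
        k, d, n = 4, 5, 300
        mus = rng.normal(0, 4, (k, d))
        x = mus[rng.integers(0, k, n)] + rng.normal(0, 1, (n, d))
        labels = np.array([f"c{i}" for i in rng.integers(0, k, n)])
        # ensure every class populated enough
        labels[:k * (d + 1)] = np.repeat([f"c{i}" for i in range(k)], d + 1)
        model = cn.fit_lda(_cells(x), labels)
        res = cn.predict_with_rejection(model, _cells(x), tau=1e-9)
        assert not (res.labels == REJECTED).any()
        inv = np.linalg.inv(model.covariance)
        scores = np.stack([
            np.log(p) - 0.5 * np.einsum("ij,jk,ik->i", x - mu, inv, x - mu)
            for p, mu in zip(model.priors, model.means)], axis=1)
        brute = np.array(model.classes)[scores.argmax(axis=1)]
        assert (res.labels == brute).all()
        # and posterior agreement with brute-force softmax
        brute_post = np.exp(scores - scores.max(axis=1, keepdims=True))
        brute_post /= brute_post.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            np.exp(_log_posteriors(model, x)), brute_post, atol=1e-10)

    def test_matched_fraction_monotone_in_tau(self):
        cells, labels = _two_class_1d(mu=(0.0, 2.0))
        model = cn.fit_lda(cells, labels)
        fracs = [cn.predict_with_rejection(model, cells, tau=t).matched_fraction
                 for t in (0.5, 0.8, 0.95, 0.99, 1.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_agrees_with_sklearn_lda(self):
        """Cross-check assignments against scikit-learn's LDA classifier
        on well-separated classes."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 1, (300, 3)),
                       rng.normal(4, 1, (300, 3))])
        labels = np.repeat(["a", "b"], 300)
        model = cn.fit_lda(_cells(x), labels)
        res = cn.predict_with_rejection(model, _cells(x), tau=1e-9)
        sk = LinearDiscriminantAnalysis().fit(x, labels)
        agree = (res.labels == sk.predict(x)).mean()
        assert agree > 0.999

    def test_invalid_tau(self):
        model = self._unit_model()
        with pytest.raises(ValueError, match="tau"):
            cn.predict_with_rejection(model, _cells([[0.0]]), tau=0.0)


class TestConcordance:
    def test_identical_matrices(self):
        x = pd.DataFrame(np.random.default_rng(0).uniform(0, 10, (6, 4)))
        assert cn.frequency_concordance(x, x) == pytest.approx(1.0)

    def test_noise_decreases_r(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.uniform(0, 10, (30, 10)))
        rs = []
        for sd in (0.1, 1.0, 5.0, 20.0):
            noisy = x + rng.normal(0, sd, x.shape)
            rs.append(cn.frequency_concordance(x, noisy))
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_zero_variance_rejected(self):
        x = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError, match="variance"):
            cn.frequency_concordance(x, x)


class TestBloodMatching:
    def test_blood_from_training_distribution_matches(self):
        cells, labels = _two_class_1d(mu=(0.0, 8.0))
        model = cn.fit_lda(cells, labels)
        res, per_subset = cn.match_blood_to_tissue(model, cells, tau=0.95)
        assert res.matched_fraction > 0.99
        assert per_subset.sum() == pytest.approx(res.matched_fraction)

    def test_far_cells_confident_but_flagged_as_outliers(self):
        """Posterior normalization can assign far-away cells with high
        confidence; the Mahalanobis flag catches them as novelty."""
        cells, labels = _two_class_1d(mu=(0.0, 8.0))
        model = cn.fit_lda(cells, labels)
        far = _cells(np.full((50, 1), 30.0))
        res = cn.predict_with_rejection(model, far, tau=0.95)
        assert (res.labels != REJECTED).all()
        flags = cn.mahalanobis_outliers(model, far)
        assert flags.all()
        near = _cells(np.zeros((50, 1)))
        assert not cn.mahalanobis_outliers(model, near).any()

    def test_ibd_blood_enriched_for_activated_subset(
            self, primary_study, primary_config, subset_ids):
        """The generator's activated EM CD4 blood spike-in: frequency of
        blood cells matched to that intestinal subset is higher in IBD
        than control subjects (one-sided Mann-Whitney)."""
        from scipy.stats import mannwhitneyu

        gut = primary_study.cells_for(primary_study.intestinal_mask())
        model = cn.fit_lda(gut, gut.label)
        meta = primary_study.metadata
        blood_meta = meta[(meta["tissue"] == "blood")
                          & ~meta["is_internal_control"]]
        blood = primary_study.cells_for(
            (meta["tissue"] == "blood") & ~meta["is_internal_control"])
        res, _ = cn.match_blood_to_tissue(
            model, blood, tau=0.95, metadata=meta, all_subsets=subset_ids)
        freq = res.pred_freq.values["cd4_act_em"]
        m = blood_meta.set_index("sample_id").loc[freq.index]
        ibd = freq[(m["diagnosis"] != "control").to_numpy()]
        ctrl = freq[(m["diagnosis"] == "control").to_numpy()]
        assert mannwhitneyu(ibd, ctrl, alternative="greater").pvalue < 0.05
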