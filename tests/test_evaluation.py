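import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import lmewscore as lw
from lmewscore import CohortTable, WScoreTable
from lmewscore.evaluation import (
    center_prediction_experiment,
    disease_classification_experiment,
    pca_lda_classify,
)

from conftest import make_toy_cohort


class TestPcaLdaClassify:
    def test_null_two_identical_gaussians(self):
        rng = np.random.default_rng(50)
        X = rng.normal(size=(1000, 68))
        labels = np.repeat(["A", "B"], 500)
        res = pca_lda_classify(X, labels, n_repeats=10, seed=1)
        # in-sample LDA on a limited number of PCs retains slight optimism
        assert 0.45 <= res.accuracy <= 0.60

    def test_perfect_separation(self):
        rng = np.random.default_rng(51)
        X = rng.normal(size=(200, 10))
        labels = np.repeat(["CN", "AD"], 100)
        X[labels == "AD", 0] += 10.0
        res = pca_lda_classify(X, labels, n_repeats=5, seed=2)
        assert res.accuracy == 1.0
        assert res.positive_label == "AD"

    def test_one_dimensional_bayes_rate(self):
        # equal-variance Gaussians at distance 2 sigma: accuracy -> Phi(1)
        rng = np.random.default_rng(52)
        n = 4000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])[:, None]
        labels = np.repeat(["A", "B"], n)
        res = pca_lda_classify(X, labels, n_repeats=5, seed=3)
        assert abs(res.accuracy - norm.cdf(1.0)) < 0.02

    def test_mean_fields_equal_mean_of_repeats(self):
        rng = np.random.default_rng(53)
        X = rng.normal(size=(60, 5))
        labels = np.repeat(["CN", "AD"], 30)
        X[labels == "AD"] += 0.5
        res = pca_lda_classify(X, labels, n_repeats=8, seed=4)
        assert res.accuracy == pytest.approx(np.mean(res.per_repeat_accuracy))
        assert res.sensitivity == pytest.approx(np.mean(res.per_repeat_sensitivity))

    def test_undersampling_balances_classes(self):
        rng = np.random.default_rng(54)
        X = rng.normal(size=(130, 4))
        labels = np.array(["CN"] * 100 + ["AD"] * 30)
        res = pca_lda_classify(X, labels, n_repeats=3, seed=5)
        assert res.n_per_class == 30

    def test_minority_too_small(self):
        X = np.zeros((12, 3))
        labels = np.array(["CN"] * 10 + ["AD"] * 2)
        with pytest.raises(ValueError, match="minority"):
            pca_lda_classify(X, labels)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(55)
        X = rng.normal(size=(80, 6))
        labels = np.repeat(["A", "B"], 40)
        a = pca_lda_classify(X, labels, n_repeats=5, seed=9)
        b = pca_lda_classify(X, labels, n_repeats=5, seed=9)
        np.testing.assert_array_equal(a.per_repeat_accuracy, b.per_repeat_accuracy)

    def test_holdout_mode_less_optimistic_than_insample_null(self):
        rng = np.random.default_rng(56)
        X = rng.normal(size=(400, 30))
        labels = np.repeat(["A", "B"], 200)
        ins = pca_lda_classify(X, labels, n_repeats=10, seed=6)
        hold = pca_lda_classify(X, labels, n_repeats=10, seed=6, holdout=True)
        assert hold.accuracy <= ins.accuracy + 0.02

    def test_label_permutation_is_chance(self):
        rng = np.random.default_rng(57)
        X = rng.normal(size=(300, 8))
        X[:150] += 1.0                      # real structure ...
        labels = rng.permutation(np.repeat(["A", "B"], 150))  # ... shuffled away
        res = pca_lda_classify(X, labels, n_repeats=20, seed=7)
        mc_se = 0.5 / np.sqrt(300)
        assert abs(res.accuracy - 0.5) < 0.06 + 3 * mc_se


class TestCenterPrediction:
    def test_noise_gives_chance_level(self):
        rng = np.random.default_rng(60)
        n, K = 400, 12
        feats = rng.normal(size=(n, K))
        centers = np.repeat([f"C{j}" for j in range(4)], n // 4)
        dx = np.array(["CN"] * n)
        res = center_prediction_experiment(
            {"raw": feats}, centers, dx, n_repeats=5, seed=1
        )["raw"]
        vals = res.matrix.to_numpy()
        iu = np.triu_indices(4, k=1)
        assert np.all(np.abs(vals[iu] - 0.5) < 0.12)

    def test_pair_count_ten_centers(self):
        rng = np.random.default_rng(61)
        n = 10 * 12
        feats = rng.normal(size=(n, 4))
        centers = np.repeat([f"C{j}" for j in range(10)], 12)
        dx = np.array(["CN"] * n)
        res = center_prediction_experiment(
            {"raw": feats}, centers, dx, n_repeats=2, seed=2
        )["raw"]
        vals = res.matrix.to_numpy()
        iu = np.triu_indices(10, k=1)
        assert np.isfinite(vals[iu]).sum() == 45

    def test_small_center_pair_skipped(self):
        rng = np.random.default_rng(62)
        feats = rng.normal(size=(42, 3))
        centers = np.array(["A"] * 20 + ["B"] * 20 + ["C"] * 2)
        dx = np.array(["CN"] * 42)
        with pytest.warns(UserWarning, match="skipped"):
            res = center_prediction_experiment(
                {"raw": feats}, centers, dx, n_repeats=2, seed=3
            )["raw"]
        assert ("A", "C") in res.skipped_pairs
        assert np.isfinite(res.matrix.loc["A", "B"])

    def test_separable_centers_detected(self):
        rng = np.random.default_rng(63)
        feats = rng.normal(size=(200, 6))
        centers = np.repeat(["A", "B"], 100)
        feats[centers == "B"] += 1.0
        dx = np.array(["CN"] * 200)
        res = center_prediction_experiment(
            {"raw": feats}, centers, dx, n_repeats=5, seed=4
        )["raw"]
        assert res.grand_mean > 0.8


class TestDiseaseClassification:
    def _cohort(self, seed=70, atrophied=True):
        rng = np.random.default_rng(seed)
        rows = []
        for ds in ("D1", "D2"):
            for dx, n in (("CN", 60), ("AD", 40)):
                f = rng.normal(size=(n, 8))
                if atrophied and dx == "AD":
                    f[:, :3] -= 1.0
                rows.append((ds, dx, f))
        feats = np.vstack([r[2] for r in rows])
        centers = np.concatenate([[r[0]] * len(r[2]) for r in rows])
        dx = np.concatenate([[r[1]] * len(r[2]) for r in rows])
        return feats, dx, centers

    def test_detects_disease_signal(self):
        feats, dx, centers = self._cohort()
        res = disease_classification_experiment(feats, dx, centers,
                                                n_repeats=10, seed=1)
        assert set(res.per_dataset) == {"D1", "D2"}
        for r in res.per_dataset.values():
            assert r.accuracy > 0.75
        assert res.merged is not None and res.merged.accuracy > 0.75

    def test_shuffled_labels_are_chance(self):
        # large groups keep the in-sample optimism of the null small
        rng = np.random.default_rng(71)
        feats = rng.normal(size=(1200, 8))
        feats[:, :3] += np.repeat([0.0, 1.0], 600)[:, None]  # center structure
        centers = np.repeat(["D1", "D2"], 600)
        dx = rng.permutation(np.array(["CN", "AD"] * 600))
        res = disease_classification_experiment(feats, dx, centers,
                                                n_repeats=20, seed=2)
        for r in res.per_dataset.values():
            assert abs(r.accuracy - 0.5) < 0.08

    def test_merged_excludes_pd_only_dataset(self):
        feats, dx, centers = self._cohort()
        rng = np.random.default_rng(72)
        pd_feats = rng.normal(size=(40, 8)) + 5.0  # wildly different PD center
        feats = np.vstack([feats, pd_feats])
        centers = np.concatenate([centers, ["D10"] * 40])
        dx = np.concatenate([dx, ["CN"] * 20 + ["PD"] * 20])
        res = disease_classification_experiment(feats, dx, centers,
                                                n_repeats=5, seed=3)
        assert "D10" in res.per_dataset  # CN-vs-PD still evaluated per dataset
        # merged pools only the AD-bearing datasets: undersampled class size
        # equals the AD count of D1+D2
        assert res.merged.n_per_class == 80

    def test_sensitivity_positive_class_is_patient(self):
        feats, dx, centers = self._cohort()
        res = disease_classification_experiment(feats, dx, centers,
                                                n_repeats=5, seed=4)
        r = res.per_dataset["D1"]
        assert r.positive_label == "patient"
        assert 0 <= r.sensitivity <= 1 and 0 <= r.specificity <= 1


class TestIntrasubject:
    def _paired(self, offset=0.2, seed=80, n=10):
        from lmewscore import CenterSpec, GeneratorConfig, GroupSpec

        g = GroupSpec(70.0, 6.0, 0.5, 14.0, 3.0, 1.4e6, 1.5e5)
        K = 6
        add = np.zeros((2, K))
        add[1] = offset
        cfg = GeneratorConfig(
            centers=[CenterSpec("A", 50, g), CenterSpec("B", 50, g)],
            roi_names=tuple(f"roi{k}" for k in range(K)),
            base_thickness=np.full(K, 2.5),
            beta_true=np.zeros((4, K)),
            center_additive=add,
            center_scale=np.ones((2, K)),
            noise_sd=0.05,
            subject_sd=0.1,
            seed=seed,
        )
        return lw.generate_paired_cohort(cfg, n, "A", "B")

    def test_identical_wscores_give_full_reduction(self):
        sc = self._paired()
        raw = sc.cohort
        wdf = raw.df.copy()
        wdf[list(raw.roi_names)] = np.tile(
            np.arange(len(raw))[:, None] % 10, (1, raw.n_rois)
        ) * 0.1  # identical per subject across centers
        w = WScoreTable(wdf, raw.roi_names)
        res = lw.intrasubject_comparison(raw, w, np.full(raw.n_rois, 0.12))
        assert res.percent_reduction == pytest.approx(100.0)
        assert res.p_raw < 0.05

    def test_unpaired_subject_listed(self):
        sc = self._paired()
        df = sc.cohort.df.iloc[1:].reset_index(drop=True)
        broken = CohortTable(df, sc.cohort.roi_names)
        wdf = df.copy()
        w = WScoreTable(wdf, sc.cohort.roi_names)
        with pytest.raises(ValueError, match="pair_0000"):
            lw.intrasubject_comparison(broken, w, np.full(sc.cohort.n_rois, 0.12))

    def test_zero_center_effect_reduction_near_zero(self):
        sc = self._paired(offset=0.0, n=200)
        raw = sc.cohort
        # "w-scores" here: same data standardized by the same scale, so the
        # reduction can only reflect noise
        wdf = raw.df.copy()
        wdf[list(raw.roi_names)] = raw.thickness() / 0.12
        w = WScoreTable(wdf, raw.roi_names)
        res = lw.intrasubject_comparison(raw, w, np.full(raw.n_rois, 0.12))
        assert abs(res.percent_reduction) < 1e-9  # identical scaling: no change


class TestScalability:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = lw.default_discovery_config(scale=0.12, seed=21,
                                          roi_names=lw.DK_ROI_NAMES[:6])
        cohort = lw.generate_cohort(cfg).cohort
        cn = cohort.cn_only()
        reference = lw.fit_lme(cn)
        return cn, reference

    def test_subset_enumeration_counts(self, setup):
        cn, reference = setup
        keep = cn.df["center_id"].isin(["D1", "D2", "D5", "D8"]).to_numpy()
        small = cn.subset(keep)
        ref_small = lw.fit_lme(small)
        res = lw.scalability_experiment(small, "D1", ref_small)
        counts = res.per_subset.groupby("n_train").size().to_dict()
        assert counts == {1: 3, 2: 3, 3: 1}

    def test_endpoint_equals_leave_one_out_model(self, setup):
        cn, reference = setup
        res = lw.scalability_experiment(
            cn, "D9", reference, max_subsets_per_size=2, seed=0
        )
        others = [c for c in cn.centers if c != "D9"]
        full = lw.fit_lme(cn.subset(cn.df["center_id"].isin(others).to_numpy()))
        test_rows = cn.subset((cn.df["center_id"] == "D9").to_numpy())
        w = lw.score_lme(full, test_rows, unseen_center_policy="marginal").scores()
        ref_w = lw.score_lme(reference, test_rows).scores()
        expected = float(np.sqrt(np.mean((w - ref_w) ** 2))) / res.reference_iqr
        assert res.per_size_mean[9] == pytest.approx(expected)

    def test_subset_cap_respected(self, setup):
        cn, reference = setup
        res = lw.scalability_experiment(
            cn, "D9", reference, max_subsets_per_size=2, seed=1
        )
        counts = res.per_subset.groupby("n_train").size()
        assert (counts <= 2).all()


class TestAtrophyReport:
    @pytest.fixture(scope="class")
    def wscores(self):
        # large enough patient groups that group-mean ranks are stable
        cfg = lw.default_discovery_config(scale=0.45, seed=23)
        cohort = lw.generate_cohort(cfg).cohort
        model = lw.fit_lme(cohort)
        return lw.score_lme(model, cohort)

    def test_seeded_rois_rank_most_negative(self, wscores):
        rep = lw.atrophy_report(wscores)
        from lmewscore.synthetic import AD_ATROPHY_ROIS, PD_ATROPHY_ROIS

        ad = rep[rep.diagnosis == "AD"]
        assert set(ad.nsmallest(10, "mean_wscore").roi) == set(AD_ATROPHY_ROIS)
        pd_rows = rep[rep.diagnosis == "PD"]
        assert set(PD_ATROPHY_ROIS) <= set(pd_rows.nsmallest(10, "mean_wscore").roi)

    def test_cn_reference_group_near_zero(self, wscores):
        rep = lw.atrophy_report(wscores, groups=("CN",))
        assert np.all(np.abs(rep.mean_wscore) < 0.25)

    def test_no_patients_errors(self, toy_cohort):
        model = lw.fit_lme(toy_cohort)
        w = lw.score_lme(model, toy_cohort)
        with pytest.raises(ValueError, match="patient"):
            lw.atrophy_report(w)
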