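"""Cross-validation machinery, diagnostic metrics and experiment runners."""

import numpy as np
import pytest
from scipy import stats

from neurofuse import (DataError, RunConfig, SyntheticSpec, compute_metrics,
                       generate_synthetic, run_ablation, run_cv,
                       run_modality_combinations, silhouette_score,
                       stratified_kfold, two_sample_t_test)
from neurofuse.evaluation import roc_coordinates


class TestStratifiedKFold:
    def test_balanced_twenty_subjects(self):
        y = np.array([0] * 10 + [1] * 10)
        folds = stratified_kfold(y, 10, seed=0)
        for _, test_idx in folds:
            assert len(test_idx) == 2
            assert y[test_idx].sum() == 1  # one case, one control each

    def test_partition_property(self):
        y = np.array([0] * 23 + [1] * 17)
        folds = stratified_kfold(y, 5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(40))
        for (_, a), (_, b) in zip(folds, folds[1:]):
            assert np.intersect1d(a, b).size == 0

    def test_deterministic(self):
        y = np.array([0] * 15 + [1] * 15)
        f1 = stratified_kfold(y, 5, seed=42)
        f2 = stratified_kfold(y, 5, seed=42)
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            np.testing.assert_array_equal(te1, te2)

    def test_class_ratio_within_one(self):
        y = np.array([0] * 31 + [1] * 19)
        for _, te in stratified_kfold(y, 5, seed=3):
            expected = 19 / 50 * len(te)
            assert abs(y[te].sum() - expected) <= 1

    def test_small_class_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(DataError, match="fewer"):
            stratified_kfold(y, 5, seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        acc, auc, sen, spe = compute_metrics(y, s, 0.5)
        assert (acc, auc, sen, spe) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_table(self):
        # TP=3, FN=1, TN=2, FP=2 at cutoff 0.5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.3, 0.6, 0.7])
        acc, auc, sen, spe = compute_metrics(y, s, 0.5)
        assert sen == pytest.approx(0.75)
        assert spe == pytest.approx(0.5)
        assert acc == pytest.approx(0.625)

    def test_auc_is_rank_statistic(self):
        """AUC equals the normalized Mann-Whitney U (ties counted half)."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = np.round(rng.uniform(size=40), 1)  # force ties
        _, auc, _, _ = compute_metrics(y, s, 0.5)
        u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3 * s + 2])
    def test_auc_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 10)
        s = rng.uniform(size=20)
        _, auc1, _, _ = compute_metrics(y, s, 0.5)
        _, auc2, _, _ = compute_metrics(y, transform(s), 0.5)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_calibration_free_auc(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.48, 0.49, 0.50, 0.51])  # all near the cutoff
        _, auc, _, _ = compute_metrics(y, s, 0.5)
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="classes"):
            compute_metrics(np.array([1, 1]), np.array([0.5, 0.6]), 0.5)


class TestTTest:
    def test_identical_samples(self):
        t, p = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t, _ = two_sample_t_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)

    def test_matches_welch_formula(self):
        a = np.array([0.8, 0.82, 0.84])
        b = np.array([0.7, 0.72, 0.74])
        t, p = two_sample_t_test(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        assert t == pytest.approx(t_expected, abs=1e-6)
        assert p == pytest.approx(p_expected, abs=1e-6)

    def test_degenerate_equal_constants(self):
        t, p = two_sample_t_test([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_sample_rejected(self):
        with pytest.raises(DataError):
            two_sample_t_test([1.0], [1.0, 2.0])


class TestSilhouette:
    def test_far_apart_tight_clusters_near_one(self):
        X = np.array([[0.0, 0], [0.1, 0], [100, 0], [100.1, 0]])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_score(X, labels) > 0.99

    def test_matches_brute_force_hand_instance(self):
        X = np.array([[0.0, 0], [1, 0], [0.5, 1], [10, 0], [11, 0], [10.5, 1]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        got = silhouette_score(X, labels)
        # per-point brute force: a = mean intra, b = mean to other cluster
        vals = []
        for i in range(6):
            same = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
            b = np.mean([np.linalg.norm(X[i] - X[j]) for j in other])
            vals.append((b - a) / max(a, b))
        assert got == pytest.approx(np.mean(vals), abs=1e-9)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 5))
        labels = rng.integers(0, 2, 200)
        assert abs(silhouette_score(X, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(DataError, match="clusters"):
            silhouette_score(np.zeros((4, 2)), np.zeros(4, dtype=int))


def _mini_cohort(seed=0, n=60):
    spec = SyntheticSpec(n_subjects=n, n_modalities=2, dims=(6, 10),
                        class_sep=6.0, modality_shift=3.0, seed=seed)
    return generate_synthetic(spec)


class TestRunCV:
    def test_report_structure(self):
        ds = _mini_cohort()
        cfg = RunConfig(epochs=15, seed=0, d_c=6)
        report = run_cv(ds, cfg, k=3)
        assert len(report.folds) == 3
        for f in report.folds:
            assert 0 <= f.acc <= 1 and 0 <= f.auc <= 1
            assert f.fusion_weights.sum() == pytest.approx(1.0, abs=1e-9)
        all_test = np.concatenate([f.test_idx for f in report.folds])
        assert sorted(all_test) == list(range(60))

    def test_metrics_self_consistent_with_stored_scores(self):
        ds = _mini_cohort(seed=1)
        cfg = RunConfig(epochs=15, seed=1, d_c=6)
        report = run_cv(ds, cfg, k=3)
        for f in report.folds:
            acc, auc, sen, spe = compute_metrics(ds.labels[f.test_idx],
                                                 f.scores, cfg.cutoff)
            assert (acc, auc, sen, spe) == (f.acc, f.auc, f.sen, f.spe)

    def test_json_and_table_render(self, tmp_path):
        ds = _mini_cohort(seed=2)
        report = run_cv(ds, RunConfig(epochs=10, seed=2, d_c=6), k=2)
        text = report.to_json(tmp_path / "m.json")
        assert (tmp_path / "m.json").read_text() == text
        table = report.table()
        assert "ACC" in table and "±" in table


class TestRunAblation:
    def test_full_vs_full_zero_difference(self):
        ds = _mini_cohort(seed=3)
        cfg = RunConfig(epochs=10, seed=3, d_c=6)
        out = run_ablation(ds, cfg, ["full", "full"], k=2)
        cmp = out["comparisons"]["full_vs_full"]
        assert cmp["auc_diff_mean"] == 0.0
        assert cmp["p"] == 1.0

    def test_variants_share_folds(self):
        ds = _mini_cohort(seed=4)
        cfg = RunConfig(epochs=10, seed=4, d_c=6)
        out = run_ablation(ds, cfg, ["full", "no_fusion"], k=2)
        f_full = out["reports"]["full"].folds
        f_nf = out["reports"]["no_fusion"].folds
        for a, b in zip(f_full, f_nf):
            np.testing.assert_array_equal(a.test_idx, b.test_idx)
        assert all(f.fusion_weights is None for f in f_nf)

    def test_unknown_variant_rejected(self):
        ds = _mini_cohort(seed=5)
        with pytest.raises(DataError, match="unknown variant"):
            run_ablation(ds, RunConfig(epochs=1, d_c=6), ["full", "typo"], k=2)


class TestModalityCombinations:
    def test_full_subset_reproduces_run_cv(self):
        ds = _mini_cohort(seed=6)
        cfg = RunConfig(epochs=10, seed=6, d_c=6)
        names = [b.name for b in ds.blocks]
        combo = run_modality_combinations(ds, cfg, [names], k=2)
        direct = run_cv(ds, cfg, k=2)
        rep = combo["subsets"]["+".join(names)]
        for a, b in zip(rep.folds, direct.folds):
            assert a.auc == b.auc and a.acc == b.acc
        w = combo["fusion_weights"]
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)

    def test_informative_modality_beats_noise_modality(self):
        spec = SyntheticSpec(n_subjects=80, n_modalities=2, dims=(8, 10),
                            class_sep=6.0, informative_modalities=(0,), seed=7)
        ds = generate_synthetic(spec)
        cfg = RunConfig(epochs=40, seed=7, d_c=6)
        combo = run_modality_combinations(ds, cfg, [["MOD0"], ["MOD1"]], k=3)
        assert (combo["subsets"]["MOD0"].mean("auc")
                >= combo["subsets"]["MOD1"].mean("auc"))

    def test_empty_subset_rejected(self):
        ds = _mini_cohort(seed=8)
        with pytest.raises(DataError, match="empty"):
            run_modality_combinations(ds, RunConfig(epochs=1, d_c=6), [[]], k=2)


def test_roc_coordinates_shape():
    y = np.array([0, 1, 0, 1, 1])
    s = np.array([0.1, 0.9, 0.4, 0.6, 0.8])
    coords = roc_coordinates(y, s)
    assert coords.shape[1] == 3
    assert coords[0, 0] == 0.0  # starts at the origin fpr
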