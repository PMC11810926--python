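import numpy as np
import pandas as pd
import pytest

from methmark.combo_eval import (
    EvalReport,
    FeatureTable,
    choose_probes,
    compute_metrics,
    enumerate_panels,
    evaluate_panel,
    extract_features,
    fit_and_score,
    reports_frame,
    select_optimal,
    train_eval,
    universal_model,
)
from methmark.functional_clustering import FunctionalGroups
from methmark.io_formats import RunConfig

from conftest import make_beta_matrix, make_manifest


def groups_of(sizes):
    labels = "abcdefg"
    groups = {}
    gi = 0
    for lab, size in zip(labels, sizes):
        groups[lab] = tuple(f"g{gi + j}" for j in range(size))
        gi += size
    return FunctionalGroups(groups=groups)


def gaussian_table(rng, genes, informative, n_tumor, n_normal, delta=0.6,
                   sigma=0.05, base=0.2, cancer=""):
    """Feature table with tumor mean base+delta on informative genes."""
    rows = {}
    labels = ["tumor"] * n_tumor + ["normal"] * n_normal
    idx = [f"s{i}" for i in range(n_tumor + n_normal)]
    for gene in genes:
        mu_n = base
        mu_t = base + (delta if gene in informative else 0.0)
        vals = np.concatenate([
            rng.normal(mu_t, sigma, n_tumor),
            rng.normal(mu_n, sigma, n_normal),
        ])
        rows[gene] = vals
    X = pd.DataFrame(rows, index=idx)
    y = pd.Series(labels, index=idx)
    return FeatureTable(X=X, y=y, cancer=cancer)


class TestEnumeratePanels:
    def test_five_two_one(self):
        assert len(enumerate_panels(groups_of([5, 2, 1]))) == 10

    def test_all_singletons(self):
        panels = enumerate_panels(groups_of([1, 1, 1]))
        assert panels == [("g0", "g1", "g2")]

    def test_two_by_two(self):
        assert len(enumerate_panels(groups_of([2, 2]))) == 4

    def test_panel_has_one_gene_per_group(self):
        groups = groups_of([3, 2])
        for panel in enumerate_panels(groups):
            for members in groups.groups.values():
                assert len(set(panel) & set(members)) == 1


class TestComputeMetrics:
    def test_hand_computed_confusion_matrix_ten_subjects(self):
        y_true = ["tumor"] * 6 + ["normal"] * 4
        y_pred = ["tumor", "tumor", "tumor", "tumor", "normal", "tumor",
                  "normal", "normal", "tumor", "normal"]
        # tp=5 fn=1 fp=1 tn=3
        m = compute_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(8 / 10)
        assert m["recall"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(5 / 6)
        assert m["f_score"] == pytest.approx(5 / 6)

    def test_f_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = rng.choice(["tumor", "normal"], 30)
            y_pred = rng.choice(["tumor", "normal"], 30)
            m = compute_metrics(y_true, y_pred)
            if m["precision"] + m["recall"] > 0:
                expected = (2 * m["precision"] * m["recall"]
                            / (m["precision"] + m["recall"]))
                assert m["f_score"] == pytest.approx(expected)
            for v in m.values():
                assert 0.0 <= v <= 1.0

    def test_no_predicted_positives(self):
        m = compute_metrics(["tumor", "normal"], ["normal", "normal"])
        assert m["precision"] == 0.0
        assert m["f_score"] == 0.0


@pytest.fixture
def small_matrix():
    # 2 genes x 2 probes; G1's first probe carries a large effect
    samples = [f"t{i}" for i in range(6)] + [f"n{i}" for i in range(6)]
    groups = {s: ("tumor" if s.startswith("t") else "normal") for s in samples}
    data = {
        "G1_p0": [0.8, 0.82, 0.78, 0.81, 0.79, 0.8, 0.3, 0.31, 0.29, 0.3, 0.32, 0.28],
        "G1_p1": [0.52, 0.5, 0.51, 0.49, 0.5, 0.51, 0.3, 0.31, 0.29, 0.3, 0.28, 0.32],
        "G2_p0": [0.7, 0.72, 0.68, 0.7, 0.71, 0.69, 0.7, 0.71, 0.7, 0.69, 0.72, 0.68],
    }
    matrix = make_beta_matrix(data, groups, samples)
    manifest = make_manifest({
        "G1_p0": ("G1", "promoter"),
        "G1_p1": ("G1", "other"),
        "G2_p0": ("G2", "promoter"),
    })
    return matrix, manifest


class TestFeatureExtraction:
    def test_single_gene_feature_row(self, small_matrix):
        matrix, manifest = small_matrix
        ft = extract_features(matrix, manifest, ["G2"], {"G2": "G2_p0"})
        assert ft.X.loc["t0", "G2"] == pytest.approx(0.7)
        assert list(ft.X.columns) == ["G2"]

    def test_max_abs_dbeta_probe_chosen(self, small_matrix):
        matrix, manifest = small_matrix
        choice = choose_probes(matrix, manifest, ["G1"])
        assert choice["G1"] == "G1_p0"  # |Δβ| = 0.5 beats 0.2

    def test_probe_choice_on_train_only(self, small_matrix):
        matrix, manifest = small_matrix
        train_ids = ["t0", "t1", "t2", "n0", "n1", "n2"]
        choice = choose_probes(matrix, manifest, ["G1"], samples=train_ids)
        ft_train = extract_features(matrix, manifest, ["G1"], choice,
                                    samples=train_ids)
        ft_test = extract_features(
            matrix, manifest, ["G1"], choice,
            samples=[s for s in matrix.sample_ids if s not in train_ids],
        )
        assert list(ft_train.X.columns) == list(ft_test.X.columns)
        # test features come from the same probe chosen on train
        assert ft_test.X.loc["t3", "G1"] == matrix.values.loc["G1_p0", "t3"]

    def test_missing_gene_error(self, small_matrix):
        matrix, manifest = small_matrix
        with pytest.raises(ValueError, match="G9"):
            choose_probes(matrix, manifest, ["G9"])

    def test_imputation_uses_given_medians(self, small_matrix):
        matrix, manifest = small_matrix
        matrix.values.loc["G2_p0", "t0"] = np.nan
        ft = extract_features(matrix, manifest, ["G2"], {"G2": "G2_p0"},
                              impute_medians={"G2": 0.123})
        assert ft.X.loc["t0", "G2"] == pytest.approx(0.123)

    def test_gene_mean_mode(self, small_matrix):
        matrix, manifest = small_matrix
        ft = extract_features(matrix, manifest, ["G1"], {},
                              feature_mode="gene_mean")
        expected = (matrix.values.loc["G1_p0", "t0"]
                    + matrix.values.loc["G1_p1", "t0"]) / 2
        assert ft.X.loc["t0", "G1"] == pytest.approx(expected)


class TestTrainEval:
    def test_separated_features_high_accuracy(self):
        cfg = RunConfig(seed=0)
        accs = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            ft = gaussian_table(rng, ["g0"], {"g0"}, 100, 100,
                                delta=0.6, sigma=0.05)
            rep_cfg = RunConfig(seed=rep)
            accs.append(train_eval(ft, rep_cfg).accuracy)
        assert min(accs) >= 0.95

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(7)
        ft = gaussian_table(rng, ["g0"], {"g0"}, 100, 100, delta=0.6)
        shuffled = pd.Series(rng.permutation(ft.y.to_numpy()), index=ft.y.index)
        report = train_eval(FeatureTable(X=ft.X, y=shuffled), RunConfig(seed=1))
        assert abs(report.accuracy - 0.5) < 0.2

    def test_all_tumor_test_flagged(self):
        rng = np.random.default_rng(3)
        train = gaussian_table(rng, ["g0"], {"g0"}, 50, 50, delta=0.6)
        test = gaussian_table(rng, ["g0"], {"g0"}, 20, 0, delta=0.6)
        report = fit_and_score(train, test, RunConfig(seed=0))
        assert "no_normal_in_test" in report.flags
        assert report.recall == pytest.approx(report.accuracy)

    def test_single_class_training_error(self):
        rng = np.random.default_rng(3)
        train = gaussian_table(rng, ["g0"], {"g0"}, 20, 0)
        test = gaussian_table(rng, ["g0"], {"g0"}, 5, 5)
        with pytest.raises(ValueError, match="both classes"):
            fit_and_score(train, test, RunConfig(seed=0))

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(9)
        ft = gaussian_table(rng, ["g0", "g1"], {"g0"}, 60, 60, delta=0.3)
        a = train_eval(ft, RunConfig(seed=5))
        b = train_eval(ft, RunConfig(seed=5))
        assert a == b

    def test_evaluate_panel_deterministic(self, small_matrix):
        matrix, manifest = small_matrix
        cfg = RunConfig(seed=2, test_fraction=0.34,
                        min_group_size_after_outliers=1)
        a = evaluate_panel(matrix, manifest, ["G1"], cfg)
        b = evaluate_panel(matrix, manifest, ["G1"], cfg)
        assert a == b
        assert a.accuracy == 1.0


class TestSelectOptimal:
    def report(self, panel, accuracy, cancer="c"):
        return EvalReport(panel=tuple(panel), cancer=cancer, accuracy=accuracy,
                          recall=1, precision=1, f_score=1, n_train=10,
                          n_test=5, seed=0)

    def test_argmax(self):
        reports = [self.report(["a"], 0.93), self.report(["b"], 0.88),
                   self.report(["c"], 0.90)]
        assert select_optimal(reports) == ("a",)

    def test_average_across_cancers(self):
        reports = [self.report(["a"], 0.9, "c1"), self.report(["a"], 0.5, "c2"),
                   self.report(["b"], 0.8, "c1"), self.report(["b"], 0.8, "c2")]
        assert select_optimal(reports) == ("b",)

    def test_tie_prefers_fewer_genes(self):
        reports = [self.report(["a", "b", "c"], 0.9), self.report(["x"], 0.9)]
        assert select_optimal(reports) == ("x",)

    def test_tie_lexicographic(self):
        reports = [self.report(["b", "c", "d"], 0.9),
                   self.report(["a", "c", "d"], 0.9)]
        assert select_optimal(reports) == ("a", "c", "d")

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_optimal([])

    def test_planted_panel_recovered(self):
        # groups a={g0,g1}, b={g2,g3}, c={g4}; only g0 and g2 informative,
        # so the uniquely best one-per-group panel is (g0, g2, g4)
        groups = groups_of([2, 2, 1])
        panels = enumerate_panels(groups)
        genes = [f"g{i}" for i in range(5)]
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            ft = gaussian_table(rng, genes, {"g0", "g2"}, 250, 250,
                                delta=0.12, sigma=0.08, base=0.4)
            reports = []
            for panel in panels:
                sub = FeatureTable(X=ft.X[list(panel)], y=ft.y)
                reports.append(train_eval(sub, RunConfig(seed=seed)))
            if select_optimal(reports) == ("g0", "g2", "g4"):
                hits += 1
        assert hits >= 9


class TestUniversalModel:
    def make_tables(self, seed, cancers, invert=False, n=60):
        rng = np.random.default_rng(seed)
        tables = {}
        for cancer in cancers:
            delta = -0.5 if invert else 0.5
            tables[cancer] = gaussian_table(
                rng, ["g0", "g1"], {"g0"}, n, n, delta=delta,
                sigma=0.05, base=0.25, cancer=cancer,
            )
        return tables

    def test_transfer_to_unseen_cancer(self):
        train = self.make_tables(0, ["c1", "c2", "c3"])
        test = self.make_tables(1, ["c9"])
        out = universal_model(train, test, RunConfig(seed=0))
        assert out["c9"].accuracy >= 0.9
        assert out["c9"].cancer == "c9"

    def test_inverted_effect_fails(self):
        train = self.make_tables(0, ["c1", "c2"])
        test = self.make_tables(1, ["c9"], invert=True)
        out = universal_model(train, test, RunConfig(seed=0))
        assert out["c9"].accuracy <= 0.5

    def test_empty_test_error(self):
        train = self.make_tables(0, ["c1"])
        with pytest.raises(ValueError):
            universal_model(train, {}, RunConfig(seed=0))

    def test_feature_mismatch_error(self):
        train = self.make_tables(0, ["c1"])
        rng = np.random.default_rng(2)
        test = {"c9": gaussian_table(rng, ["other"], set(), 10, 10)}
        with pytest.raises(ValueError, match="differ"):
            universal_model(train, test, RunConfig(seed=0))


def test_reports_frame_columns():
    rep = EvalReport(panel=("a", "b"), cancer="c1", accuracy=0.9, recall=0.8,
                     precision=0.7, f_score=0.75, n_train=10, n_test=5, seed=0)
    df = reports_frame([rep])
    assert df.loc[0, "panel"] == "a+b"
    assert df.loc[0, "accuracy"] == 0.9
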