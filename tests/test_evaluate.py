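"""Baselines, summary statistics, pipeline orchestration and reports."""

import numpy as np
import pytest

import eegtwin as et

# Per-subject accuracies (percent) of the published comparison table:
# columns = tuned LS twin SVM, LDA, back-propagation net, PNN, ten subjects.
TABLE_COLUMNS = {
    "pso-ls-twin-svm": [88.19, 64.35, 93.42, 65.34, 76.35,
                        67.34, 75.23, 88.89, 78.34, 67.24],
    "lda": [87.24, 57.32, 91.34, 63.24, 54.87,
            70.23, 70.43, 83.25, 73.42, 70.78],
    "bp": [72.43, 62.34, 97.53, 71.34, 52.34,
           74.45, 74.14, 87.24, 76.35, 66.24],
    "pnn": [83.45, 61.35, 88.24, 70.12, 50.35,
            65.24, 58.33, 91.34, 73.24, 70.43],
}
TABLE_MEANS = {"pso-ls-twin-svm": 76.47, "lda": 72.21, "bp": 73.44, "pnn": 71.21}


class TestSummarize:
    @pytest.mark.parametrize("column", list(TABLE_COLUMNS))
    def test_published_column_means(self, column):
        """Mean of each published per-subject column matches its printed mean."""
        mean, _, _ = et.summarize(TABLE_COLUMNS[column])
        assert round(mean, 2) == TABLE_MEANS[column]

    def test_constant_list(self):
        mean, sd, se = et.summarize([80.0, 80.0, 80.0])
        assert (mean, sd, se) == (80.0, 0.0, 0.0)

    def test_two_point_closed_form(self):
        mean, sd, se = et.summarize([70.0, 90.0])
        assert mean == 80.0
        assert sd == pytest.approx(np.sqrt(200.0))  # 14.142...
        assert se == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            et.summarize([])

    def test_published_se_row_is_inconsistent(self):
        """The printed "SE" row matches neither the sample SD nor SD/sqrt(n).

        Documented discrepancy: for the first column the printed value is
        11.24 while the sample SD is ~10.66 and SD/sqrt(10) is ~3.37.  Both
        statistics are therefore emitted side by side.
        """
        _, sd, se = et.summarize(TABLE_COLUMNS["pso-ls-twin-svm"])
        assert sd == pytest.approx(10.66, abs=0.01)
        assert se == pytest.approx(3.37, abs=0.01)
        assert not np.isclose(11.24, sd, atol=0.5)
        assert not np.isclose(11.24, se, atol=0.5)


def _blob_features(rng, n=100, sep=8.0, d=2):
    x0 = rng.standard_normal((n, d)) + sep / 2
    x1 = rng.standard_normal((n, d)) - sep / 2
    return et.FeatureMatrix(np.vstack([x0, x1]),
                            np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)],
                            [f"f{i}" for i in range(d)])


class TestLDA:
    def test_separable_blobs(self, rng):
        feats = _blob_features(rng)
        assert et.baseline_lda(feats, folds=5, seed=0) >= 98.0

    def test_shuffled_labels_at_chance(self, rng):
        feats = _blob_features(rng)
        shuffled = et.FeatureMatrix(feats.values, rng.permutation(feats.labels),
                                    feats.feature_names)
        acc = et.baseline_lda(shuffled, folds=5, seed=0)
        assert abs(acc - 50.0) < 100 * 1.96 * np.sqrt(0.25 / 200)

    def test_symmetric_1d_threshold_at_zero(self, rng):
        """Classes at -1/+1 with equal variance: boundary within |0.05|."""
        x = np.r_[rng.standard_normal(500) * 0.3 - 1,
                  rng.standard_normal(500) * 0.3 + 1][:, None]
        y = np.r_[np.zeros(500, dtype=int), np.ones(500, dtype=int)]
        lda = et.LDAClassifier().fit(x, y)
        boundary = lda.threshold_ / lda.w_[0]
        assert abs(boundary) < 0.05


class TestPNN:
    def test_tiny_bandwidth_memorizes(self, rng):
        feats = _blob_features(rng, n=30, sep=2.0)
        pnn = et.PNNClassifier(bandwidth=1e-3).fit(feats.values, feats.labels)
        assert np.mean(pnn.predict(feats.values) == feats.labels) == 1.0

    def test_huge_bandwidth_predicts_majority(self, rng):
        """Flat densities with empirical priors degenerate to the majority class."""
        X = np.vstack([rng.standard_normal((80, 2)) + 2,
                       rng.standard_normal((20, 2)) - 2])
        y = np.r_[np.zeros(80, dtype=int), np.ones(20, dtype=int)]
        pnn = et.PNNClassifier(bandwidth=1e4, priors="empirical").fit(X, y)
        assert np.all(pnn.predict(rng.standard_normal((50, 2)) * 4) == 0)

    def test_separable_blobs(self, rng):
        feats = _blob_features(rng)
        assert et.baseline_pnn(feats, smoothing=1.0, folds=5, seed=0) >= 95.0

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            et.PNNClassifier(bandwidth=0.0)


@pytest.fixture(scope="module")
def fast_config(small_bank=None):
    return et.PipelineConfig(
        filter_bank=et.FilterBankSpec(bands=[(4, 8), (8, 12), (12, 16),
                                             (16, 24), (24, 32)]),
        outer_folds=5, band_folds=3,
        kernel=et.KernelSpec("rbf", gamma=0.5),
        seed=0,
    )


class TestPipeline:
    def test_strong_effect_high_accuracy(self, fast_config):
        cfg = et.SimulationConfig(n_trials_per_class=50, n_channels=8,
                                  erd_depth=0.8, seed=21)
        acc = et.run_pipeline(et.generate_subject(cfg, 0), fast_config)
        assert acc >= 90.0

    def test_no_effect_at_chance(self, fast_config):
        cfg = et.SimulationConfig(n_trials_per_class=50, n_channels=8,
                                  erd_depth=0.0, seed=21)
        acc = et.run_pipeline(et.generate_subject(cfg, 0), fast_config)
        assert abs(acc - 50.0) < 100 * 1.96 * np.sqrt(0.25 / 100)

    def test_rerun_identical(self, fast_config):
        cfg = et.SimulationConfig(n_trials_per_class=30, n_channels=8,
                                  erd_depth=0.5, seed=4)
        ep = et.generate_subject(cfg, 0)
        snapshot = et.PipelineConfig.from_dict(fast_config.to_dict())
        assert et.run_pipeline(ep, fast_config) == et.run_pipeline(ep, snapshot)

    def test_artifact_contaminated_subject_still_decodable(self, fast_config):
        """EOG channel is auto-detected, regressed out, and dropped."""
        cfg = et.SimulationConfig(n_trials_per_class=40, n_channels=8,
                                  erd_depth=0.8, artifact_rate=0.6,
                                  artifact_gain=8.0, seed=13)
        acc = et.run_pipeline(et.generate_subject(cfg, 0), fast_config)
        assert acc >= 85.0


class TestCompareMethods:
    def test_single_subject_single_method(self, fast_config):
        cfg = et.SimulationConfig(n_trials_per_class=30, n_channels=8,
                                  erd_depth=0.7, seed=8)
        report = et.compare_methods([et.generate_subject(cfg, 0)],
                                    ["ls-twin-svm"], fast_config)
        assert report.per_subject_accuracy.shape == (1, 1)
        assert report.mean[0] == report.per_subject_accuracy[0, 0]

    def test_report_structure_mirrors_published_table(self, fast_config):
        """3 subjects x 3 methods: accuracy matrix plus Mean/SD/SE rows."""
        subjects = [
            et.generate_subject(
                et.SimulationConfig(n_trials_per_class=30, n_channels=8,
                                    erd_depth=d, seed=31), i)
            for i, d in enumerate([0.3, 0.6, 0.9])
        ]
        report = et.compare_methods(subjects, ["ls-twin-svm", "lda", "pnn"],
                                    fast_config)
        df = report.to_dataframe()
        assert list(df.columns) == ["ls-twin-svm", "lda", "pnn"]
        assert list(df.index) == ["1", "2", "3", "Mean", "SD", "SE"]
        mean, sd, se = et.summarize(report.per_subject_accuracy[:, 0])
        assert report.mean[0] == pytest.approx(mean, abs=1e-9)
        assert report.standard_error[0] == pytest.approx(se, abs=1e-9)

    def test_shared_splits_reproducible(self, fast_config):
        cfg = et.SimulationConfig(n_trials_per_class=30, n_channels=8,
                                  erd_depth=0.6, seed=9)
        subjects = [et.generate_subject(cfg, 0)]
        a = et.compare_methods(subjects, ["ls-twin-svm", "lda"], fast_config)
        b = et.compare_methods(subjects, ["ls-twin-svm", "lda"], fast_config)
        np.testing.assert_array_equal(a.per_subject_accuracy,
                                      b.per_subject_accuracy)

    def test_unknown_method_rejected(self, fast_config, small_subject):
        with pytest.raises(ValueError, match="unknown method"):
            et.compare_methods([small_subject], ["boosted-trees"], fast_config)


class TestConfigRoundtrip:
    def test_yaml_roundtrip(self, tmp_path, fast_config):
        cfg = fast_config.replace(
            optimizer=et.OptimizerConfig(algorithm="pso", max_iterations=5,
                                         population=4, seed=2))
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        back = et.PipelineConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()
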