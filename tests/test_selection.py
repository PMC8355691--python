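"""Screening, per-method selection, repeated subsampling and consensus."""

import numpy as np
import pandas as pd
import pytest

from fusimorph.selection import (
    FrequencyTable,
    SelectionConfig,
    consensus_sets,
    repeated_selection,
    rfe,
    select_kbest,
    ttest_screen,
)


def toy_matrix(n=37, n_ruptured=12, informative=2, noise=10, delta=3.0, seed=0):
    """Small labelled matrix with `informative` strongly shifted features."""
    rng = np.random.default_rng(seed)
    labels = np.array(["ruptured"] * n_ruptured + ["unruptured"] * (n - n_ruptured))
    cols = {}
    for i in range(informative):
        shift = np.where(labels == "ruptured", delta, 0.0)
        cols[f"signal{i}"] = shift + rng.normal(0, 1, n)
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), labels


class TestScreen:
    def test_strong_effect_survives(self):
        X, y = toy_matrix(delta=5.0)
        kept = ttest_screen(X, y, alpha=0.1)
        assert "signal0" in kept and "signal1" in kept

    def test_constant_feature_excluded(self):
        X, y = toy_matrix()
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            kept = ttest_screen(X, y)
        assert "flat" not in kept

    def test_missing_values_excluded(self):
        X, y = toy_matrix()
        X.loc[0, "noise0"] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            kept = ttest_screen(X, y)
        assert "noise0" not in kept

    def test_null_calibration(self):
        # under the null each feature survives with probability ~ alpha
        rng = np.random.default_rng(123)
        n, p = 60, 1000
        labels = np.array(["ruptured"] * 30 + ["unruptured"] * 30)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        frac = len(ttest_screen(X, labels, alpha=0.1)) / p
        assert 0.07 < frac < 0.13

    def test_single_class_rejected(self):
        X, _ = toy_matrix()
        with pytest.raises(ValueError):
            ttest_screen(X, np.array(["ruptured"] * len(X)))


class TestKBest:
    def test_separator_ranks_first(self):
        X, y = toy_matrix(informative=1, delta=8.0)
        assert select_kbest(X, y, 1) == ["signal0"]

    def test_identity_when_k_equals_p(self):
        X, y = toy_matrix()
        assert set(select_kbest(X, y, X.shape[1])) == set(X.columns)

    def test_duplicate_informative_both_rank_above_noise(self):
        X, y = toy_matrix(informative=1, delta=6.0)
        X["signal_copy"] = X["signal0"] + np.random.default_rng(1).normal(0, 0.01, len(X))
        chosen = select_kbest(X, y, 2)
        assert set(chosen) == {"signal0", "signal_copy"}


class TestRFE:
    def test_jointly_separating_features_retained(self):
        rng = np.random.default_rng(5)
        n = 40
        labels = np.array(["ruptured"] * 20 + ["unruptured"] * 20)
        u = np.where(labels == "ruptured", 1.0, -1.0)
        X = pd.DataFrame(
            {
                "part1": u + rng.normal(0, 0.3, n),
                "noiseA": rng.normal(0, 1, n),
                "part2": -u + rng.normal(0, 0.3, n),
                "noiseB": rng.normal(0, 1, n),
            }
        )
        for estimator in ("linear_svm", "logreg_l2"):
            assert set(rfe(X, labels, estimator, 2)) == {"part1", "part2"}

    def test_identity_when_k_equals_p(self):
        X, y = toy_matrix(noise=3)
        assert set(rfe(X, y, "logreg_l2", X.shape[1])) == set(X.columns)

    def test_elimination_matches_single_fit_oracle(self):
        # with one elimination step, RFE must drop exactly the feature with
        # the smallest |coefficient| of a single full fit
        from sklearn.linear_model import LogisticRegression

        X, y = toy_matrix(informative=2, noise=1, delta=2.0, seed=9)
        Xs = (X - X.mean()) / X.std()
        clf = LogisticRegression(solver="liblinear").fit(
            Xs.to_numpy(), (y == "ruptured").astype(int)
        )
        weakest = Xs.columns[int(np.argmin(np.abs(clf.coef_[0])))]
        kept = rfe(X, y, "logreg_l2", X.shape[1] - 1)
        assert weakest not in kept

    def test_random_forest_variant_runs(self):
        X, y = toy_matrix(informative=1, noise=4, delta=6.0)
        assert "signal0" in rfe(X, y, "random_forest", 2, seed=3)


class TestRepeatedSelection:
    @pytest.fixture(scope="class")
    def table(self):
        X, y = toy_matrix(informative=2, noise=10, delta=6.0, seed=2)
        config = SelectionConfig(k=2, seed=5, methods=("kbest_t", "rfe_lr"))
        return repeated_selection(X, y, config)

    def test_separating_features_selected_every_round(self, table):
        assert table.counts["kbest_t"]["signal0"] == 30
        assert table.counts["kbest_t"]["signal1"] == 30

    def test_same_seed_reproducible(self):
        X, y = toy_matrix(informative=1, delta=6.0)
        config = SelectionConfig(k=2, seed=11, methods=("kbest_t", "rfe_lr"))
        t1 = repeated_selection(X, y, config)
        t2 = repeated_selection(X, y, config)
        assert t1.counts == t2.counts

    def test_counts_bounded_by_reps(self, table):
        for counter in table.counts.values():
            assert all(0 < c <= 30 for c in counter.values())
            assert sum(counter.values()) <= 30 * 2  # k selections per round

    def test_frame_layout(self, table):
        frame = table.to_frame(top=4)
        assert "kbest_t_feature" in frame.columns and "rfe_lr_freq" in frame.columns
        assert len(frame) == 4

    def test_k_capped_at_five(self):
        with pytest.raises(ValueError):
            SelectionConfig(k=6)


class TestConsensus:
    def test_reference_frequency_table_reproduces_top2_union(self):
        # a reference frequency table with known rankings; the union of each method's
        # two most frequent features is the five-feature headline set
        counts = {
            "kbest_t": {
                "Curvature_mean_PD": 26, "CrossArea_mean_PD2": 18,
                "Curvature_integration_P": 13, "CrossArea_max_PD2": 11,
                "Curvature_mean_P": 9, "Ratio_Dpnordnor1": 9,
            },
            "rfe_svm": {
                "Curvature_mean_PD": 23, "Curvature_integration_P": 22,
                "LineDist": 18, "Diameter_normalD2": 18,
                "Eccentricity_std_P2": 17, "PointDist": 6,
            },
            "rfe_lr": {
                "Curvature_mean_PD": 28, "Eccentricity_std_P2": 22,
                "Curvature_integration_P": 20, "LineDist": 19,
                "Ratio_Dpnordnor1": 17, "Diameter_normalD2": 8,
            },
            "rfe_rf": {
                "Diameter_normalD2": 25, "Curvature_mean_PD": 19,
                "Eccentricity_std_P2": 15, "Eccentricity_variation_D2": 12,
                "Ratio_Dpnordnor1": 10, "Curvature_integration_P": 9,
            },
        }
        screened = sorted({n for c in counts.values() for n in c})
        table = FrequencyTable(counts=counts, reps=30, screened=screened)
        result = consensus_sets(table)
        assert result["top2_union"] == {
            "Curvature_mean_PD",
            "Diameter_normalD2",
            "Eccentricity_std_P2",
            "Curvature_integration_P",
            "CrossArea_mean_PD2",
        }
        # features selected at least two-thirds of the runs by some method
        assert result["frequent"] == {
            "Curvature_mean_PD",
            "Diameter_normalD2",
            "Eccentricity_std_P2",
            "Curvature_integration_P",
        }

    def test_single_dominant_feature(self):
        table = FrequencyTable(
            counts={"kbest_t": {"a": 29, "b": 4, "c": 2}}, reps=30, screened=["a", "b", "c"]
        )
        result = consensus_sets(table)
        assert result["frequent"] == {"a"}
        assert result["top2_union"] == {"a", "b"}

    def test_all_below_cutoff_gives_empty_frequent(self):
        table = FrequencyTable(
            counts={"kbest_t": {"a": 19, "b": 12}}, reps=30, screened=["a", "b"]
        )
        assert consensus_sets(table)["frequent"] == set()

    def test_rank2_ties_all_included(self):
        table = FrequencyTable(
            counts={"kbest_t": {"a": 30, "b": 21, "c": 21, "d": 3}},
            reps=30,
            screened=list("abcd"),
        )
        with pytest.warns(UserWarning, match="tie"):
            top = table.top("kbest_t", n=2)
        assert set(top) == {"a", "b", "c"}
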