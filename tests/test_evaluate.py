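"""Splits, accuracy/AUC/sensitivity metrics, correlation, and the
feature-subset and network-comparison runners."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adbn.errors import InputError, StratificationError
from adbn.evaluate import (
    ConfusionMatrix,
    compare_networks,
    evaluate_feature_subsets,
    holdout_split,
    kfold_indices,
    multiclass_accuracy,
    multiclass_auc,
    pearson_correlation,
    sensitivity_specificity,
)


class TestSplits:
    def test_fraction_arithmetic(self):
        df = pd.DataFrame({"x": range(100)})
        dev, test = holdout_split(df, 0.1, seed=0)
        assert len(test) == 10 and len(dev) == 90
        assert set(dev.index).isdisjoint(test.index)

    def test_stratified_proportions(self):
        df = pd.DataFrame({"g": ["a"] * 90 + ["b"] * 10})
        dev, test = holdout_split(df, 0.1, stratify_by="g", seed=1)
        assert (test["g"] == "a").sum() == 9
        assert (test["g"] == "b").sum() == 1

    def test_deterministic_given_seed(self):
        df = pd.DataFrame({"x": range(50), "g": ["a", "b"] * 25})
        a = holdout_split(df, 0.3, stratify_by="g", seed=9)
        b = holdout_split(df, 0.3, stratify_by="g", seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_small_stratum_named_in_error(self):
        df = pd.DataFrame({"g": ["a"] * 10 + ["rare"]})
        with pytest.raises(StratificationError, match="rare"):
            holdout_split(df, 0.1, stratify_by="g", seed=0)

    def test_kfold_shapes_and_partition(self):
        assert sorted(np.bincount(kfold_indices(10, 10, 0))) == [1] * 10
        sizes = sorted(np.bincount(kfold_indices(10, 3, 0)))
        assert sizes == [3, 3, 4]
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, min(n, 8) + 1))
            a = kfold_indices(n, k, int(rng.integers(1000)))
            assert len(a) == n and set(a) == set(range(k))
        with pytest.raises(InputError):
            kfold_indices(3, 5, 0)


class TestMulticlassAccuracy:
    def test_proportion_and_boundary(self):
        out = multiclass_accuracy(list("aaabbbcccc"), list("aaabbbccca"))
        assert out["mca"] == pytest.approx(0.9)
        perfect = multiclass_accuracy(["x"] * 20, ["x"] * 20)
        assert perfect["mca"] == 1.0 and perfect["ci95"][1] == 1.0

    def test_clopper_pearson_7_of_10(self):
        out = multiclass_accuracy(list("aaaaaaaaaa"),
                                  list("aaaaaaabbb"))
        lo, hi = out["ci95"]
        assert lo == pytest.approx(0.3475, abs=2e-4)
        assert hi == pytest.approx(0.9333, abs=2e-4)
        assert lo <= out["mca"] <= hi

    def test_ci_coverage_simulation(self):
        rng = np.random.default_rng(0)
        p, n, reps = 0.7, 50, 2000
        covered = 0
        x = rng.binomial(n, p, size=reps)
        for xi in x:
            lo = 0.0 if xi == 0 else stats.beta.ppf(0.025, xi, n - xi + 1)
            hi = 1.0 if xi == n else stats.beta.ppf(0.975, xi + 1, n - xi)
            covered += lo <= p <= hi
        assert covered / reps >= 0.93


class TestMulticlassAuc:
    def _posterior(self, scores):
        p = np.asarray(scores, dtype=float)
        return p / p.sum(axis=1, keepdims=True)

    def test_perfect_separation(self):
        truth = ["a", "a", "b", "b"]
        post = self._posterior([[9, 1], [8, 2], [1, 9], [2, 8]])
        assert multiclass_auc(truth, post, ["a", "b"]) == 1.0

    def test_uninformative_posteriors_give_half(self):
        truth = ["a", "b", "a", "c"]
        post = np.full((4, 3), 1 / 3)
        assert multiclass_auc(truth, post, ["a", "b", "c"]) == \
            pytest.approx(0.5)

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(1)
        truth = np.array(["a", "b", "c", "a", "b", "c"])
        post = self._posterior(rng.random((6, 3)) + 0.01)
        got = multiclass_auc(truth, post, ["a", "b", "c"])
        # brute-force one-vs-rest concordance with midrank ties
        aucs = []
        for ci, c in enumerate(["a", "b", "c"]):
            pos = post[truth == c, ci]
            neg = post[truth != c, ci]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            aucs.append(conc / (len(pos) * len(neg)))
        assert got == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_binary_equals_mann_whitney(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 30
            truth = rng.choice(["p", "n"], size=n)
            if len(set(truth)) < 2:
                continue
            score = rng.random(n)
            post = np.column_stack([score, 1 - score])
            u = stats.mannwhitneyu(score[truth == "p"], score[truth == "n"],
                                   alternative="two-sided").statistic
            n_pos = (truth == "p").sum()
            n_neg = n - n_pos
            binary_auc_expected = u / (n_pos * n_neg)
            from adbn.evaluate import _binary_auc
            assert _binary_auc(truth == "p", score) == \
                pytest.approx(binary_auc_expected, abs=1e-12)
            # both one-vs-rest directions equal the same Mann-Whitney AUC
            # (ranking class n by 1-s mirrors ranking class p by s), so the
            # binary macro AUC is the classical AUC itself
            got = multiclass_auc(truth, post, ["p", "n"])
            assert got == pytest.approx(binary_auc_expected, abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        truth = ["a", "a", "b", "b"]
        post = self._posterior([[5, 4, 1]] * 2 + [[1, 5, 4]] * 2)
        with pytest.warns(UserWarning, match="absent"):
            multiclass_auc(truth, post, ["a", "b", "c"])


class TestSensitivitySpecificity:
    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2]), ["a", "b", "c"])
        out = sensitivity_specificity(cm)
        assert all(v["sensitivity"] == 1.0 and v["specificity"] == 1.0
                   for v in out.values())

    def test_two_class_hand_arithmetic(self):
        cm = ConfusionMatrix(np.array([[8, 2], [3, 7]]), ["pos", "neg"])
        out = sensitivity_specificity(cm)
        assert out["pos"]["sensitivity"] == pytest.approx(0.8)
        assert out["pos"]["specificity"] == pytest.approx(0.7)

    def test_empty_truth_row_reported_as_unavailable(self):
        cm = ConfusionMatrix(np.array([[4, 0], [0, 0]]), ["a", "b"])
        out = sensitivity_specificity(cm)
        assert out["b"]["sensitivity"] is None


class TestPearsonCorrelation:
    def test_affine_identity(self):
        x = np.array([1, 2, 3, 4, 5])
        out = pearson_correlation(x, 2 * x + 1)
        assert out["r"] == pytest.approx(1.0)

    def test_anti_monotone_negative(self):
        out = pearson_correlation([1, 2, 3, 4], [9, 7, 4, 1])
        assert out["r"] < 0

    def test_synthetic_diagnosis_cdr_in_expected_band(self):
        from adbn.simulate import CohortSimSpec, generate_cohort

        table = generate_cohort(CohortSimSpec(n_subjects=900, seed=11))
        df = table.df.dropna(subset=["cdr", "diagnosis"])
        d = df["diagnosis"].map({"HC": 0, "MCI": 1, "AD": 2}).to_numpy()
        c = pd.to_numeric(df["cdr"]).to_numpy()
        out = pearson_correlation(d, c)
        assert 0.76 <= out["r"] <= 0.84
        assert out["p"] < 1e-10


class TestRunners:
    def test_subset_reports_deterministic_and_ordered(self, ground_truth_net):
        from adbn.pipeline import default_constraints
        from adbn.simulate import sample_from_network

        df = sample_from_network(ground_truth_net, 1500, seed=3)
        cons = default_constraints(ground_truth_net.nodes)
        subsets = [["age"],
                   ["age", "apoe", "gm_volume", "csf_volume",
                    "pib_pet_voxels", "mmse", "lmdr"]]
        r1 = evaluate_feature_subsets(df, subsets, "cdr", cons,
                                      score="bic", seed=0)
        r2 = evaluate_feature_subsets(df, subsets, "cdr", cons,
                                      score="bic", seed=0)
        keys = sorted(r1)
        assert [r1[k].to_dict() for k in keys] == \
            [r2[k].to_dict() for k in keys]
        rich = "+".join(sorted(subsets[1]))
        assert r1[rich].auc >= r1["age"].auc

    def test_empty_subset_rejected(self, ground_truth_net):
        from adbn.simulate import sample_from_network

        df = sample_from_network(ground_truth_net, 50, seed=0)
        with pytest.raises(InputError):
            evaluate_feature_subsets(df, [[]], "cdr")

    def test_compare_networks_identity_and_reversal(self):
        from adbn.bayesnet import BayesianNetworkModel

        a = BayesianNetworkModel(
            nodes=["x", "y", "z"],
            categories={v: ["0", "1"] for v in "xyz"},
            edges={("x", "y"), ("y", "z")},
        )
        assert compare_networks(a, a) == {
            "added": [], "removed": [], "reversed": [],
            "node_symmetric_difference": [],
        }
        b = BayesianNetworkModel(
            nodes=["x", "y", "z"],
            categories={v: ["0", "1"] for v in "xyz"},
            edges={("y", "x"), ("y", "z")},
        )
        diff = compare_networks(a, b)
        assert diff["reversed"] == [("x", "y")]
        assert diff["added"] == [] and diff["removed"] == []
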