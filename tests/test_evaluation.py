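import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowps import (
    choose_threshold,
    importance_correlations,
    paired_ttest,
    roc_auc,
    run_experiment,
    sensitivity_specificity,
)
from flowps.evaluation import EvaluationError


def exhaustive_threshold(scores, labels, B):
    """Oracle: try every candidate midpoint plus sentinels, smallest tau wins."""
    distinct = sorted(set(scores))
    candidates = (
        [-np.inf]
        + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
        + [np.inf]
    )
    best = None
    for tau in candidates:
        fp = sum(1 for s, l in zip(scores, labels) if s >= tau and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < tau and l == 1)
        pen = B * fp + fn
        if best is None or pen < best[0] - 1e-12:
            best = (pen, tau)
    return best[1]


class TestRocAuc:
    def test_perfect(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]),
                       np.array([0, 0, 1, 1])) == 1.0

    def test_partial(self):
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                       np.array([0, 0, 1, 1])) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert roc_auc(np.full(6, 0.5),
                       np.array([0, 1, 0, 1, 0, 1])) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 5, size=n) / 4.0
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pairs = [
                (1.0 if sp > sn else 0.5 if sp == sn else 0.0)
                for sp, lp in zip(scores, labels) if lp == 1
                for sn, ln in zip(scores, labels) if ln == 0
            ]
            assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs))

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None)
    def test_monotone_invariance_and_complement(self, seed):
        r = np.random.default_rng(seed)
        scores = r.uniform(size=10)
        labels = np.array([0, 1] * 5)
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(a)
        assert roc_auc(1 - scores, labels) == pytest.approx(1 - a)


class TestChooseThreshold:
    def test_clean_split(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        tau = choose_threshold(scores, labels, 1.0)
        assert tau == pytest.approx(0.5)
        sn, sp = sensitivity_specificity(scores, labels, tau)
        assert (sn, sp) == (1.0, 1.0)

    def test_huge_b_tolerates_no_false_positive(self):
        # top-scored sample is a non-responder: only tau=inf avoids the FP
        scores = np.array([0.2, 0.9, 0.6, 0.8])
        labels = np.array([0, 0, 1, 1])
        tau = choose_threshold(scores, labels, 1e9)
        fp = sum(1 for s, l in zip(scores, labels) if s >= tau and l == 0)
        assert fp == 0
        assert tau == np.inf

    def test_tiny_b_tolerates_no_false_negative(self):
        scores = np.array([0.2, 0.9, 0.1, 0.8])
        labels = np.array([0, 0, 1, 1])
        tau = choose_threshold(scores, labels, 1e-9)
        fn = sum(1 for s, l in zip(scores, labels) if s < tau and l == 1)
        assert fn == 0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 6, size=n) / 5.0
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            B = float(rng.choice([0.1, 0.25, 1.0, 4.0, 10.0]))
            assert choose_threshold(scores, labels, B) == pytest.approx(
                exhaustive_threshold(scores.tolist(), labels.tolist(), B)
            )

    def test_tau_non_decreasing_in_b(self, rng):
        for _ in range(50):
            scores = rng.uniform(size=12)
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max():
                continue
            taus = [choose_threshold(scores, labels, B)
                    for B in (0.1, 0.25, 1.0, 4.0, 10.0)]
            assert taus == sorted(taus)


class TestSensitivitySpecificity:
    def test_tau_above_everything(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        assert sensitivity_specificity(scores, labels, 0.9) == (0.0, 1.0)

    def test_hand_confusion_counts(self):
        scores = np.array([0.2, 0.6, 0.4, 0.8])
        labels = np.array([0, 1, 0, 1])
        assert sensitivity_specificity(scores, labels, 0.5) == (1.0, 1.0)
        assert sensitivity_specificity(scores, labels, 0.3) == (1.0, 0.5)

    def test_monotone_in_tau(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[0], labels[1] = 0, 1
        taus = np.linspace(-0.1, 1.1, 25)
        sns, sps = zip(*(sensitivity_specificity(scores, labels, t)
                         for t in taus))
        assert all(a >= b - 1e-12 for a, b in zip(sns, sns[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(sps, sps[1:]))


class TestPairedTTest:
    def test_known_value(self):
        base = np.array([0.5, 0.6, 0.7])
        res = paired_ttest(base + np.array([0.1, 0.05, 0.15]), base)
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.p_value == pytest.approx(0.0742, abs=1e-3)
        assert res.n == 3 and not res.degenerate

    def test_identical_vectors_degenerate(self):
        a = np.array([0.5, 0.6, 0.7])
        res = paired_ttest(a, a.copy())
        assert res.degenerate
        assert np.isnan(res.t)

    def test_swap_negates_t(self):
        a = np.array([0.5, 0.65, 0.7, 0.8])
        b = np.array([0.45, 0.6, 0.72, 0.7])
        assert paired_ttest(a, b).t == pytest.approx(-paired_ttest(b, a).t)
        assert paired_ttest(a, b).p_value == pytest.approx(
            paired_ttest(b, a).p_value
        )

    def test_length_validation(self):
        with pytest.raises(EvaluationError):
            paired_ttest([0.1], [0.2])


class TestImportanceCorrelations:
    def test_identical_vectors(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        cm = importance_correlations({"a": v, "b": v.copy()})
        assert cm.pair("a", "b") == (pytest.approx(1.0), pytest.approx(1.0))

    def test_reversed_ranks(self):
        cm = importance_correlations(
            {"a": np.array([1.0, 2.0, 3.0, 4.0]),
             "b": np.array([4.0, 3.0, 2.0, 1.0])}
        )
        assert cm.pair("a", "b")[1] == pytest.approx(-1.0)

    def test_spearman_hand_value(self):
        cm = importance_correlations(
            {"a": np.array([1.0, 2.0, 3.0, 4.0]),
             "b": np.array([1.0, 3.0, 2.0, 4.0])}
        )
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=2
        assert cm.pair("a", "b")[1] == pytest.approx(0.8)

    def test_constant_vector_flagged_not_nan(self):
        cm = importance_correlations(
            {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 2.0, 3.0])}
        )
        assert not cm.defined[0, 1]
        assert np.isfinite(cm.pearson).all()

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(0)
        cm = importance_correlations(
            {m: rng.uniform(size=6) for m in "abc"}
        )
        np.testing.assert_allclose(cm.pearson, cm.pearson.T)
        np.testing.assert_allclose(np.diag(cm.pearson), 1.0)
        assert np.all(np.abs(cm.pearson) <= 1 + 1e-12)

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(EvaluationError):
            importance_correlations(
                {"a": np.ones(4), "b": np.ones(5)}
            )


class TestRunExperiment:
    CONFIG = {
        "seed": 17,
        "datasets": [
            {"name": "d0",
             "synthetic": {"n_samples": 16, "n_informative": 3, "n_noise": 3,
                           "geometry": "global", "effect_size": 3.0,
                           "responder_fraction": 0.5}},
            {"name": "d1",
             "synthetic": {"n_samples": 16, "n_informative": 3, "n_noise": 3,
                           "geometry": "global", "effect_size": 3.0,
                           "responder_fraction": 0.5}},
        ],
        "methods": [
            {"method": "bernoulli_nb", "preset": "advanced"},
            {"method": "svm_linear"},
        ],
        "grid": {"m_values": [0, 1], "k_values": [6, 14],
                 "confidence_p": 0.92},
        "balance": {"B": [0.25, 1.0, 4.0]},
    }

    def test_schema_and_summary(self, tmp_path):
        result = run_experiment(self.CONFIG, out_dir=tmp_path)
        frame = result.summary_frame()
        assert set(frame["method"]) == {"bernoulli_nb", "svm_linear"}
        assert {"median_auc_with", "median_auc_without",
                "paired_p"} <= set(frame.columns)
        assert (tmp_path / "summary.tsv").exists()
        assert (tmp_path / "per_sample.tsv").exists()
        comp = result.comparisons["svm_linear"]
        assert len(comp.auc_with) == 2
        assert result.correlations_with is not None

    def test_deterministic_rerun(self):
        a = run_experiment(self.CONFIG)
        b = run_experiment(self.CONFIG)
        for m in a.comparisons:
            np.testing.assert_array_equal(
                a.comparisons[m].auc_with, b.comparisons[m].auc_with
            )
        np.testing.assert_array_equal(
            a.per_sample["score_with"].to_numpy(),
            b.per_sample["score_with"].to_numpy(),
        )


class TestEqualizeClasses:
    def test_subsamples_majority_to_parity(self):
        from flowps.evaluation import equalize_classes

        from conftest import synthetic

        ds = synthetic(n=30, informative=2, noise=2, frac=0.3, seed=1)
        eq = equalize_classes(ds, seed=0)
        assert int(eq.labels.sum()) == int((1 - eq.labels).sum())
        # minority class fully retained, order preserved
        minority = [s for s, l in zip(ds.sample_ids, ds.labels) if l == 1]
        kept = [s for s, l in zip(eq.sample_ids, eq.labels) if l == 1]
        assert kept == minority

    def test_already_balanced_untouched(self):
        from flowps.evaluation import equalize_classes

        from conftest import synthetic

        ds = synthetic(n=20, informative=2, noise=2, frac=0.5, seed=2)
        assert equalize_classes(ds, seed=0) is ds

    def test_deterministic(self):
        from flowps.evaluation import equalize_classes

        from conftest import synthetic

        ds = synthetic(n=31, informative=2, noise=2, frac=0.35, seed=3)
        a = equalize_classes(ds, seed=5)
        b = equalize_classes(ds, seed=5)
        assert a.sample_ids == b.sample_ids
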