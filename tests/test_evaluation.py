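import itertools

import numpy as np
import pytest

from milkguard.evaluation import (
    UNDETERMINED,
    ConfusionMatrix,
    MetricsReport,
    aggregate,
    is_undetermined,
    iteration_sweep,
    metrics,
    sample_size_study,
    split_sweep,
)


def centroid_classifier(X_tr, y_tr, X_te, seed):
    """Cheap deterministic stand-in learner: nearest class centroid."""
    c0 = X_tr[y_tr == 0].mean(axis=0)
    c1 = X_tr[y_tr == 1].mean(axis=0)
    d0 = np.linalg.norm(X_te - c0, axis=1)
    d1 = np.linalg.norm(X_te - c1, axis=1)
    return (d1 < d0).astype(int)


def blobs(n=120, gap=4.0, sd=1.0, seed=0, pos_frac=0.5):
    rng = np.random.default_rng(seed)
    n1 = int(n * pos_frac)
    X = np.vstack([rng.normal(0, sd, (n - n1, 2)),
                   rng.normal(gap, sd, (n1, 2))])
    y = np.r_[np.zeros(n - n1), np.ones(n1)].astype(int)
    return X, y


class TestMetrics:
    def test_perfect_two_sample_matrix(self):
        rep = metrics(ConfusionMatrix(tp=1, tn=1, fp=0, fn=0))
        for name in ("accuracy", "sensitivity", "specificity", "precision",
                     "npv", "f1"):
            assert getattr(rep, name) == 1.0
        assert rep.false_alarm == 0.0

    def test_nothing_flagged_leaves_precision_undetermined(self):
        rep = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=3))
        assert is_undetermined(rep.precision)
        assert is_undetermined(rep.f1)
        assert rep.sensitivity == 0.0  # determined: 0/(0+3)

    def test_worked_example(self):
        rep = metrics(ConfusionMatrix(tp=3, fp=1, tn=5, fn=1))
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(5 / 6)
        assert rep.precision == pytest.approx(0.75)
        assert rep.npv == pytest.approx(5 / 6)
        assert rep.false_alarm == pytest.approx(1 / 6)
        assert rep.f1 == pytest.approx(0.75)

    def test_enumeration_matches_formula_oracle(self):
        """All 6^4 matrices with counts 0..5, including zero denominators."""
        def safe(num, den):
            return num / den if den else None
        for tp, tn, fp, fn in itertools.product(range(6), repeat=4):
            if tp + tn + fp + fn == 0:
                with pytest.raises(ValueError):
                    ConfusionMatrix(tp, tn, fp, fn)
                continue
            rep = metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
            expected = {
                "accuracy": safe(tp + tn, tp + tn + fp + fn),
                "sensitivity": safe(tp, tp + fn),
                "specificity": safe(tn, fp + tn),
                "precision": safe(tp, tp + fp),
                "npv": safe(tn, tn + fn),
                "false_alarm": safe(fp, fp + tn),
            }
            p, s = expected["precision"], expected["sensitivity"]
            expected["f1"] = (None if p is None or s is None or p + s == 0
                              else 2 * p * s / (p + s))
            for name, want in expected.items():
                got = getattr(rep, name)
                if want is None:
                    assert is_undetermined(got), (name, tp, tn, fp, fn)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_accuracy_is_prevalence_weighted_mean_of_sens_spec(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 30, 4)
            rep = metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            P, N = tp + fn, tn + fp
            assert rep.accuracy == pytest.approx(
                (rep.sensitivity * P + rep.specificity * N) / (P + N))

    def test_count_consistency(self):
        rep = metrics(ConfusionMatrix(tp=7, tn=11, fp=3, fn=2))
        assert round(rep.sensitivity * 9, 9) == pytest.approx(7)
        assert round(rep.precision * 10, 9) == pytest.approx(7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, tn=1, fp=0, fn=0)


class TestAggregate:
    def test_mean_and_sample_sd(self):
        reps = [metrics(ConfusionMatrix(tp=8, tn=10, fp=0, fn=2)),
                metrics(ConfusionMatrix(tp=9, tn=10, fp=0, fn=1))]
        agg = aggregate(reps)
        assert agg.sensitivity == pytest.approx(0.85)
        assert agg.sd["sensitivity"] == pytest.approx(
            np.std([0.8, 0.9], ddof=1))

    def test_undetermined_repeats_excluded_not_zeroed(self):
        reps = [metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=2)),
                metrics(ConfusionMatrix(tp=2, tn=5, fp=0, fn=0))]
        agg = aggregate(reps)
        assert agg.precision == 1.0  # mean over the determined repeat only
        reps_all_und = [metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=2))] * 2
        assert is_undetermined(aggregate(reps_all_und).precision)


class TestSweeps:
    def test_single_ratio_is_selected(self):
        X, y = blobs()
        best, per = split_sweep(X, y, centroid_classifier, ratios=[0.7],
                                repeats=2, seed=0)
        assert best == 0.7 and set(per) == {0.7}

    def test_rerun_is_deterministic(self):
        X, y = blobs(seed=1)
        a = split_sweep(X, y, centroid_classifier, repeats=2, seed=5)
        b = split_sweep(X, y, centroid_classifier, repeats=2, seed=5)
        assert a[0] == b[0]
        for r in a[1]:
            assert a[1][r].f1 == b[1][r].f1

    def test_separable_data_ties_to_largest_training_fraction(self):
        X, y = blobs(gap=30.0, sd=0.3)
        best, per = split_sweep(X, y, centroid_classifier, repeats=3, seed=2)
        assert all(per[r].f1 == 1.0 for r in per)
        assert best == 0.9

    def test_iteration_single_candidate_and_tie_rule(self):
        X, y = blobs(gap=30.0, sd=0.3, seed=3)
        best, _ = iteration_sweep(X, y, centroid_classifier, iterations=[1],
                                  seed=0)
        assert best == 1
        # separable: every count reaches F1=1 -> fewest iterations wins
        best, per = iteration_sweep(X, y, centroid_classifier,
                                    iterations=[1, 5, 10], seed=0)
        assert best == 1

    def test_iteration_selection_matches_reported_curve(self):
        X, y = blobs(gap=2.0, sd=1.2, seed=4)
        best, per = iteration_sweep(X, y, centroid_classifier,
                                    iterations=[1, 5, 10], seed=1)
        f1s = {n: per[n].f1 for n in per}
        expected = max(sorted(f1s, reverse=True), key=lambda n: (f1s[n], -n))
        assert best == expected

    def test_sample_size_full_fraction_equals_plain_split(self):
        X, y = blobs(seed=5)
        out = sample_size_study(X, y, centroid_classifier, fractions=[1.0],
                                repeats=2, seed=3)
        direct = split_sweep(X, y, centroid_classifier, ratios=[0.9],
                             repeats=2, seed=3 + 0)[1][0.9]
        assert out[1.0].f1 == pytest.approx(direct.f1)

    def test_power_grows_and_variance_shrinks_with_sample_size(self):
        X, y = blobs(n=600, gap=1.8, sd=1.0, seed=6)
        out = sample_size_study(X, y, centroid_classifier,
                                fractions=[0.2, 0.6, 1.0], repeats=6, seed=0)
        f1s = [out[f].f1 for f in (0.2, 0.6, 1.0)]
        sds = [out[f].sd["f1"] for f in (0.2, 0.6, 1.0)]
        # allow one inversion in each trend
        assert sum(a > b for a, b in zip(f1s, f1s[1:])) <= 1
        assert sum(a < b for a, b in zip(sds, sds[1:])) <= 1

    def test_single_class_rejected(self):
        X, y = blobs()
        with pytest.raises(ValueError, match="both classes"):
            split_sweep(X, np.zeros_like(y), centroid_classifier)
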