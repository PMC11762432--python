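import numpy as np
import pytest

from hierattn.evaluation import (
    bootstrap_ci,
    bootstrap_report,
    calibration_table,
    compute_metrics,
    stratified_report,
)


def _from_confusion(tp, fn, fp, tn, p_pos=0.9, p_neg=0.1):
    y = np.r_[np.ones(tp), np.ones(fn), np.zeros(fp), np.zeros(tn)]
    p = np.r_[np.full(tp, p_pos), np.full(fn, p_neg),
              np.full(fp, p_pos), np.full(tn, p_neg)]
    return y, p


def _concordance(y, p):
    """Brute-force pairwise concordance probability (ties count 1/2)."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _kappa_closed_form(tp, fn, fp, tn):
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / n ** 2
    return (po - pe) / (1 - pe)


class TestComputeMetrics:
    def test_hand_derived_confusion_matrix(self):
        y, p = _from_confusion(40, 10, 20, 30)
        m = compute_metrics(y, p, threshold=0.5)
        assert m["precision"] == pytest.approx(40 / 60, abs=1e-9)
        assert m["recall"] == pytest.approx(0.8)
        assert m["cohens_kappa"] == pytest.approx(0.4)

    def test_perfect_separation(self):
        y = np.r_[np.ones(20), np.zeros(30)]
        p = np.r_[np.linspace(0.6, 1, 20), np.linspace(0, 0.4, 30)]
        m = compute_metrics(y, p)
        assert m["roc_auc"] == 1.0
        assert m["pr_auc"] == 1.0

    def test_constant_scores_are_uninformative(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        m = compute_metrics(y, np.full(20, 0.3))
        assert m["roc_auc"] == pytest.approx(0.5)

    def test_single_class_aucs_missing_with_reason(self):
        m = compute_metrics(np.ones(10), np.random.default_rng(0).random(10))
        assert m["roc_auc"] is None and m["pr_auc"] is None
        assert "single-class" in m["missing_reason"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0.5])


def test_roc_auc_equals_pairwise_concordance():
    """Trapezoidal ROC-AUC equals the brute-force concordance probability on
    50 random samples of n <= 500."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(20, 501))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        p = np.round(rng.random(n), 2)          # coarse grid forces ties
        auc = compute_metrics(y, p)["roc_auc"]
        assert auc == pytest.approx(_concordance(y, p), abs=1e-12)


def test_kappa_precision_recall_match_closed_form():
    """Class metrics match contingency computation for 100 random confusion
    matrices."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        tp, fn, fp, tn = rng.integers(1, 60, 4)
        y, p = _from_confusion(tp, fn, fp, tn)
        m = compute_metrics(y, p)
        assert m["cohens_kappa"] == pytest.approx(_kappa_closed_form(tp, fn, fp, tn))
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["recall"] == pytest.approx(tp / (tp + fn))


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        a = bootstrap_ci(y, p, "roc_auc", n_bootstrap=200, seed=9)
        b = bootstrap_ci(y, p, "roc_auc", n_bootstrap=200, seed=9)
        assert a == b

    def test_degenerate_metric_collapses_interval(self):
        y = np.ones(50)
        p = np.full(50, 0.9)
        point, lo, hi, _ = bootstrap_ci(y, p, "recall", n_bootstrap=100, seed=0)
        assert point == lo == hi == 1.0

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(3)

        def sample(n):
            p = rng.random(n)
            y = (rng.random(n) < p).astype(int)
            return bootstrap_ci(y, p, "roc_auc", n_bootstrap=200, seed=1)

        _, lo_s, hi_s, _ = sample(200)
        _, lo_l, hi_l, _ = sample(20000)
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_percentile_interval_contains_point_estimate(self):
        """Percentile CI covers the point estimate in >= 99% of seeded runs."""
        rng = np.random.default_rng(4)
        inside = 0
        runs = 40
        for k in range(runs):
            n = 400
            p = rng.random(n)
            y = (rng.random(n) < p).astype(int)
            point, lo, hi, _ = bootstrap_ci(y, p, "roc_auc",
                                            n_bootstrap=300, seed=k)
            inside += lo <= point <= hi
        assert inside >= runs - 1

    def test_report_has_all_metrics_and_ordered_cis(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        p = np.clip(rng.random(300), 0, 1)
        rep = bootstrap_report(y, p, n_bootstrap=100, seed=0)
        assert set(rep.metrics) == {"cohens_kappa", "roc_auc", "pr_auc",
                                    "precision", "recall"}
        for name, ci in rep.metrics.items():
            assert ci.ci_low <= ci.point + 1e-12
            assert ci.point <= ci.ci_high + 1e-12
        assert rep.n_bootstrap == 100


class TestCalibration:
    def test_single_bin_case(self):
        tab = calibration_table(np.zeros(40), np.full(40, 0.03))
        assert tab.loc[0, "n"] == 40
        assert tab.loc[0, "observed_proportion"] == 0.0
        assert tab["n"].iloc[1:].sum() == 0

    def test_bin_counts_partition_sample(self):
        rng = np.random.default_rng(6)
        p = rng.random(777)
        y = rng.integers(0, 2, 777)
        tab = calibration_table(y, p)
        assert len(tab) == 20
        assert tab["n"].sum() == 777
        assert np.allclose(tab["p_high"] - tab["p_low"], 0.05)

    def test_right_closed_edges(self):
        tab = calibration_table(np.array([0, 1, 1]),
                                np.array([0.05, 0.051, 1.0]))
        assert tab.loc[0, "n"] == 1      # p = 0.05 in first bin
        assert tab.loc[1, "n"] == 1      # p = 0.051 in second bin
        assert tab.loc[19, "n"] == 1     # p = 1.0 in last bin

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            calibration_table(np.array([0]), np.array([1.2]))

    def test_well_calibrated_scores_land_near_bin_midpoints(self):
        rng = np.random.default_rng(7)
        n = 100_000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        tab = calibration_table(y, p)
        gaps = (tab["observed_proportion"] - tab["midpoint"]).abs()
        assert (gaps[tab["n"] > 0] <= 0.02).all()


class TestStratified:
    def test_two_strata_two_reports(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        strata = np.r_[["F"] * 120, ["M"] * 80]
        reps = stratified_report(y, p, strata, n_bootstrap=50)
        assert set(reps) == {"F", "M"}
        assert reps["F"].n == 120 and reps["M"].n == 80

    def test_single_class_stratum_keeps_class_metrics(self):
        y = np.r_[np.ones(60), np.random.default_rng(9).integers(0, 2, 60)]
        p = np.random.default_rng(10).random(120)
        strata = np.r_[["A"] * 60, ["B"] * 60]
        reps = stratified_report(y, p, strata, n_bootstrap=50)
        assert reps["A"].metrics["roc_auc"].point is None
        assert reps["A"].metrics["recall"].point is not None
        assert reps["B"].metrics["roc_auc"].point is not None

    def test_stronger_signal_gives_higher_stratum_auc(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.standard_normal(n)
        strata = np.r_[["A"] * (n // 2), ["B"] * (n // 2)]
        slope = np.where(strata == "A", 2.5, 0.3)
        y = (rng.random(n) < 1 / (1 + np.exp(-slope * x))).astype(int)
        p = 1 / (1 + np.exp(-x))
        reps = stratified_report(y, p, strata, n_bootstrap=50)
        assert reps["A"].metrics["roc_auc"].point > reps["B"].metrics["roc_auc"].point
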