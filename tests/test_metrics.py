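import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score as sk_f1

from ffpefilter import (
    ConfusionMatrix,
    build_confusion,
    compute_metrics,
    round_half_up,
    stratified_report,
    sweep_threshold,
)

from table1_fixture import TABLE1, row


class TestBuildConfusion:
    def test_enumeration(self):
        cm = build_confusion(["T", "T", "A", "A"], ["T", "A", "A", "T"])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = build_confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_degenerate_all_predicted_artifact(self):
        cm = build_confusion([1, 1, 1], [0, 0, 0])
        assert (cm.tp, cm.fn) == (0, 3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_confusion([1, 0], [1])


class TestComputeMetrics:
    def test_published_all_stratum_for_the_network(self):
        _, _, tp, tn, fp, fn, spec, sens, prec, f1, acc = row(
            "neural classifier", "All (public WES dataset)")
        ms = compute_metrics(ConfusionMatrix(tp, tn, fp, fn)).rounded(3)
        assert (ms.sensitivity, ms.specificity, ms.precision, ms.f1, ms.accuracy) == \
               (0.708, 0.996, 0.742, 0.724, 0.992)

    def test_published_all_stratum_for_the_orientation_filter(self):
        _, _, tp, tn, fp, fn, *_ = row("MuTect filter", "All (public WES dataset)")
        ms = compute_metrics(ConfusionMatrix(tp, tn, fp, fn)).rounded(3)
        assert (ms.specificity, ms.sensitivity) == (0.407, 0.969)

    @pytest.mark.parametrize("r", TABLE1, ids=lambda r: f"{r[0]}-{r[1]}")
    def test_full_published_table_regression(self, r):
        """All five metrics rederive from each row's counts at 3 decimals."""
        _, _, tp, tn, fp, fn, spec, sens, prec, f1, acc = r
        ms = compute_metrics(ConfusionMatrix(tp, tn, fp, fn)).rounded(3)
        assert ms.specificity == spec
        assert ms.sensitivity == sens
        assert ms.precision == prec
        assert ms.f1 == f1
        assert ms.accuracy == acc

    def test_perfect_classifier(self):
        ms = compute_metrics(ConfusionMatrix(1, 1, 0, 0))
        assert (ms.accuracy, ms.specificity, ms.sensitivity, ms.precision, ms.f1) == \
               (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_flags(self):
        ms = compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=2))
        assert ms.precision == 0.0 and "precision" in ms.undefined
        assert ms.f1 == 0.0
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=200)
    @given(tp=st.integers(0, 500), tn=st.integers(0, 500),
           fp=st.integers(0, 500), fn=st.integers(0, 500))
    def test_f1_equals_counts_formula(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        ms = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
        alt = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        assert ms.f1 == pytest.approx(alt, abs=1e-12)


def brute_force_best_f1(probs, truth):
    """Independent oracle: try every achievable cut point directly."""
    best = 0.0
    for thr in np.concatenate((np.unique(probs), [0.0, 1.0])):
        pred = (np.asarray(probs) >= thr).astype(int)
        best = max(best, sk_f1(truth, pred, zero_division=0))
    return best


class TestSweepThreshold:
    def test_separated_toy_case_returns_lowest_optimal_candidate(self):
        probs = [0.9, 0.8, 0.2, 0.1]
        truth = [1, 1, 0, 0]
        best_t, best_f1 = sweep_threshold(probs, truth)
        assert best_f1 == pytest.approx(1.0)
        assert best_t == pytest.approx(0.5)  # midpoint of 0.2 and 0.8, lowest optimum

    def test_never_worse_than_default_cutoff(self):
        rng = np.random.default_rng(0)
        probs = rng.random(200)
        truth = rng.integers(0, 2, 200)
        _, best_f1 = sweep_threshold(probs, truth)
        from ffpefilter import build_confusion, compute_metrics
        at_half = compute_metrics(build_confusion(truth, (probs >= 0.5).astype(int))).f1
        assert best_f1 >= at_half - 1e-12

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            probs = np.round(rng.random(n), 3)
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                continue
            _, best = sweep_threshold(probs, truth)
            assert best == pytest.approx(brute_force_best_f1(probs, truth), abs=1e-12)

    def test_inverted_scores_fall_back_to_all_positive(self):
        probs = [0.1, 0.2, 0.8, 0.9]
        truth = [1, 1, 0, 0]
        _, best = sweep_threshold(probs, truth)
        all_pos = sk_f1(truth, [1, 1, 1, 1])
        assert best == pytest.approx(all_pos)

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        probs = rng.random(100)
        truth = rng.integers(0, 2, 100)
        base = sweep_threshold(probs, truth)
        perm = rng.permutation(100)
        assert sweep_threshold(probs[perm], truth[perm]) == base

    def test_single_class_truth_raises(self):
        with pytest.raises(ValueError):
            sweep_threshold([0.1, 0.9], [1, 1])


class TestStratifiedReport:
    def _data(self):
        truth = [1, 1, 0, 0, 1, 0]
        pred = [1, 0, 0, 1, 1, 0]
        maf = [0.03, 0.2, 0.05, 0.04, 0.3, 0.02]
        sub = ["C>T", "G>A", "G>T", "C>A", "A>G", "C>T"]
        cancer = ["breast", "breast", "lung", "lung", "breast", "lung"]
        return truth, pred, maf, sub, cancer

    def test_low_maf_stratum_is_open_interval(self):
        truth, pred, maf, sub, cancer = self._data()
        rep = stratified_report(truth, pred, maf=maf, substitution=sub, cancer_type=cancer)
        low = rep[rep.stratum.str.startswith("Low MAF")].iloc[0]
        # MAF 0.05 and boundary values are excluded; 0.03, 0.04, 0.02 are in
        assert low.tp + low.tn + low.fp + low.fn == 3

    def test_substitution_groups_follow_strand_complements(self):
        truth, pred, maf, sub, cancer = self._data()
        rep = stratified_report(truth, pred, maf=maf, substitution=sub, cancer_type=cancer)
        cg = rep[rep.stratum == "C:G>T:A"].iloc[0]   # C>T and G>A calls
        gc = rep[rep.stratum == "G:C>T:A"].iloc[0]   # G>T and C>A calls
        assert cg.tp + cg.tn + cg.fp + cg.fn == 3
        assert gc.tp + gc.tn + gc.fp + gc.fn == 2

    def test_per_cancer_counts_sum_to_overall(self):
        truth, pred, maf, sub, cancer = self._data()
        rep = stratified_report(truth, pred, cancer_type=cancer).set_index("stratum")
        for c in ("tp", "tn", "fp", "fn"):
            assert rep.loc["breast", c] + rep.loc["lung", c] == rep.loc["All", c]

    def test_empty_stratum_flagged_not_error(self):
        rep = stratified_report([1, 0], [1, 0], maf=[0.5, 0.6])
        low = rep[rep.stratum.str.startswith("Low MAF")].iloc[0]
        assert bool(low["empty"]) and np.isnan(low["f1"])


def test_round_half_up_convention():
    assert round_half_up(0.7075, 3) == 0.708
    assert round_half_up(0.0465, 3) == 0.047
    assert round_half_up(0.2424, 3) == 0.242
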