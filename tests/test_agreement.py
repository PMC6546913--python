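"""Confusion matrices, weighted Cohen's kappa and Light's kappa."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from her2fish.agreement import (
    DEFAULT_CLASS_ORDER,
    ConfusionMatrix,
    RaterLabels,
    accuracy,
    confusion,
    detector_vs_team_kappa,
    identity_weights,
    lights_kappa,
    linear_weights,
    merge_unidentifiable,
    per_class_accuracy,
    quadratic_weights,
    stratified_agreement,
    weighted_kappa,
)


def kappa_oracle(counts: np.ndarray, weights: np.ndarray) -> float:
    """Direct element-by-element evaluation of the definition formula."""
    n = counts.sum()
    num = den = 0.0
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    k = counts.shape[0]
    for i in range(k):
        for j in range(k):
            num += weights[i, j] * counts[i, j] / n
            den += weights[i, j] * row[i] * col[j]
    return 1.0 - num / den


def random_labels(rng, n, class_order=DEFAULT_CLASS_ORDER, p=None):
    return tuple(str(c) for c in rng.choice(class_order, size=n, p=p))


class TestConfusion:
    def test_identical_raters_give_diagonal_matrix(self, rng):
        labels = random_labels(rng, 40)
        m = confusion(RaterLabels("a", labels), RaterLabels("b", labels))
        assert np.trace(m.counts) == 40
        assert accuracy(m) == 1.0

    def test_single_off_diagonal_cell(self):
        a = RaterLabels("a", ("low",) * 5)
        b = RaterLabels("b", ("high",) * 5)
        m = confusion(a, b)
        assert m.counts[DEFAULT_CLASS_ORDER.index("low"),
                        DEFAULT_CLASS_ORDER.index("high")] == 5
        assert np.trace(m.counts) == 0

    def test_row_sums_reproduce_first_raters_marginals(self, rng):
        la = random_labels(rng, 30)
        lb = random_labels(rng, 30)
        m = confusion(RaterLabels("a", la), RaterLabels("b", lb))
        for i, cls in enumerate(DEFAULT_CLASS_ORDER):
            assert m.counts[i].sum() == la.count(cls)

    def test_misaligned_raters_rejected(self):
        with pytest.raises(ValueError):
            confusion(RaterLabels("a", ("low",) * 3), RaterLabels("b", ("low",) * 4))

    def test_five_class_labels_merge_to_unidentifiable(self):
        assert merge_unidentifiable("uncertain") == "unidentifiable"
        assert merge_unidentifiable("artifact") == "unidentifiable"
        assert merge_unidentifiable("low") == "low"


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self, rng):
        d = np.diag(rng.integers(1, 20, size=4))
        assert weighted_kappa(ConfusionMatrix(d, DEFAULT_CLASS_ORDER)) == 1.0

    def test_chance_product_matrix_is_zero(self):
        # observed proportions equal to the outer product of the marginals
        row = np.array([0.3, 0.7])
        col = np.array([0.6, 0.4])
        counts = np.outer(row, col) * 100
        m = ConfusionMatrix(counts.round().astype(int), ("normal", "low"))
        assert weighted_kappa(m, linear_weights(("normal", "low"))) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_matches_frozen_oracle_value(self):
        counts = np.array([[10, 2, 0, 0], [1, 8, 3, 0], [0, 2, 9, 1], [0, 0, 1, 13]])
        m = ConfusionMatrix(counts, DEFAULT_CLASS_ORDER)
        # value computed with kappa_oracle (direct formula) and frozen
        assert weighted_kappa(m) == pytest.approx(0.7899159663865546, abs=1e-12)
        assert weighted_kappa(m) == pytest.approx(kappa_oracle(counts, linear_weights()), abs=1e-14)

    def test_matches_direct_formula_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 15, size=(4, 4))
            counts[0, 0] += 1  # non-empty
            m = ConfusionMatrix(counts, DEFAULT_CLASS_ORDER)
            for w in (linear_weights(), quadratic_weights(), identity_weights()):
                assert weighted_kappa(m, w) == pytest.approx(kappa_oracle(counts, w), abs=1e-12)

    def test_identity_weights_reduce_to_sklearn_cohen_kappa(self, rng):
        """Independent library cross-check of the unweighted special case."""
        for _ in range(20):
            la = rng.integers(0, 4, size=60)
            lb = rng.integers(0, 4, size=60)
            order = DEFAULT_CLASS_ORDER
            a = RaterLabels("a", tuple(order[i] for i in la))
            b = RaterLabels("b", tuple(order[i] for i in lb))
            ours = weighted_kappa(confusion(a, b), identity_weights())
            assert ours == pytest.approx(cohen_kappa_score(la, lb), abs=1e-12)

    def test_linear_ordinal_weights_match_sklearn_on_graded_classes(self, rng):
        """On the purely ordinal 3-class scale our linear weights coincide
        with sklearn's linear-weighted kappa (weights differ by a scale
        factor, which cancels)."""
        order = ("normal", "low", "high")
        for _ in range(20):
            la = rng.integers(0, 3, size=80)
            lb = rng.integers(0, 3, size=80)
            a = RaterLabels("a", tuple(order[i] for i in la), order)
            b = RaterLabels("b", tuple(order[i] for i in lb), order)
            ours = weighted_kappa(confusion(a, b), linear_weights(order))
            theirs = cohen_kappa_score(la, lb, weights="linear")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_class_order_permutation(self, rng):
        la = random_labels(rng, 50)
        lb = random_labels(rng, 50)
        base = weighted_kappa(
            confusion(RaterLabels("a", la), RaterLabels("b", lb)), linear_weights()
        )
        perm = ("high", "unidentifiable", "normal", "low")
        permuted = weighted_kappa(
            confusion(RaterLabels("a", la, perm), RaterLabels("b", lb, perm)),
            linear_weights(perm),
        )
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_degenerate_marginals(self):
        order = ("normal", "low")
        # both raters concentrated in one class: zero expected and zero
        # observed disagreement, defined as perfect agreement
        all_same = ConfusionMatrix(np.array([[7, 0], [0, 0]]), order)
        assert weighted_kappa(all_same, linear_weights(order)) == 1.0
        # systematically opposite raters: full observed disagreement equals
        # the expected disagreement, so chance-corrected agreement is 0
        opposite = ConfusionMatrix(np.array([[0, 7], [0, 0]]), order)
        assert weighted_kappa(opposite, linear_weights(order)) == pytest.approx(0.0)

    def test_weight_matrix_validation(self):
        m = ConfusionMatrix(np.eye(4, dtype=int) * 3, DEFAULT_CLASS_ORDER)
        bad = linear_weights()
        bad = bad.copy(); bad[0, 0] = 0.5
        with pytest.raises(ValueError):
            weighted_kappa(m, bad)

    def test_per_class_accuracy_diagonal_fraction(self):
        counts = np.array([[8, 2, 0, 0], [0, 5, 5, 0], [0, 0, 0, 0], [0, 0, 0, 4]])
        m = ConfusionMatrix(counts, DEFAULT_CLASS_ORDER)
        acc = per_class_accuracy(m)
        assert acc["unidentifiable"] == pytest.approx(0.8)
        assert acc["normal"] == pytest.approx(0.5)
        assert np.isnan(acc["low"])
        assert 0.0 <= accuracy(m) <= 1.0


class TestMultiRater:
    def test_identical_raters_score_one(self, rng):
        labels = random_labels(rng, 30)
        raters = [RaterLabels(f"r{i}", labels) for i in range(3)]
        assert lights_kappa(raters) == 1.0
        assert detector_vs_team_kappa(raters[0], raters[1:]) == 1.0

    def test_rater_order_does_not_matter(self, rng):
        raters = [RaterLabels(f"r{i}", random_labels(rng, 40)) for i in range(3)]
        assert lights_kappa(raters) == pytest.approx(
            lights_kappa(list(reversed(raters))), abs=1e-14
        )

    def test_independent_raters_converge_to_zero(self):
        rng = np.random.default_rng(77)
        p = [0.1, 0.4, 0.3, 0.2]
        raters = [
            RaterLabels(f"r{i}", random_labels(rng, 10_000, p=p)) for i in range(3)
        ]
        assert abs(lights_kappa(raters)) < 0.03

    def test_single_member_team_equals_pairwise(self, rng):
        a = RaterLabels("det", random_labels(rng, 60))
        b = RaterLabels("r1", random_labels(rng, 60))
        pairwise = weighted_kappa(confusion(a, b))
        assert detector_vs_team_kappa(a, [b]) == pytest.approx(pairwise)
        # three copies of one rater average to the same pairwise value
        assert detector_vs_team_kappa(a, [b, b, b]) == pytest.approx(pairwise)


class TestStratified:
    def test_stratum_sizes_conserved(self, rng):
        n = 60
        quality = ["high" if rng.random() < 0.6 else "low" for _ in range(n)]
        raters = [RaterLabels(f"r{i}", random_labels(rng, n)) for i in range(3)]
        rep = stratified_agreement(quality, raters)
        assert rep["high"].n + rep["low"].n == rep["overall"].n == n

    def test_empty_stratum_reported_undefined(self, rng):
        n = 20
        raters = [RaterLabels(f"r{i}", random_labels(rng, n)) for i in range(2)]
        rep = stratified_agreement(["high"] * n, raters)
        assert rep["low"].n == 0
        assert rep["low"].lights_kappa is None
        assert rep["high"].lights_kappa is not None

    def test_noise_in_low_stratum_degrades_its_kappa(self):
        """Label noise confined to the low-quality stratum lowers agreement
        there while leaving the clean stratum at 1."""
        rng = np.random.default_rng(11)
        n = 400
        quality = ["high"] * (n // 2) + ["low"] * (n // 2)
        base = random_labels(rng, n)
        noisy = list(base)
        for i in range(n // 2, n):
            if rng.random() < 0.5:
                noisy[i] = str(rng.choice(DEFAULT_CLASS_ORDER))
        raters = [RaterLabels("clean", base), RaterLabels("noisy", tuple(noisy))]
        rep = stratified_agreement(quality, raters)
        assert rep["high"].lights_kappa == 1.0
        assert rep["low"].lights_kappa < rep["high"].lights_kappa
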