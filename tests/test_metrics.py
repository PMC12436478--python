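"""Evaluation statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from echostrain import metrics as met


def mann_whitney_auc(scores, labels):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked correctly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels):
    """Best J over every threshold between/beyond all unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    best = (-np.inf, None, None, None)
    for th in cands:
        pred = scores >= th
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        if sens + spec - 1 > best[0] + 1e-12:
            best = (sens + spec - 1, th, sens, spec)
    return best


class TestDice:
    def test_identical_masks(self):
        m = np.random.default_rng(0).integers(0, 2, (10, 10))
        assert met.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5)); a[0, 0] = 1
        b = np.zeros((5, 5)); b[4, 4] = 1
        assert met.dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(200); a[:100] = 1
        b = np.zeros(200); b[50:150] = 1
        assert met.dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert met.dice(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_symmetry_and_class_selection(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, (20, 20))
        b = rng.integers(0, 3, (20, 20))
        for c in (1, 2):
            assert met.dice(a, b, c) == met.dice(b, a, c)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            met.dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestBlandAltman:
    def test_identical_series(self):
        r = met.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_constant_offset(self):
        r = met.bland_altman(np.arange(5) + 0.01, np.arange(5, dtype=float))
        assert r.bias == pytest.approx(0.01)
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        diffs = np.array([-0.01, 0.00, 0.01, 0.02])
        r = met.bland_altman(diffs, np.zeros(4))
        bias = diffs.mean()
        sd = diffs.std(ddof=1)
        assert r.bias == pytest.approx(bias)
        assert r.loa_low == pytest.approx(bias - 1.96 * sd)
        assert r.loa_high == pytest.approx(bias + 1.96 * sd)

    def test_loa_width_identity(self):
        rng = np.random.default_rng(0)
        r = met.bland_altman(rng.normal(size=30), rng.normal(size=30))
        assert r.loa_high - r.loa_low == pytest.approx(2 * 1.96 * r.sd_diff)

    def test_too_short(self):
        with pytest.raises(ValueError):
            met.bland_altman([1.0], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert met.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores(self):
        assert met.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_u_statistic_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 2)  # induce ties
            assert met.roc_auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            met.roc_auc([0.1, 0.9], [1, 1])


class TestYouden:
    def test_perfect_separation(self):
        r = met.youden_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = labels.astype(float).copy()
        flip = rng.choice(100, 10, replace=False)
        scores[flip] = 1 - scores[flip]
        scores += rng.normal(0, 0.01, 100)
        r = met.youden_operating_point(scores, labels)
        j, th, sens, spec = exhaustive_youden(scores, labels)
        assert r.sensitivity + r.specificity - 1 == pytest.approx(j)
        assert r.threshold == pytest.approx(th)

    def test_constant_scores_degenerate(self):
        r = met.youden_operating_point([0.5] * 8, [0, 1] * 4)
        assert r.sensitivity + r.specificity - 1 == pytest.approx(0.0)


class TestStratifiedKFold:
    def test_exact_positive_count_per_fold(self):
        labels = np.array([1] * 20 + [0] * 80)
        folds = met.stratified_kfold(labels, k=5, seed=0)
        for _, te in folds:
            assert labels[te].sum() == 4

    def test_partition_properties(self):
        labels = np.random.default_rng(0).integers(0, 2, 53)
        folds = met.stratified_kfold(labels, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(53))

    def test_seeded_reproducibility(self):
        labels = np.random.default_rng(0).integers(0, 2, 40)
        a = met.stratified_kfold(labels, seed=5)
        b = met.stratified_kfold(labels, seed=5)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            met.stratified_kfold([0] * 20 + [1] * 3, k=5)


class TestTTest:
    def test_identical_samples(self):
        t, p = met.independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        a = np.array([0.91, 0.93, 0.90, 0.95, 0.92])
        b = np.array([0.88, 0.86, 0.90, 0.87, 0.89])
        t, p = met.independent_t_test(a, b)
        # Welch formula computed directly
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        t_direct = (a.mean() - b.mean()) / se
        df = (a.var(ddof=1) / 5 + b.var(ddof=1) / 5) ** 2 / (
            (a.var(ddof=1) / 5) ** 2 / 4 + (b.var(ddof=1) / 5) ** 2 / 4)
        p_direct = 2 * stats.t.sf(abs(t_direct), df)
        assert t == pytest.approx(t_direct)
        assert p == pytest.approx(p_direct)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(2.0, 1.0, 50)
        _, p = met.independent_t_test(a, b)
        assert p < 0.05

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            met.independent_t_test([1.0], [1.0, 2.0])
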