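"""Bias metrics against independent brute-force counting oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fairaudit import (aaod, bias_report, disparate_impact, eod,
                       group_confusion, group_loss_disparity, group_rates,
                       is_defined, spd)
from fairaudit.metrics import UNDEFINED, aggregate_defined


# -- independent naive oracle ------------------------------------------------

def naive_counts(pred, label, group, g):
    tp = tn = fp = fn = 0
    for p, y, gg in zip(pred, label, group):
        if gg != g:
            continue
        if p == 1 and y == 1:
            tp += 1
        elif p == 0 and y == 0:
            tn += 1
        elif p == 1 and y == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def naive_rate(num, den):
    return num / den if den else float("nan")


def naive_spd(pred, group):
    r = {}
    for g in (0, 1):
        rows = [p for p, gg in zip(pred, group) if gg == g]
        r[g] = naive_rate(sum(rows), len(rows))
    return r[0] - r[1]


def naive_tpr(pred, label, group, g):
    tp, tn, fp, fn = naive_counts(pred, label, group, g)
    return naive_rate(tp, tp + fn)


def naive_fpr(pred, label, group, g):
    tp, tn, fp, fn = naive_counts(pred, label, group, g)
    return naive_rate(fp, fp + tn)


class TestGroupConfusion:
    def test_perfect_classifier_has_no_errors(self):
        label = np.array([0, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        gc = group_confusion(label, label, group)
        assert gc.privileged.fp == gc.privileged.fn == 0
        assert gc.unprivileged.fp == gc.unprivileged.fn == 0

    def test_inverted_classifier_has_no_hits(self):
        label = np.array([0, 1, 0, 1])
        group = np.array([0, 0, 1, 1])
        gc = group_confusion(1 - label, label, group)
        assert gc.privileged.tp == gc.privileged.tn == 0
        assert gc.unprivileged.tp == gc.unprivileged.tn == 0

    def test_hand_enumerated_four_rows(self):
        pred = [1, 0, 1, 1]
        label = [1, 0, 0, 1]
        group = [0, 0, 1, 1]
        gc = group_confusion(pred, label, group)
        assert (gc.privileged.tp, gc.privileged.fp) == (1, 1)
        assert (gc.unprivileged.tp, gc.unprivileged.tn) == (1, 1)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            group_confusion([1, 0], [1], [0, 1])

    def test_counts_sum_to_group_sizes(self):
        rng = np.random.default_rng(0)
        pred, label, group = (rng.integers(0, 2, 200) for _ in range(3))
        gc = group_confusion(pred, label, group)
        assert gc.privileged.n == int(group.sum())
        assert gc.unprivileged.n == int((1 - group).sum())


class TestGroupRates:
    def test_tpr_arithmetic(self):
        pred = [1, 1, 1, 0, 0]
        label = [1, 1, 1, 1, 0]
        group = [1, 1, 1, 1, 1]
        r = group_rates(group_confusion(pred, label, group)).privileged
        assert r["TPR"] == pytest.approx(0.75)

    def test_empty_denominator_is_undefined_not_zero(self):
        pred, label, group = [0, 1], [0, 0], [1, 1]  # no positives anywhere
        r = group_rates(group_confusion(pred, label, group))
        assert math.isnan(r.privileged["TPR"])
        assert math.isnan(r.unprivileged["TPR"])  # empty group: all undefined

    def test_complement_identities(self):
        rng = np.random.default_rng(7)
        pred = rng.integers(0, 2, 400)
        label = rng.integers(0, 2, 400)
        group = rng.integers(0, 2, 400)
        r = group_rates(group_confusion(pred, label, group))
        for side in (r.privileged, r.unprivileged):
            assert side["TPR"] + side["FNR"] == pytest.approx(1.0)
            assert side["TNR"] + side["FPR"] == pytest.approx(1.0)
            assert side["PPV"] + side["FDR"] == pytest.approx(1.0)
            assert side["NPV"] + side["FOR"] == pytest.approx(1.0)


class TestBiasMetricsAgainstOracle:
    """Every metric equals the naive re-count on many random triples."""

    def test_oracle_equivalence_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            pred = rng.integers(0, 2, n)
            label = rng.integers(0, 2, n)
            group = rng.integers(0, 2, n)
            if group.min() == group.max():
                continue
            expected_spd = naive_spd(pred, group)
            assert spd(pred, group) == pytest.approx(expected_spd)

            t0, t1 = (naive_tpr(pred, label, group, g) for g in (0, 1))
            got_eod = eod(pred, label, group)
            if math.isnan(t0) or math.isnan(t1):
                assert math.isnan(got_eod)
            else:
                assert got_eod == pytest.approx(t0 - t1)

            f0, f1 = (naive_fpr(pred, label, group, g) for g in (0, 1))
            got_aaod = aaod(pred, label, group, signed=False)
            if any(map(math.isnan, (t0, t1, f0, f1))):
                assert math.isnan(got_aaod)
            else:
                assert got_aaod == pytest.approx(
                    0.5 * (abs(f0 - f1) + abs(t0 - t1)))

            r_priv = pred[group == 1].mean()
            got_di = disparate_impact(pred, group)
            if r_priv == 0:
                assert math.isnan(got_di)
            else:
                assert got_di == pytest.approx(
                    pred[group == 0].mean() / r_priv)

    def test_spd_examples(self):
        # rates 0.5 (unpriv) vs 1.0 (priv) -> -0.5
        pred = [1, 0, 1, 1]
        group = [0, 0, 1, 1]
        assert spd(pred, group) == pytest.approx(-0.5)
        assert spd([1, 1, 1, 1], group) == 0.0

    def test_di_spd_identity(self):
        """DI = 1 + SPD / P(pos | priv) on random vectors."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            pred = rng.integers(0, 2, 60)
            group = rng.integers(0, 2, 60)
            r_priv = pred[group == 1].mean() if (group == 1).any() else 0
            if r_priv == 0 or not (group == 0).any():
                continue
            assert disparate_impact(pred, group) == pytest.approx(
                1 + spd(pred, group) / r_priv)

    def test_eod_hand_counts(self):
        # TPR unpriv 0.6 (3/5), TPR priv 0.9 (9/10) -> EOD -0.3
        pred = [1] * 3 + [0] * 2 + [1] * 9 + [0] * 1
        label = [1] * 5 + [1] * 10
        group = [0] * 5 + [1] * 10
        assert eod(pred, label, group) == pytest.approx(-0.3)

    def test_eod_invariant_to_added_negatives(self):
        pred = [1, 0, 1, 1]
        label = [1, 1, 1, 1]
        group = [0, 0, 1, 1]
        base = eod(pred, label, group)
        pred2 = pred + [1, 0, 1]
        label2 = label + [0, 0, 0]
        group2 = group + [0, 1, 1]
        assert eod(pred2, label2, group2) == pytest.approx(base)

    def test_aaod_magnitude_arithmetic(self):
        # |dFPR| = 0.1, |dTPR| = 0.3 -> magnitude 0.2, via counts:
        # priv: TPR 0.9 (9/10), FPR 0.1 (1/10)
        # unpriv: TPR 0.6 (6/10), FPR 0.2 (2/10)
        pred = ([1] * 9 + [0] + [1] + [0] * 9        # priv
                + [1] * 6 + [0] * 4 + [1] * 2 + [0] * 8)  # unpriv
        label = [1] * 10 + [0] * 10 + [1] * 10 + [0] * 10
        group = [1] * 20 + [0] * 20
        assert aaod(pred, label, group, signed=False) == pytest.approx(0.2)
        assert aaod(pred, label, group) == pytest.approx(-0.2)  # TPR gap < 0

    def test_aaod_zero_for_identical_confusions(self):
        pred = [1, 0, 1, 0]
        label = [1, 0, 0, 1]
        group = [1, 1, 0, 0]
        # identical per-group confusion patterns
        pred2 = [1, 0, 1, 0, 1, 0, 1, 0]
        label2 = [1, 0, 1, 0, 1, 0, 1, 0]
        group2 = [1, 1, 1, 1, 0, 0, 0, 0]
        assert aaod(pred2, label2, group2) == 0.0

    def test_aaod_at_least_half_eod(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pred = rng.integers(0, 2, 40)
            label = rng.integers(0, 2, 40)
            group = rng.integers(0, 2, 40)
            a = aaod(pred, label, group, signed=False)
            e = eod(pred, label, group)
            if is_defined(a) and is_defined(e):
                assert a >= 0.5 * abs(e) - 1e-12


class TestGroupLossDisparity:
    def test_identical_error_rates_give_zero(self):
        # both groups have one hit and one miss: error rate 0.5 each
        pred = np.array([1, 0, 0, 1])
        label = np.array([1, 1, 0, 0])
        group = np.array([1, 1, 0, 0])
        assert group_loss_disparity(pred, label, group) == pytest.approx(0.0)

    def test_hand_means(self):
        # group 1 error rate 0.1 (1/10), group 0 error rate 0.35 (7/20)
        label = np.array([1] * 10 + [1] * 20)
        pred = np.array([1] * 9 + [0] + [1] * 13 + [0] * 7)
        group = np.array([1] * 10 + [0] * 20)
        assert group_loss_disparity(pred, label, group) == pytest.approx(0.25)

    def test_zero_one_equals_accuracy_gap(self):
        rng = np.random.default_rng(2)
        pred = rng.integers(0, 2, 100).astype(float)
        label = rng.integers(0, 2, 100)
        group = rng.integers(0, 2, 100)
        acc1 = (pred[group == 1].astype(int) == label[group == 1]).mean()
        acc0 = (pred[group == 0].astype(int) == label[group == 0]).mean()
        assert group_loss_disparity(pred, label, group) == pytest.approx(
            abs(acc1 - acc0))


@st.composite
def triples(draw):
    n = draw(st.integers(min_value=4, max_value=60))
    bits = st.lists(st.integers(0, 1), min_size=n, max_size=n)
    pred = np.array(draw(bits))
    label = np.array(draw(bits))
    group = np.array(draw(bits))
    return pred, label, group


class TestProperties:
    @given(triples())
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariance(self, triple):
        pred, label, group = triple
        perm = np.random.default_rng(0).permutation(len(pred))
        a = (spd(pred, group), eod(pred, label, group),
             aaod(pred, label, group, signed=False))
        b = (spd(pred[perm], group[perm]),
             eod(pred[perm], label[perm], group[perm]),
             aaod(pred[perm], label[perm], group[perm], signed=False))
        for x, y in zip(a, b):
            assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)

    @given(triples())
    @settings(max_examples=200, deadline=None)
    def test_privileged_swap_symmetry(self, triple):
        """Swapping the privileged designation negates SPD and EOD,
        inverts DI, and preserves the AAOD magnitude."""
        pred, label, group = triple
        s = spd(pred, group)
        if is_defined(s):
            assert spd(pred, 1 - group) == pytest.approx(-s)
            assert abs(s) <= 1.0
        e = eod(pred, label, group)
        if is_defined(e):
            assert eod(pred, label, 1 - group) == pytest.approx(-e)
            assert abs(e) <= 1.0
        d = disparate_impact(pred, group)
        d_swap = disparate_impact(pred, 1 - group)
        if is_defined(d) and is_defined(d_swap) and d > 0:
            assert d_swap == pytest.approx(1.0 / d)
        a = aaod(pred, label, group, signed=False)
        a_swap = aaod(pred, label, 1 - group, signed=False)
        if is_defined(a):
            assert a_swap == pytest.approx(a)


class TestAggregation:
    def test_undefined_entries_skipped_and_counted(self):
        mean, sd, skipped = aggregate_defined([0.5, UNDEFINED, 1.0])
        assert mean == pytest.approx(0.75)
        assert skipped == 1

    def test_all_undefined(self):
        mean, sd, skipped = aggregate_defined([UNDEFINED, UNDEFINED])
        assert math.isnan(mean) and skipped == 2

    def test_bias_report_records_convention(self):
        pred = [1, 0, 1, 0]
        label = [1, 0, 0, 1]
        group = [1, 1, 0, 0]
        rep = bias_report(pred, label, group)
        assert rep.convention["sign"] == "unprivileged - privileged"
        assert rep.n_privileged == 2 and rep.n_unprivileged == 2
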