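import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import mutual_info_score

from hmfw import (
    ExpressionDataset,
    FilterBudget,
    SYSchedule,
    entropy,
    feature_budget,
    information_gain,
    mmi,
    ms1,
    ms2,
    msmmi_select,
    mutual_information,
    rf_fim_rank,
    spearman,
    sy_schedule,
)
from hmfw.filters import FilterError


def _ds_from_matrix(mat, labels):
    mat = np.asarray(mat, dtype=float)
    return ExpressionDataset(
        mat,
        np.asarray(labels),
        [f"g{j}" for j in range(mat.shape[1])],
        [f"s{i}" for i in range(mat.shape[0])],
    )


class TestEntropyAndIG:
    @pytest.mark.parametrize(
        "labels,expected",
        [([0, 0, 1, 1], 1.0), ([0, 0, 0], 0.0), ([0, 1, 2, 3], 2.0)],
    )
    def test_known_values_bits(self, labels, expected):
        assert entropy(labels) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(FilterError):
            entropy([])

    @pytest.mark.parametrize(
        "parts,expected",
        [
            ([[0, 1], [2, 3]], 1.0),  # perfect split recovers H(D)
            ([[0, 1, 2, 3]], 0.0),  # no split, no gain
            ([[0, 2], [1, 3]], 0.0),  # each part stays maximally mixed
        ],
    )
    def test_information_gain(self, parts, expected):
        assert information_gain([0, 0, 1, 1], parts) == pytest.approx(expected)

    def test_non_partition_rejected(self):
        with pytest.raises(FilterError):
            information_gain([0, 0, 1, 1], [[0, 1], [1, 2, 3]])


class TestMutualInformation:
    def test_worked_example_nonlinear_pair(self):
        a = [0, 1, 2, 3, 4]
        b = [0.2, 0.8, 2.3, 3.6, 4.8]
        assert mutual_information(a, b) == pytest.approx(1.609, abs=1e-3)

    def test_worked_example_weak_pair(self):
        c = [0, 1, 2, 3, 4]
        d = [0.2, 0.4, 0.2, 0.4, 0.2]
        assert mutual_information(c, d) == pytest.approx(0.673, abs=1e-3)

    def test_independent_uniform_is_zero(self):
        assert mutual_information([0, 1, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_matches_sklearn_plugin_estimator(self):
        """Independent oracle: sklearn's contingency-based MI (nats)."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.integers(0, 4, size=30)
            y = rng.integers(0, 3, size=30)
            assert mutual_information(x, y) == pytest.approx(
                mutual_info_score(x, y), abs=1e-12
            )

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_self_information(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 3), min_size=len(xs), max_size=len(xs)))
        assert mutual_information(xs, ys) == pytest.approx(
            mutual_information(ys, xs), abs=1e-12
        )
        # MI(x, x) = H(x) in nats
        h_nats = entropy(xs) * math.log(2)
        assert mutual_information(xs, xs) == pytest.approx(h_nats, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(FilterError):
            mutual_information([0, 1], [0, 1, 2])


class TestSpearman:
    def test_worked_example_with_ties(self):
        f1 = [0.8, 0.8, 0.7, 0.4, 0.9, 0.6, 0.7]
        f2 = [0.5, 0, 0, 0.1, 0.5, 0.1, 0.1]
        assert spearman(f1, f2) == pytest.approx(0.384, abs=1e-3)

    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_matches_scipy_without_ties(self):
        """The printed formula equals Pearson-of-ranks when there are no ties."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.permutation(n).astype(float) + rng.uniform(0, 0.4, n)
            y = rng.permutation(n).astype(float) + rng.uniform(0, 0.4, n)
            assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(FilterError):
            spearman([1.0], [2.0])


class TestMMIandMS:
    def test_mmi_label_copy_wins_with_entropy_value(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        mat = np.column_stack([labels.astype(float), np.ones(6)])
        ds = _ds_from_matrix(mat, labels)
        j, v = mmi([0, 1], ds)
        assert j == 0
        assert v == pytest.approx(entropy(labels) * math.log(2), abs=1e-12)

    def test_mmi_constant_tie_goes_to_lowest_index(self):
        labels = np.array([0, 1, 0, 1])
        mat = np.ones((4, 3))
        ds = _ds_from_matrix(mat, labels)
        j, v = mmi([2, 1, 0], ds)
        assert j == 0 and v == pytest.approx(0.0)

    def test_ms1_prefers_anticorrelated(self):
        mat = np.array([[1, 1, 3], [2, 2, 2], [3, 3, 1.0]])
        ds = _ds_from_matrix(mat, [0, 1, 0])
        j, v = ms1(0, [1, 2], ds)
        assert j == 2 and v == pytest.approx(-1.0)

    def test_ms1_matches_brute_force(self):
        rng = np.random.default_rng(5)
        ds = _ds_from_matrix(rng.normal(size=(15, 7)), rng.integers(0, 2, 15))
        j, v = ms1(0, range(1, 7), ds)
        pairs = [(spearman(ds.matrix[:, 0], ds.matrix[:, k]), k) for k in range(1, 7)]
        exp_v, exp_j = min(pairs)
        assert (j, v) == (exp_j, pytest.approx(exp_v))

    def test_ms2_single_selected_reduces_to_ms1(self):
        rng = np.random.default_rng(6)
        ds = _ds_from_matrix(rng.normal(size=(12, 6)), rng.integers(0, 2, 12))
        assert ms2([0], [1, 2, 3], ds) == ms1(0, [1, 2, 3], ds)

    def test_ms2_matches_brute_force(self):
        rng = np.random.default_rng(8)
        ds = _ds_from_matrix(rng.normal(size=(14, 8)), rng.integers(0, 2, 14))
        selected, cands = [0, 1, 2], [3, 4, 5, 6, 7]
        j, v = ms2(selected, cands, ds)
        best = min(
            (min(spearman(ds.matrix[:, c], ds.matrix[:, p]) for p in selected), c)
            for c in cands
        )
        assert (j, v) == (best[1], pytest.approx(best[0]))

    def test_ms2_overlap_rejected(self):
        rng = np.random.default_rng(9)
        ds = _ds_from_matrix(rng.normal(size=(10, 4)), rng.integers(0, 2, 10))
        with pytest.raises(FilterError):
            ms2([0, 1], [1, 2], ds)


class TestSchedule:
    @pytest.mark.parametrize(
        "i,I,exp_s,exp_y",
        [(0, 10, 1.0, 0.0), (10, 10, 0.0, 1.0), (5, 10, math.sqrt(2) / 2, math.sqrt(2) / 2)],
    )
    def test_endpoints_and_midpoint(self, i, I, exp_s, exp_y):
        s, y = sy_schedule(SYSchedule(i=i, I=I))
        assert s == pytest.approx(exp_s)
        assert y == pytest.approx(exp_y)
        assert s * s + y * y == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(FilterError):
            SYSchedule(i=11, I=10)


class TestFeatureBudget:
    def _ds(self, n, f):
        rng = np.random.default_rng(0)
        return _ds_from_matrix(rng.normal(size=(n, f)), [0, 1] * (n // 2))

    def test_negative_raw_clamps_to_k_min(self):
        # e=4 with p=0.8 puts cos(3.2 rad) ~ -0.998; a huge negative term
        ds = self._ds(4, 1000)
        budget = FilterBudget(randnum_a_low=10, randnum_a_high=20, p=0.8, k_min=5)

        class FixedRng:
            def uniform(self, lo, hi):
                return (lo + hi) / 2

        assert feature_budget(ds, budget, "M2", FixedRng()) == 5

    def test_always_within_clamp_bounds(self):
        ds = self._ds(62, 2000)
        budget = FilterBudget(k_min=5, k_max_fraction=0.5)
        rng = np.random.default_rng(1)
        k_max = math.ceil(0.5 * 2000)
        for _ in range(1000):
            k = feature_budget(ds, budget, "M2", rng)
            assert 5 <= k <= k_max

    def test_monotone_in_baseline_at_fixed_draw(self):
        ds = self._ds(62, 2000)

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def uniform(self, lo, hi):
                self.calls += 1
                return lo if self.calls == 1 else 5.0  # baseline at range floor

        lo_b = feature_budget(ds, FilterBudget(randnum_a_low=10, randnum_a_high=20), "M2", FixedRng())
        hi_b = feature_budget(ds, FilterBudget(randnum_a_low=40, randnum_a_high=50), "M2", FixedRng())
        assert hi_b >= lo_b

    def test_m1_stage_uses_expanded_baseline(self):
        ds = self._ds(62, 2000)

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def uniform(self, lo, hi):
                self.calls += 1
                return (lo + hi) / 2 if self.calls == 1 else 1.0  # tiny cosine term

        k1 = feature_budget(ds, FilterBudget(), "M1", FixedRng())
        k2 = feature_budget(ds, FilterBudget(), "M2", FixedRng())
        assert k1 > k2  # baseline midpoint 150 vs 15


class TestRFFIM:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(21)
        labels = rng.integers(0, 2, 60)
        mat = rng.normal(size=(60, 200))
        mat[:, 0] = labels.astype(float)
        ds = _ds_from_matrix(mat, labels)
        ranking = rf_fim_rank(ds, k1=5, seed=0)
        assert 0 in ranking.indices

    def test_contract_and_determinism(self, small_synth):
        ds, _ = small_synth
        r1 = rf_fim_rank(ds, k1=30, seed=4)
        r2 = rf_fim_rank(ds, k1=30, seed=4)
        assert len(r1.entries) == 30
        scores = [s for _, s in r1.entries]
        assert scores == sorted(scores, reverse=True)
        assert r1.entries == r2.entries

    def test_k1_out_of_range(self, small_synth):
        ds, _ = small_synth
        with pytest.raises(FilterError):
            rf_fim_rank(ds, k1=0, seed=0)


def msmmi_brute_force(candidates, ds, k2, schedule, bins=None):
    """Independent greedy oracle: re-evaluates every term from scratch each step."""
    s, y = schedule.s, schedule.y
    remaining = sorted(set(candidates))
    selected = []
    while len(selected) < k2:
        scores = []
        for f in remaining:
            rel = s * mutual_information(ds.labels, ds.matrix[:, f], bins=bins)
            if not selected:
                red = 0.0
            elif len(selected) == 1:
                red = spearman(ds.matrix[:, selected[0]], ds.matrix[:, f])
            else:
                red = min(spearman(ds.matrix[:, p], ds.matrix[:, f]) for p in selected)
            scores.append((-(rel - y * red), f))
        scores.sort()
        selected.append(scores[0][1])
        remaining.remove(scores[0][1])
    return selected


class TestMsmmiSelect:
    def test_pure_mi_ordering_at_schedule_start(self, tiny_ds):
        sched = SYSchedule(i=0, I=10)
        got = msmmi_select(range(6), tiny_ds, k2=6, schedule=sched, bins=4)
        mis = [
            mutual_information(tiny_ds.labels, tiny_ds.matrix[:, j], bins=4)
            for j in range(6)
        ]
        expected = sorted(range(6), key=lambda j: (-mis[j], j))
        assert got == expected

    def test_k2_one_is_argmax_mi(self, tiny_ds):
        sched = SYSchedule(i=3, I=10)
        got = msmmi_select(range(6), tiny_ds, k2=1, schedule=sched, bins=4)
        assert got == [mmi(range(6), tiny_ds, bins=4)[0]]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for trial in range(100):
            n_feat = int(rng.integers(4, 9))
            n = int(rng.integers(8, 20))
            ds = _ds_from_matrix(
                rng.normal(size=(n, n_feat)), rng.integers(0, 2, n)
            )
            k2 = int(rng.integers(1, n_feat + 1))
            sched = SYSchedule(i=int(rng.integers(0, 11)), I=10)
            got = msmmi_select(range(n_feat), ds, k2, sched, bins=4)
            exp = msmmi_brute_force(range(n_feat), ds, k2, sched, bins=4)
            assert got == exp, f"trial {trial}"

    def test_candidate_order_invariance_and_subset(self, tiny_ds):
        sched = SYSchedule(i=5, I=10)
        a = msmmi_select([0, 1, 2, 3, 4, 5], tiny_ds, 4, sched, bins=4)
        b = msmmi_select([5, 3, 1, 4, 2, 0], tiny_ds, 4, sched, bins=4)
        assert a == b
        assert len(set(a)) == 4 and set(a) <= set(range(6))

    def test_k2_too_large_rejected(self, tiny_ds):
        with pytest.raises(FilterError):
            msmmi_select(range(6), tiny_ds, 7, SYSchedule(0, 10))
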