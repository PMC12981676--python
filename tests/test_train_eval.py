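"""Splits, metric oracles, improvement reporting, early stopping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kanpm.core_data import InteractionRecord
from kanpm.train_eval import (
    EarlyStopper,
    MetricReport,
    SplitSpec,
    concordance_index,
    mse,
    relative_change,
    repeat_experiment,
    rm_squared,
    split_dataset,
)


def _interactions(n_drugs=12, n_proteins=12, n=None, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [(f"d{i}", f"p{j}") for i in range(n_drugs) for j in range(n_proteins)]
    if n is not None:
        keep = rng.choice(len(pairs), size=n, replace=False)
        pairs = [pairs[k] for k in keep]
    return [InteractionRecord(d, p, float(rng.standard_normal()))
            for d, p in pairs]


def _ci_bruteforce(y, p):
    """Independent O(n^2) double-loop oracle for the concordance index."""
    num, z = 0.0, 0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] > y[j]:
                z += 1
                if p[i] > p[j]:
                    num += 1.0
                elif p[i] == p[j]:
                    num += 0.5
    return num / z


class TestSplits:
    def test_warm_sizes_follow_floor_remainder_rule(self):
        inter = _interactions(40, 25, n=1000)
        res = split_dataset(inter, SplitSpec("warm", seed=1))
        assert (len(res.train), len(res.val), len(res.test)) == (800, 100, 100)

    def test_warm_union_is_exactly_the_input(self):
        inter = _interactions(10, 10, n=73)
        res = split_dataset(inter, SplitSpec("warm", seed=2))
        combined = res.train + res.val + res.test
        assert len(combined) == 73
        key = lambda r: (r.drug_id, r.protein_id)
        assert sorted(map(key, combined)) == sorted(map(key, inter))

    def test_same_seed_idempotent(self):
        inter = _interactions(10, 10, n=60)
        a = split_dataset(inter, SplitSpec("unseen_drug", seed=5))
        b = split_dataset(inter, SplitSpec("unseen_drug", seed=5))
        for pa, pb in zip(a, b):
            assert [(r.drug_id, r.protein_id) for r in pa] == \
                   [(r.drug_id, r.protein_id) for r in pb]

    def test_unseen_drug_ids_disjoint_from_train_and_val(self):
        inter = _interactions(20, 8)
        res = split_dataset(inter, SplitSpec("unseen_drug", seed=3))
        test_drugs = {r.drug_id for r in res.test}
        seen = {r.drug_id for r in res.train} | {r.drug_id for r in res.val}
        assert test_drugs and not (test_drugs & seen)

    def test_unseen_protein_symmetric(self):
        inter = _interactions(8, 20)
        res = split_dataset(inter, SplitSpec("unseen_protein", seed=4))
        test_prots = {r.protein_id for r in res.test}
        seen = {r.protein_id for r in res.train} | {r.protein_id for r in res.val}
        assert test_prots and not (test_prots & seen)

    def test_all_unseen_both_id_sets_disjoint_and_discards_counted(self):
        inter = _interactions(15, 15)
        res = split_dataset(inter, SplitSpec("all_unseen", seed=6))
        for attr in ("drug_id", "protein_id"):
            test_ids = {getattr(r, attr) for r in res.test}
            seen = {getattr(r, attr) for r in res.train} | \
                   {getattr(r, attr) for r in res.val}
            assert test_ids and not (test_ids & seen)
        kept = len(res.train) + len(res.val) + len(res.test)
        assert kept + res.n_discarded == len(inter)
        assert res.n_discarded > 0  # mixed buckets necessarily occur

    def test_too_few_entities_error_names_mode(self):
        inter = _interactions(4, 20)
        with pytest.raises(ValueError, match="unseen_drug"):
            split_dataset(inter, SplitSpec("unseen_drug", seed=0))

    def test_too_few_interactions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_interactions(3, 3), SplitSpec("warm"))


class TestMSE:
    def test_perfect_prediction_zero(self):
        assert mse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        assert mse([0, 0], [1, 3]) == pytest.approx(5.0)

    def test_quadratic_scaling(self, rng):
        y, p = rng.standard_normal(20), rng.standard_normal(20)
        assert mse(2 * y, 2 * p) == pytest.approx(4 * mse(y, p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([1, 2], [1, 2, 3])


class TestConcordanceIndex:
    def test_perfect_ranking_is_one(self):
        assert concordance_index([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_reversed_ranking_is_zero(self):
        assert concordance_index([1, 2, 3], [3, 2, 1]) == 0.0

    def test_constant_predictions_half(self):
        assert concordance_index([1, 2, 3], [5, 5, 5]) == 0.5

    def test_hand_computed_two_thirds(self):
        assert concordance_index([1, 2, 3], [1, 3, 2]) == pytest.approx(2 / 3)

    def test_all_labels_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            concordance_index([2, 2, 2], [1, 2, 3])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            y = rng.integers(0, 6, size=n).astype(float)  # label ties likely
            p = np.round(rng.standard_normal(n), 1)       # prediction ties too
            if np.all(y == y[0]):
                continue
            assert concordance_index(y, p) == pytest.approx(
                _ci_bruteforce(y, p))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(15)
        p = rng.standard_normal(15)
        base = concordance_index(y, p)
        assert concordance_index(y, np.exp(p)) == pytest.approx(base)
        assert concordance_index(y, 3 * p + 7) == pytest.approx(base)


class TestRmSquared:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert rm_squared(y, y) == pytest.approx(1.0)

    def test_equal_r2_r02_collapses_to_r2(self, rng):
        # y = k p exactly: the through-origin fit is perfect, r0^2 = r^2 = 1
        p = rng.uniform(1, 2, 10)
        assert rm_squared(3 * p, p) == pytest.approx(1.0)

    def test_arithmetic_oracle_four_points(self):
        """Spreadsheet-style independent recomputation of both formulas."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        p = np.array([1.1, 1.9, 3.2, 3.8])
        r2 = np.corrcoef(p, y)[0, 1] ** 2
        k = (y * p).sum() / (p * p).sum()
        r02 = 1 - ((y - k * p) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        expected = r2 * (1 - np.sqrt(max(r2 - r02, 0)))
        assert rm_squared(y, p) == pytest.approx(expected)

    def test_radicand_clamp_never_nan(self, rng):
        for _ in range(1000):
            y = rng.standard_normal(8)
            p = rng.standard_normal(8)
            val = rm_squared(y, p)
            assert np.isfinite(val)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            rm_squared([1, 1, 1], [1, 2, 3])


class TestRelativeChange:
    def test_decrease_phrasing(self):
        assert relative_change(0.218, 0.204, "decrease") == 6.42

    def test_increase_phrasing(self):
        assert relative_change(0.894, 0.898, "increase") == 0.45

    def test_no_change_is_zero(self):
        assert relative_change(0.5, 0.5, "decrease") == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 1.0)


class TestRepeatExperiment:
    def test_identical_metrics_have_zero_sd(self):
        report = repeat_experiment(lambda s: {"mse": 0.5, "n": 10}, seed=3,
                                   n_repeats=4)
        assert report.mean("mse") == 0.5
        assert report.sd("mse") == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        vals = iter([1.0, 2.0, 3.0])
        report = repeat_experiment(lambda s: {"ci": next(vals), "n": 5},
                                   seed=0, n_repeats=3)
        assert report.mean("ci") == pytest.approx(2.0)
        assert report.sd("ci") == pytest.approx(1.0)

    def test_cell_formatting_matches_convention(self):
        report = MetricReport(per_seed=[{"mse": 0.2}, {"mse": 0.208}], n=10)
        assert report.cell("mse") == "0.204 (0.006)"

    def test_seeds_are_consecutive(self):
        seen = []
        repeat_experiment(lambda s: seen.append(s) or {"x": 0.0, "n": 1},
                          seed=11, n_repeats=3)
        assert seen == [11, 12, 13]


class TestEarlyStopper:
    def test_stops_exactly_21_epochs_after_best_on_flat_trace(self):
        stopper = EarlyStopper(patience=20)
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(epoch, 1.0):  # constant validation loss
                stopped_at = epoch
                break
        # epoch 1 is the best; epochs 2..22 are the 21 non-improving ones
        assert stopped_at == 22
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        trace = [5.0, 4.0, 4.5, 3.9, 4.2, 4.2, 4.2]
        stops = [stopper.update(e, v) for e, v in enumerate(trace, start=1)]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 4
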