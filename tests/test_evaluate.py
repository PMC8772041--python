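from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import matthews_corrcoef

from conftest import make_chain
from oracles import brute_metrics
from metalbind import extract_all, extract_fragments
from metalbind.evaluate import (
    chain_split,
    from_predictions,
    kfold_cv,
    metrics,
    summarize,
    undersample_eval,
)


class StubPipeline:
    """Deterministic label-free rule: call positive iff the center residue
    is acidic/amide (D/E/N).  Records every training and test set it sees."""

    fitted_sets = None

    def __init__(self, record=None, rule=None):
        self.record = record
        self.rule = rule or (lambda f: f.residues[len(f) // 2] in "DEN")

    def fit(self, fragments):
        if self.record is not None:
            self.record.append(list(fragments))
        return self

    def predict(self, fragments):
        calls = np.array([self.rule(f) for f in fragments])
        return calls.astype(float), calls


class TestMetrics:
    @pytest.mark.parametrize("counts,expect", [
        ((50, 0, 50, 0), (100.0, 100.0, 100.0, 1.0)),       # perfect
        ((5, 5, 5, 5), (50.0, 50.0, 50.0, 0.0)),            # chance
        ((20, 5, 80, 10), (200 / 3, 1600 / 17, 2000 / 23, 0.6471)),
    ])
    def test_hand_computed_values(self, counts, expect):
        r = metrics(*counts)
        assert r.sn == pytest.approx(expect[0], abs=0.01)
        assert r.sp == pytest.approx(expect[1], abs=0.01)
        assert r.acc == pytest.approx(expect[2], abs=0.01)
        assert r.mcc == pytest.approx(expect[3], abs=1e-4)

    def test_zero_denominator_defines_mcc_zero(self):
        assert metrics(0, 0, 10, 5).mcc == 0.0   # no predicted positives
        assert metrics(0, 3, 7, 0).mcc == 0.0    # no true positives

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 5, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_matches_brute_recount_and_sklearn(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [c for _, c in pairs]
        r = from_predictions(y_true, y_pred)
        tp, fp, tn, fn, sn, sp, acc, mcc = brute_metrics(pairs)
        assert (r.tp, r.fp, r.tn, r.fn) == (tp, fp, tn, fn)
        assert r.sn == pytest.approx(sn) and r.sp == pytest.approx(sp)
        assert r.acc == pytest.approx(acc)
        assert r.mcc == pytest.approx(mcc)
        if len(set(y_true)) == 2:  # sklearn as independent cross-check
            assert r.mcc == pytest.approx(
                matthews_corrcoef([int(t) for t in y_true], [int(c) for c in y_pred]))

    def test_total_equals_count(self):
        assert metrics(1, 2, 3, 4).total == 10


def _signal_fragments(n_chains=6, seed=0):
    """Chains whose binding sites sit on D residues, so the stub rule works."""
    rng = np.random.default_rng(seed)
    chains = []
    for c in range(n_chains):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        binding = tuple(i for i, aa in enumerate(seq) if aa == "D")[:4]
        chains.append(make_chain(seq, binding=binding, chain_id=f"c{c}"))
    return chains


class TestKFoldCV:
    def test_every_fragment_tested_exactly_once(self):
        frags = extract_all(_signal_fragments())
        tested = []

        class Recorder(StubPipeline):
            def predict(self, fs):
                tested.extend((f.chain_id, f.center) for f in fs)
                return super().predict(fs)

        kfold_cv(frags, lambda seed: Recorder(), k=5, seed=0)
        assert sorted(tested) == sorted((f.chain_id, f.center) for f in frags)
        assert len(tested) == len(set(tested)) == len(frags)

    def test_majority_negative_rule_gives_sn0_sp100(self):
        frags = extract_all(_signal_fragments())
        result = kfold_cv(frags, lambda seed: StubPipeline(rule=lambda f: False),
                          k=5, seed=0)
        assert result.pooled.sn == 0.0 and result.pooled.sp == 100.0

    def test_duplicating_fragments_preserves_pooled_rates(self):
        frags = extract_all(_signal_fragments())
        a = kfold_cv(frags, lambda seed: StubPipeline(), k=5, seed=0).pooled
        b = kfold_cv(frags + frags, lambda seed: StubPipeline(), k=5, seed=0).pooled
        assert (a.sn, a.sp, a.acc, a.mcc) == pytest.approx((b.sn, b.sp, b.acc, b.mcc))

    def test_group_by_chain_keeps_chains_whole(self):
        frags = extract_all(_signal_fragments(n_chains=9))
        fold_of_chain = {}

        class Recorder(StubPipeline):
            def __init__(self, fold):
                super().__init__()
                self.fold = fold

            def predict(self, fs):
                for f in fs:
                    fold_of_chain.setdefault(f.chain_id, set()).add(self.fold)
                return super().predict(fs)

        fold_counter = iter(range(100))
        kfold_cv(frags, lambda seed: Recorder(next(fold_counter)), k=3,
                 seed=0, group_by_chain=True)
        assert all(len(folds) == 1 for folds in fold_of_chain.values())

    def test_single_class_training_fold_rejected(self):
        chain = make_chain("A" * 60, binding=(5,))
        with pytest.raises(ValueError):
            kfold_cv(extract_fragments(chain), lambda seed: StubPipeline(), k=5, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv([], lambda seed: StubPipeline(), k=1)


class TestUndersampling:
    def _pools(self):
        frags = extract_all(_signal_fragments(n_chains=8))
        pos = [f for f in frags if f.label]
        neg = [f for f in frags if not f.label]
        return pos, neg

    def test_each_repeat_trains_exactly_balanced(self):
        pos, neg = self._pools()
        seen = []
        undersample_eval(pos, neg, lambda seed: StubPipeline(record=seen),
                         repeats=3, seed=0, k=2)
        assert seen  # one record per CV fold per repeat
        for training in seen:
            n_pos = sum(f.label for f in training)
            n_neg = len(training) - n_pos
            # folds of an exactly balanced set differ by at most 1 per class
            assert abs(n_pos - n_neg) <= 1

    def test_repeat_pool_is_balanced_one_to_one(self):
        pos, neg = self._pools()
        tested = []

        class Recorder(StubPipeline):
            def predict(self, fs):
                tested.append(list(fs))
                return super().predict(fs)

        result = undersample_eval(pos, neg, lambda seed: Recorder(),
                                  repeats=2, seed=0, k=2)
        for cv in result.repeats:
            assert cv.pooled.total == 2 * len(pos)
            assert cv.pooled.tp + cv.pooled.fn == len(pos)  # exactly 1:1

    def test_single_repeat_equals_its_run(self):
        pos, neg = self._pools()
        result = undersample_eval(pos, neg, lambda seed: StubPipeline(),
                                  repeats=1, seed=0, k=2)
        only = result.repeats[0].pooled
        assert (result.mean.sn, result.mean.mcc) == (only.sn, only.mcc)
        assert result.std.mcc == 0.0

    def test_different_seeds_draw_different_negatives(self):
        pos, neg = self._pools()
        seen_a, seen_b = [], []
        undersample_eval(pos, neg, lambda s: StubPipeline(record=seen_a),
                         repeats=1, seed=0, k=2)
        undersample_eval(pos, neg, lambda s: StubPipeline(record=seen_b),
                         repeats=1, seed=99, k=2)
        ids = lambda sets: {(f.chain_id, f.center) for tr in sets for f in tr if not f.label}
        assert ids(seen_a) != ids(seen_b)

    def test_fewer_negatives_than_positives_rejected(self):
        pos, neg = self._pools()
        with pytest.raises(ValueError):
            undersample_eval(pos, pos[: len(pos) // 2], lambda s: StubPipeline())


class TestChainSplit:
    def _chains(self, n, n_binding=1):
        return [SimpleNamespace(chain_id=f"c{i}", n_binding=n_binding)
                for i in range(n)]

    def test_eighty_twenty_on_ten_chains(self):
        plan = chain_split(self._chains(10), seed=0)
        assert len(plan.train_ids) == 8 and len(plan.test_ids) == 2

    def test_floor_rule_at_1237_chains(self):
        plan = chain_split(self._chains(1237), seed=0)
        assert len(plan.train_ids) == 989 and len(plan.test_ids) == 248

    def test_assignment_partitions_chains_and_is_deterministic(self):
        chains = self._chains(17)
        a = chain_split(chains, seed=5)
        b = chain_split(chains, seed=5)
        assert a.assignments == b.assignments
        assert set(a.train_ids) | set(a.test_ids) == {c.chain_id for c in chains}
        assert not set(a.train_ids) & set(a.test_ids)

    def test_zero_positive_side_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="metalbind.evaluate"):
            chain_split(self._chains(5, n_binding=0), seed=0)
        assert any("zero positive" in r.message for r in caplog.records)

    def test_fewer_than_two_chains_rejected(self):
        with pytest.raises(ValueError):
            chain_split(self._chains(1))


def test_summarize_mean_and_dispersion():
    rs = [metrics(10, 0, 10, 0), metrics(5, 5, 5, 5)]
    mean, std = summarize(rs)
    assert mean.acc == pytest.approx(75.0)
    assert std.mcc == pytest.approx(0.5)
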