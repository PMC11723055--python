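import numpy as np
import pytest

from epiloop.evaluation import (ConfusionCounts, confusion, grid_search,
                                grid_search_values, metrics,
                                single_feature_predictions)
from epiloop.thresholding import FIFO_DEPTH


class TestConfusion:
    def test_perfect_predictions(self):
        labels = [True] * 5 + [False] * 5
        c = confusion(labels, labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 5, 0)

    def test_all_positive_predictions(self):
        labels = [True] * 3 + [False] * 7
        c = confusion(labels, [True] * 10)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 7, 0, 0)

    def test_empty_inputs(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestMetrics:
    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (rep.precision, rep.accuracy, rep.recall, rep.f2) == (1, 1, 1, 1)

    def test_worked_example(self):
        rep = metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5))
        assert rep.precision == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.93)
        assert rep.recall == pytest.approx(8 / 13)
        assert rep.f2 == pytest.approx(40 / 62)

    def test_zero_denominators_reported_absent(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert rep.precision is None and rep.recall is None and rep.f2 is None
        assert rep.accuracy == 1.0

    def test_as_printed_recall_compat_formula(self):
        rep = metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5),
                      recall_formula="as_printed")
        assert rep.recall == pytest.approx(8 / 93)

    def test_f2_equals_fbeta_identity(self, rng):
        """F2 = 5TP/(5TP+4FN+FP) is the F-beta measure at beta=2 derived
        from precision and recall — checked on 1000 random tables."""
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(1, 200, size=4)
            rep = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            p, r = rep.precision, rep.recall
            fbeta = (1 + 4) * p * r / (4 * p + r)
            assert rep.f2 == pytest.approx(fbeta)


class TestSingleFeaturePredictions:
    def test_warmup_never_fires(self, rng):
        preds = single_feature_predictions(rng.uniform(1, 2, 50), 0, 0)
        assert not preds[:FIFO_DEPTH].any()
        assert preds[FIFO_DEPTH:].all()  # zero threshold, positive values

    def test_matches_streaming_oracle(self, rng):
        """Vectorised rolling form equals an explicit per-epoch loop."""
        values = rng.uniform(0, 10, 200)
        M, N = 2, 1
        preds = single_feature_predictions(values, M, N)
        for k in range(len(values)):
            if k < 4:
                expected = False
            else:
                win = values[k - 4:k]
                th = M * win.mean() + N * win.std()
                expected = values[k] > th
            assert preds[k] == expected


class TestGridSearch:
    def test_grid_has_25_cells(self, bonn_cfg, planted_grid_recording):
        rec, labels = planted_grid_recording
        result = grid_search(rec, labels, "amp", cfg=bonn_cfg)
        assert len(result.table) == 25
        assert set(zip(result.table.M, result.table.N)) == {
            (m, n) for m in range(1, 6) for n in range(1, 6)}
        assert result.table.best.sum() == 1

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_values(rng.uniform(0, 1, 50), np.zeros(50, bool),
                               m_values=[])

    @pytest.mark.parametrize("feature", ["amp", "slp", "ll"])
    def test_planted_optimum_recovered(self, bonn_cfg, planted_grid_recording,
                                       feature):
        """Seizures were planted between 2*AVE+STD and 3*AVE of background,
        so (2, 1) must win the F2 grid for every degree-1 feature."""
        rec, labels = planted_grid_recording
        assert grid_search(rec, labels, feature, cfg=bonn_cfg).best == (2, 1)

    def test_predicted_positives_monotone_in_m_and_n(self, rng):
        """Raising M or N raises every epoch's threshold, so the predicted
        positive count (and hence recall) can only fall — the monotone trend
        the published recall column shows from M=1 down to M=5."""
        values = rng.uniform(0, 10, 400)
        counts = {(m, n): int(single_feature_predictions(values, m, n).sum())
                  for m in range(1, 6) for n in range(1, 6)}
        for m in range(1, 6):
            for n in range(1, 6):
                if m < 5:
                    assert counts[(m + 1, n)] <= counts[(m, n)]
                if n < 5:
                    assert counts[(m, n + 1)] <= counts[(m, n)]

    def test_recall_column_non_increasing_in_m(self, bonn_cfg,
                                               planted_grid_recording):
        rec, labels = planted_grid_recording
        t = grid_search(rec, labels, "ll", cfg=bonn_cfg).table
        recall_at = {(int(r.M), int(r.N)): (0.0 if r.recall != r.recall
                                            else float(r.recall))
                     for r in t.itertuples()}
        for n in range(1, 6):
            col = [recall_at[(m, n)] for m in range(1, 6)]
            assert all(a >= b for a, b in zip(col, col[1:]))

    def test_recall_at_55_not_above_11(self, bonn_cfg, planted_grid_recording):
        rec, labels = planted_grid_recording
        result = grid_search(rec, labels, "amp", cfg=bonn_cfg)
        assert result.report(5, 5).recall <= result.report(1, 1).recall

    def test_unknown_feature_rejected(self, bonn_cfg, planted_grid_recording):
        rec, labels = planted_grid_recording
        with pytest.raises(ValueError):
            grid_search(rec, labels, "entropy", cfg=bonn_cfg)
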