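"""Detection rates, annotation error, and the read-length-swept ROC/AUC."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragbench import (
    ConfusionCounts,
    annotation_error,
    confusion,
    mean_annotation_error,
    metric_table,
    mock_predictor,
    oracle_predictor,
    rates,
    roc_auc,
)
from fragbench.fragsim import BenchmarkSet
from fragbench.predict import GenePrediction, Interval, PredictionSet
from tests.conftest import make_balanced_truth


class TestRates:
    def test_hand_evaluated_tables(self):
        r = rates(ConfusionCounts(tp=3, fn=1))
        assert r.sensitivity == 0.75
        # PPV-vs-specificity distinction: 75 coding hits, 25 false alarms
        r = rates(ConfusionCounts(tp=75, fp=25))
        assert r.ppv == 0.75
        assert r.specificity == 0.0  # 25 non-coding reads, all misclassified
        r = rates(ConfusionCounts(tp=75))
        assert r.specificity is None  # no non-coding reads at all: undefined, not 0
        r = rates(ConfusionCounts(tp=40, fp=10, fn=10, tn=40))
        assert r.sensitivity == 0.8 and r.specificity == 0.8
        assert r.accuracy == 0.8 and r.ppv == 0.8

    @pytest.mark.parametrize("s", [0.2, 0.5, 0.9])
    def test_f_measure_fixed_point(self, s):
        """sens == spec == s implies f-measure == s (harmonic mean fixed point)."""
        n = 1000
        counts = ConfusionCounts(
            tp=int(s * n), fn=n - int(s * n), tn=int(s * n), fp=n - int(s * n)
        )
        assert rates(counts).f_measure == pytest.approx(int(s * n) / n)

    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        fn=st.integers(0, 500),
        tn=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_rates_against_brute_force(self, tp, fp, fn, tn):
        r = rates(ConfusionCounts(tp, fp, fn, tn))
        assert r.sensitivity == (tp / (tp + fn) if tp + fn else None)
        assert r.specificity == (tn / (tn + fp) if tn + fp else None)
        assert r.ppv == (tp / (tp + fp) if tp + fp else None)
        if tp + fp + fn + tn:
            assert r.accuracy == (tp + tn) / (tp + fp + fn + tn)
        if r.sensitivity is not None and r.specificity is not None:
            s, p = r.sensitivity, r.specificity
            assert r.f_measure == (2 * s * p / (s + p) if s + p else None)
            if r.f_measure is not None:
                eps = 1e-12  # harmonic mean up to float rounding
                assert min(s, p) - eps <= r.f_measure <= max(s, p) + eps

    def test_accuracy_identity_with_class_sizes(self):
        """acc == (sens*P + spec*N)/(P+N) for P coding, N non-coding reads."""
        c = ConfusionCounts(tp=70, fn=30, fp=10, tn=90)
        r = rates(c)
        P, N = c.tp + c.fn, c.fp + c.tn
        assert r.accuracy == pytest.approx((r.sensitivity * P + r.specificity * N) / (P + N))


class TestConfusion:
    def test_perfect_predictor_on_3to1_design(self, bench):
        """3000:1000-style design: oracle gives TP=coding, TN=non-coding, 0 errors."""
        counts = confusion(bench, oracle_predictor(bench))
        n_coding = sum(f.is_coding for f in bench.fragments)
        assert (counts.tp, counts.tn) == (n_coding, len(bench.fragments) - n_coding)
        assert counts.fp == counts.fn == 0

    def test_always_coding_predictor(self, bench):
        always = PredictionSet(
            predictor_name="always",
            predictions={
                f.read_id: GenePrediction(
                    read_id=f.read_id, intervals=(Interval(0, f.read_length),)
                )
                for f in bench.fragments
            },
        )
        counts = confusion(bench, always)
        assert counts.fn == counts.tn == 0
        assert counts.total == len(bench.fragments)
        # the 3:1 coding bias pins the always-coding accuracy at exactly 0.75
        assert rates(counts).accuracy == 0.75

    def test_counts_conserve_stratum_size(self, bench):
        m = mock_predictor(bench, 0.7, 0.7, seed=4)
        for L in bench.read_lengths:
            for ftype in "ABCD":
                counts = confusion(bench, m, read_length=L, ftype=ftype)
                assert counts.total == len(bench.stratum(L, ftype))

    def test_empty_stratum_rejected(self, bench):
        with pytest.raises(ValueError, match="empty stratum"):
            confusion(bench, oracle_predictor(bench), read_length=999)


class TestAnnotationError:
    def _frag(self, truth, L=100):
        f = make_balanced_truth(2, read_length=L)[0]
        return dataclasses.replace(f, truth_interval=truth)

    def _pred(self, s, e):
        return GenePrediction(read_id="r", intervals=(Interval(s, e),))

    def test_exact_prediction_zero_error(self):
        assert annotation_error(self._pred(20, 80), self._frag((20, 80))) == 0.0

    def test_hand_evaluation(self):
        """|10-0| + |90-100| over |Fgb|=100 -> 20%."""
        frag = self._frag((0, 100))
        assert annotation_error(self._pred(10, 90), frag) == pytest.approx(20.0)

    def test_symmetry_of_absolute_differences(self):
        frag = self._frag((10, 90))
        err1 = annotation_error(self._pred(0, 100), frag)
        swapped = self._frag((0, 100))
        err2 = 100.0 * (abs(10 - 0) + abs(90 - 100)) / 80
        assert err1 == pytest.approx(100.0 * (10 + 10) / 80) == pytest.approx(err2)

    def test_error_uncapped_and_normalizer_flag(self):
        frag = self._frag((0, 50), L=100)
        pred = self._pred(49, 100)
        assert annotation_error(pred, frag) == pytest.approx(100.0 * (49 + 50) / 50)
        assert annotation_error(pred, frag, normalize_by_read_length=True) == pytest.approx(
            100.0 * (49 + 50) / 100
        )

    def test_type_d_not_applicable(self):
        frag = self._frag(None)
        assert annotation_error(self._pred(0, 10), frag) is None

    def test_mean_over_stratum(self, bench):
        pset = oracle_predictor(bench)
        mean, n_ann, n_missed = mean_annotation_error(bench, pset)
        assert mean == 0.0
        assert n_ann == sum(f.is_coding for f in bench.fragments)
        assert n_missed == 0

    def test_missed_reads_counted_not_penalized(self, bench):
        pset = mock_predictor(bench, sens=0.5, spec=1.0, seed=8)
        mean, n_ann, n_missed = mean_annotation_error(bench, pset)
        n_coding = sum(f.is_coding for f in bench.fragments)
        assert n_ann + n_missed == n_coding
        assert mean == 0.0  # no coordinate noise

    def test_error_grows_with_coordinate_noise(self, bench):
        means = []
        for sd in (0.0, 4.0, 16.0):
            errs = []
            for seed in range(5):
                pset = mock_predictor(bench, 1.0, 1.0, coord_noise_sd=sd, seed=seed)
                errs.append(mean_annotation_error(bench, pset)[0])
            means.append(np.mean(errs))
        assert means[0] == 0.0 and means[0] < means[1] < means[2]


class TestRocAuc:
    def test_chance_diagonal(self):
        assert roc_auc([(0.0, 0.0), (1.0, 1.0)]) == 0.5

    def test_perfect_corner(self):
        assert roc_auc([(0.0, 1.0)]) == 1.0

    def test_matches_independent_integration_oracle(self):
        """Trapezoid result equals sklearn's AUC on random operating points."""
        from sklearn.metrics import auc as sk_auc

        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = [(float(f), float(t)) for f, t in rng.random((7, 2))]
            expected_x = np.concatenate(([0.0], np.sort([p[0] for p in pts]), [1.0]))
            order = np.lexsort(([p[1] for p in pts], [p[0] for p in pts]))
            expected_y = np.concatenate(
                ([0.0], np.array([p[1] for p in pts])[order], [1.0])
            )
            assert roc_auc(pts) == pytest.approx(sk_auc(expected_x, expected_y))

    def test_duplicate_points_do_not_change_auc(self):
        pts = [(0.2, 0.6), (0.5, 0.8)]
        assert roc_auc(pts) == pytest.approx(roc_auc(pts + pts))

    def test_mock_family_auc_increases_with_p(self):
        frags = make_balanced_truth(4000)
        bench = BenchmarkSet(
            fragments=tuple(frags), read_lengths=(300,), n_per_type=2000, seed=0
        )
        aucs = []
        for p in (0.6, 0.7, 0.8, 0.9):
            pset = mock_predictor(frags, p, p, seed=int(p * 100))
            from fragbench.metrics import roc_points

            aucs.append(roc_auc(roc_points(bench, pset)))
        assert aucs == sorted(aucs)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([])
        with pytest.raises(ValueError):
            roc_auc([(1.2, 0.5)])


class TestMetricTable:
    def test_table_shape_and_pooling_consistency(self, bench):
        m = mock_predictor(bench, 0.8, 0.8, seed=3)
        table = metric_table(bench, [m])
        assert len(table) == len(bench.read_lengths) * 5  # ALL + 4 types
        for L in bench.read_lengths:
            sub = table[table["read_length"] == L]
            pooled = sub[sub["stratum"] == "ALL"].iloc[0]
            per_type = sub[sub["stratum"] != "ALL"]
            for col in ("tp", "fp", "fn", "tn"):
                assert pooled[col] == per_type[col].sum()

    def test_undefined_cells_are_nan_not_zero(self, bench):
        m = oracle_predictor(bench)
        table = metric_table(bench, [m])
        d_rows = table[table["stratum"] == "D"]
        assert d_rows["sensitivity"].isna().all()  # no coding truth in type D
        assert (d_rows["specificity"] == 1.0).all()
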