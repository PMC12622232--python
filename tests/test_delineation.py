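import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocpu.delineation import (
    ConfusionMatrix,
    LabeledValue,
    confusion_at_threshold,
    evaluate_per_family,
    mcc,
    method_concordance,
    optimize_threshold,
)
from pocpu.pairs import GenomePair
from pocpu.synthetic import FamilySpec, generate_family_dataset


def labeled(pairs_with_values, family="F"):
    """[(same_genus, value), ...] -> list[LabeledValue] with synthetic pair ids."""
    out = []
    for i, (same, value) in enumerate(pairs_with_values):
        pair = GenomePair(f"a{i:04d}", f"b{i:04d}", family, same)
        out.append(LabeledValue(pair=pair, value=value))
    return out


def brute_force_best_mcc(values):
    """Independent oracle: MCC at every observed value +/- epsilon and extremes."""
    vals = sorted({lv.value for lv in values})
    eps = 1e-9
    candidates = [max(vals[0] - 1, 0)]
    for v in vals:
        candidates += [max(v - eps, 0), v, v + eps]
    return max(mcc(confusion_at_threshold(values, t)) for t in candidates)


class TestConfusionAtThreshold:
    def test_boundary_value_predicted_negative(self):
        values = labeled([(True, 60), (False, 40), (False, 55), (True, 50)])
        cm = confusion_at_threshold(values, 50)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 1, 1)

    def test_all_positive_when_all_above(self):
        values = labeled([(True, 100)] * 5)
        cm = confusion_at_threshold(values, 50)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (5, 0, 0, 0)

    def test_no_negative_predictions_at_zero_threshold(self):
        values = labeled([(True, 10), (False, 20), (True, 0.5)])
        cm = confusion_at_threshold(values, 0)
        assert cm.tn == cm.fn == 0

    def test_counts_sum_to_input_size(self):
        rng = np.random.default_rng(0)
        values = labeled([(bool(rng.integers(2)), float(v)) for v in rng.uniform(0, 100, 50)])
        cm = confusion_at_threshold(values, 37.5)
        assert cm.total == 50

    def test_raising_threshold_never_adds_positives(self):
        rng = np.random.default_rng(1)
        values = labeled([(bool(rng.integers(2)), float(v)) for v in rng.uniform(0, 100, 80)])
        positives = [
            confusion_at_threshold(values, t).tp + confusion_at_threshold(values, t).fp
            for t in np.linspace(0, 100, 21)
        ]
        assert positives == sorted(positives, reverse=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([], 50)


class TestMcc:
    def test_genus_delineation_benchmark_matrices(self):
        # POCPu, POCP, and the Streptomycetaceae family at the 50% threshold.
        assert mcc(ConfusionMatrix(tp=209660, fp=67329, tn=253860, fn=12966)) == pytest.approx(0.72, abs=0.005)
        assert mcc(ConfusionMatrix(tp=220307, fp=188155, tn=133034, fn=2319)) == pytest.approx(0.46, abs=0.005)
        assert mcc(ConfusionMatrix(tp=93338, fp=7110, tn=1231, fn=2974)) == pytest.approx(0.16, abs=0.005)

    def test_perfect_classification(self):
        assert mcc(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0)) == 1.0

    def test_zero_marginal_convention(self):
        assert mcc(ConfusionMatrix(tp=5, fp=0, tn=0, fn=0)) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=0, max_value=10**7)] * 4))
    def test_bounded_and_antisymmetric(self, counts):
        tp, fp, tn, fn = counts
        value = mcc(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
        swapped = mcc(ConfusionMatrix(tp=fn, fp=tn, tn=fp, fn=tp))
        assert -1 <= value <= 1
        assert value + swapped == pytest.approx(0, abs=1e-12)


class TestOptimizeThreshold:
    def test_separable_classes_tie_break_toward_50(self):
        values = labeled([(True, v) for v in (70, 75, 80)] + [(False, v) for v in (10, 20, 30)])
        result = optimize_threshold(values)
        assert result.mcc_at_threshold == pytest.approx(1.0)
        assert result.threshold == pytest.approx(50.0)

    def test_interleaved_values_match_brute_force(self):
        values = labeled([(i % 2 == 0, float(10 + 5 * i)) for i in range(16)])
        result = optimize_threshold(values)
        assert result.mcc_at_threshold == pytest.approx(brute_force_best_mcc(values))

    def test_generator_known_boundary_recovered(self):
        spec = FamilySpec(
            family="F", genera=(("G1", 4), ("G2", 4)),
            within_value_range=(62.0, 90.0), between_value_range=(20.0, 58.0),
            seed=5,
        )
        values = generate_family_dataset([spec])
        result = optimize_threshold(values)
        assert result.mcc_at_threshold == pytest.approx(1.0)
        assert 58.0 <= result.threshold <= 62.0

    def test_optimized_never_below_default(self):
        rng = np.random.default_rng(3)
        values = labeled(
            [(bool(rng.integers(2)), float(v)) for v in rng.uniform(0, 100, 60)]
        )
        result = optimize_threshold(values)
        assert result.mcc_at_threshold >= result.mcc_at_default
        assert result.delta_mcc == pytest.approx(
            result.mcc_at_threshold - result.mcc_at_default
        )

    def test_brent_mode_never_beats_sweep(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            values = labeled(
                [(bool(rng.integers(2)), float(v)) for v in rng.uniform(0, 100, 40)]
            )
            sweep = optimize_threshold(values, mode="sweep")
            brent = optimize_threshold(values, mode="brent")
            assert brent.mcc_at_threshold <= sweep.mcc_at_threshold + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            optimize_threshold(labeled([(True, 60), (True, 70)]))

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.floats(min_value=0, max_value=100)),
            min_size=2,
            max_size=60,
        )
    )
    def test_sweep_equals_brute_force_property(self, raw):
        if not any(s for s, _ in raw) or all(s for s, _ in raw):
            return  # single-class inputs are rejected by precondition
        values = labeled(raw)
        result = optimize_threshold(values)
        assert result.mcc_at_threshold == pytest.approx(brute_force_best_mcc(values))


class TestEvaluatePerFamily:
    def test_two_separable_families_plus_global(self):
        specs = [
            FamilySpec("F1", (("G1", 3), ("G2", 3)), (70, 90), (10, 30), seed=1),
            FamilySpec("F2", (("G3", 3), ("G4", 3)), (80, 95), (20, 40), seed=2),
        ]
        values = generate_family_dataset(specs)
        results = evaluate_per_family(values)
        assert [r.family for r in results] == ["F1", "F2", "global"]
        for r in results:
            assert r.mcc_at_threshold == pytest.approx(1.0)
            assert r.n_pairs == r.n_within + r.n_between

    def test_single_class_family_flagged(self):
        values = labeled([(True, 80), (True, 70)], family="F1") + labeled(
            [(True, 85), (False, 20)], family="F2"
        )
        results = {r.family: r for r in evaluate_per_family(values)}
        assert results["F1"].flag == "single_class"
        assert results["F1"].threshold is None
        assert results["F2"].mcc_at_threshold == pytest.approx(1.0)

    def test_known_per_family_boundaries_recovered(self):
        specs = [
            FamilySpec(f"F{i}", (("GA", 3), ("GB", 3)),
                       (55.0 + 5 * i, 90.0), (10.0, 45.0 + 5 * i), seed=10 + i)
            for i in range(5)
        ]
        values = generate_family_dataset(specs)
        results = {r.family: r for r in evaluate_per_family(values)}
        for i in range(5):
            r = results[f"F{i}"]
            assert r.mcc_at_threshold == pytest.approx(1.0)
            assert 45.0 + 5 * i <= r.threshold <= 55.0 + 5 * i


class TestMethodConcordance:
    def test_identity_fit(self):
        x = np.linspace(10, 90, 10)
        res = method_concordance(x, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.n == 10

    def test_outlier_matches_closed_form_ols(self):
        x = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 50.0])
        y = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 95.0])
        res = method_concordance(x, y)
        # closed-form OLS
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * ((y - y.mean()) ** 2).sum())
        assert res.slope == pytest.approx(slope)
        assert res.r_squared == pytest.approx(r2)
        assert res.r_squared < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            method_concordance([1, 2], [1, 2])
        with pytest.raises(ValueError):
            method_concordance([5, 5, 5], [1, 2, 3])
        with pytest.raises(ValueError):
            method_concordance([1, 2, 3], [4, 4, 4])
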