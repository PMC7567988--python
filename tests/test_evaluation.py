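import numpy as np
import pytest
from hypothesis import given, strategies as st

from metapred import (
    METAMORPHIC,
    MONOMORPHIC,
    ClassifierParams,
    ConfusionMatrix,
    GridSpec,
    LabeledDataset,
    cross_validate,
    default_grid,
    descriptor_correlation,
    evaluate,
    fit_discriminant,
    grid_search,
    mcc,
    rates,
)
from metapred.evaluation import DiscriminantLine

from conftest import make_profile


def expand_to_vectors(cm):
    """Binary truth/prediction vectors whose Pearson correlation is the MCC."""
    truth = [1] * cm.tp + [0] * cm.fp + [0] * cm.tn + [1] * cm.fn
    pred = [1] * cm.tp + [1] * cm.fp + [0] * cm.tn + [0] * cm.fn
    return np.array(truth), np.array(pred)


counts = st.integers(min_value=0, max_value=60)


@pytest.mark.parametrize(
    "cm,expected",
    [
        (ConfusionMatrix(tp=50, fp=0, tn=50, fn=0), 1.0),
        (ConfusionMatrix(tp=0, fp=50, tn=0, fn=50), -1.0),
        (ConfusionMatrix(tp=25, fp=25, tn=25, fn=25), 0.0),
    ],
)
def test_mcc_calibration(cm, expected):
    assert mcc(cm) == pytest.approx(expected, abs=1e-12)


def test_mcc_equals_pearson_correlation():
    cm = ConfusionMatrix(tp=13, fp=4, tn=20, fn=7)
    truth, pred = expand_to_vectors(cm)
    assert mcc(cm) == pytest.approx(np.corrcoef(truth, pred)[0, 1], abs=1e-12)


def test_mcc_degenerate_factor_convention():
    # no positive predictions at all: TP+FP = 0
    assert mcc(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5)) == 0.0


def test_mcc_empty_matrix_rejected():
    with pytest.raises(ValueError):
        mcc(ConfusionMatrix(tp=0, fp=0, tn=0, fn=0))


@given(counts, counts, counts, counts)
def test_mcc_class_swap_invariance(tp, fp, tn, fn):
    if tp + fp + tn + fn == 0:
        return
    assert mcc(ConfusionMatrix(tp, fp, tn, fn)) == pytest.approx(
        mcc(ConfusionMatrix(tp=tn, fp=fn, tn=tp, fn=fp)), abs=1e-12
    )


@given(counts, counts, counts, counts)
def test_mcc_matches_pearson_oracle(tp, fp, tn, fn):
    cm = ConfusionMatrix(tp, fp, tn, fn)
    if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
        return
    truth, pred = expand_to_vectors(cm)
    assert mcc(cm) == pytest.approx(np.corrcoef(truth, pred)[0, 1], abs=1e-10)


def test_mcc_matches_sklearn():
    from sklearn.metrics import matthews_corrcoef

    rng = np.random.default_rng(42)
    for _ in range(50):
        tp, fp, tn, fn = rng.integers(0, 40, size=4)
        cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
        if cm.total == 0:
            continue
        truth, pred = expand_to_vectors(cm)
        assert mcc(cm) == pytest.approx(matthews_corrcoef(truth, pred), abs=1e-10)


@pytest.mark.parametrize(
    "cm,expected",
    [
        (ConfusionMatrix(tp=50, fp=0, tn=50, fn=0), (1.0, 1.0, 1.0)),
        (ConfusionMatrix(tp=1, fp=1, tn=3, fn=1), (0.5, 0.75, 4 / 6)),
        (ConfusionMatrix(tp=0, fp=0, tn=5, fn=5), (0.0, 1.0, 0.5)),
    ],
)
def test_rates(cm, expected):
    r = rates(cm)
    assert (r.tpr, r.tnr, r.acc) == pytest.approx(expected)


@pytest.mark.parametrize(
    "cm,missing",
    [
        (ConfusionMatrix(tp=0, fp=3, tn=2, fn=0), "TPR"),
        (ConfusionMatrix(tp=3, fp=0, tn=0, fn=2), "TNR"),
    ],
)
def test_rates_empty_class_named(cm, missing):
    with pytest.raises(ValueError, match=missing):
        rates(cm)


def _flat_dataset(n, label):
    """n profiles whose DI trace is constant 1.0."""
    return [
        (f"{label}_{i}", make_profile([[1, 0, 0]] * 40, identifier=f"{label}_{i}"), label)
        for i in range(n)
    ]


def _hot_dataset(n, label):
    """n profiles with a uniform-probability (DI 3) core segment."""
    entries = []
    for i in range(n):
        rows = [[0.96, 0.02, 0.02]] * 40
        rows[10:30] = [[1 / 3, 1 / 3, 1 / 3]] * 20
        entries.append(
            (f"{label}hot_{i}", make_profile(rows, identifier=f"{label}hot_{i}"), label)
        )
    return entries


def test_evaluate_all_monomorphic_flat():
    dataset = LabeledDataset(_flat_dataset(6, MONOMORPHIC))
    cm = evaluate(dataset, ClassifierParams(cr=10, di_thre=1.4))
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (0, 0, 6, 0)


def test_evaluate_separable_construction():
    dataset = LabeledDataset(_hot_dataset(4, METAMORPHIC) + _flat_dataset(5, MONOMORPHIC))
    cm = evaluate(dataset, ClassifierParams(cr=15, di_thre=2.1))
    assert cm.fp == 0 and cm.fn == 0
    assert cm.tp == 4 and cm.tn == 5
    assert cm.total == len(dataset)


def test_evaluate_threshold_three_classifies_everything_monomorphic():
    """DI never exceeds 3 and the inequality is strict, so di_thre=3
    calls every sequence monomorphic."""
    dataset = LabeledDataset(_hot_dataset(4, METAMORPHIC) + _flat_dataset(5, MONOMORPHIC))
    cm = evaluate(dataset, ClassifierParams(cr=15, di_thre=3.0))
    assert cm.tp == 0 and cm.fp == 0
    assert cm.fn == 4 and cm.tn == 5


def test_evaluate_too_short_profiles_listed():
    short = [("tiny", make_profile([[1, 0, 0]] * 12, identifier="tiny"), MONOMORPHIC)]
    dataset = LabeledDataset(short + _flat_dataset(2, MONOMORPHIC))
    with pytest.raises(Exception, match="tiny"):
        evaluate(dataset, ClassifierParams(cr=10, di_thre=2.0, terminal_exclude=5))


def test_dataset_rejects_duplicates_and_bad_labels():
    entries = _flat_dataset(2, MONOMORPHIC)
    with pytest.raises(ValueError, match="duplicate"):
        LabeledDataset(entries + [entries[0]])
    with pytest.raises(ValueError, match="label"):
        LabeledDataset([(entries[0][0], entries[0][1], "maybe")])


def test_grid_search_single_cell():
    dataset = LabeledDataset(_hot_dataset(3, METAMORPHIC) + _flat_dataset(3, MONOMORPHIC))
    grid = GridSpec(cr_values=(10,), di_thre_values=(2.0,))
    params, best, table = grid_search(dataset, grid)
    assert (params.cr, params.di_thre) == (10, 2.0)
    assert len(table) == 1
    assert best == pytest.approx(1.0)


def test_grid_search_exhaustive_against_reevaluation():
    """Every table cell must equal an independent evaluate() call, and
    the argmax must be the lexicographically first maximal cell."""
    dataset = LabeledDataset(_hot_dataset(3, METAMORPHIC) + _flat_dataset(4, MONOMORPHIC))
    grid = GridSpec(cr_values=(6, 10, 14), di_thre_values=(1.5, 2.0, 2.5, 2.9))
    params, best, table = grid_search(dataset, grid)
    assert len(table) == 12
    seen_best = None
    for row in table.itertuples(index=False):
        cm = evaluate(
            dataset,
            ClassifierParams(cr=int(row.cr), di_thre=float(row.di_thre)),
        )
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (row.tp, row.fp, row.tn, row.fn)
        assert mcc(cm) == pytest.approx(row.mcc, abs=1e-12)
        if seen_best is None or mcc(cm) > seen_best[0]:
            seen_best = (mcc(cm), int(row.cr), float(row.di_thre))
    assert best == pytest.approx(seen_best[0])
    assert (params.cr, params.di_thre) == seen_best[1:]


def test_grid_search_identical_profiles_mixed_labels_degenerate():
    """Identical profiles force one-sided predictions in every cell, so
    the denominator convention makes the best MCC zero."""
    profile_rows = [[0.9, 0.05, 0.05]] * 40
    entries = [
        (f"e{i}", make_profile(profile_rows, identifier=f"e{i}"),
         METAMORPHIC if i % 2 else MONOMORPHIC)
        for i in range(6)
    ]
    _, best, table = grid_search(LabeledDataset(entries), default_grid())
    assert best == 0.0
    assert (table["mcc"] == 0.0).all()


def test_grid_search_tie_break_lexicographic():
    """All-zero MCC everywhere: the reported optimum is the smallest
    (CR, DI_thre) cell."""
    # single-label dataset: every cell has MCC 0 by the degenerate rule
    dataset = LabeledDataset(_flat_dataset(3, MONOMORPHIC))
    grid = GridSpec(cr_values=(6, 8), di_thre_values=(1.5, 2.0))
    params, best, _ = grid_search(dataset, grid)
    assert best == 0.0
    assert (params.cr, params.di_thre) == (6, 1.5)


def test_cross_validate_fold_structure():
    entries = _hot_dataset(6, METAMORPHIC) + _flat_dataset(6, MONOMORPHIC)
    dataset = LabeledDataset(entries)
    grid = GridSpec(cr_values=(10,), di_thre_values=(2.0,))
    result = cross_validate(dataset, k=6, grid=grid, seed=1)
    assert len(result.folds) == 6
    sizes = [f.test_cm.total for f in result.folds]
    assert sizes == [2] * 6
    assert sum(sizes) == len(dataset)


def test_cross_validate_uneven_folds():
    entries = _hot_dataset(4, METAMORPHIC) + _flat_dataset(6, MONOMORPHIC)
    dataset = LabeledDataset(entries)
    grid = GridSpec(cr_values=(10,), di_thre_values=(2.0,))
    result = cross_validate(dataset, k=3, grid=grid, seed=1)
    sizes = sorted(f.test_cm.total for f in result.folds)
    assert sizes == [3, 3, 4]  # first n mod k chunks take the extra entry


def test_cross_validate_deterministic_given_seed():
    entries = _hot_dataset(5, METAMORPHIC) + _flat_dataset(7, MONOMORPHIC)
    dataset = LabeledDataset(entries)
    grid = GridSpec(cr_values=(8, 12), di_thre_values=(1.8, 2.2))
    r1 = cross_validate(dataset, k=4, grid=grid, seed=99)
    r2 = cross_validate(dataset, k=4, grid=grid, seed=99)
    for f1, f2 in zip(r1.folds, r2.folds):
        assert f1.test_cm == f2.test_cm
        assert f1.params == f2.params


def test_cross_validate_k_larger_than_dataset():
    dataset = LabeledDataset(_flat_dataset(3, MONOMORPHIC))
    with pytest.raises(ValueError, match="exceeds"):
        cross_validate(dataset, k=5)


def test_fit_discriminant_two_separable_points():
    line, best = fit_discriminant(
        [(1.2, 1.2, MONOMORPHIC), (2.8, 2.8, METAMORPHIC)]
    )
    assert best == pytest.approx(1.0)
    assert line.predict(2.8, 2.8) == METAMORPHIC
    assert line.predict(1.2, 1.2) == MONOMORPHIC


def test_fit_discriminant_seeded_separable_cloud():
    rng = np.random.default_rng(3)
    points = []
    for _ in range(10):
        points.append((1.1 + rng.uniform(0, 0.4), 1.1 + rng.uniform(0, 0.4), MONOMORPHIC))
        points.append((2.2 + rng.uniform(0, 0.5), 2.2 + rng.uniform(0, 0.5), METAMORPHIC))
    line, best = fit_discriminant(points)
    assert best == pytest.approx(1.0)
    for a, b, label in points:
        assert line.predict(a, b) == label


def test_fit_discriminant_vertical_boundary():
    """Only the first descriptor is informative: the optimal boundary is
    vertical (infinite slope), which the normal form handles."""
    points = [
        (1.2, 2.0, MONOMORPHIC), (1.3, 1.1, MONOMORPHIC),
        (2.6, 1.0, METAMORPHIC), (2.7, 2.4, METAMORPHIC),
    ]
    line, best = fit_discriminant(points)
    assert best == pytest.approx(1.0)
    for a, b, label in points:
        assert line.predict(a, b) == label


def test_fit_discriminant_degenerate_identical_points():
    points = [
        (2.0, 2.0, MONOMORPHIC), (2.0, 2.0, METAMORPHIC),
        (2.0, 2.0, MONOMORPHIC), (2.0, 2.0, METAMORPHIC),
    ]
    _, best = fit_discriminant(points)
    assert best == 0.0


def test_fit_discriminant_one_class_rejected():
    with pytest.raises(ValueError, match="both labels"):
        fit_discriminant([(1.5, 1.5, MONOMORPHIC), (1.6, 1.6, MONOMORPHIC)])


def test_discriminant_line_validation():
    with pytest.raises(ValueError):
        DiscriminantLine(a=float("inf"), b=0.0, c=1.0, orientation=1)
    with pytest.raises(ValueError):
        DiscriminantLine(a=1.0, b=0.0, c=1.0, orientation=0)


def test_descriptor_correlation_collinear():
    points = [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)]
    assert descriptor_correlation(points) == pytest.approx(1.0)


def test_descriptor_correlation_zero_slope():
    assert descriptor_correlation([(0, 0), (1, 1), (2, 0)]) == pytest.approx(0.0, abs=1e-12)


def test_descriptor_correlation_matches_pearson_squared():
    rng = np.random.default_rng(8)
    a = rng.uniform(1, 3, size=40)
    b = 0.7 * a + rng.normal(scale=0.2, size=40)
    expected = np.corrcoef(a, b)[0, 1] ** 2
    assert descriptor_correlation(list(zip(a, b))) == pytest.approx(expected, abs=1e-12)


def test_descriptor_correlation_constant_rejected():
    with pytest.raises(ValueError, match="constant"):
        descriptor_correlation([(1.0, 2.0), (1.0, 2.5), (1.0, 2.2)])
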