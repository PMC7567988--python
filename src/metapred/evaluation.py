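"""Training and evaluation of the diversity-index classifier.

Covers the confusion-matrix metrics (Matthews correlation coefficient,
true-positive/true-negative rates, accuracy), the exhaustive
MCC-maximizing grid search over (CR, DI_thre), k-fold cross-validation
with random shuffling, and the two-descriptor linear discriminant that
combines window-max diversity indices from two secondary-structure
predictors.  Metamorphic is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .classifier import (
    METAMORPHIC,
    MONOMORPHIC,
    ClassifierParams,
    SequenceTooShortError,
    di_trace,
    max_moving_average,
)
from .profiles import SSProfile, read_profile, write_profile

__all__ = [
    "ConfusionMatrix",
    "LabeledDataset",
    "GridSpec",
    "DiscriminantLine",
    "Rates",
    "FoldResult",
    "CrossValidationResult",
    "mcc",
    "rates",
    "evaluate",
    "grid_search",
    "cross_validate",
    "fit_discriminant",
    "descriptor_correlation",
    "default_grid",
]

LABELS = (METAMORPHIC, MONOMORPHIC)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary classification; metamorphic is positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Rates(NamedTuple):
    tpr: float
    tnr: float
    acc: float


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix, in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; when any of
    the four marginal factors is zero the predictions (or the truth) are
    one-sided, the coefficient is undefined, and 0 is returned — the
    standard convention, which keeps degenerate grid cells comparable.
    """
    if cm.total == 0:
        raise ValueError("cannot compute MCC of an all-zero confusion matrix")
    denom = (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def rates(cm: ConfusionMatrix) -> Rates:
    """True-positive rate, true-negative rate and accuracy."""
    if cm.tp + cm.fn == 0:
        raise ValueError("TPR undefined: no positive (metamorphic) examples")
    if cm.tn + cm.fp == 0:
        raise ValueError("TNR undefined: no negative (monomorphic) examples")
    return Rates(
        tpr=cm.tp / (cm.tp + cm.fn),
        tnr=cm.tn / (cm.tn + cm.fp),
        acc=(cm.tp + cm.tn) / cm.total,
    )


@dataclass
class LabeledDataset:
    """Profiles with metamorphic/monomorphic labels.

    ``entries`` is a list of ``(identifier, SSProfile, label)`` tuples with
    unique identifiers.
    """

    entries: List[Tuple[str, SSProfile, str]]

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers in dataset: {dupes}")
        for ident, _, label in self.entries:
            if label not in LABELS:
                raise ValueError(f"{ident}: label must be one of {LABELS}, got {label!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> List[str]:
        return [label for _, _, label in self.entries]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.entries[i] for i in indices])

    @classmethod
    def from_manifest(
        cls, manifest_path: Union[str, Path], format: str = "normalized_tsv"
    ) -> "LabeledDataset":
        """Load a TSV manifest with columns identifier, profile_path, label.

        Relative profile paths resolve against the manifest's directory.
        """
        manifest_path = Path(manifest_path)
        table = pd.read_csv(manifest_path, sep="\t")
        required = {"identifier", "profile_path", "label"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        entries = []
        for rec in table.itertuples(index=False):
            p = Path(rec.profile_path)
            if not p.is_absolute():
                p = manifest_path.parent / p
            profile = read_profile(p, format=format, identifier=rec.identifier)
            entries.append((str(rec.identifier), profile, str(rec.label)))
        return cls(entries)

    def to_manifest(self, out_dir: Union[str, Path]) -> Path:
        """Write each profile as a normalized TSV plus a manifest.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for ident, profile, label in self.entries:
            fname = f"{ident}.tsv"
            write_profile(profile, out_dir / fname)
            rows.append({"identifier": ident, "profile_path": fname, "label": label})
        manifest = out_dir / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        return manifest


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive-search grid over window length and DI threshold."""

    cr_values: Tuple[int, ...]
    di_thre_values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cr_values or not self.di_thre_values:
            raise ValueError("grid must be non-empty")
        if list(self.cr_values) != sorted(self.cr_values):
            raise ValueError("cr_values must be sorted ascending")
        if list(self.di_thre_values) != sorted(self.di_thre_values):
            raise ValueError("di_thre_values must be sorted ascending")


def default_grid() -> GridSpec:
    """Window lengths 6..15, thresholds 1.4..2.6 in steps of 0.05."""
    return GridSpec(
        cr_values=tuple(range(6, 16)),
        di_thre_values=tuple(round(1.4 + 0.05 * i, 2) for i in range(25)),
    )


def _window_maxima(
    dataset: LabeledDataset, cr: int, terminal_exclude: int
) -> np.ndarray:
    too_short = []
    out = np.empty(len(dataset))
    for i, (ident, profile, _) in enumerate(dataset.entries):
        try:
            out[i] = max_moving_average(di_trace(profile), cr, terminal_exclude)
        except SequenceTooShortError:
            too_short.append(ident)
    if too_short:
        raise SequenceTooShortError(
            f"profiles too short for cr={cr}, terminal_exclude={terminal_exclude}: "
            f"{too_short}"
        )
    return out


def _confusion_from_predictions(pred_meta: np.ndarray, true_meta: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(np.sum(pred_meta & true_meta)),
        fp=int(np.sum(pred_meta & ~true_meta)),
        tn=int(np.sum(~pred_meta & ~true_meta)),
        fn=int(np.sum(~pred_meta & true_meta)),
    )


def evaluate(dataset: LabeledDataset, params: ClassifierParams) -> ConfusionMatrix:
    """Confusion matrix of the classifier at ``params`` over a dataset."""
    wmax = _window_maxima(dataset, params.cr, params.terminal_exclude)
    true_meta = np.array([lab == METAMORPHIC for lab in dataset.labels])
    pred_meta = wmax > params.di_thre
    return _confusion_from_predictions(pred_meta, true_meta)


def grid_search(
    dataset: LabeledDataset,
    grid: Optional[GridSpec] = None,
    terminal_exclude: int = 5,
) -> Tuple[ClassifierParams, float, pd.DataFrame]:
    """Exhaustive MCC-maximizing search over the (CR, DI_thre) grid.

    Returns the best parameters, their MCC, and the full table of grid
    cells (columns cr, di_thre, tp, fp, tn, fn, mcc, tpr, tnr, acc) from
    which an MCC heat map can be rendered.  Ties are broken toward the
    smallest CR, then the smallest DI_thre.
    """
    grid = grid or default_grid()
    true_meta = np.array([lab == METAMORPHIC for lab in dataset.labels])
    records = []
    best: Optional[Tuple[float, ClassifierParams]] = None
    for cr in grid.cr_values:
        wmax = _window_maxima(dataset, cr, terminal_exclude)
        for thre in grid.di_thre_values:
            cm = _confusion_from_predictions(wmax > thre, true_meta)
            cell_mcc = mcc(cm)
            try:
                r = rates(cm)
            except ValueError:  # one true class absent from the dataset
                r = Rates(float("nan"), float("nan"), cm.total and (cm.tp + cm.tn) / cm.total)
            records.append(
                {
                    "cr": cr, "di_thre": thre,
                    "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                    "mcc": cell_mcc, "tpr": r.tpr, "tnr": r.tnr, "acc": r.acc,
                }
            )
            if best is None or cell_mcc > best[0]:
                best = (
                    cell_mcc,
                    ClassifierParams(cr=cr, di_thre=thre, terminal_exclude=terminal_exclude),
                )
    assert best is not None
    return best[1], best[0], pd.DataFrame.from_records(records)


@dataclass
class FoldResult:
    fold: int
    params: ClassifierParams
    train_mcc: float
    test_mcc: float
    test_cm: ConfusionMatrix


@dataclass
class CrossValidationResult:
    folds: List[FoldResult]
    mean_train_mcc: float
    sd_train_mcc: float
    mean_test_mcc: float
    sd_test_mcc: float


def cross_validate(
    dataset: LabeledDataset,
    k: int,
    grid: Optional[GridSpec] = None,
    seed: int = 0,
    terminal_exclude: int = 5,
) -> CrossValidationResult:
    """k-fold cross-validation with a seeded random shuffle.

    The dataset is shuffled once and split into ``k`` chunks differing in
    size by at most one (the first ``n mod k`` chunks take the extra
    entry).  Each fold trains by grid search on the other ``k - 1`` chunks
    and evaluates on the held-out chunk.  Summary statistics are the mean
    and sample standard deviation (ddof=1) across folds.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    chunks, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        chunks.append(perm[start : start + size])
        start += size

    folds = []
    for i, test_idx in enumerate(chunks):
        train_idx = np.concatenate([c for j, c in enumerate(chunks) if j != i])
        train_set = dataset.subset(train_idx.tolist())
        test_set = dataset.subset(test_idx.tolist())
        params, train_mcc, _ = grid_search(train_set, grid, terminal_exclude)
        test_cm = evaluate(test_set, params)
        folds.append(
            FoldResult(
                fold=i,
                params=params,
                train_mcc=train_mcc,
                test_mcc=mcc(test_cm),
                test_cm=test_cm,
            )
        )
    train_mccs = np.array([f.train_mcc for f in folds])
    test_mccs = np.array([f.test_mcc for f in folds])
    return CrossValidationResult(
        folds=folds,
        mean_train_mcc=float(train_mccs.mean()),
        sd_train_mcc=float(train_mccs.std(ddof=1)),
        mean_test_mcc=float(test_mccs.mean()),
        sd_test_mcc=float(test_mccs.std(ddof=1)),
    )


@dataclass(frozen=True)
class DiscriminantLine:
    """Decision line in the (DI_a, DI_b) descriptor plane.

    Stored in Hessian normal form ``a*x + b*y = c`` with ``(a, b)`` a unit
    normal; ``orientation = +1`` means the metamorphic side satisfies
    ``a*x + b*y > c``.  Slope/intercept of the boundary are exposed as
    properties (slope is ``inf`` for a vertical boundary).
    """

    a: float
    b: float
    c: float
    orientation: int

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c)):
            raise ValueError("line coefficients must be finite")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def slope(self) -> float:
        if self.b == 0:
            return math.inf
        return -self.a / self.b

    @property
    def intercept(self) -> float:
        if self.b == 0:
            return math.nan
        return self.c / self.b

    def predict(self, di_a: float, di_b: float) -> str:
        side = self.a * di_a + self.b * di_b - self.c
        is_meta = side > 0 if self.orientation == 1 else side < 0
        return METAMORPHIC if is_meta else MONOMORPHIC


def fit_discriminant(
    points: Sequence[Tuple[float, float, str]],
) -> Tuple[DiscriminantLine, float]:
    """Fit the MCC-maximizing line separating two per-sequence descriptors.

    Each point is ``(di_a, di_b, label)`` where the descriptors are
    window-max diversity indices from two secondary-structure predictors.
    The search enumerates line normals at one-degree steps over [0°, 180°)
    and, per direction, candidate offsets at the midpoints between
    consecutive projected points (plus one offset outside each extreme),
    trying both orientations — this visits every distinct labeling a line
    can induce on the sample.  Ties keep the first (smallest angle, then
    smallest offset, metamorphic-above first) optimum.
    """
    X = np.array([[p[0], p[1]] for p in points], dtype=float)
    y = np.array([p[2] == METAMORPHIC for p in points])
    if len(points) == 0 or y.all() or not y.any():
        raise ValueError("discriminant fitting requires points of both labels")

    best_mcc = -2.0
    best_line: Optional[DiscriminantLine] = None
    for theta_deg in range(180):
        theta = math.radians(theta_deg)
        normal = np.array([math.cos(theta), math.sin(theta)])
        proj = X @ normal
        uniq = np.unique(proj)
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        offsets = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
        above = proj[None, :] > offsets[:, None]  # (n_offsets, n_points)
        for orientation in (1, -1):
            pred = above if orientation == 1 else ~above
            tp = (pred & y).sum(axis=1)
            fp = (pred & ~y).sum(axis=1)
            fn = (~pred & y).sum(axis=1)
            tn = (~pred & ~y).sum(axis=1)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            with np.errstate(invalid="ignore", divide="ignore"):
                cell = np.where(
                    denom > 0,
                    (tp * tn - fp * fn) / np.sqrt(denom.astype(float)),
                    0.0,
                )
            j = int(np.argmax(cell))
            if cell[j] > best_mcc:
                best_mcc = float(cell[j])
                best_line = DiscriminantLine(
                    a=float(normal[0]),
                    b=float(normal[1]),
                    c=float(offsets[j]),
                    orientation=orientation,
                )
    assert best_line is not None
    return best_line, best_mcc


def descriptor_correlation(points: Sequence[Tuple[float, float]]) -> float:
    """Squared Pearson correlation (OLS R²) between two DI descriptors."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (di_a, di_b) points")
    a, b = arr[:, 0], arr[:, 1]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("descriptor correlation undefined for a constant descriptor")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
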