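"""One-rule (decision-stump) activity classification and its evaluation.

The classifier is a single if-then-else rule on one fluctuation column: a
kinase is predicted active when the RMSF of one residue falls on one side of
a threshold. Fitting is an exhaustive search over every (column, midpoint
threshold) pair minimizing weighted Gini impurity; the deliberate
constraint to depth one keeps the model fully interpretable, and repeated
random holdout quantifies how stable the selected residue and its threshold
are.

Conventions pinned for determinism (and matched by the brute-force oracle in
the test suite):

* candidate thresholds are midpoints between consecutive distinct sorted
  values of a column;
* ties in impurity break toward the lowest column position, then the lowest
  threshold;
* the below-threshold class is the side majority, with an exact tie going to
  ``active``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from kinoflex.alignment import FluctuationMatrix

__all__ = [
    "DecisionStumpClassifier",
    "StumpModel",
    "EvaluationReport",
    "AblationReport",
    "fit_stump",
    "balanced_accuracy",
    "resampled_evaluation",
    "ablation_cascade",
    "lasso_select",
]

ACTIVE, INACTIVE = "active", "inactive"


def _as_xy(X, y=None):
    """Normalize input to (values array, column ids, binary y with 1=active)."""
    if isinstance(X, FluctuationMatrix):
        cols = list(X.values.columns)
        return X.X, cols, X.y
    if isinstance(X, pd.DataFrame):
        arr, cols = X.to_numpy(dtype=float), list(X.columns)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        cols = list(range(arr.shape[1]))
    if y is None:
        raise ValueError("y is required unless X is a FluctuationMatrix")
    return arr, cols, _as_binary(y)


def _as_binary(y) -> np.ndarray:
    """Map labels to 1 = active / 0 = inactive."""
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        bad = set(np.unique(y)) - {ACTIVE, INACTIVE}
        if bad:
            raise ValueError(f"string labels must be 'active'/'inactive'; got {sorted(bad)}")
        return (y == ACTIVE).astype(int)
    return y.astype(int)


def _best_split(X: np.ndarray, y: np.ndarray):
    """Vectorized exhaustive stump search.

    Returns (column position, threshold, impurity, orientation) minimizing
    the weighted Gini impurity over all columns and midpoint thresholds.
    """
    n, p = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    cum_act = np.cumsum(ys, axis=0)
    total_act = cum_act[-1]

    nb = np.arange(1, n, dtype=float)[:, None]
    na = n - nb
    ab = cum_act[:-1].astype(float)
    aa = total_act[None, :] - ab

    gini_b = 1.0 - (ab / nb) ** 2 - ((nb - ab) / nb) ** 2
    gini_a = 1.0 - (aa / na) ** 2 - ((na - aa) / na) ** 2
    imp = (nb * gini_b + na * gini_a) / n
    imp = np.where(Xs[1:] > Xs[:-1], imp, np.inf)

    best = imp.min()
    if not np.isfinite(best):
        raise ValueError("no valid split: every column is constant")
    rows, cols = np.nonzero(imp == best)
    j = int(cols.min())
    i = int(rows[cols == j].min())

    threshold = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    mean_below = ab[i, j] / (i + 1)
    mean_above = aa[i, j] / (n - i - 1)
    orientation = ACTIVE if mean_below >= mean_above else INACTIVE
    return j, float(threshold), float(best), orientation


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity (active = positive class).

    Robust to class imbalance; requires both classes in ``y_true``.
    """
    yt = _as_binary(y_true)
    yp = _as_binary(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    if yt.min() == yt.max():
        raise ValueError("y_true must contain both classes")
    sens = float(np.mean(yp[yt == 1] == 1))
    spec = float(np.mean(yp[yt == 0] == 0))
    return 0.5 * (sens + spec)


class DecisionStumpClassifier(ClassifierMixin, BaseEstimator):
    """Single-rule activity classifier on a fluctuation matrix.

    Fitted attributes
    -----------------
    column_ : column id of the selected feature (alignment column)
    column_pos_ : positional index of that column in the training X
    threshold_ : split threshold in A (midpoint between two observed values)
    orientation_ : class predicted below the threshold ('active'/'inactive')
    train_impurity_ : weighted Gini impurity of the selected split
    train_balanced_accuracy_ : balanced accuracy on the training rows
    """

    classes_ = np.array([ACTIVE, INACTIVE])

    def fit(self, X, y=None):
        arr, cols, yb = _as_xy(X, y)
        if len(arr) < 2:
            raise ValueError("need at least 2 training rows")
        if yb.min() == yb.max():
            raise ValueError("training data must contain both classes")
        j, thr, imp, orient = _best_split(arr, yb)
        self.column_pos_ = j
        self.column_ = cols[j]
        self.threshold_ = thr
        self.orientation_ = orient
        self.train_impurity_ = imp
        self.feature_columns_ = cols
        self.train_balanced_accuracy_ = balanced_accuracy(yb, self._predict_values(arr[:, j]))
        return self

    def _predict_values(self, v: np.ndarray) -> np.ndarray:
        below = v <= self.threshold_
        other = INACTIVE if self.orientation_ == ACTIVE else ACTIVE
        return np.where(below, self.orientation_, other)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, FluctuationMatrix):
            v = X.values[self.column_].to_numpy(dtype=float)
        elif isinstance(X, pd.DataFrame):
            v = X[self.column_].to_numpy(dtype=float)
        else:
            v = np.asarray(X, dtype=float)[:, self.column_pos_]
        return self._predict_values(v)

    def to_model(self) -> "StumpModel":
        return StumpModel(
            column=self.column_,
            threshold=self.threshold_,
            orientation=self.orientation_,
            train_impurity=self.train_impurity_,
            train_balanced_accuracy=self.train_balanced_accuracy_,
        )


@dataclass(frozen=True)
class StumpModel:
    """The learned one-rule model: (column, threshold, orientation) + stats."""

    column: object
    threshold: float
    orientation: str
    train_impurity: float
    train_balanced_accuracy: float


def fit_stump(X, y=None) -> DecisionStumpClassifier:
    """Fit the exhaustive one-rule classifier; thin estimator wrapper."""
    return DecisionStumpClassifier().fit(X, y)


@dataclass
class EvaluationReport:
    """Aggregate of a repeated random-holdout evaluation of the stump."""

    repeats: int
    train_fraction: float
    mean_balanced_accuracy: float
    sd_balanced_accuracy: float
    records: list[dict]
    column_selection_frequency: dict

    def __post_init__(self) -> None:
        accs = np.array([r["balanced_accuracy"] for r in self.records])
        if len(accs) != self.repeats:
            raise ValueError("records length must equal repeats")
        if not math.isclose(accs.mean(), self.mean_balanced_accuracy, abs_tol=1e-12):
            raise ValueError("mean inconsistent with per-repeat records")
        freq_total = sum(self.column_selection_frequency.values())
        if not math.isclose(freq_total, 1.0, abs_tol=1e-9):
            raise ValueError("column selection frequencies must sum to 1")

    @property
    def modal_column(self):
        """Most frequently selected column; ties toward the lower column id."""
        best = max(self.column_selection_frequency.values())
        cands = [c for c, f in self.column_selection_frequency.items() if f == best]
        return sorted(cands)[0]

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "sd_balanced_accuracy": self.sd_balanced_accuracy,
            "column_selection_frequency": {
                str(k): v for k, v in sorted(self.column_selection_frequency.items(), key=lambda kv: str(kv[0]))
            },
            "records": self.records,
        }

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def resampled_evaluation(
    X,
    y=None,
    train_fraction: float = 0.7,
    repeats: int = 100,
    base_seed: int = 0,
    max_redraws: int = 1000,
) -> EvaluationReport:
    """Repeated random-holdout evaluation of the one-rule classifier.

    Each repeat draws a simple random split with ``floor(n * train_fraction)``
    training rows, fits the stump on the training rows and scores balanced
    accuracy on the validation rows. Splits leaving a single class on either
    side are redrawn (bounded, then an error). Fully reproducible from
    ``base_seed``.
    """
    arr, cols, yb = _as_xy(X, y)
    n = len(arr)
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    if yb.min() == yb.max():
        raise ValueError("both classes must be present")
    n_train = int(math.floor(n * train_fraction))
    if n_train < 2 or n - n_train < 2:
        raise ValueError(f"train_fraction {train_fraction} leaves a degenerate split")

    rng = np.random.default_rng(base_seed)
    records = []
    counts: dict = {}
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        for _ in range(max_redraws):
            perm = rep_rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if yb[tr].min() != yb[tr].max() and yb[va].min() != yb[va].max():
                break
        else:
            raise RuntimeError("could not draw a two-class split within the retry budget")
        j, thr, imp, orient = _best_split(arr[tr], yb[tr])
        clf = DecisionStumpClassifier()
        clf.column_pos_, clf.column_ = j, cols[j]
        clf.threshold_, clf.orientation_ = thr, orient
        acc = balanced_accuracy(yb[va], clf._predict_values(arr[va, j]))
        records.append(
            {
                "repeat": rep,
                "seed": rep_seed,
                "column": cols[j],
                "threshold": thr,
                "balanced_accuracy": acc,
                "n_train": int(n_train),
                "n_validation": int(n - n_train),
            }
        )
        counts[cols[j]] = counts.get(cols[j], 0) + 1

    accs = np.array([r["balanced_accuracy"] for r in records])
    return EvaluationReport(
        repeats=repeats,
        train_fraction=train_fraction,
        mean_balanced_accuracy=float(accs.mean()),
        sd_balanced_accuracy=float(accs.std()),  # population sd over repeats
        records=records,
        column_selection_frequency={c: k / repeats for c, k in counts.items()},
    )


@dataclass
class AblationReport:
    """Rounds of the feature-ablation cascade on the one-rule classifier."""

    rounds: list[dict]

    def __post_init__(self) -> None:
        for r in self.rounds:
            if r["selected_column"] in r["removed_columns"]:
                raise ValueError("a round selected a column it had already removed")

    def selected_columns(self) -> list:
        return [r["selected_column"] for r in self.rounds]

    def to_json(self, path: str | Path) -> None:
        import json

        payload = [
            {**r, "removed_columns": [str(c) for c in r["removed_columns"]],
             "selected_column": str(r["selected_column"])}
            for r in self.rounds
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


def ablation_cascade(
    fm: FluctuationMatrix,
    rounds: int,
    train_fraction: float = 0.7,
    repeats: int = 100,
    base_seed: int = 0,
) -> AblationReport:
    """Iteratively remove the modal selected column and re-evaluate.

    Each round runs a full resampled evaluation, records the modal selected
    column with the round's mean +- sd balanced accuracy, removes that
    column, and repeats — probing which residues carry redundant copies of
    the activity signal (the way the residues just downstream of the DFG
    motif back each other up).
    """
    if rounds >= fm.values.shape[1]:
        raise ValueError("rounds must be smaller than the number of columns")
    current = fm
    removed: list = []
    out = []
    for r in range(rounds):
        report = resampled_evaluation(
            current, train_fraction=train_fraction, repeats=repeats, base_seed=base_seed + r
        )
        sel = report.modal_column
        out.append(
            {
                "round": r,
                "removed_columns": list(removed),
                "selected_column": sel,
                "mean_balanced_accuracy": report.mean_balanced_accuracy,
                "sd_balanced_accuracy": report.sd_balanced_accuracy,
            }
        )
        removed.append(sel)
        current = current.drop_columns([sel])
    return AblationReport(rounds=out)


def lasso_select(X, y=None, penalty: float = 1.0) -> list[tuple[object, float]]:
    """L1-penalized logistic selection of informative fluctuation columns.

    Columns are standardized internally (zero mean, unit variance); the
    return value is the list of (column id, coefficient) pairs with nonzero
    coefficients, ranked by decreasing |coefficient|. ``penalty`` is the L1
    strength (inverse of scikit-learn's C); ``penalty -> 0`` approaches the
    unpenalized logistic fit and a very large penalty shrinks every
    coefficient to zero.
    """
    arr, cols, yb = _as_xy(X, y)
    scale = arr.std(axis=0)
    if np.all(scale == 0):
        raise ValueError("all columns are constant; nothing to select")
    safe = np.where(scale == 0, 1.0, scale)
    Z = (arr - arr.mean(axis=0)) / safe
    C = 1.0 / max(penalty, 1e-12)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-10, max_iter=50_000
    )
    clf.fit(Z, yb)
    coefs = clf.coef_.ravel()
    ranked = sorted(
        ((cols[i], float(coefs[i])) for i in np.nonzero(coefs)[0]),
        key=lambda t: -abs(t[1]),
    )
    return ranked
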