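"""One-vs-rest max-margin subtype classification.

Four binary linear SVMs (one per subtype) are trained on standardized
features chosen by greedy sequential forward selection (SFS) under an inner
stratified CV scored by balanced accuracy; the regularization constant is
picked by an inner grid search on the selected subset.  At prediction time
each model reports the signed geometric distance of the sample to its
hyperplane (positive toward the model's subtype) and the four distances are
fused by argmax, ties broken in canonical subtype order.

Outer evaluation is leakage-safe stratified 5-fold CV: location atlases,
imputation medians, scaling statistics, selected features, and
hyperparameters are all recomputed from each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io_core import SUBTYPES
from .location_atlas import all_location_features, build_all_atlases

__all__ = [
    "ModelConfig",
    "BinaryModel",
    "OvrBundle",
    "PerformanceReport",
    "standardize_fit",
    "standardize_apply",
    "balanced_accuracy",
    "sfs_select",
    "train_binary",
    "train_ovr",
    "decision_distances",
    "fuse",
    "cross_validate",
    "metrics",
    "roc_curve",
    "assign_folds",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the OvR training procedure."""

    c_grid: tuple = tuple(2.0**k for k in range(-5, 6))
    sfs_c: float = 1.0  # fixed C during the SFS search
    inner_folds: int = 3
    sfs_threshold: float = 0.005  # balanced-accuracy units
    max_features: int = 20
    seed: int = 0


@dataclass
class BinaryModel:
    """One trained subtype-vs-rest linear max-margin model."""

    subtype: str
    feature_names: list[str]  # in selection order
    mean: np.ndarray  # standardization statistics, per selected feature
    sd: np.ndarray
    weights: np.ndarray
    offset: float
    c_value: float

    def distance(self, row: pd.Series) -> float:
        """Signed geometric distance of a raw feature row to the hyperplane."""
        missing = [f for f in self.feature_names if f not in row.index]
        if missing:
            raise KeyError(f"row is missing selected features: {missing}")
        x = row[self.feature_names].to_numpy(dtype=np.float64)
        z = (x - self.mean) / self.sd
        norm = np.linalg.norm(self.weights)
        return float((z @ self.weights + self.offset) / norm)


@dataclass
class OvrBundle:
    """The four one-vs-rest models, keyed in canonical subtype order."""

    models: dict  # subtype → BinaryModel

    def __post_init__(self) -> None:
        if set(self.models) != set(SUBTYPES):
            raise ValueError(f"bundle must hold exactly the models {SUBTYPES}")


@dataclass
class PerformanceReport:
    """Table-1-style metric suite (percent scale) plus ROC data."""

    per_subtype: dict  # subtype → {accuracy, balanced_accuracy, sensitivity,
    #                               specificity, auc, roc: [(fpr, tpr), ...]}
    overall_accuracy: float
    overall_balanced_accuracy: float
    confusion_matrix: np.ndarray  # rows = true, cols = predicted, canonical order
    seed: int | None = None
    fold_assignment: dict | None = None

    def to_dict(self) -> dict:
        return {
            "per_subtype": {
                s: {k: (v if k != "roc" else [list(p) for p in v])
                    for k, v in d.items()}
                for s, d in self.per_subtype.items()
            },
            "overall_accuracy": self.overall_accuracy,
            "overall_balanced_accuracy": self.overall_balanced_accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "subtype_order": list(SUBTYPES),
            "seed": self.seed,
            "fold_assignment": self.fold_assignment,
        }


# ---------------------------------------------------------------------------
# Standardization


def standardize_fit(X: pd.DataFrame) -> tuple[pd.Series, pd.Series, list[str]]:
    """Per-column mean and population sd on training rows.

    Returns (mean, sd, kept) where ``kept`` excludes constant columns
    (sd == 0), which are ineligible for selection.
    """
    if len(X) < 2:
        raise ValueError("need >= 2 training rows to standardize")
    mean = X.mean()
    sd = X.std(ddof=0)
    kept = [c for c in X.columns if sd[c] > 0]
    return mean, sd, kept


def standardize_apply(mean: pd.Series, sd: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    mean = mean.reindex(X.columns)
    safe_sd = sd.reindex(X.columns).replace(0.0, 1.0)
    return (X - mean) / safe_sd


# ---------------------------------------------------------------------------
# Scoring helpers


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls (fraction scale)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = []
    for cls in np.unique(y_true):
        sel = y_true == cls
        recalls.append(float(np.mean(y_pred[sel] == cls)))
    return float(np.mean(recalls))


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency
    (n / (2 n_c)), countering the ~1:3 one-vs-rest imbalance."""
    y = np.asarray(y)
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    return np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))


def _svm_fit_batch(
    X3: np.ndarray,
    y: np.ndarray,
    c_values: np.ndarray,
    sample_weight: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Batched primal solver for the L2-regularized squared-hinge SVM.

    Minimizes 0.5 ||w||² + C Σ_i s_i max(0, 1 − y_i w·x_i)² by damped
    Newton iteration on the generalized Hessian (the same objective
    liblinear's primal L2-loss solver optimizes; the bias enters through an
    appended constant column and is regularized like any weight).

    X3 : (B, n, d) design matrices, bias column included.
    c_values : scalar or (B,) regularization constants.
    Returns W : (B, d).
    """
    B, n, d = X3.shape
    ys = np.where(np.asarray(y) == 1, 1.0, -1.0)
    sw = np.broadcast_to(np.atleast_1d(np.asarray(c_values, dtype=np.float64))[:, None], (B, n)) * sample_weight[None, :]
    W = np.zeros((B, d))
    eye = np.eye(d)

    def objective(Wc):
        f = np.einsum("bnd,bd->bn", X3, Wc)
        m = 1.0 - ys[None, :] * f
        return 0.5 * (Wc**2).sum(axis=1) + (sw * np.square(np.maximum(m, 0.0))).sum(axis=1), m

    obj, m = objective(W)
    for _ in range(max_iter):
        act = m > 0
        r = np.where(act, m, 0.0)
        grad = W - 2.0 * np.einsum("bn,bnd->bd", sw * r * ys[None, :], X3)
        if np.all(np.linalg.norm(grad, axis=1) < tol * n):
            break
        H = eye[None, :, :] + 2.0 * np.einsum("bnd,bn,bne->bde", X3, sw * act, X3)
        step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        gd = (grad * step).sum(axis=1)  # directional derivative, < 0
        t = np.ones(B)
        for _ in range(30):
            obj_new, m_new = objective(W + t[:, None] * step)
            ok = obj_new <= obj + 1e-4 * t * gd
            if ok.all():
                break
            t = np.where(ok, t, t * 0.5)
        W = W + t[:, None] * step
        obj, m = objective(W)
    return W


def _with_bias(X: np.ndarray) -> np.ndarray:
    return np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, c_value: float) -> tuple[np.ndarray, float]:
    """Fit one class-weighted linear max-margin model; returns (weights, offset)."""
    W = _svm_fit_batch(_with_bias(X)[None, :, :], y, np.array([c_value]), _class_weights(y))[0]
    return W[:-1], float(W[-1])


def _batch_balanced_accuracy(pred_pos: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Balanced accuracy per batch row; pred_pos: (B, n) booleans."""
    pos = np.asarray(y) == 1
    tpr = pred_pos[:, pos].mean(axis=1)
    tnr = (~pred_pos[:, ~pos]).mean(axis=1)
    return 0.5 * (tpr + tnr)


def _inner_cv_score_batch(
    designs: np.ndarray, y: np.ndarray, c_values, splits: list
) -> np.ndarray:
    """Mean inner-CV balanced accuracy for a batch of candidate designs.

    designs : (B, n, d) feature matrices (no bias column).
    c_values : scalar (shared) or (B,) per-design C.
    """
    B, n, d = designs.shape
    scores = np.zeros(B)
    used = 0
    for train_idx, test_idx in splits:
        # degenerate folds (a class absent from either side) are skipped;
        # only reachable on very small cohorts
        if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
            continue
        Xtr = np.concatenate(
            [designs[:, train_idx, :], np.ones((B, len(train_idx), 1))], axis=2
        )
        Xte = np.concatenate(
            [designs[:, test_idx, :], np.ones((B, len(test_idx), 1))], axis=2
        )
        W = _svm_fit_batch(Xtr, y[train_idx], c_values, _class_weights(y[train_idx]))
        f = np.einsum("bnd,bd->bn", Xte, W)
        scores += _batch_balanced_accuracy(f > 0, y[test_idx])
        used += 1
    return scores / used if used else scores


def _inner_cv_score(X: np.ndarray, y: np.ndarray, c_value: float, splits: list) -> float:
    """Mean inner-CV balanced accuracy of the linear SVM on one design."""
    return float(_inner_cv_score_batch(X[None, :, :], y, c_value, splits)[0])


def _inner_splits(y: np.ndarray, n_folds: int, seed: int) -> list:
    min_class = int(np.bincount(np.asarray(y)).min())
    n_folds = max(2, min(n_folds, min_class))  # keep every class in every fold
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


# ---------------------------------------------------------------------------
# Sequential forward selection


def sfs_select(
    X: pd.DataFrame,
    y: np.ndarray,
    config: ModelConfig | None = None,
) -> list[str]:
    """Greedy forward selection maximizing inner-CV balanced accuracy.

    The first feature is always added (argmax of single-feature scores);
    afterwards selection stops when the best achievable improvement falls
    below ``config.sfs_threshold`` or ``config.max_features`` is reached.
    Ties take the lowest column index.  Deterministic given (X, y, config).
    """
    config = config or ModelConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present for selection")
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=np.float64)
    splits = _inner_splits(y, config.inner_folds, config.seed)

    selected: list[int] = []
    current_score = -np.inf
    while len(selected) < config.max_features:
        remaining = [j for j in range(len(cols)) if j not in selected]
        if not remaining:
            break
        # batch of candidate designs: selected columns + one candidate each
        designs = np.empty((len(remaining), len(y), len(selected) + 1))
        if selected:
            designs[:, :, :-1] = Xv[:, selected]
        designs[:, :, -1] = Xv[:, remaining].T
        scores = _inner_cv_score_batch(designs, y, config.sfs_c, splits)
        best_local = int(np.argmax(scores))  # first max → lowest column index
        best_j = remaining[best_local]
        best_score = float(scores[best_local])
        if selected and best_score - current_score < config.sfs_threshold:
            break
        selected.append(best_j)
        current_score = best_score
    return [cols[j] for j in selected]


# ---------------------------------------------------------------------------
# Training


def train_binary(
    table: pd.DataFrame, labels: pd.Series, subtype: str, config: ModelConfig
) -> BinaryModel:
    """Train one subtype-vs-rest model: standardize, SFS, C grid search,
    final fit on the full training fold."""
    y = (labels.to_numpy() == subtype).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"subtype {subtype!r} absent from training fold (or alone)")
    mean, sd, kept = standardize_fit(table)
    Z = standardize_apply(mean, sd, table[kept])
    chosen = sfs_select(Z, y, config)
    Zsel = Z[chosen].to_numpy(dtype=np.float64)

    splits = _inner_splits(y, config.inner_folds, config.seed)
    c_grid = np.asarray(config.c_grid, dtype=np.float64)
    designs = np.broadcast_to(Zsel[None, :, :], (len(c_grid),) + Zsel.shape)
    c_scores = _inner_cv_score_batch(designs, y, c_grid, splits)
    best_c = float(c_grid[int(np.argmax(c_scores))])

    weights, offset = _fit_linear_svm(Zsel, y, best_c)
    return BinaryModel(
        subtype=subtype,
        feature_names=chosen,
        mean=mean[chosen].to_numpy(dtype=np.float64),
        sd=sd[chosen].to_numpy(dtype=np.float64),
        weights=weights,
        offset=offset,
        c_value=best_c,
    )


def train_ovr(
    table: pd.DataFrame, labels: pd.Series, config: ModelConfig | None = None
) -> OvrBundle:
    """Train the four one-vs-rest models on one training fold."""
    config = config or ModelConfig()
    present = set(labels)
    missing = [s for s in SUBTYPES if s not in present]
    if missing:
        raise ValueError(f"subtypes absent from training data: {missing}")
    models = {s: train_binary(table, labels, s, config) for s in SUBTYPES}
    return OvrBundle(models=models)


# ---------------------------------------------------------------------------
# Prediction


def decision_distances(bundle: OvrBundle, row: pd.Series) -> np.ndarray:
    """Four signed geometric hyperplane distances in canonical subtype order."""
    d = np.array([bundle.models[s].distance(row) for s in SUBTYPES])
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite decision distance")
    return d


def fuse(distances) -> str:
    """Max-distance fusion: argmax over the four signed distances, exact
    ties broken by canonical subtype order."""
    d = np.asarray(distances, dtype=np.float64)
    if d.shape != (4,) or not np.all(np.isfinite(d)):
        raise ValueError("expected four finite distances in canonical order")
    return SUBTYPES[int(np.argmax(d))]


# ---------------------------------------------------------------------------
# Evaluation


def roc_curve(scores, y_true) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all score thresholds plus trapezoidal AUC.

    Tied scores move as one block (diagonal segment), so the trapezoidal
    area equals the rank/Mann-Whitney AUC with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_true).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += int((~y_sorted[i:j]).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def metrics(
    y_true,
    y_pred,
    scores: pd.DataFrame | None = None,
    seed: int | None = None,
    fold_assignment: dict | None = None,
) -> PerformanceReport:
    """Metric suite on pooled predictions (percent scale).

    ``scores`` (optional) holds one column of decision distances per subtype
    for per-class ROC/AUC.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("prediction/label length mismatch")
    n = len(y_true)
    per_subtype = {}
    for s in SUBTYPES:
        pos = y_true == s
        if pos.sum() == 0 or pos.sum() == n:
            per_subtype[s] = {"flag": "class absent: one-vs-rest metrics undefined"}
            continue
        pred_pos = y_pred == s
        sens = float(np.mean(pred_pos[pos])) * 100.0
        spec = float(np.mean(~pred_pos[~pos])) * 100.0
        acc = float(np.mean(pred_pos == pos)) * 100.0
        entry = {
            "accuracy": acc,
            "balanced_accuracy": (sens + spec) / 2.0,
            "sensitivity": sens,
            "specificity": spec,
        }
        if scores is not None:
            points, auc = roc_curve(scores[s].to_numpy(), pos)
            entry["auc"] = auc
            entry["roc"] = points
        per_subtype[s] = entry

    overall_acc = float(np.mean(y_true == y_pred)) * 100.0
    overall_bal = balanced_accuracy(y_true, y_pred) * 100.0
    cm = np.zeros((4, 4), dtype=int)
    index = {s: k for k, s in enumerate(SUBTYPES)}
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return PerformanceReport(
        per_subtype=per_subtype,
        overall_accuracy=overall_acc,
        overall_balanced_accuracy=overall_bal,
        confusion_matrix=cm,
        seed=seed,
        fold_assignment=fold_assignment,
    )


def assign_folds(labels: pd.Series, k: int, seed: int) -> dict[str, int]:
    """Stratified fold assignment: subject id → fold index in 1..k."""
    counts = labels.value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"classes with fewer than k={k} members: "
            f"{dict(too_small)}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = {}
    ids = list(labels.index)
    for fold, (_, test_idx) in enumerate(
        skf.split(np.zeros(len(labels)), labels.to_numpy()), start=1
    ):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


def _impute_with(medians: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    out = X.copy()
    for col in out.columns[out.isna().any()]:
        out[col] = out[col].fillna(medians[col])
    return out


def cross_validate(
    table: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    seed: int = 0,
    config: ModelConfig | None = None,
    tc_masks: dict | None = None,
    return_artifacts: bool = False,
):
    """Leakage-safe stratified k-fold CV with max-distance fusion.

    When ``tc_masks`` (subject id → boolean TC volume) is given, the 16
    location features are appended per fold from atlases built on that
    fold's training subjects only.  Missing (flagged) values are imputed
    with training-fold column medians.  Returns a pooled
    :class:`PerformanceReport` (and per-fold artifacts when requested).
    """
    config = config or ModelConfig()
    assignment = assign_folds(labels, k, seed)
    ids = list(table.index)
    y_all = labels.reindex(table.index)

    predictions = pd.Series(index=table.index, dtype=object)
    score_frame = pd.DataFrame(index=table.index, columns=list(SUBTYPES), dtype=float)
    artifacts = []

    for fold in range(1, k + 1):
        test_ids = [i for i in ids if assignment[i] == fold]
        train_ids = [i for i in ids if assignment[i] != fold]
        fold_table = table.copy()

        atlases = None
        if tc_masks is not None:
            from .io_core import SubjectRecord  # noqa: F401 (doc pointer)

            atlases = _fold_atlases(tc_masks, y_all, train_ids)
            loc = pd.DataFrame(
                {sid: all_location_features(tc_masks[sid], atlases) for sid in ids}
            ).T
            loc.index = pd.Index(ids)
            fold_table = pd.concat([fold_table, loc.reindex(fold_table.index)], axis=1)

        medians = fold_table.loc[train_ids].median()
        train_X = _impute_with(medians, fold_table.loc[train_ids])
        test_X = _impute_with(medians, fold_table.loc[test_ids])

        bundle = train_ovr(train_X, y_all.loc[train_ids], config)
        for sid in test_ids:
            d = decision_distances(bundle, test_X.loc[sid])
            predictions.loc[sid] = fuse(d)
            score_frame.loc[sid] = d

        if return_artifacts:
            artifacts.append(
                {
                    "fold": fold,
                    "train_ids": train_ids,
                    "test_ids": test_ids,
                    "atlases": atlases,
                    "impute_medians": medians,
                    "bundle": bundle,
                }
            )

    report = metrics(
        y_all.to_numpy(),
        predictions.to_numpy(),
        scores=score_frame,
        seed=seed,
        fold_assignment=assignment,
    )
    if return_artifacts:
        return report, artifacts
    return report


def _fold_atlases(tc_masks: dict, labels: pd.Series, train_ids: list[str]) -> dict:
    """Atlas pairs from training subjects only (raw-mask variant of
    :func:`gbmrad.location_atlas.build_all_atlases`)."""
    from .location_atlas import AtlasPair

    pairs = {}
    for subtype in SUBTYPES:
        plus = [tc_masks[i] for i in train_ids if labels.loc[i] == subtype]
        minus = [tc_masks[i] for i in train_ids if labels.loc[i] != subtype]
        if not plus or not minus:
            raise ValueError(f"fold has no {subtype!r} training subject")
        pairs[subtype] = AtlasPair(
            subtype=subtype,
            p_plus=np.mean(plus, axis=0),
            p_minus=np.mean(minus, axis=0),
            n_plus=len(plus),
            n_minus=len(minus),
        )
    return pairs
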