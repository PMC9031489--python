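"""Feature normalization/imputation, mRMR ranking, cost-weighted
maximum-margin classification and leave-one-subject-out validation.

All per-fold preprocessing (z-scoring, mean imputation, feature ranking)
is fitted on the training patients only; the held-out patient's epochs
never influence it.  The margin solvers are scikit-learn's SVC — the
contract here is the per-class cost weighting and kernel semantics, not
the optimizer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import META_COLUMNS

log = logging.getLogger(__name__)

POSITIVE = "seizure"


@dataclass(frozen=True)
class ModelConfig:
    """Classifier hyper-parameters.

    ``kernel='linear'`` is parameterized by the regularization penalty
    ``lam`` (the margin solver's cost is ``1/(lam * n_train)``);
    ``kernel='gaussian'`` by ``box_constraint`` and ``kernel_scale`` with
    ``k(u, v) = exp(-||u - v||^2 / (2 scale^2))``.  ``c1``/``c2`` weight
    misclassifications of the non-seizure / seizure class, mitigating the
    heavy class imbalance of seizure data.  ``n_features`` is an integer
    rank cutoff of the mRMR ordering, or ``"full"``.
    """

    kernel: str = "gaussian"
    lam: float = 1e-5
    box_constraint: float = 1.0
    kernel_scale: float = 1.0
    c1: float = 1.0
    c2: float = 1.0
    n_features: object = "full"

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "linear" and self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.kernel == "gaussian" and (self.box_constraint <= 0 or self.kernel_scale <= 0):
            raise ValueError("box constraint and kernel scale must be positive")
        if self.c1 < 1 or self.c2 < 1:
            raise ValueError("misclassification costs must be >= 1")


@dataclass
class FoldResult:
    """Predictions for one held-out patient of a LOSO run."""

    patient_id: str
    group: str
    scores: np.ndarray
    predicted: np.ndarray        # boolean, True = seizure
    truth: np.ndarray            # boolean
    selected_features: list
    epoch_start_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    epoch_end_s: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# normalization and imputation
# ---------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    """Training-fold z-scoring followed by train-mean imputation.

    After z-scoring, the training mean of every feature is zero, so missing
    cells become 0; constant (zero-variance) and fully-missing columns map
    to 0 everywhere.
    """

    columns: list
    means: np.ndarray
    sds: np.ndarray


def normalize_fit(train: pd.DataFrame, columns) -> FeatureTransform:
    means = np.empty(len(columns))
    sds = np.empty(len(columns))
    for j, c in enumerate(columns):
        col = train[c].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if ok.sum() == 0:
            log.warning("feature %s has no finite training values; imputed to 0", c)
            means[j], sds[j] = 0.0, 0.0
            continue
        means[j] = col[ok].mean()
        sds[j] = col[ok].std(ddof=0)
    return FeatureTransform(list(columns), means, sds)


def normalize_apply(tf: FeatureTransform, rows: pd.DataFrame) -> pd.DataFrame:
    """Z-score with training statistics and impute missing values to the
    (zero) training mean.  Returns only the feature columns."""
    out = {}
    for j, c in enumerate(tf.columns):
        col = rows[c].to_numpy(dtype=float)
        if tf.sds[j] > 0:
            z = (col - tf.means[j]) / tf.sds[j]
        else:
            z = np.zeros_like(col)
        z[~np.isfinite(z)] = 0.0
        out[c] = z
    return pd.DataFrame(out, index=rows.index)


# ---------------------------------------------------------------------------
# mutual information and mRMR
# ---------------------------------------------------------------------------

def _discretize(col: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` codes; features with
    few distinct values (e.g. near-binary ones) keep one code per value."""
    finite = np.isfinite(col)
    uniq = np.unique(col[finite])
    if uniq.size <= n_bins:
        codes = np.full(col.shape, -1.0)
        codes[finite] = np.searchsorted(uniq, col[finite])
    else:
        ranks = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
        codes = np.asarray(ranks, dtype=float)
        codes[~np.isfinite(codes)] = -1       # missing -> its own bin
    return codes.astype(int)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete code vectors."""
    if a.size != b.size or a.size == 0:
        raise ValueError("need two equal-length non-empty code vectors")
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (pa @ pb)[mask])))


def mrmr_rank(X: pd.DataFrame, y, k: int | None = None, n_bins: int = 10) -> list:
    """Greedy minimum-redundancy-maximum-relevance ranking (MID criterion).

    Each step adds the feature maximizing MI(feature; class) minus the mean
    MI with the already-selected features, with MI estimated by
    equal-frequency discretization into ``n_bins`` bins.  Ties break toward
    the earlier column in the canonical feature order, so the ranking is
    deterministic.
    """
    cols = list(X.columns)
    if k is None:
        k = len(cols)
    if k > len(cols):
        raise ValueError(f"requested {k} features but only {len(cols)} available")
    y = np.asarray(y).astype(int)
    codes = {c: _discretize(X[c].to_numpy(dtype=float), n_bins) for c in cols}
    relevance = {c: mutual_information(codes[c], y) for c in cols}
    selected: list = []
    remaining = list(cols)
    pair_mi: dict = {}
    while len(selected) < k:
        best_name, best_score = None, -np.inf
        for c in remaining:
            if selected:
                red = np.mean([
                    pair_mi.setdefault((c, s), mutual_information(codes[c], codes[s]))
                    for s in selected
                ])
            else:
                red = 0.0
            score = relevance[c] - red
            if score > best_score + 1e-15:
                best_name, best_score = c, score
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def train(config: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Fit a cost-weighted maximum-margin classifier.

    ``y`` is boolean (True = seizure).  Raises when the training fold
    contains a single class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training fold contains a single class")
    weights = {False: config.c1, True: config.c2}
    if config.kernel == "linear":
        c = 1.0 / (config.lam * len(y))
        clf = SVC(kernel="linear", C=c, class_weight=weights)
    else:
        gamma = 1.0 / (2.0 * config.kernel_scale ** 2)
        clf = SVC(kernel="rbf", C=config.box_constraint, gamma=gamma,
                  class_weight=weights)
    clf.fit(X, y)
    return clf


def predict(clf, X: np.ndarray):
    """Continuous decision scores (larger = more seizure-like) and their
    sign-thresholded labels."""
    X = np.asarray(X, dtype=float)
    scores = clf.decision_function(X)
    return scores, scores > 0


# ---------------------------------------------------------------------------
# LOSO cross-validation and grid search
# ---------------------------------------------------------------------------

def _feature_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c not in META_COLUMNS]


def loso_cv(dataset: pd.DataFrame, config: ModelConfig) -> list[FoldResult]:
    """Leave-one-subject-out validation over a per-epoch feature table.

    ``dataset`` carries the meta columns (``patient_id``, ``group``,
    ``label``, epoch bounds) plus feature columns.  For each patient, the
    normalizer, imputer and mRMR ranking are fitted on the remaining
    patients, a classifier is trained and the held-out epochs are scored.
    Folds whose training data is single-class are skipped with a log entry.
    """
    patients = list(dict.fromkeys(dataset["patient_id"]))
    if len(patients) < 2:
        raise ValueError("LOSO needs at least two patients")
    cols = _feature_columns(dataset)
    results = []
    for pid in patients:
        test = dataset[dataset["patient_id"] == pid]
        train_rows = dataset[dataset["patient_id"] != pid]
        y_train = (train_rows["label"] == POSITIVE).to_numpy()
        if y_train.all() or not y_train.any():
            log.warning("fold %s skipped: single-class training data", pid)
            continue
        tf = normalize_fit(train_rows, cols)
        Xtr = normalize_apply(tf, train_rows)
        Xte = normalize_apply(tf, test)
        if config.n_features == "full":
            chosen = list(cols)
        else:
            chosen = mrmr_rank(Xtr, y_train, int(config.n_features))
        clf = train(config, Xtr[chosen].to_numpy(), y_train)
        scores, labels = predict(clf, Xte[chosen].to_numpy())
        results.append(FoldResult(
            patient_id=pid,
            group=str(test["group"].iloc[0]),
            scores=scores,
            predicted=labels,
            truth=(test["label"] == POSITIVE).to_numpy(),
            selected_features=chosen,
            epoch_start_s=test["epoch_start_s"].to_numpy(dtype=float),
            epoch_end_s=test["epoch_end_s"].to_numpy(dtype=float),
        ))
    return results


def mean_pathological_auc(folds: list[FoldResult]) -> float:
    """Mean per-patient AUC over patients with both classes present
    (controls have no positive epochs, so their AUC is undefined and they
    are excluded from the mean)."""
    from .evaluation import roc_auc

    aucs = [roc_auc(f.scores, f.truth) for f in folds]
    aucs = [a for a in aucs if np.isfinite(a)]
    return float(np.mean(aucs)) if aucs else np.nan


def grid_search(dataset: pd.DataFrame, configs, n_features_menu=("full",)):
    """Exhaustive LOSO evaluation of every (config, feature-count) pair.

    Selection criterion: highest mean per-pathological-patient AUC; ties
    break toward fewer features, then the smaller seizure-class cost.
    Returns the winning config, its folds, and the full results table.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("empty hyper-parameter grid")
    rows = []
    best = None
    for base, k in itertools.product(configs, n_features_menu):
        cfg = replace(base, n_features=k)
        folds = loso_cv(dataset, cfg)
        auc = mean_pathological_auc(folds)
        nfeat = len(_feature_columns(dataset)) if k == "full" else int(k)
        rows.append({
            "kernel": cfg.kernel, "lam": cfg.lam,
            "box_constraint": cfg.box_constraint, "kernel_scale": cfg.kernel_scale,
            "c1": cfg.c1, "c2": cfg.c2, "n_features": k,
            "mean_pathological_auc": auc,
        })
        key = (-(auc if np.isfinite(auc) else -np.inf), nfeat, cfg.c2)
        if best is None or key < best[0]:
            best = (key, cfg, folds)
    return best[1], best[2], pd.DataFrame(rows)


#: Default hyper-parameter grid, spanning the ranges that performed best in
#: published neonatal HRV seizure-detection experiments.
def default_grid(kernel: str = "gaussian") -> list[ModelConfig]:
    grid = []
    if kernel in ("linear", "both"):
        for lam in (1e-8, 1e-7, 1e-5, 1e-3):
            for c2 in (1.0, 2.0, 7.0, 40.0):
                grid.append(ModelConfig(kernel="linear", lam=lam, c2=c2))
    if kernel in ("gaussian", "both"):
        for box in (0.5, 1.0, 5.0):
            for scale in (0.1, 1.0, 5.0, 25.0):
                for c2 in (1.0, 5.0, 200.0):
                    grid.append(ModelConfig(kernel="gaussian", box_constraint=box,
                                            kernel_scale=scale, c2=c2))
    return grid
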