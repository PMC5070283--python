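"""Leave-one-out cross-validation harness and the three classifiers.

Classifiers: linear discriminant (LDC, Ledoit-Wolf shrinkage when the
training covariance is singular), Gaussian Naive Bayes (NBC) and a
soft-margin SVM with Gaussian RBF kernel (nSVM). Features are standardized
with training-fold statistics only; zero-variance features are dropped with
a warning. Fold hygiene is strict: static pair selection and dynamic state
centroids are re-fit inside every fold on training subjects only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .dataio import (
    Band,
    FoldResult,
    Modality,
    StudyDataset,
)
from .dynamic_fnc import (
    DEFAULT_LAMBDA_GRID,
    WindowSpec,
    compute_dfnc,
    dfnc_features,
)
from .static_fnc import StaticFNCSelector, static_fnc

__all__ = [
    "CLASSIFIER_NAMES",
    "FNCClassifier",
    "fit_predict",
    "loocv_folds",
    "run_pipeline_loocv",
    "accuracy_table",
    "PipelineResult",
]

CLASSIFIER_NAMES = ("NBC", "nSVM", "LDC")


class FNCClassifier(BaseEstimator, ClassifierMixin):
    """One of the three study classifiers behind a common sklearn interface.

    Parameters
    ----------
    kind : {"LDC", "NBC", "nSVM"}
    C, gamma : nSVM hyperparameters (gamma="scale" = 1/(d * var) on the
        standardized training fold).
    shrinkage : LDC shrinkage policy; "auto" (Ledoit-Wolf) is used whenever
        the training problem is singular (features >= subjects), otherwise
        the unregularized solver.
    var_floor : NBC variance floor (GaussianNB var_smoothing).
    """

    def __init__(
        self,
        kind: str = "LDC",
        C: float = 1.0,
        gamma: str | float = "scale",
        shrinkage: str = "auto",
        var_floor: float = 1e-9,
    ):
        self.kind = kind
        self.C = C
        self.gamma = gamma
        self.shrinkage = shrinkage
        self.var_floor = var_floor

    def _make(self, n_samples: int, n_features: int):
        kind = self.kind.upper()
        if kind == "LDC":
            if n_features >= n_samples:
                return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage)
            return LinearDiscriminantAnalysis()
        if kind == "NBC":
            return GaussianNB(var_smoothing=self.var_floor)
        if kind == "NSVM":
            return SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.shape[0] != 2 or counts.min() < 2:
            raise ValueError("need two classes with >= 2 training subjects each")
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2
            )
        if not keep.any():
            raise ValueError("all features are constant")
        self.keep_ = keep
        self.scaler_ = StandardScaler().fit(X[:, keep])
        self.model_ = self._make(*X.shape)
        self.model_.fit(self.scaler_.transform(X[:, keep]), y)
        self.classes_ = self.model_.classes_
        return self

    def _prep(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self.scaler_.transform(X[:, self.keep_])

    def predict(self, X):
        return self.model_.predict(self._prep(X))

    def confidence(self, X):
        """Per-sample confidence in the predicted label.

        Max posterior probability where available; |decision function|
        mapped through a logistic for the SVM. Used only for ensemble
        tie-breaking.
        """
        Xp = self._prep(X)
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(Xp).max(axis=1)
        df = np.abs(self.model_.decision_function(Xp))
        return 1.0 / (1.0 + np.exp(-df))


def fit_predict(spec: FNCClassifier | str, X_train, y_train, X_test) -> np.ndarray:
    """Fit a classifier spec on the training fold and predict the test fold."""
    clf = FNCClassifier(kind=spec) if isinstance(spec, str) else spec
    return clf.fit(X_train, y_train).predict(X_test)


def loocv_folds(
    subject_ids, labels=None
) -> list[tuple[list[str], str]]:
    """Deterministic leave-one-out folds in sorted subject-id order."""
    ids = sorted(subject_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    if labels is not None:
        labels = np.asarray(labels)
        if np.unique(labels).shape[0] < 2:
            raise ValueError("single-class cohort: LOOCV undefined")
    return [([s for s in ids if s != test], test) for test in ids]


class PipelineResult:
    """LOOCV results for one or more feature sources."""

    def __init__(self):
        self.folds: dict[str, list[FoldResult]] = {}
        self.confidences: dict[str, dict[str, dict[str, float]]] = {}

    def accuracy(self, source: str, classifier: str) -> float:
        rs = self.folds[source]
        return float(np.mean([r.predicted[classifier] == r.true_label for r in rs]))

    def table(self, classifiers=CLASSIFIER_NAMES) -> pd.DataFrame:
        return accuracy_table(self, classifiers)


def accuracy_table(result: PipelineResult, classifiers=CLASSIFIER_NAMES) -> pd.DataFrame:
    """Accuracy (%) per classifier and source, plus Average/(std) rows."""
    cols = {}
    for source in result.folds:
        accs = [100.0 * result.accuracy(source, c) for c in classifiers]
        spread = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        cols[source] = accs + [float(np.mean(accs)), spread]
    return pd.DataFrame(cols, index=list(classifiers) + ["Average", "(std)"])


def _source_name(keys: list[tuple[Modality, Band]]) -> str:
    parts = []
    for mod, band in keys:
        parts.append("fmri" if mod == Modality.FMRI else f"meg-{band.value}")
    return "+".join(parts)


def run_pipeline_loocv(
    dataset: StudyDataset,
    mode: str,
    sources: list[list[tuple[Modality, Band]]] | None = None,
    classifiers=CLASSIFIER_NAMES,
    seed: int = 0,
    q: float = 0.05,
    max_lag: int = 0,
    window: WindowSpec | None = None,
    k: int = 5,
    lam: float | str = "cv",
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> PipelineResult:
    """LOOCV classification over modality/band sources.

    ``mode`` is "static" (per-pair Fisher-z features, Welch-t + BH-FDR
    selection per fold per key, selected features concatenated across a
    source's keys) or "dynamic" (per-subject window stacks computed once;
    per fold, k states per group fit on training subjects per key and each
    subject reduced to 2k centroid-regression betas, concatenated across
    keys). Per-subject connectivity never depends on other subjects, so
    stacks and pair vectors are precomputed; everything fold-dependent is
    re-fit per fold.
    """
    if mode not in ("static", "dynamic"):
        raise ValueError("mode must be 'static' or 'dynamic'")
    sources = sources or [[key] for key in dataset.keys]
    all_keys = sorted({key for src in sources for key in src}, key=str)
    ids = dataset.subject_ids
    labels = {s: dataset.groups[s].value for s in ids}

    features: dict = {}
    for key in all_keys:
        if mode == "static":
            features[key] = {
                s: static_fnc(dataset.subjects[s][key], max_lag=max_lag).pairs for s in ids
            }
        else:
            features[key] = {
                s: compute_dfnc(
                    dataset.subjects[s][key],
                    spec=window,
                    lam=lam,
                    lambda_grid=lambda_grid,
                ).pair_vectors
                for s in ids
            }

    result = PipelineResult()
    folds = loocv_folds(ids, [labels[s] for s in ids])
    for src in sources:
        name = _source_name(src)
        fold_results: list[FoldResult] = []
        conf: dict[str, dict[str, float]] = {c: {} for c in classifiers}
        for fold_i, (train_ids, test_id) in enumerate(folds):
            y_train = np.array([labels[s] for s in train_ids])
            train_blocks, test_blocks, info = [], [], {}
            for key in src:
                if mode == "static":
                    Z = np.vstack([features[key][s] for s in train_ids])
                    sel = StaticFNCSelector(q=q).fit(Z, y_train)
                    train_blocks.append(sel.transform(Z))
                    test_blocks.append(sel.transform(features[key][test_id][None, :]))
                    info[_source_name([key])] = {
                        "selected_pairs": sel.selected_.tolist()
                    }
                else:
                    tr, te, feat = dfnc_features(
                        [features[key][s] for s in train_ids],
                        y_train,
                        [features[key][test_id]],
                        k=k,
                        seed=seed + 1000 * fold_i,
                    )
                    train_blocks.append(tr)
                    test_blocks.append(te)
                    info[_source_name([key])] = {"k": k}
            X_train = np.hstack(train_blocks)
            X_test = np.hstack(test_blocks)
            predicted = {}
            for cname in classifiers:
                clf = FNCClassifier(kind=cname).fit(X_train, y_train)
                predicted[cname] = str(clf.predict(X_test)[0])
                conf[cname][test_id] = float(clf.confidence(X_test)[0])
            fold_results.append(
                FoldResult(
                    subject_id=test_id,
                    true_label=labels[test_id],
                    predicted=predicted,
                    feature_info={"mode": mode, **info},
                )
            )
        result.folds[name] = fold_results
        result.confidences[name] = conf
    return result
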