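"""Dynamic functional network connectivity: tapered sliding windows,
graphical-LASSO regularized covariance per window, per-subject penalty
cross-validation, per-group k-means connectivity states, elbow model
selection and centroid-regression beta features.

Per window the pipeline is: weighted covariance of the tapered window ->
L1-penalized precision (graphical LASSO, off-diagonal penalty) -> covariance
from the regularized inverse -> correlation -> Fisher z. Windowed matrices
live in pair space (upper triangle); a subject's stack is N windows x pairs,
with N = floor((T - w)/step) + 1 (119 for T=149, 270 for T=300 at w=31,
step 1).

The state stage is fit/transform shaped and exposed as a scikit-learn
transformer (:class:`DynamicStateFeaturizer`): fit learns k centroids per
group from training subjects' windows; transform regresses each subject's
windows on the 2k centroids and averages the betas into a 2k-vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as _sig_windows
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .dataio import ComponentTimecourseSet
from .static_fnc import despike, fisher_z

__all__ = [
    "WindowSpec",
    "DynamicFNCStack",
    "StateSet",
    "make_taper",
    "sliding_windows",
    "weighted_covariance",
    "graphical_lasso",
    "select_lambda",
    "compute_dfnc",
    "cluster_states",
    "validity_elbow",
    "centroid_regression",
    "DynamicStateFeaturizer",
    "dfnc_features",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(np.log10(0.01), 0.0, 10).tolist())


@dataclass(frozen=True)
class WindowSpec:
    """Tapered sliding-window specification.

    ``weights`` is a length-``width`` non-negative taper, symmetric with its
    maximum at the center, normalized to sum to ``width``.
    """

    width: int = 31
    step: int = 1
    sigma: float = 3.0
    weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            object.__setattr__(self, "weights", _taper_weights(self.width, self.sigma))


@dataclass
class DynamicFNCStack:
    """One subject's windowed connectivity stack.

    ``z`` is N x C x C (Fisher-z correlation from the regularized inverse
    covariance, zero diagonal); ``starts`` the window start indices;
    ``lam`` the subject's graphical-LASSO penalty.
    """

    z: np.ndarray
    starts: np.ndarray
    lam: float
    subject_id: str = ""
    modality: str = ""
    band: str = ""

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def pair_vectors(self) -> np.ndarray:
        """N x C(C-1)/2 matrix of window vectors in pair space."""
        iu = np.triu_indices(self.z.shape[1], k=1)
        return self.z[:, iu[0], iu[1]]


@dataclass
class StateSet:
    """Per-group connectivity states ("centrotypes") in pair space."""

    group: str
    k: int
    centroids: np.ndarray  # k x n_pairs
    occupancy: np.ndarray  # window counts per state
    labels: np.ndarray  # state assignment of each clustered window
    inertia: float = float("nan")


def _taper_weights(w: int, sigma: float) -> np.ndarray:
    if w < 3:
        raise ValueError("window width must be >= 3")
    if sigma < 0:
        raise ValueError("taper sigma must be non-negative")
    if sigma == 0:
        return np.ones(w)
    half = int(np.ceil(3 * sigma))
    kern = _sig_windows.gaussian(2 * half + 1, std=sigma)
    kern = kern / kern.sum()
    rect = np.ones(w)
    weights = np.convolve(rect, kern, mode="same")  # center crop of full conv
    weights = weights * (w / weights.sum())
    if weights.max() - weights.min() < 1e-9 * weights.max():
        warnings.warn("taper is numerically flat for this sigma", stacklevel=3)
    return weights


def make_taper(width: int = 31, sigma: float = 3.0, step: int = 1) -> WindowSpec:
    """Rectangular window convolved with a truncated (+-3 sigma) Gaussian."""
    return WindowSpec(width=width, step=step, sigma=sigma)


def sliding_windows(T: int, spec: WindowSpec) -> list[tuple[int, np.ndarray]]:
    """Full windows only: starts 0, step, ...; count = floor((T-w)/step)+1."""
    if T < spec.width:
        raise ValueError(f"T={T} is shorter than the window width {spec.width}")
    return [(s, spec.weights) for s in range(0, T - spec.width + 1, spec.step)]


def weighted_covariance(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted covariance (weight-sum normalization) of a w x C window."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    if x.shape[0] != weights.shape[0]:
        raise ValueError("window and weights lengths differ")
    if np.any(x.std(axis=0) == 0):
        bad = int(np.argmin(x.std(axis=0)))
        raise ValueError(f"zero-variance column {bad} in window")
    wn = weights / weights.sum()
    mu = wn @ x
    xc = x - mu
    cov = (xc * wn[:, None]).T @ xc
    return (cov + cov.T) / 2.0


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    max_iter: int = 100,
    tol: float = 1e-4,
    enet_tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse precision estimate: maximize log det(T) - tr(S T) - lam*||T||_1,off.

    Returns ``(precision, covariance)`` where covariance is the inverse of
    the regularized precision. ``lam = 0`` is the unpenalized limit
    (direct inverse of the, if needed, ridge-stabilized covariance).
    """
    S = np.asarray(S, dtype=float)
    S = (S + S.T) / 2.0
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    w = np.linalg.eigvalsh(S)
    if w.min() < 1e-8:
        S = S + (1e-8 - min(w.min(), 0.0)) * np.eye(S.shape[0])
    if lam == 0:
        prec = np.linalg.inv(S)
        return (prec + prec.T) / 2.0, S.copy()
    last_exc: Exception | None = None
    for ridge in (0.0, 1e-6, 1e-4, 1e-3):
        try:
            with warnings.catch_warnings():
                # residual dual gaps ~tol are expected and harmless here
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                cov, prec = _sk_glasso(
                    S + ridge * np.eye(S.shape[0]),
                    alpha=float(lam),
                    max_iter=max_iter,
                    tol=tol,
                    enet_tol=enet_tol,
                )
            return (prec + prec.T) / 2.0, (cov + cov.T) / 2.0
        except FloatingPointError as exc:  # ill-conditioned window: stabilize
            last_exc = exc
    raise RuntimeError(
        f"graphical lasso failed to converge (lambda={lam}, dim={S.shape[0]}): {last_exc}"
    ) from last_exc


def _gauss_loglik(prec: np.ndarray, S: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S @ prec))


def select_lambda(
    window_covs: list[np.ndarray] | np.ndarray,
    grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 3,
) -> float:
    """Per-subject penalty by contiguous-fold cross-validation.

    Windows are split into ``n_folds`` contiguous blocks (contiguity limits
    temporal leakage between overlapping windows). For each candidate, the
    graphical LASSO is fit on the mean training-fold covariance and scored
    by the Gaussian log-likelihood of the mean held-out covariance; the
    penalty maximizing the mean held-out log-likelihood wins, ties going to
    the larger (sparser) penalty.
    """
    covs = np.asarray(window_covs, dtype=float)
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0:
        raise ValueError("empty penalty grid")
    if len(grid) == 1:
        return grid[0]
    n = covs.shape[0]
    if n < n_folds:
        n_folds = max(2, n)
    folds = np.array_split(np.arange(n), n_folds)
    scores = np.zeros(len(grid))
    ok = np.zeros(len(grid), dtype=bool)
    for gi, lam in enumerate(grid):
        lls = []
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            if train.size == 0 or fold.size == 0:
                continue
            S_train = covs[train].mean(axis=0)
            S_test = covs[fold].mean(axis=0)
            try:
                prec, _ = graphical_lasso(S_train, lam)
            except RuntimeError:
                lls = []
                break
            lls.append(_gauss_loglik(prec, S_test))
        if lls:
            scores[gi] = np.mean(lls)
            ok[gi] = True
    if not ok.any():
        raise RuntimeError("graphical lasso failed for every penalty in the grid")
    best = scores[ok].max()
    # ties -> larger penalty
    candidates = [g for g, s, o in zip(grid, scores, ok) if o and s >= best - 1e-12]
    return max(candidates)


def compute_dfnc(
    tc_set: ComponentTimecourseSet,
    spec: WindowSpec | None = None,
    lam: float | str = "cv",
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_folds: int = 3,
    apply_despike: bool = True,
) -> DynamicFNCStack:
    """Windowed regularized connectivity stack for one subject.

    ``lam`` is either a fixed penalty or ``"cv"`` to optimize it for this
    subject by :func:`select_lambda`.
    """
    spec = spec or WindowSpec()
    data = tc_set.data
    T, C = data.shape
    if apply_despike and T >= 5:
        data = np.column_stack([despike(data[:, j]) for j in range(C)])
    wins = sliding_windows(T, spec)
    covs = []
    for s, w in wins:
        S = weighted_covariance(data[s : s + spec.width], w)
        # solve on the correlation scale: the penalty then acts uniformly
        # across pairs and the coordinate solver stays well conditioned
        d = np.sqrt(np.diag(S))
        covs.append(S / np.outer(d, d))
    if lam == "cv":
        lam_val = select_lambda(covs, grid=lambda_grid, n_folds=n_folds)
    else:
        lam_val = float(lam)
    zs = np.empty((len(wins), C, C))
    for i, S in enumerate(covs):
        _, cov = graphical_lasso(S, lam_val)
        d = np.sqrt(np.diag(cov))
        corr = np.clip(cov / np.outer(d, d), -1.0, 1.0)
        z = fisher_z(corr)
        np.fill_diagonal(z, 0.0)
        zs[i] = (z + z.T) / 2.0
    return DynamicFNCStack(
        z=zs,
        starts=np.array([s for s, _ in wins]),
        lam=lam_val,
        subject_id=tc_set.subject_id,
        modality=tc_set.modality.value,
        band=tc_set.band.value,
    )


def _metric_transform(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return x
    if metric == "cosine":
        n = np.linalg.norm(x, axis=1, keepdims=True)
        return x / np.where(n == 0, 1.0, n)
    if metric == "correlation":
        xc = x - x.mean(axis=1, keepdims=True)
        n = np.linalg.norm(xc, axis=1, keepdims=True)
        return xc / np.where(n == 0, 1.0, n)
    raise ValueError(f"unknown metric {metric!r}")


def cluster_states(
    windows: np.ndarray,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
    group: str = "",
    n_init: int = 10,
) -> StateSet:
    """k-means connectivity states from windows in pair space.

    k-means++ initialization, ``n_init`` restarts, best inertia kept.
    ``cosine``/``correlation`` metrics are realized by row-normalizing
    (after centering, for correlation) before Euclidean k-means.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2:
        raise ValueError("windows must be n_windows x n_pairs")
    if windows.shape[0] < k:
        raise ValueError(f"need at least k={k} windows, got {windows.shape[0]}")
    X = _metric_transform(windows, metric)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    # report centroids as means of the raw (untransformed) member windows
    centroids = np.vstack([windows[labels == j].mean(axis=0) for j in range(k)])
    occupancy = np.bincount(labels, minlength=k)
    return StateSet(
        group=group,
        k=k,
        centroids=centroids,
        occupancy=occupancy,
        labels=labels,
        inertia=float(km.inertia_),
    )


def validity_elbow(
    windows: np.ndarray, k_range: tuple[int, ...], seed: int = 0, metric: str = "euclidean"
) -> tuple[int, dict[int, float]]:
    """Elbow selection of k from the within/between cluster validity index.

    index(k) = mean within-cluster distance / mean between-centroid
    distance; k* is the point of maximum curvature (largest discrete second
    difference of the index over the sorted k grid). Returns ``(k*, index)``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    index: dict[int, float] = {}
    for k in ks:
        st = cluster_states(windows, k, seed=seed, metric=metric)
        within = np.mean(
            np.linalg.norm(windows - st.centroids[st.labels], axis=1)
        )
        if k == 1:
            index[k] = float(within)
            continue
        iu = np.triu_indices(k, 1)
        between = np.mean(
            np.linalg.norm(st.centroids[iu[0]] - st.centroids[iu[1]], axis=1)
        )
        index[k] = float(within / between)
    if len(ks) == 1:
        return ks[0], index
    if len(ks) == 2:
        warnings.warn("k range too short for curvature; returning the smallest k", stacklevel=2)
        return ks[0], index
    vals = np.array([index[k] for k in ks])
    curv = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    if curv.max() <= 0:
        warnings.warn("validity index shows no elbow; returning the smallest k", stacklevel=2)
        return ks[0], index
    return ks[1 + int(np.argmax(curv))], index


def centroid_regression(
    window_vectors: np.ndarray | DynamicFNCStack, centroids: np.ndarray
) -> np.ndarray:
    """Mean per-window OLS betas of window vectors on the 2k state centroids.

    Both the window vector and the centroid columns are mean-centered in
    pair space; no intercept. A rank-deficient centroid design falls back
    to a 1e-6 ridge with a warning.
    """
    if isinstance(window_vectors, DynamicFNCStack):
        window_vectors = window_vectors.pair_vectors
    Y = np.asarray(window_vectors, dtype=float)
    Cmat = np.asarray(centroids, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != Cmat.shape[1]:
        raise ValueError("windows and centroids disagree on pair dimension")
    X = (Cmat - Cmat.mean(axis=1, keepdims=True)).T  # n_pairs x 2k
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient centroid design; using 1e-6 ridge", stacklevel=2)
        G = X.T @ X + 1e-6 * np.eye(X.shape[1])
        betas = np.linalg.solve(G, X.T @ Yc.T)
    else:
        betas, *_ = np.linalg.lstsq(X, Yc.T, rcond=None)
    return betas.mean(axis=1)


class DynamicStateFeaturizer(BaseEstimator, TransformerMixin):
    """Per-group k-means states + centroid-regression betas (2k features).

    fit(X, y): X is a length-n list/array of per-subject window matrices
    (n_windows x n_pairs); k centroids are fit per group label on the
    pooled training windows. transform(X) regresses every subject's
    windows on the 2k stacked centroids (group blocks in sorted label
    order) and averages the betas.

    Attributes
    ----------
    classes_ : sorted group labels
    state_sets_ : dict label -> StateSet
    centroids_ : (2k) x n_pairs stacked centroid matrix
    """

    def __init__(self, k: int = 5, seed: int = 0, metric: str = "euclidean"):
        self.k = k
        self.seed = seed
        self.metric = metric

    def fit(self, X, y):
        y = np.asarray(y)
        stacks = [np.asarray(s, dtype=float) for s in X]
        if len(stacks) != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] != 2:
            raise ValueError("need exactly two groups")
        self.state_sets_ = {}
        blocks = []
        for gi, g in enumerate(self.classes_):
            wins = np.vstack([s for s, lbl in zip(stacks, y) if lbl == g])
            st = cluster_states(
                wins, self.k, seed=self.seed + gi, metric=self.metric, group=str(g)
            )
            self.state_sets_[str(g)] = st
            blocks.append(st.centroids)
        self.centroids_ = np.vstack(blocks)
        return self

    def transform(self, X):
        check_is_fitted(self, "centroids_")
        return np.vstack(
            [centroid_regression(np.asarray(s, dtype=float), self.centroids_) for s in X]
        )


def dfnc_features(
    train_stacks: list[np.ndarray],
    train_labels: np.ndarray,
    test_stacks: list[np.ndarray],
    k: int = 5,
    seed: int = 0,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray, DynamicStateFeaturizer]:
    """Fold-hygienic dynamic features: states fit on training subjects only."""
    feat = DynamicStateFeaturizer(k=k, seed=seed, metric=metric).fit(
        train_stacks, train_labels
    )
    return feat.transform(train_stacks), feat.transform(test_stacks), feat
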