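"""Group spatial ICA: PCA reductions, repeated infomax with stability
selection, dual-regression back-reconstruction and spectral component
screening.

The stage follows the standard two-level reduction: per-subject temporal
PCA (economy decomposition), concatenation, group-level EM-PCA, whitening,
then infomax ICA repeated from random starts; run-wise components are
clustered by absolute spatial correlation and a per-cluster quality index
(intra- minus extra-cluster similarity) scores stability. Subject
timecourses are recovered from group maps by least-squares (dual)
regression. This stage is optional in the pipeline — the connectivity
stages accept externally supplied component timecourses directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import welch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PCAModel",
    "ICADecomposition",
    "StabilityReport",
    "ComponentSpectralMetrics",
    "reduce_subject_pca",
    "reduce_group_empca",
    "whiten",
    "run_infomax",
    "icasso_stability",
    "back_reconstruct",
    "component_spectral_metrics",
    "select_components",
    "amari_index",
    "GroupICA",
]


@dataclass
class PCAModel:
    """Retained principal subspace: orthonormal basis, variances, mean."""

    basis: np.ndarray  # original-dim x R, orthonormal columns
    variances: np.ndarray  # length R, non-increasing
    mean: np.ndarray
    R: int


@dataclass
class ICADecomposition:
    unmixing: np.ndarray  # C_ic x R (applied to whitened data)
    maps: np.ndarray  # C_ic x features (source maps)
    seed: int = 0
    n_iter: int = 0
    lr_trace: list = field(default_factory=list)


@dataclass
class StabilityReport:
    quality: np.ndarray  # per-cluster index in [-1, 1]
    assignments: np.ndarray  # cluster id of each run-wise component
    chosen_run: int = 0


@dataclass
class ComponentSpectralMetrics:
    dynamic_range: float
    lf_hf_ratio: float


def reduce_subject_pca(tc: np.ndarray, R: int) -> tuple[PCAModel, np.ndarray]:
    """Economy-size temporal PCA of a T x V data matrix.

    Rows (timepoints) are mean-centered over features; the top-R temporal
    eigenvectors of the T x T covariance are retained. Returns the model
    and the reduced R x V data (basis' @ centered data).
    """
    tc = np.asarray(tc, dtype=float)
    T, V = tc.shape
    if R > min(T, V):
        raise ValueError(f"R={R} exceeds min(T, V)={min(T, V)}")
    mean = tc.mean(axis=1)
    xc = tc - mean[:, None]
    # economy route: eigendecompose the smaller Gram matrix
    U, s, _ = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (V - 1)
    model = PCAModel(basis=U[:, :R], variances=variances[:R], mean=mean, R=R)
    return model, model.basis.T @ xc


def reduce_group_empca(
    stacked: np.ndarray,
    R: int,
    tol: float = 1e-12,
    max_iter: int = 5000,
    seed: int = 0,
) -> tuple[PCAModel, np.ndarray]:
    """EM algorithm for PCA on a D x V stack (memory-light group reduction).

    Iterates the two EM linear solves; the explained variance of the
    current subspace is monotonically non-decreasing, and iteration stops
    when the subspace itself stops moving (projector change below ``tol``).
    The converged subspace is orthonormalized and rotated to principal
    axes. Warns and returns the best iterate on non-convergence.
    """
    Y = np.asarray(stacked, dtype=float)
    D, V = Y.shape
    if R > min(D, V):
        raise ValueError(f"R={R} exceeds data dimensions {Y.shape}")
    mean = Y.mean(axis=1)
    Yc = Y - mean[:, None]
    rng = np.random.default_rng(seed)
    C = rng.normal(size=(D, R))
    Q_prev = None
    converged = False
    for _ in range(max_iter):
        X = np.linalg.solve(C.T @ C, C.T @ Yc)
        C = (Yc @ X.T) @ np.linalg.inv(X @ X.T)
        Q, _ = np.linalg.qr(C)
        if Q_prev is not None:
            # Frobenius distance between successive subspace projectors
            s = np.linalg.svd(Q_prev.T @ Q, compute_uv=False)
            if 2.0 * (R - float((s**2).sum())) < tol:
                converged = True
                break
        Q_prev = Q
    if not converged:
        warnings.warn("EM-PCA did not converge; returning the best iterate", stacklevel=2)
    Q, _ = np.linalg.qr(C)
    M = Q.T @ Yc
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    basis = Q @ U
    variances = s**2 / (V - 1)
    model = PCAModel(basis=basis, variances=variances, mean=mean, R=R)
    return model, basis.T @ Yc


def whiten(reduced: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten rows of an R x N matrix: output covariance = identity.

    Returns (whitened data, whitening matrix W such that white = W @ centered).
    """
    X = np.asarray(reduced, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / Xc.shape[1]
    w, E = np.linalg.eigh(cov)
    if w.min() <= 0:
        raise ValueError("reduced data is rank deficient; cannot whiten")
    Wm = (E / np.sqrt(w)) @ E.T
    return Wm @ Xc, Wm


def run_infomax(
    white: np.ndarray,
    C_ic: int | None = None,
    seed: int = 0,
    lr: float = 0.01,
    anneal: float = 0.9,
    tol: float = 1e-7,
    max_passes: int = 512,
    block: int = 128,
    max_anneals: int = 200,
) -> ICADecomposition:
    """Natural-gradient infomax ICA with a logistic nonlinearity.

    Operates on whitened rows (sources as rows, samples as columns). The
    learning rate is annealed (x ``anneal``) whenever a pass blows up
    (non-finite or exploding weights) and the pass is retried from its
    starting weights; iteration stops when the per-pass relative weight
    change drops below ``tol``.
    """
    X = np.asarray(white, dtype=float)
    n, N = X.shape
    C_ic = n if C_ic is None else int(C_ic)
    if C_ic > n:
        raise ValueError(f"C_ic={C_ic} exceeds whitened dimension {n}")
    Xs = X[:C_ic]
    rng = np.random.default_rng(seed)
    W = np.eye(C_ic)
    lr_trace: list[float] = []
    n_anneals = 0
    eye = np.eye(C_ic)
    n_pass = 0
    while n_pass < max_passes:
        W_start = W.copy()
        perm = rng.permutation(N)
        blew_up = False
        for lo in range(0, N, block):
            idx = perm[lo : lo + block]
            u = W @ Xs[:, idx]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (eye + (1.0 - 2.0 * y) @ u.T / idx.size) @ W
            W = W + lr * grad
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                blew_up = True
                break
        if blew_up:
            n_anneals += 1
            if n_anneals > max_anneals or lr < 1e-12:
                raise RuntimeError("infomax diverged despite learning-rate annealing")
            lr *= anneal
            W = W_start
            continue
        lr_trace.append(lr)
        n_pass += 1
        delta = np.linalg.norm(W - W_start) / max(np.linalg.norm(W_start), 1e-30)
        if delta < tol:
            break
        # gentle decay keeps late passes stable and guarantees termination
        lr *= 0.995
    maps = W @ Xs
    return ICADecomposition(
        unmixing=np.hstack([W, np.zeros((C_ic, n - C_ic))]) if n > C_ic else W,
        maps=maps,
        seed=seed,
        n_iter=n_pass,
        lr_trace=lr_trace,
    )


def icasso_stability(
    white: np.ndarray,
    C_ic: int | None = None,
    n_runs: int = 20,
    seed: int = 0,
    **infomax_kwargs,
) -> tuple[StabilityReport, ICADecomposition]:
    """Repeated infomax with agglomerative stability clustering.

    Components from all runs are clustered by absolute Pearson correlation
    of their maps (average linkage, cut at C_ic clusters). Cluster quality
    = mean intra-cluster similarity minus mean extra-cluster similarity;
    the returned decomposition is the run whose components best match the
    cluster centrotypes.
    """
    if n_runs < 2:
        raise ValueError("ICASSO needs at least 2 runs")
    X = np.asarray(white, dtype=float)
    C_ic = X.shape[0] if C_ic is None else int(C_ic)
    runs = [run_infomax(X, C_ic, seed=seed + i, **infomax_kwargs) for i in range(n_runs)]
    comps = np.vstack([r.maps for r in runs])  # (n_runs*C_ic) x V
    sim = np.abs(np.corrcoef(comps))
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    Z = linkage(dist, method="average")
    assign = fcluster(Z, t=C_ic, criterion="maxclust") - 1
    if np.unique(assign).shape[0] != C_ic:
        raise RuntimeError(
            f"degenerate ICASSO clustering: {np.unique(assign).shape[0]} clusters "
            f"for {C_ic} requested (n_runs={n_runs})"
        )
    quality = np.empty(C_ic)
    centrotype = np.empty(C_ic, dtype=int)
    for c in range(C_ic):
        members = np.flatnonzero(assign == c)
        others = np.flatnonzero(assign != c)
        intra_mat = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = (intra_mat.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, others)].mean() if others.size else 0.0
        quality[c] = intra - extra
        centrotype[c] = members[int(np.argmax(intra_mat.mean(axis=1)))]
    # run whose components are most similar to the cluster centrotypes
    run_scores = np.zeros(n_runs)
    for ri in range(n_runs):
        rows = np.arange(ri * C_ic, (ri + 1) * C_ic)
        run_scores[ri] = sim[np.ix_(rows, centrotype)].max(axis=1).mean()
    chosen = int(np.argmax(run_scores))
    report = StabilityReport(quality=quality, assignments=assign, chosen_run=chosen)
    return report, runs[chosen]


def back_reconstruct(group_maps: np.ndarray, subject_data: np.ndarray) -> np.ndarray:
    """Dual-regression timecourses: least-squares fit of data on group maps.

    Solves data ~ TC @ maps for TC; returns the T x C_ic subject
    timecourses.
    """
    maps = np.asarray(group_maps, dtype=float)
    X = np.asarray(subject_data, dtype=float)
    if maps.shape[1] != X.shape[1]:
        raise ValueError("maps and data disagree on the feature dimension")
    G = maps @ maps.T
    if np.linalg.cond(G) > 1e10:
        raise ValueError("rank-deficient group map matrix")
    return X @ maps.T @ np.linalg.inv(G)


def component_spectral_metrics(
    tc: np.ndarray, fs: float, nperseg: int | None = None
) -> ComponentSpectralMetrics:
    """Spectral screening metrics of one component timecourse.

    ``lf_hf_ratio``: integral of Welch power below 0.10 Hz over the
    integral between 0.15 and 0.25 Hz. ``dynamic_range``: peak power minus
    the minimum power at frequencies to the right of the peak.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.shape[0] < 32:
        raise ValueError("need at least 32 samples")
    if fs / 2.0 < 0.25:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve the 0.15-0.25 Hz band")
    nperseg = min(tc.shape[0], 128) if nperseg is None else nperseg
    f, p = welch(tc, fs=fs, nperseg=nperseg)
    lf = np.trapezoid(p[f < 0.10], f[f < 0.10])
    hf_mask = (f >= 0.15) & (f <= 0.25)
    hf = np.trapezoid(p[hf_mask], f[hf_mask])
    ratio = float(lf / hf) if hf > 0 else np.inf
    peak = int(np.argmax(p))
    dyn = float(p[peak] - p[peak:].min())
    return ComponentSpectralMetrics(dynamic_range=dyn, lf_hf_ratio=ratio)


def select_components(
    metrics: list[ComponentSpectralMetrics],
    lf_hf_threshold: float = 2.0,
    dynamic_range_threshold: float = 0.0,
) -> list[int]:
    """Rule-based retention: keep components passing both spectral thresholds."""
    return [
        i
        for i, m in enumerate(metrics)
        if m.lf_hf_ratio >= lf_hf_threshold and m.dynamic_range >= dynamic_range_threshold
    ]


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P = W_est @ A from a scaled permutation.

    0 for a perfect unmixing; commonly < 0.05 counts as recovered.
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * n * (n - 1)))


class GroupICA(BaseEstimator, TransformerMixin):
    """Two-level group spatial ICA with ICASSO stability selection.

    fit(X): X is a list of subject T x V matrices. transform(X) returns a
    subject's back-reconstructed T x C_ic timecourses.

    Parameters mirror the usual group-ICA settings: ``subject_pcs`` per-
    subject retained PCs, ``group_pcs`` group-level EM-PCA dimension,
    ``n_components`` independent components, ``n_runs`` ICASSO repeats.
    """

    def __init__(
        self,
        n_components: int = 20,
        subject_pcs: int = 30,
        group_pcs: int | None = None,
        n_runs: int = 10,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.subject_pcs = subject_pcs
        self.group_pcs = group_pcs
        self.n_runs = n_runs
        self.seed = seed

    def fit(self, X, y=None):
        subjects = [np.asarray(x, dtype=float) for x in X]
        reduced = [reduce_subject_pca(x, self.subject_pcs)[1] for x in subjects]
        stacked = np.vstack(reduced)
        group_pcs = self.group_pcs or self.n_components
        self.group_pca_, group_reduced = reduce_group_empca(
            stacked, group_pcs, seed=self.seed
        )
        white, self.whitening_ = whiten(group_reduced)
        self.stability_, decomposition = icasso_stability(
            white, self.n_components, n_runs=self.n_runs, seed=self.seed
        )
        self.decomposition_ = decomposition
        self.components_ = decomposition.maps
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return back_reconstruct(self.components_, X)
        return [back_reconstruct(self.components_, x) for x in X]
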