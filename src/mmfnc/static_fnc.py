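"""Static functional network connectivity and univariate feature selection.

Static FNC is one correlation matrix per subject computed over the full
timecourse length (optionally the maximum-lagged correlation), Fisher
z-transformed and vectorized into pair space. Feature selection is a
per-pair Welch two-sample t-test between groups with Benjamini-Hochberg
FDR control, fit on training subjects only; the selector is exposed as a
scikit-learn transformer so it slots into cross-validation pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .dataio import ComponentTimecourseSet, vectorize_upper

__all__ = [
    "despike",
    "static_fnc",
    "StaticFNC",
    "fisher_z",
    "pairwise_group_test",
    "PairTestResult",
    "bh_fdr",
    "StaticFNCSelector",
    "select_static_features",
]

_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class StaticFNC:
    """A subject's static connectivity: correlation, Fisher z, pair vector."""

    corr: np.ndarray
    z: np.ndarray
    pairs: np.ndarray  # Fisher-z upper triangle, row-major i < j
    subject_id: str = ""
    modality: str = ""
    band: str = ""


@dataclass(frozen=True)
class PairTestResult:
    """Per-pair group-difference test: t, p, BH q, selection flag."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    selected: np.ndarray


def despike(x: np.ndarray, c: float = 4.0, window: int = 5) -> np.ndarray:
    """Replace samples deviating > c MADs from a running median (window 5).

    The MAD is taken globally over the median residuals and scaled by the
    Gaussian consistency factor 1.4826, so ``c`` counts approximate sigmas;
    a constant series is returned unchanged. Matches the role despiking
    plays ahead of FNC: suppress isolated motion-like spikes without
    touching clean samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("despike expects a 1-D series")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 samples to despike")
    med = _running_median(x, window)
    resid = x - med
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        return x.copy()
    out = x.copy()
    spikes = np.abs(resid) > c * 1.4826 * mad
    out[spikes] = med[spikes]
    return out


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    from scipy.ndimage import median_filter

    return median_filter(x, size=window, mode="nearest")


def static_fnc(tc_set: ComponentTimecourseSet, max_lag: int = 0, apply_despike: bool = True) -> StaticFNC:
    """Full-length pairwise correlation (optionally max-lagged), Fisher z'd."""
    data = tc_set.data
    T, C = data.shape
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        raise ValueError(f"zero-variance component {tc_set.component_ids[bad]!r}")
    if apply_despike and T >= 5:
        data = np.column_stack([despike(data[:, j]) for j in range(C)])
    if max_lag == 0:
        corr = np.corrcoef(data.T)
    else:
        corr = _max_lag_corr(data, max_lag)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    z = fisher_z(corr)
    np.fill_diagonal(z, 0.0)
    return StaticFNC(
        corr=corr,
        z=z,
        pairs=vectorize_upper(z),
        subject_id=tc_set.subject_id,
        modality=tc_set.modality.value,
        band=tc_set.band.value,
    )


def _max_lag_corr(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Signed correlation of maximal absolute value over lags -L..L."""
    T, C = data.shape
    z = (data - data.mean(0)) / data.std(0)
    corr = np.eye(C)
    for i in range(C):
        for j in range(i + 1, C):
            best = 0.0
            for lag in range(-max_lag, max_lag + 1):
                if lag >= 0:
                    r = np.mean(z[lag:, i] * z[: T - lag, j]) * T / (T - lag)
                else:
                    r = np.mean(z[: T + lag, i] * z[-lag:, j]) * T / (T + lag)
                if abs(r) > abs(best):
                    best = r
            corr[i, j] = corr[j, i] = np.clip(best, -1.0, 1.0)
    return corr


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's z = arctanh(r), with |r| clipped at 1 - 1e-7."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r_arr, -_Z_CLIP, _Z_CLIP))
    return float(z) if np.isscalar(r) else z


def pairwise_group_test(z_features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t-test per pair (column). Returns (t, two-sided p)."""
    z_features = np.asarray(z_features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(f"need exactly two groups, got {classes.tolist()}")
    a = z_features[labels == classes[0]]
    b = z_features[labels == classes[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return np.asarray(t), np.asarray(p)


def bh_fdr(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (adjusted q-values, rejection flags)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


class StaticFNCSelector(BaseEstimator, TransformerMixin):
    """Select pair features with significant group differences (Welch t + BH-FDR).

    Parameters
    ----------
    q : float, default 0.05
        BH false-discovery-rate level.
    fallback_top1 : bool, default True
        If no pair survives FDR, fall back to the single smallest-p pair
        (with a warning) so downstream classifiers always receive >= 1
        feature.

    Attributes (after fit)
    ----------------------
    selected_ : int array of selected column indices
    tests_ : PairTestResult with per-pair t, p, q and flags
    """

    def __init__(self, q: float = 0.05, fallback_top1: bool = True):
        self.q = q
        self.fallback_top1 = fallback_top1

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be subjects x pairs")
        t, p = pairwise_group_test(X, y)
        q_adj, reject = bh_fdr(p, q=self.q) if self.q > 0 else (np.ones_like(p), np.zeros(p.shape, bool))
        if not reject.any():
            if not self.fallback_top1:
                raise ValueError("no pair passes FDR selection")
            warnings.warn(
                "no pair passed BH-FDR; falling back to the top-1 pair by p-value",
                stacklevel=2,
            )
            reject = np.zeros_like(reject)
            reject[int(np.argmin(p))] = True
        self.tests_ = PairTestResult(t=t, p=p, q=q_adj, selected=reject)
        self.selected_ = np.flatnonzero(reject)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_]


def select_static_features(
    z_features: np.ndarray, labels: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`StaticFNCSelector`.

    Returns (selected pair indices, subjects x selected feature matrix).
    """
    sel = StaticFNCSelector(q=q).fit(z_features, labels)
    return sel.selected_, sel.transform(z_features)
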