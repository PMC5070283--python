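"""Core data model, file formats and the pair-space vectorization convention.

Every connectivity feature in this package lives in "pair space": the
row-major upper triangle (i < j) of a symmetric C x C matrix, giving
C(C-1)/2 features (703 for C=38 fMRI components, 496 for C=32 MEG
components). A single repo-wide ordering prevents silent misalignment
between the static and dynamic pipelines.

Timecourses are exchanged as TSV tables (rows = samples, columns =
components, header row of component identifiers); results as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupLabel",
    "Modality",
    "Band",
    "ComponentTimecourseSet",
    "StudyDataset",
    "FoldResult",
    "pair_count",
    "pair_index",
    "vectorize_upper",
    "unvectorize_upper",
    "read_timecourses",
    "write_timecourses",
    "write_results",
    "read_results",
]


class GroupLabel(str, Enum):
    """Diagnostic group. Exactly two classes in any study."""

    HC = "HC"
    SZ = "SZ"


class Modality(str, Enum):
    FMRI = "fmri"
    MEG = "meg"


class Band(str, Enum):
    """MEG envelope frequency band; ``NONE`` is reserved for fMRI."""

    NONE = "none"
    DELTA = "delta"
    THETA = "theta"
    ALPHA = "alpha"
    BETA = "beta"
    GAMMA = "gamma"


MEG_BANDS = (Band.DELTA, Band.THETA, Band.ALPHA, Band.BETA, Band.GAMMA)

#: Effective sampling rates in Hz: fMRI TR = 2 s; MEG Hilbert envelopes are
#: down-sampled to 1 Hz.
DEFAULT_SAMPLING_RATE = {Modality.FMRI: 0.5, Modality.MEG: 1.0}


@dataclass(frozen=True)
class ComponentTimecourseSet:
    """One subject's component timecourses for one modality/band.

    ``data`` is T samples x C components; all values finite, T >= 2, C >= 2.
    """

    subject_id: str
    group: GroupLabel
    modality: Modality
    band: Band
    data: np.ndarray
    sampling_rate: float
    component_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError(f"timecourse data must be 2-D, got shape {data.shape}")
        T, C = data.shape
        if T < 2 or C < 2:
            raise ValueError(f"need T >= 2 and C >= 2, got T={T}, C={C}")
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]} "
                f"(subject {self.subject_id}, {self.modality.value}/{self.band.value})"
            )
        if (self.band == Band.NONE) != (self.modality == Modality.FMRI):
            raise ValueError("band must be 'none' iff modality is 'fmri'")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.component_ids:
            object.__setattr__(
                self, "component_ids", tuple(f"IC{i + 1:02d}" for i in range(C))
            )
        elif len(self.component_ids) != C:
            raise ValueError("component_ids length must equal number of components")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


@dataclass
class StudyDataset:
    """All subjects of a two-group study across modalities/bands.

    ``subjects`` maps subject id -> {(modality, band): ComponentTimecourseSet};
    coverage must be identical across subjects and every subject has exactly
    one group label.
    """

    subjects: dict[str, dict[tuple[Modality, Band], ComponentTimecourseSet]]
    groups: dict[str, GroupLabel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.subjects) != set(self.groups):
            raise ValueError("subjects and group labels must cover the same ids")
        keysets = {frozenset(v) for v in self.subjects.values()}
        if len(keysets) > 1:
            raise ValueError("modality/band coverage differs across subjects")
        for sid, sets in self.subjects.items():
            for key, tc in sets.items():
                if tc.group != self.groups[sid]:
                    raise ValueError(f"group label mismatch for subject {sid}")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    @property
    def keys(self) -> list[tuple[Modality, Band]]:
        any_subject = next(iter(self.subjects.values()))
        return sorted(any_subject, key=lambda mb: (mb[0].value, mb[1].value))

    def labels(self, subject_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.subject_ids if subject_ids is None else list(subject_ids)
        return np.array([self.groups[s].value for s in ids])

    def timecourses(
        self, modality: Modality, band: Band, subject_ids: Sequence[str] | None = None
    ) -> list[ComponentTimecourseSet]:
        ids = self.subject_ids if subject_ids is None else list(subject_ids)
        return [self.subjects[s][(modality, band)] for s in ids]


@dataclass
class FoldResult:
    """Held-out prediction record for one leave-one-out fold."""

    subject_id: str
    true_label: str
    predicted: dict[str, str]  # classifier name -> predicted label
    feature_info: dict = field(default_factory=dict)


def pair_count(C: int) -> int:
    """Number of unordered component pairs, C(C-1)/2."""
    if C < 2:
        raise ValueError("need at least two components")
    return C * (C - 1) // 2


def pair_index(C: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle ordering of pairs (i, j), i < j."""
    return [(i, j) for i in range(C) for j in range(i + 1, C)]


def vectorize_upper(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Vectorize a symmetric matrix into pair space (row-major, i < j)."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    asym = np.abs(m - m.T).max()
    if asym > tol:
        raise ValueError(f"matrix is asymmetric (max |m - m.T| = {asym:.3g})")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def unvectorize_upper(v: np.ndarray, diag: np.ndarray | float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` given the diagonal."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    # C solves C(C-1)/2 = n
    C = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
    if pair_count(C) != n:
        raise ValueError(f"vector length {n} is not a triangular number")
    m = np.zeros((C, C))
    iu = np.triu_indices(C, k=1)
    m[iu] = v
    m = m + m.T
    np.fill_diagonal(m, diag)
    return m


def read_timecourses(
    path: str | Path,
    subject_id: str,
    group: GroupLabel | str,
    modality: Modality | str,
    band: Band | str = Band.NONE,
    sampling_rate: float | None = None,
) -> ComponentTimecourseSet:
    """Read a TSV timecourse table (rows = samples, header = component ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed timecourse table {path}: {exc}") from exc
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric column(s) {non_numeric} in {path}")
    modality = Modality(modality)
    band = Band(band)
    if sampling_rate is None:
        sampling_rate = DEFAULT_SAMPLING_RATE[modality]
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        r, c = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(f"non-numeric/NaN cell at row {r}, column {df.columns[c]!r} in {path}")
    return ComponentTimecourseSet(
        subject_id=subject_id,
        group=GroupLabel(group),
        modality=modality,
        band=band,
        data=data,
        sampling_rate=float(sampling_rate),
        component_ids=tuple(str(c) for c in df.columns),
    )


def write_timecourses(tc: ComponentTimecourseSet, path: str | Path) -> Path:
    """Write a timecourse set as a TSV table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(tc.data, columns=list(tc.component_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def write_results(results: Sequence[FoldResult], path: str | Path, extra: dict | None = None) -> Path:
    """Serialize fold results to JSON (byte-stable: sorted keys, fixed floats)."""
    results = list(results)
    if not results:
        raise ValueError("nothing to write: empty result set")
    classifiers = sorted({name for r in results for name in r.predicted})
    summary = {}
    for name in classifiers:
        hits = [r.predicted[name] == r.true_label for r in results if name in r.predicted]
        summary[name] = round(float(np.mean(hits)), 10)
    doc = {
        "folds": [
            {
                "subject_id": r.subject_id,
                "true_label": r.true_label,
                "predicted": dict(sorted(r.predicted.items())),
                "feature_info": r.feature_info,
            }
            for r in sorted(results, key=lambda r: r.subject_id)
        ],
        "accuracy": summary,
    }
    if extra:
        doc["extra"] = extra
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_results(path: str | Path) -> dict:
    """Read a results JSON document back as a plain dict."""
    return json.loads(Path(path).read_text())
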