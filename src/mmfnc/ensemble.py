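"""Multimodal fusion: feature concatenation and majority-vote ensembling.

Two fusion routes mirror the study design: (1) concatenating selected
features from fMRI and one MEG band before classification, and (2) a
majority vote over the per-source predictions of one classifier — three
members for static (fMRI+delta, fMRI+alpha, fMRI+beta), five for dynamic
(fMRI paired with each band). Panels are odd-sized by construction, but a
general tie-break is defined: highest mean member confidence, then fixed
class order (HC first); ties are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import Band, MEG_BANDS
from .classify import PipelineResult

__all__ = ["VotePanel", "concat_features", "majority_vote", "build_study_panels", "panel_accuracy"]

#: Fixed class order used as the final tie-break.
CLASS_ORDER = ("HC", "SZ")


@dataclass
class VotePanel:
    """Per-subject predictions (and optional confidences) of >= 2 members."""

    members: list[str]
    predictions: dict[str, dict[str, str]]  # member -> subject -> label
    confidences: dict[str, dict[str, float]] = field(default_factory=dict)
    true_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a vote panel needs at least 2 members")
        subjects = None
        for m in self.members:
            if m not in self.predictions:
                raise ValueError(f"missing predictions for member {m!r}")
            s = set(self.predictions[m])
            if subjects is None:
                subjects = s
            elif s != subjects:
                missing = sorted(subjects.symmetric_difference(s))
                raise ValueError(f"member {m!r} subject mismatch: {missing}")
        self.subjects = sorted(subjects or [])


def concat_features(
    blocks: list[np.ndarray], sources: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Column-wise concatenation in declared source order with provenance.

    All blocks must hold the same subjects in the same row order. Returns
    the fused matrix and one provenance label per column.
    """
    if len(blocks) != len(sources):
        raise ValueError("blocks and source names differ in length")
    n_rows = {b.shape[0] for b in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"subject-count mismatch across sources: {sorted(n_rows)}")
    provenance = [
        f"{src}:{j}" for src, b in zip(sources, blocks) for j in range(b.shape[1])
    ]
    return np.hstack(blocks), provenance


def majority_vote(panel: VotePanel) -> tuple[dict[str, str], dict[str, bool]]:
    """Equal-weight majority vote; returns (final labels, tie flags)."""
    final: dict[str, str] = {}
    tied: dict[str, bool] = {}
    for subj in panel.subjects:
        votes = [panel.predictions[m][subj] for m in panel.members]
        labels, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        winners = [str(l) for l, c in zip(labels, counts) if c == top]
        if len(winners) == 1:
            final[subj] = winners[0]
            tied[subj] = False
            continue
        tied[subj] = True
        # mean member confidence per tied class, if available
        means = {}
        for lab in winners:
            cs = [
                panel.confidences[m][subj]
                for m in panel.members
                if panel.predictions[m][subj] == lab
                and m in panel.confidences
                and subj in panel.confidences.get(m, {})
            ]
            if cs:
                means[lab] = float(np.mean(cs))
        if means and len(set(means.values())) > 1:
            final[subj] = max(means, key=means.get)
        else:
            order = {c: i for i, c in enumerate(CLASS_ORDER)}
            final[subj] = min(winners, key=lambda l: order.get(l, len(order)))
    return final, tied


def panel_accuracy(panel: VotePanel) -> float:
    """Accuracy of the majority vote against the panel's true labels."""
    if not panel.true_labels:
        raise ValueError("panel carries no true labels")
    final, _ = majority_vote(panel)
    return float(np.mean([final[s] == panel.true_labels[s] for s in panel.subjects]))


STATIC_PANEL_BANDS = (Band.DELTA, Band.ALPHA, Band.BETA)


def build_study_panels(
    result: PipelineResult, classifier: str, mode: str
) -> dict[str, VotePanel]:
    """Assemble the study's ensembles from per-source LOOCV results.

    static: MEG-only panel over delta/alpha/beta and the fMRI+MEG panel of
    three concatenated sources; dynamic: the corresponding five-band
    panels. Raises naming any missing member.
    """
    if mode == "static":
        bands = STATIC_PANEL_BANDS
    elif mode == "dynamic":
        bands = MEG_BANDS
    else:
        raise ValueError("mode must be 'static' or 'dynamic'")
    panels = {}
    for panel_name, members in (
        ("meg", [f"meg-{b.value}" for b in bands]),
        ("fmri+meg", [f"fmri+meg-{b.value}" for b in bands]),
    ):
        missing = [m for m in members if m not in result.folds]
        if missing:
            raise ValueError(f"missing ensemble member result(s): {missing}")
        predictions = {
            m: {r.subject_id: r.predicted[classifier] for r in result.folds[m]}
            for m in members
        }
        confidences = {m: dict(result.confidences[m][classifier]) for m in members}
        truth = {r.subject_id: r.true_label for r in result.folds[members[0]]}
        panels[panel_name] = VotePanel(
            members=members,
            predictions=predictions,
            confidences=confidences,
            true_labels=truth,
        )
    return panels
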