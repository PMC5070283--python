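"""Two-group, multi-band synthetic cohorts with planted connectivity structure.

The generator emulates the study design the pipeline targets: a 91-subject
two-group cohort (46 SZ / 45 HC) with one fMRI session (T=149, C=38,
TR = 2 s) and five MEG envelope bands (T=300, C=32, 1 Hz), with

* planted *static* group differences: selected component pairs whose
  long-run correlation differs between groups by a signed ``delta_r``
  (present by default in fMRI, delta, alpha and beta; absent in theta and
  gamma, mirroring the band pattern the method is meant to detect), and
* planted *dynamic* structure: each subject's timecourse is piecewise
  stationary, switching between k per-group covariance "states" along a
  first-order Markov chain, which makes the windowed-covariance states the
  dynamic pipeline estimates literally true.

State correlation matrices are built around the group static correlation
matrix (SPD-repaired static + state-specific deviation), so planted static
effects survive in every state and the long-run correlation approaches the
group static model. A ``state_divergence`` knob interpolates between
identical state sets across groups (0, a pure null for dynamics) and fully
group-specific states (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import (
    Band,
    ComponentTimecourseSet,
    GroupLabel,
    MEG_BANDS,
    Modality,
    StudyDataset,
)

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "build_group_model",
    "simulate_subject",
    "simulate_study",
    "nearest_spd_correlation",
]

#: Default planted static effects: (target, (i, j), delta_r). Targets follow
#: the band pattern the method detects (effects in fmri/delta/alpha/beta,
#: none in theta/gamma). Pair indices are arbitrary; no anatomical claim.
DEFAULT_EFFECT_PAIRS: tuple[tuple[str, tuple[int, int], float], ...] = (
    ("fmri", (0, 1), 0.35),
    ("fmri", (0, 2), 0.30),
    ("fmri", (1, 2), 0.30),
    ("fmri", (3, 4), -0.30),
    ("fmri", (3, 5), 0.30),
    ("fmri", (6, 7), -0.25),
    ("delta", (0, 1), 0.30),
    ("delta", (0, 2), 0.30),
    ("delta", (2, 3), -0.25),
    ("alpha", (1, 2), 0.30),
    ("alpha", (4, 5), -0.25),
    ("beta", (0, 1), 0.30),
    ("beta", (1, 3), 0.30),
    ("beta", (2, 4), -0.25),
    ("beta", (5, 6), 0.25),
)


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (defaults = the study conditions)."""

    n_per_group: tuple[int, int] = (46, 45)  # (SZ, HC)
    c_fmri: int = 38
    c_meg: int = 32
    t_fmri: int = 149
    t_meg: int = 300
    bands: tuple[Band, ...] = MEG_BANDS
    include_fmri: bool = True
    effect_pairs: tuple[tuple[str, tuple[int, int], float], ...] = DEFAULT_EFFECT_PAIRS
    n_states_per_group: int = 5
    state_strength: float = 0.4  # scale of state deviations from the static model
    state_divergence: float = 0.5  # 0 = identical state sets across groups
    mix_dynamic: float = 0.5  # variance share of the switching component
    dwell: float = 0.9  # Markov stay probability
    smoothing: dict[str, float] = field(
        default_factory=lambda: {"fmri": 0.6, "meg": 0.3}
    )  # AR(1) low-pass coefficient per modality
    base_rank: int = 4  # rank of the shared low-rank correlation background
    base_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.bands = tuple(Band(b) for b in self.bands)
        self.effect_pairs = tuple(
            (str(t), (int(p[0]), int(p[1])), float(d)) for t, p, d in self.effect_pairs
        )
        if any(n < 0 for n in self.n_per_group) or sum(self.n_per_group) == 0:
            raise ValueError("n_per_group must be non-negative with at least one subject")
        if not (0.0 < self.dwell <= 1.0):
            raise ValueError("dwell probability must be in (0, 1]")
        if not (0.0 <= self.mix_dynamic <= 1.0):
            raise ValueError("mix_dynamic must be in [0, 1]")
        if not (0.0 <= self.state_divergence <= 1.0):
            raise ValueError("state_divergence must be in [0, 1]")
        if self.n_states_per_group < 1:
            raise ValueError("need at least one state per group")
        for mod, a in self.smoothing.items():
            if not (0.0 <= a < 1.0):
                raise ValueError(f"smoothing[{mod!r}] must be in [0, 1)")
        if not self.include_fmri and not self.bands:
            raise ValueError("at least one modality/band must be simulated")
        active = {b.value for b in self.bands} | ({"fmri"} if self.include_fmri else set())
        for t, (i, j), _ in self.effect_pairs:
            if t not in active:
                continue
            C = self.c_fmri if t == "fmri" else self.c_meg
            if not (0 <= i < j < C):
                raise ValueError(
                    f"effect pair ({i}, {j}) invalid for {t} with C={C} "
                    "(need 0 <= i < j < C)"
                )

    @property
    def keys(self) -> list[tuple[Modality, Band]]:
        keys: list[tuple[Modality, Band]] = []
        if self.include_fmri:
            keys.append((Modality.FMRI, Band.NONE))
        keys.extend((Modality.MEG, b) for b in self.bands)
        return keys

    def dims(self, key: tuple[Modality, Band]) -> tuple[int, int]:
        if key[0] == Modality.FMRI:
            return self.t_fmri, self.c_fmri
        return self.t_meg, self.c_meg

    def effects_for(self, key: tuple[Modality, Band]) -> list[tuple[tuple[int, int], float]]:
        target = "fmri" if key[0] == Modality.FMRI else key[1].value
        return [(pair, dr) for t, pair, dr in self.effect_pairs if t == target]


@dataclass
class PlantedTruth:
    """Ground truth exported alongside a simulated study."""

    effect_pairs: list  # (target, (i, j), delta_r)
    state_correlations: dict  # (group, key) -> list of C x C arrays
    static_correlations: dict  # (group, key) -> C x C array
    state_sequences: dict  # (subject_id, key) -> int array of length T

    def to_jsonable(self) -> dict:
        def keyname(k):
            return "|".join(str(p) for p in k)

        return {
            "effect_pairs": [[t, list(p), d] for t, p, d in self.effect_pairs],
            "state_correlations": {
                keyname(k): [m.tolist() for m in v] for k, v in self.state_correlations.items()
            },
            "static_correlations": {
                keyname(k): v.tolist() for k, v in self.static_correlations.items()
            },
            "state_sequences": {
                keyname(k): np.asarray(v).tolist() for k, v in self.state_sequences.items()
            },
        }


def nearest_spd_correlation(m: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to an SPD correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result re-normalized to
    unit diagonal.
    """
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eig_floor, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def _random_correlation(C: int, rank: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Low-rank-plus-diagonal random correlation matrix with modest off-diagonals."""
    B = rng.normal(size=(C, rank)) * scale / np.sqrt(rank)
    cov = B @ B.T + np.eye(C)
    return nearest_spd_correlation(cov)


def _plant_effects(
    corr: np.ndarray, effects: list[tuple[tuple[int, int], float]], tol: float = 0.05
) -> np.ndarray:
    """Perturb selected pairs by delta_r, then repair to the nearest SPD correlation."""
    if not effects:
        return corr.copy()
    target = corr.copy()
    for (i, j), dr in effects:
        r_new = corr[i, j] + dr
        if abs(r_new) >= 0.999:
            raise ValueError(
                f"planted correlation {r_new:.3f} at pair ({i}, {j}) leaves (-1, 1); "
                "use a smaller delta_r"
            )
        target[i, j] = target[j, i] = r_new
    repaired = nearest_spd_correlation(target)
    worst = max(abs(repaired[i, j] - target[i, j]) for (i, j), _ in effects)
    if worst > tol:
        raise ValueError(
            f"SPD repair moved a planted pair by {worst:.3f} (> {tol}); "
            "use a smaller delta_r"
        )
    return repaired


def build_group_model(config: SimulationConfig) -> dict:
    """Build per-group static and state correlation matrices for every key.

    Returns ``{group: {"static": {key: C x C}, "states": {key: [C x C, ...]}}}``
    where group B (SZ) differs from group A (HC) only by the planted
    ``effect_pairs`` (up to SPD-projection leakage) and, if
    ``state_divergence > 0``, by group-specific state deviations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10C]))
    model: dict = {g: {"static": {}, "states": {}} for g in (GroupLabel.HC, GroupLabel.SZ)}
    for key in config.keys:
        T, C = config.dims(key)
        base = _random_correlation(C, config.base_rank, config.base_scale, rng)
        effects = config.effects_for(key)
        static_hc = base
        static_sz = _plant_effects(base, effects)
        model[GroupLabel.HC]["static"][key] = static_hc
        model[GroupLabel.SZ]["states"][key] = []
        model[GroupLabel.SZ]["static"][key] = static_sz
        model[GroupLabel.HC]["states"][key] = []
        k = config.n_states_per_group
        d = config.state_divergence
        devs_hc, devs_sz = [], []
        for _ in range(k):
            # common deviation pattern; group-specific part scaled by divergence
            P = _symmetric_deviation(C, config.state_strength, rng)
            Q = _symmetric_deviation(C, config.state_strength, rng)
            devs_hc.append(P)
            devs_sz.append(np.sqrt(1.0 - d**2) * P + d * Q)
        # mean-match the deviation sets: groups may differ in *which* states
        # they visit without shifting the long-run (static) correlation
        shift = np.mean(devs_sz, axis=0) - np.mean(devs_hc, axis=0)
        devs_sz = [dev - shift for dev in devs_sz]
        if config.state_strength == 0:
            devs_hc = [np.zeros((C, C))] * k
            devs_sz = [np.zeros((C, C))] * k
        for dev_hc, dev_sz in zip(devs_hc, devs_sz):
            model[GroupLabel.HC]["states"][key].append(
                nearest_spd_correlation(static_hc + dev_hc)
            )
            model[GroupLabel.SZ]["states"][key].append(
                nearest_spd_correlation(static_sz + dev_sz)
            )
    return model


def _symmetric_deviation(C: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    D = rng.normal(scale=scale, size=(C, C))
    D = (D + D.T) / np.sqrt(2.0)
    np.fill_diagonal(D, 0.0)
    return D


def _markov_sequence(T: int, k: int, dwell: float, rng: np.random.Generator) -> np.ndarray:
    seq = np.empty(T, dtype=int)
    seq[0] = rng.integers(k)
    for t in range(1, T):
        if k == 1 or rng.random() < dwell:
            seq[t] = seq[t - 1]
        else:
            others = [s for s in range(k) if s != seq[t - 1]]
            seq[t] = others[rng.integers(len(others))]
    return seq


def _ar1_smooth(x: np.ndarray, a: float) -> np.ndarray:
    """Unit-variance-preserving AR(1) low-pass along axis 0."""
    if a == 0:
        return x
    y = np.empty_like(x)
    y[0] = x[0]
    c = np.sqrt(1.0 - a * a)
    for t in range(1, x.shape[0]):
        y[t] = a * y[t - 1] + c * x[t]
    return y


def simulate_subject(
    model: dict,
    config: SimulationConfig,
    subject_seed: int,
    subject_id: str,
    group: GroupLabel,
) -> tuple[dict, dict]:
    """Simulate one subject's timecourses for every modality/band.

    Returns ``(timecourse_sets, state_sequences)`` keyed by (modality, band).
    """
    rng = np.random.default_rng(subject_seed)
    gm = model[group]
    out: dict = {}
    seqs: dict = {}
    for key in config.keys:
        T, C = config.dims(key)
        static = gm["static"][key]
        states = gm["states"][key]
        chol_static = np.linalg.cholesky(static)
        chols = [np.linalg.cholesky(s) for s in states]
        seq = _markov_sequence(T, len(states), config.dwell, rng)
        u = rng.normal(size=(T, C)) @ chol_static.T
        e = rng.normal(size=(T, C))
        v = np.empty_like(e)
        for s in range(len(states)):
            mask = seq == s
            if mask.any():
                v[mask] = e[mask] @ chols[s].T
        m = config.mix_dynamic
        x = np.sqrt(1.0 - m) * u + np.sqrt(m) * v
        a = config.smoothing.get(key[0].value, 0.0)
        x = _ar1_smooth(x, a)
        out[key] = ComponentTimecourseSet(
            subject_id=subject_id,
            group=group,
            modality=key[0],
            band=key[1],
            data=x,
            sampling_rate=0.5 if key[0] == Modality.FMRI else 1.0,
        )
        seqs[key] = seq
    return out, seqs


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, PlantedTruth]:
    """Simulate the full two-group cohort and export the planted ground truth."""
    model = build_group_model(config)
    n_sz, n_hc = config.n_per_group
    roster = [(f"SZ{i + 1:03d}", GroupLabel.SZ) for i in range(n_sz)] + [
        (f"HC{i + 1:03d}", GroupLabel.HC) for i in range(n_hc)
    ]
    ss = np.random.SeedSequence([config.seed, 0x5EED])
    child_seeds = ss.generate_state(len(roster)) % (2**31)
    subjects: dict = {}
    groups: dict = {}
    state_sequences: dict = {}
    for (sid, g), child in zip(roster, child_seeds):
        sets, seqs = simulate_subject(model, config, int(child), sid, g)
        subjects[sid] = sets
        groups[sid] = g
        for key, seq in seqs.items():
            state_sequences[(sid, key)] = seq
    truth = PlantedTruth(
        effect_pairs=list(config.effect_pairs),
        state_correlations={
            (g.value, key): model[g]["states"][key]
            for g in (GroupLabel.HC, GroupLabel.SZ)
            for key in config.keys
        },
        static_correlations={
            (g.value, key): model[g]["static"][key]
            for g in (GroupLabel.HC, GroupLabel.SZ)
            for key in config.keys
        },
        state_sequences=state_sequences,
    )
    dataset = StudyDataset(
        subjects=subjects, groups=groups, metadata={"seed": config.seed, "synthetic": True}
    )
    return dataset, truth
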