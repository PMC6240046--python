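"""Protocol-faithful synthetic data with a planted, recoverable ground truth.

The generators emulate an auditory targeted-memory-reactivation protocol
delivered during slow-wave sleep: 25 cue sounds presented twice (50 cue
trials) and 5 control sounds presented five times (25 control trials),
grouped in blocks of five 500 ms presentations separated by 4-8 s jittered
ISIs. Sounds are modelled with 5 s boxcars. BOLD-like volumes are built on a
small voxel grid with a contiguous synthetic parcellation (default 115
parcels) whose parcels are grouped into modules; trial-wise parcel
amplitudes are drawn from per-condition multivariate normals with higher
within-module than between-module correlation, and the cue condition adds a
planted cross-module coupling boost to one "occipital" seed parcel. The
behavioral generator plants a negative across-subject association between
that boost and overnight forgetting of object locations.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .betaseries import build_design

__all__ = [
    "ProtocolSpec",
    "TrialEvents",
    "NetworkGroundTruth",
    "BehaviorEffect",
    "SimulatedBold",
    "generate_protocol",
    "generate_parcellation",
    "generate_bold",
    "generate_behavior",
    "nearest_pd",
]


@dataclass
class ProtocolSpec:
    """Stimulation-protocol parameters.

    Defaults reproduce the study protocol: 25 cue sounds x 2 repetitions and
    5 control sounds x 5 repetitions, 500 ms sounds modelled as 5 s boxcars,
    4-8 s jittered ISI, blocks of five same-condition presentations,
    TR = 2.511 s.
    """

    n_cue_sounds: int = 25
    cue_repetitions: int = 2
    n_control_sounds: int = 5
    control_repetitions: int = 5
    sound_duration: float = 0.5
    model_duration: float = 5.0
    isi_range: tuple[float, float] = (4.0, 8.0)
    block_size: int = 5
    tr: float = 2.511
    n_scans: int | None = None  # None: sized to events + 30 s tail
    start_offset: float = 10.0  # silence before the first presentation

    def validate(self) -> None:
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range lower bound exceeds upper bound")
        for name in ("sound_duration", "model_duration", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        n_cue = self.n_cue_sounds * self.cue_repetitions
        n_ctl = self.n_control_sounds * self.control_repetitions
        if n_cue == 0 and n_ctl == 0:
            raise ValueError("both conditions have zero presentations")
        for n, cond in ((n_cue, "cue"), (n_ctl, "control")):
            if n > 0 and n % self.block_size:
                raise ValueError(
                    f"{cond} presentations ({n}) not divisible by block_size"
                )

    @property
    def n_trials(self) -> int:
        return (
            self.n_cue_sounds * self.cue_repetitions
            + self.n_control_sounds * self.control_repetitions
        )


@dataclass
class TrialEvents:
    """Ordered sound-presentation events plus the sampling grid they live on."""

    table: pd.DataFrame  # onset, duration, trial_type, sound_id, block_index
    tr: float
    n_scans: int

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def condition_counts(self) -> dict[str, int]:
        return self.table["trial_type"].value_counts().to_dict()


def generate_protocol(spec: ProtocolSpec, rng_seed: int) -> TrialEvents:
    """Lay out the sound-presentation schedule.

    Presentations are grouped into condition-homogeneous blocks of
    ``block_size`` (10 cue + 5 control blocks under defaults), block order is
    randomised, sound identities are shuffled over their condition's slots,
    and each presentation is followed by a uniform ISI from ``isi_range``.
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(rng_seed)

    cue_sounds = np.repeat(
        [f"cue{i + 1:02d}" for i in range(spec.n_cue_sounds)], spec.cue_repetitions
    )
    ctl_sounds = np.repeat(
        [f"ctl{i + 1:02d}" for i in range(spec.n_control_sounds)],
        spec.control_repetitions,
    )
    for cond, arr in (("cue", cue_sounds), ("control", ctl_sounds)):
        if arr.size == 0:
            warnings.warn(f"condition {cond!r} has zero presentations", stacklevel=2)
    rng.shuffle(cue_sounds)
    rng.shuffle(ctl_sounds)

    blocks = [("cue", b) for b in np.split(cue_sounds, len(cue_sounds) // spec.block_size)] if cue_sounds.size else []
    blocks += [
        ("control", b)
        for b in np.split(ctl_sounds, len(ctl_sounds) // spec.block_size)
    ] if ctl_sounds.size else []
    order = rng.permutation(len(blocks))

    rows = []
    t = spec.start_offset
    for block_index, bi in enumerate(order):
        cond, sounds = blocks[bi]
        for sid in sounds:
            rows.append(
                dict(
                    onset=round(t, 6),
                    duration=spec.model_duration,
                    trial_type=cond,
                    sound_id=sid,
                    block_index=block_index,
                )
            )
            t += spec.sound_duration + rng.uniform(*spec.isi_range)
    table = pd.DataFrame(rows)

    last_end = table["onset"].iloc[-1] + spec.model_duration
    min_scans = int(np.ceil((last_end + 30.0) / spec.tr))
    if spec.n_scans is None:
        n_scans = min_scans
    else:
        n_scans = spec.n_scans
        if n_scans * spec.tr < last_end:
            raise ValueError(
                f"run too short: {n_scans} scans hold {n_scans * spec.tr:.1f}s but "
                f"events need at least {min_scans} scans"
            )
    return TrialEvents(table=table, tr=spec.tr, n_scans=n_scans)


def generate_parcellation(
    grid_shape: tuple[int, int, int], n_parcels: int = 115, rng_seed: int = 0
) -> np.ndarray:
    """Grow a contiguous random parcellation over a voxel grid.

    Parcels are grown from random seed voxels by randomised multi-source
    flood fill over 6-neighbourhoods, so every parcel is non-empty and
    face-connected and every voxel receives a label in 1..n_parcels.
    """
    n_vox = int(np.prod(grid_shape))
    if n_parcels > n_vox:
        raise ValueError(f"{n_parcels} parcels requested but grid has {n_vox} voxels")
    rng = np.random.default_rng(rng_seed)
    labels = np.zeros(grid_shape, dtype=np.int16)
    flat_seeds = rng.choice(n_vox, size=n_parcels, replace=False)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    heap = []
    # label seed voxels up front so no parcel can be swallowed by a neighbour
    for parcel, fs in enumerate(flat_seeds, start=1):
        ijk = np.unravel_index(fs, grid_shape)
        labels[ijk] = parcel
    for parcel, fs in enumerate(flat_seeds, start=1):
        i, j, k = np.unravel_index(fs, grid_shape)
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if (
                0 <= ni < grid_shape[0]
                and 0 <= nj < grid_shape[1]
                and 0 <= nk < grid_shape[2]
                and not labels[ni, nj, nk]
            ):
                heapq.heappush(heap, (rng.random(), parcel, (ni, nj, nk)))
    while heap:
        _, parcel, (i, j, k) = heapq.heappop(heap)
        if labels[i, j, k]:
            continue
        labels[i, j, k] = parcel
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if (
                0 <= ni < grid_shape[0]
                and 0 <= nj < grid_shape[1]
                and 0 <= nk < grid_shape[2]
                and not labels[ni, nj, nk]
            ):
                heapq.heappush(heap, (rng.random(), parcel, (ni, nj, nk)))
    return labels


def nearest_pd(cov: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite matrix
    by clipping eigenvalues at ``eps``."""
    sym = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, eps, None)
    return (vecs * vals) @ vecs.T


def _default_parcel_modules(n_parcels: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module assignment over parcel ids."""
    return (np.arange(n_parcels) * n_modules // n_parcels + 1).astype(int)


@dataclass
class NetworkGroundTruth:
    """Planted correlation structure of trial-wise parcel amplitudes.

    ``parcel_module`` groups the parcels into modules; amplitudes correlate
    at ``within_module_r`` inside a module and ``between_module_r`` across
    modules. In the cue condition only, ``seed_cross_boost`` is added to the
    correlations between the seed parcel and every parcel outside its
    module, raising the seed's inter-modular coupling (and hence its
    participation coefficient) during cueing.
    """

    n_parcels: int = 115
    n_modules: int = 5
    parcel_module: np.ndarray | None = None
    seed_parcel: int = 1  # 1-based parcel label
    within_module_r: float = 0.6
    between_module_r: float = 0.1
    seed_cross_boost: float = 0.25
    amplitude_mean: float = 1.0
    noise_sd: float = 0.3
    ar1_rho: float = 0.3
    voxel_amp_sd: float = 0.1  # idiosyncratic voxel amplitude scatter

    def __post_init__(self):
        if self.parcel_module is None:
            self.parcel_module = _default_parcel_modules(self.n_parcels, self.n_modules)
        self.parcel_module = np.asarray(self.parcel_module, dtype=int)
        if len(self.parcel_module) != self.n_parcels:
            raise ValueError("parcel_module must have one entry per parcel")
        if not self.within_module_r > self.between_module_r:
            raise ValueError("within_module_r must exceed between_module_r")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.voxel_amp_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def covariance(self, condition: str) -> np.ndarray:
        """Per-condition amplitude covariance (unit variances), PD-projected."""
        mod = self.parcel_module
        same = mod[:, None] == mod[None, :]
        C = np.where(same, self.within_module_r, self.between_module_r).astype(float)
        np.fill_diagonal(C, 1.0)
        if condition == "cue" and self.seed_cross_boost != 0.0:
            s = self.seed_parcel - 1
            cross = mod != mod[s]
            C[s, cross] += self.seed_cross_boost
            C[cross, s] += self.seed_cross_boost
        elif condition not in ("cue", "control"):
            raise ValueError(f"unknown condition {condition!r}")
        C = nearest_pd(C)
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("covariance not positive definite after projection")
        return C


@dataclass
class SimulatedBold:
    """Simulated run: voxel series plus everything needed for oracle checks."""

    bold: np.ndarray  # x, y, z, t
    nuisance: pd.DataFrame  # motion_1..6, compartment_1..3
    parcel_amplitudes: np.ndarray  # n_parcels x n_trials (planted)
    voxel_amplitudes: np.ndarray  # n_vox x n_trials (planted, flat order)
    events: TrialEvents
    parcellation: np.ndarray

    @property
    def voxel_series(self) -> np.ndarray:
        """node x scan view (flat voxel order)."""
        nt = self.bold.shape[-1]
        return self.bold.reshape(-1, nt)


def _random_walk_nuisance(n_scans: int, rng, sd: float = 0.05) -> pd.DataFrame:
    cols = [f"motion_{i + 1}" for i in range(6)] + [
        f"compartment_{i + 1}" for i in range(3)
    ]
    walks = np.cumsum(rng.normal(0.0, sd, size=(n_scans, 9)), axis=0)
    walks -= walks.mean(axis=0)
    return pd.DataFrame(walks, columns=cols)


def _ar1_noise(shape, rho, sd, rng):
    """AR(1) innovations along the last axis with stationary variance sd^2."""
    white = rng.normal(0.0, sd, size=shape)
    if rho == 0.0:
        return white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    innov_sd = np.sqrt(1.0 - rho**2)
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + innov_sd * white[..., t]
    return out


def draw_trial_amplitudes(
    truth: NetworkGroundTruth, conditions, rng: np.random.Generator
) -> np.ndarray:
    """Draw planted parcel amplitudes (n_parcels x n_trials) per condition.

    Each trial's amplitude vector comes from the multivariate normal of its
    condition (cue trials use the seed-boosted covariance).
    """
    conditions = np.asarray(conditions)
    chol = {c: np.linalg.cholesky(truth.covariance(c)) for c in ("cue", "control")}
    mean = np.full(truth.n_parcels, truth.amplitude_mean)
    out = np.empty((truth.n_parcels, len(conditions)))
    for t, cond in enumerate(conditions):
        out[:, t] = mean + chol[cond] @ rng.standard_normal(truth.n_parcels)
    return out


def generate_bold(
    events: TrialEvents,
    parcellation: np.ndarray,
    truth: NetworkGroundTruth,
    rng_seed: int,
    drift_amplitude: float = 0.5,
    nuisance_amplitude: float = 0.3,
) -> SimulatedBold:
    """Simulate a BOLD-like run with planted beta-amplitude structure.

    Per trial, parcel amplitudes are drawn from the condition's multivariate
    normal (the cue condition uses the seed-boosted covariance); each voxel's
    amplitude is its parcel's amplitude plus idiosyncratic scatter; the time
    series is the trial-wise HRF design times the voxel amplitudes, plus a
    slow sinusoidal drift, AR(1) noise, and a linear contribution of six
    simulated motion and three compartment nuisance series.
    """
    if int(parcellation.max()) != truth.n_parcels or np.any(parcellation < 1):
        raise ValueError("parcellation labels do not match ground-truth n_parcels")
    rng = np.random.default_rng(rng_seed)
    labels = np.asarray(events.table["trial_type"])
    n_trials = len(labels)
    n_scans, tr = events.n_scans, events.tr

    parcel_amp = draw_trial_amplitudes(truth, labels, rng)

    flat_labels = parcellation.reshape(-1).astype(int)
    voxel_amp = parcel_amp[flat_labels - 1, :]
    if truth.voxel_amp_sd > 0:
        voxel_amp = voxel_amp + rng.normal(
            0.0, truth.voxel_amp_sd, size=voxel_amp.shape
        )

    nuisance = _random_walk_nuisance(n_scans, rng)
    design = build_design(
        events.table, tr, n_scans, nuisance=None, cutoff=max(128.0, 4 * tr)
    )
    X = design.matrix[:, design.trial_indices]  # scans x trials
    Y = voxel_amp @ X.T  # vox x scans

    if drift_amplitude > 0:
        tgrid = np.arange(n_scans) * tr
        period = rng.uniform(200.0, 400.0)
        phase = rng.uniform(0, 2 * np.pi, size=(Y.shape[0], 1))
        Y = Y + drift_amplitude * np.sin(2 * np.pi * tgrid / period + phase)
    if nuisance_amplitude > 0:
        w = rng.normal(0.0, nuisance_amplitude, size=(Y.shape[0], 9))
        Y = Y + w @ nuisance.to_numpy().T
    if truth.noise_sd > 0:
        Y = Y + _ar1_noise(Y.shape, truth.ar1_rho, truth.noise_sd, rng)

    bold = Y.reshape(*parcellation.shape, n_scans)
    return SimulatedBold(
        bold=bold,
        nuisance=nuisance,
        parcel_amplitudes=parcel_amp,
        voxel_amplitudes=voxel_amp,
        events=events,
        parcellation=parcellation,
    )


@dataclass
class BehaviorEffect:
    """Brain-behavior coupling parameters for the behavioral generator.

    Units are centimetres of object-placement error. ``coupling`` is the
    slope of per-subject overnight forgetting on the (mean-centred) planted
    network-integration effect: negative coupling means subjects with a
    larger cue-induced integration boost forget less. Cued items carry the
    full slope; uncued items carry ``uncued_weight`` of it, reflecting a
    context-general rather than item-specific benefit.
    """

    error_mean: float = 2.74
    item_sd: float = 0.85
    subject_sd: float = 0.5
    forgetting_mean: float = 0.37
    forgetting_sd: float = 0.25
    item_noise_sd: float = 1.0
    coupling: float = -2.5
    uncued_weight: float = 0.6
    n_items: int = 50

    def validate(self):
        for name in ("item_sd", "subject_sd", "forgetting_sd", "item_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.uncued_weight <= 1:
            raise ValueError("uncued_weight must lie in [0, 1]")


def _truncated_at_zero(values: np.ndarray, resample, rng, max_iter: int = 100):
    """Resample negative entries until all are non-negative."""
    out = values.copy()
    for _ in range(max_iter):
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = resample(neg.sum(), rng)
    return np.abs(out)  # pathological parameters; keep distances valid


def generate_behavior(
    n_subjects: int,
    effect: BehaviorEffect | None = None,
    pc_effects: np.ndarray | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-item object-placement errors at Test 1 and Test 2.

    Each subject contributes ``n_items`` items (default 50, half cued).
    Test 1 errors are truncated normal at 0; Test 2 adds per-subject
    forgetting (linearly reduced by the planted integration effect via
    ``effect.coupling``) plus item-level retest noise, truncated at 0.
    Returns a long table with one row per subject/item and a
    ``planted_pc_effect`` column.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    eff = effect or BehaviorEffect()
    eff.validate()
    rng = np.random.default_rng(rng_seed)
    if pc_effects is None:
        pc_effects = rng.uniform(0.0, 0.5, size=n_subjects)
    pc_effects = np.asarray(pc_effects, dtype=float)
    if len(pc_effects) != n_subjects:
        raise ValueError("pc_effects must have one value per subject")
    centred = pc_effects - pc_effects.mean()

    n_cued = eff.n_items // 2
    rows = []
    for s in range(n_subjects):
        subj_mean = eff.error_mean + rng.normal(0.0, eff.subject_sd)
        base_forget = eff.forgetting_mean + rng.normal(0.0, eff.forgetting_sd)
        e1 = _truncated_at_zero(
            rng.normal(subj_mean, eff.item_sd, size=eff.n_items),
            lambda n, r: r.normal(subj_mean, eff.item_sd, size=n),
            rng,
        )
        cued = np.zeros(eff.n_items, dtype=bool)
        cued[rng.choice(eff.n_items, size=n_cued, replace=False)] = True
        weight = np.where(cued, 1.0, eff.uncued_weight)
        forget = base_forget + eff.coupling * centred[s] * weight
        e2 = _truncated_at_zero(
            e1 + forget + rng.normal(0.0, eff.item_noise_sd, size=eff.n_items),
            lambda n, r: r.normal(
                (e1 + forget).mean(), eff.item_noise_sd, size=n
            ),
            rng,
        )
        for i in range(eff.n_items):
            rows.append(
                dict(
                    subject=s,
                    item=i,
                    cued=bool(cued[i]),
                    error_test1=e1[i],
                    error_test2=e2[i],
                    planted_pc_effect=pc_effects[s],
                )
            )
    return pd.DataFrame(rows)
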