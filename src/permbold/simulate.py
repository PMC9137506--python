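"""Synthetic Go/NoGo fMRI cohort generator.

Emulates the study conditions every downstream stage needs: 200-volume
runs at TR 2 s with one trial per volume (80% Go / 20% NoGo), four
mutually exclusive trial outcomes, gamma-HRF-shaped responses in
localized regions, additive Gaussian noise, a slow drift, a
motion-correlated nuisance signal, and a two-group cohort generated
directly in a common voxel space with a configurable activation deficit
in one group.  Ground-truth activation amplitudes are recorded per voxel
so recovery can be scored exactly.

Motion enters only as the six nuisance time series plus a spatially
weighted additive signal; no image resampling or scanner physics is
simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .glm import HrfKernel, convolve_events, gamma_hrf

__all__ = [
    "OUTCOME_COLUMNS",
    "GROUPS",
    "TaskConfig",
    "ActiveRegion",
    "CohortSpec",
    "SubjectDataset",
    "generate_task_sequence",
    "simulate_performance",
    "simulate_subject",
    "generate_cohort",
    "ellipsoid_voxels",
    "default_active_regions",
    "default_cohort_spec",
    "write_cohort",
    "read_cohort",
]

OUTCOME_COLUMNS = ("correct_go", "correct_nogo", "omission", "commission")

#: group labels: the second group carries the activation deficit
GROUPS = ("control", "deficit")

#: default per-group performance accuracies (Go, NoGo), chosen to match
#: the reference cohort's group mean accuracies (control ~ 0.89 Go /
#: 0.94 NoGo; deficit group ~ 0.91 Go / 0.85 NoGo).
DEFAULT_ACCURACIES = {
    "control": (0.89, 0.94),
    "deficit": (0.91, 0.85),
}


@dataclass(frozen=True)
class TaskConfig:
    """Event-related Go/NoGo run: one trial per EPI volume."""

    n_trials: int = 200
    nogo_fraction: float = 0.20
    tr_seconds: float = 2.0
    stimulus_ms: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not 0.0 <= self.nogo_fraction <= 1.0:
            raise ConfigurationError("nogo_fraction must be in [0, 1]")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")


@dataclass(frozen=True)
class ActiveRegion:
    """A set of voxels with a task-locked response.

    ``amplitude`` maps group label -> coefficient applied to the
    HRF-convolved regressor of event column ``event`` (default: correct
    NoGo).  The injected NoGo-minus-Go truth at these voxels equals the
    amplitude for event==1 (correct NoGo) and minus it for event==0.
    """

    voxels: np.ndarray  # (k, 3) integer indices
    amplitude: Mapping[str, float]
    event: int = 1
    name: str = ""


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort in a common voxel grid."""

    n_per_group: int = 15
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 3.5)
    active_regions: tuple[ActiveRegion, ...] = ()
    noise_sd: float = 1.0
    motion_sd: float = 0.1
    drift_amplitude: float = 1.0
    motion_coupling: float = 0.5
    baseline: float = 100.0
    outside_intensity: float = 1.0
    accuracies: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACCURACIES))
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if any(g < 1 for g in self.grid_shape):
            raise ConfigurationError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel sizes must be positive")
        if self.noise_sd < 0 or self.motion_sd < 0:
            raise ConfigurationError("noise/motion SDs must be non-negative")
        for region in self.active_regions:
            vox = np.asarray(region.voxels)
            if vox.size and (vox.min() < 0 or
                             (vox >= np.array(self.grid_shape)).any()):
                raise ConfigurationError(f"region {region.name!r} exceeds grid")
            if not all(np.isfinite(a) for a in region.amplitude.values()):
                raise ConfigurationError("region amplitudes must be finite")


@dataclass(frozen=True)
class SubjectDataset:
    """One simulated subject: BOLD run, performance, motion, ground truth."""

    bold: np.ndarray          # (x, y, z, n)
    Z: np.ndarray             # (n, 4) one-hot outcomes
    motion: np.ndarray        # (n, 6): translations mm, rotations deg
    group: str
    truth: np.ndarray         # (x, y, z) injected NoGo-minus-Go amplitude
    tr_seconds: float = 2.0
    subject_id: str = "sub-00"
    seed: int = 0

    def __post_init__(self):
        n = self.bold.shape[-1]
        if self.Z.shape[0] != n or self.motion.shape[0] != n:
            raise ConfigurationError("bold, Z and motion time dimensions differ")


# ---------------------------------------------------------------------------
# task schedule and performance
# ---------------------------------------------------------------------------

def generate_task_sequence(cfg: TaskConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random Go/NoGo label sequence with exactly round(n * nogo_fraction)
    NoGo trials at uniformly random positions."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_nogo = int(round(cfg.n_trials * cfg.nogo_fraction))
    labels = np.full(cfg.n_trials, "go", dtype="<U4")
    positions = rng.choice(cfg.n_trials, size=n_nogo, replace=False)
    labels[positions] = "nogo"
    return labels


def simulate_performance(
    sequence: np.ndarray,
    go_accuracy: float,
    nogo_accuracy: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One-hot n x 4 performance matrix Z.

    Go trials become correct-Go with probability ``go_accuracy`` and
    omission errors otherwise; NoGo trials become correct-NoGo with
    probability ``nogo_accuracy`` and commission errors otherwise.
    """
    sequence = np.asarray(sequence)
    if sequence.size == 0:
        raise ConfigurationError("empty trial sequence")
    if not (0 <= go_accuracy <= 1 and 0 <= nogo_accuracy <= 1):
        raise ConfigurationError("accuracies must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = sequence.size
    Z = np.zeros((n, 4), dtype=np.int8)
    is_go = sequence == "go"
    u = rng.random(n)
    Z[is_go & (u < go_accuracy), 0] = 1          # correct Go
    Z[is_go & (u >= go_accuracy), 2] = 1         # omission
    Z[~is_go & (u < nogo_accuracy), 1] = 1       # correct NoGo
    Z[~is_go & (u >= nogo_accuracy), 3] = 1      # commission
    return Z


# ---------------------------------------------------------------------------
# geometry helpers and defaults
# ---------------------------------------------------------------------------

def ellipsoid_voxels(center: Sequence[float], radii: Sequence[float],
                     grid_shape: Sequence[int]) -> np.ndarray:
    """Integer voxel indices inside an axis-aligned ellipsoid."""
    grid = np.indices(grid_shape)
    d2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return np.argwhere(d2 <= 1.0)


def brain_mask_truth(grid_shape: Sequence[int]) -> np.ndarray:
    """The synthetic 'brain': an ellipsoid filling ~90% of each axis."""
    center = [(g - 1) / 2 for g in grid_shape]
    radii = [0.45 * g for g in grid_shape]
    mask = np.zeros(grid_shape, dtype=bool)
    vox = ellipsoid_voxels(center, radii, grid_shape)
    mask[tuple(vox.T)] = True
    return mask


def default_active_regions(
    grid_shape: Sequence[int] = (16, 16, 12),
    base_amplitude: float = 1.0,
    deficit: float = 0.5,
) -> tuple[ActiveRegion, ...]:
    """Three localized response regions inside the synthetic brain.

    Two 'activation' blobs respond to correct-NoGo events with amplitude
    ``base_amplitude`` in the control group and ``base_amplitude -
    deficit`` in the deficit group; one 'deactivation' blob responds
    negatively in both groups (no group difference), mimicking the
    positive and negative response clusters a Go/NoGo study reports.
    """
    gx, gy, gz = grid_shape
    regions = []
    spec = [
        ("frontal", (0.68, 0.62, 0.60), (2.2, 2.2, 1.8), +1.0, True),
        ("parietal", (0.35, 0.30, 0.55), (2.0, 2.0, 1.6), +1.0, True),
        ("default_mode", (0.50, 0.72, 0.38), (1.8, 1.8, 1.4), -0.8, False),
    ]
    for name, frac, radii, sign, has_deficit in spec:
        center = (frac[0] * (gx - 1), frac[1] * (gy - 1), frac[2] * (gz - 1))
        vox = ellipsoid_voxels(center, radii, grid_shape)
        amp_ctrl = sign * base_amplitude
        amp_def = sign * base_amplitude - (deficit if has_deficit else 0.0)
        regions.append(ActiveRegion(
            voxels=vox, name=name,
            amplitude={"control": amp_ctrl, "deficit": amp_def},
        ))
    return tuple(regions)


def default_cohort_spec(
    n_per_group: int = 15,
    effect: float = 0.5,
    noise_sd: float = 1.0,
    base_amplitude: float = 1.0,
    grid_shape: tuple[int, int, int] = (16, 16, 12),
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Cohort spec with the default region layout.

    ``effect`` is the group amplitude deficit in units of ``noise_sd``;
    ``base_amplitude`` is the control-group correct-NoGo response
    amplitude in units of ``noise_sd``.
    """
    regions = default_active_regions(
        grid_shape,
        base_amplitude=base_amplitude * noise_sd,
        deficit=effect * noise_sd,
    )
    return CohortSpec(n_per_group=n_per_group, grid_shape=grid_shape,
                      active_regions=regions, noise_sd=noise_sd, seed=seed,
                      **kwargs)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _simulate_motion(n: int, motion_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Six smooth AR(1) motion series scaled to SD ``motion_sd``."""
    rho = 0.95
    eps = rng.standard_normal((n, 6))
    m = np.empty((n, 6))
    m[0] = eps[0]
    for t in range(1, n):
        m[t] = rho * m[t - 1] + np.sqrt(1 - rho ** 2) * eps[t]
    return m * motion_sd


def simulate_subject(
    cfg: TaskConfig,
    spec: CohortSpec,
    Z: np.ndarray,
    group: str,
    seed: int | np.random.Generator = 0,
    hrf: HrfKernel | None = None,
    subject_id: str = "sub-00",
) -> SubjectDataset:
    """Forward model: baseline + sum_j amplitude_j(group) * (h * z_j) at
    active voxels + slow cosine drift + motion-correlated nuisance +
    i.i.d. Gaussian noise."""
    Z = np.asarray(Z)
    n = Z.shape[0]
    if Z.shape[1] != 4 or not np.all(Z.sum(axis=1) == 1):
        raise ConfigurationError("Z must be one-hot n x 4")
    if n != cfg.n_trials:
        raise ConfigurationError(
            f"Z has {n} rows but the task defines {cfg.n_trials} trials")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    used_seed = seed if isinstance(seed, int) else -1
    if hrf is None:
        hrf = gamma_hrf(tr_seconds=cfg.tr_seconds)

    brain = brain_mask_truth(spec.grid_shape)
    bold = np.where(brain, spec.baseline, spec.outside_intensity)[..., None]
    bold = np.repeat(bold.astype(float), n, axis=-1)

    # task-locked responses
    events = convolve_events(Z, hrf)  # n x 4
    truth = np.zeros(spec.grid_shape)
    for region in spec.active_regions:
        if group not in region.amplitude:
            raise ConfigurationError(f"region {region.name!r} lacks amplitude for {group!r}")
        amp = float(region.amplitude[group])
        idx = tuple(np.asarray(region.voxels).T)
        bold[idx] += amp * events[:, region.event]
        # injected NoGo-minus-Go contrast amplitude
        if region.event == 1:
            truth[idx] += amp
        elif region.event == 0:
            truth[idx] -= amp

    # slow drift (half-cycle cosine, random phase) inside the brain
    t = np.arange(n)
    phase = rng.uniform(0, 2 * np.pi)
    drift = spec.drift_amplitude * np.cos(np.pi * t / n + phase)
    bold[brain] += drift

    # motion series and motion-correlated spatial nuisance
    motion = _simulate_motion(n, spec.motion_sd, rng)
    weights = rng.normal(0.0, spec.motion_coupling, size=(int(brain.sum()), 6))
    bold[brain] += (motion @ weights.T).T

    if spec.noise_sd > 0:
        bold += rng.normal(0.0, spec.noise_sd, size=bold.shape)

    return SubjectDataset(bold=bold, Z=np.asarray(Z, dtype=np.int8),
                          motion=motion, group=group, truth=truth,
                          tr_seconds=cfg.tr_seconds, subject_id=subject_id,
                          seed=used_seed)


def generate_cohort(spec: CohortSpec, cfg: TaskConfig) -> list[SubjectDataset]:
    """Two-group cohort with per-subject independent randomness.

    Per-subject seeds come from ``np.random.SeedSequence(spec.seed)``
    spawned once per subject (the documented splitting rule), so a fixed
    master seed reproduces the cohort bit-for-bit while subjects stay
    independent.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_group)
    cohort: list[SubjectDataset] = []
    hrf = gamma_hrf(tr_seconds=cfg.tr_seconds)
    i = 0
    for group in GROUPS:
        go_acc, nogo_acc = spec.accuracies[group]
        for k in range(spec.n_per_group):
            rng = np.random.default_rng(streams[i])
            seq = generate_task_sequence(cfg, rng)
            Z = simulate_performance(seq, go_acc, nogo_acc, rng)
            sid = f"sub-{i:02d}"
            cohort.append(simulate_subject(cfg, spec, Z, group, rng, hrf=hrf,
                                           subject_id=sid))
            i += 1
    return cohort


# ---------------------------------------------------------------------------
# on-disk cohort (NIfTI + TSV + manifest)
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_cohort(cohort: Sequence[SubjectDataset], spec: CohortSpec,
                 out_dir: str | Path) -> Path:
    """Write one NIfTI + events TSV + motion TSV per subject and a JSON
    manifest tying files to groups and seeds.  Returns the manifest path."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(spec.voxel_size_mm)
    entries = []
    for ds in cohort:
        base = out / ds.subject_id
        nib.save(nib.Nifti1Image(ds.bold.astype(np.float32), aff),
                 str(base) + "_bold.nii")
        nib.save(nib.Nifti1Image(ds.truth.astype(np.float32), aff),
                 str(base) + "_truth.nii")
        outcome = np.array(OUTCOME_COLUMNS)[np.argmax(ds.Z, axis=1)]
        trial_type = np.where(np.isin(outcome, ("correct_go", "omission")),
                              "go", "nogo")
        pd.DataFrame({
            "volume_index": np.arange(ds.Z.shape[0]),
            "trial_type": trial_type,
            "outcome": outcome,
        }).to_csv(str(base) + "_events.tsv", sep="\t", index=False)
        pd.DataFrame(ds.motion, columns=[
            "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
        ]).to_csv(str(base) + "_motion.tsv", sep="\t", index=False)
        entries.append({
            "subject_id": ds.subject_id,
            "group": ds.group,
            "bold": f"{ds.subject_id}_bold.nii",
            "events": f"{ds.subject_id}_events.tsv",
            "motion": f"{ds.subject_id}_motion.tsv",
            "truth": f"{ds.subject_id}_truth.nii",
        })
    manifest = {
        "master_seed": spec.seed,
        "n_per_group": spec.n_per_group,
        "groups": list(GROUPS),
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "noise_sd": spec.noise_sd,
        "n_true_active_voxels": int(np.count_nonzero(
            _truth_volume(spec))),
        "subjects": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _truth_volume(spec: CohortSpec) -> np.ndarray:
    truth = np.zeros(spec.grid_shape)
    for region in spec.active_regions:
        idx = tuple(np.asarray(region.voxels).T)
        sign = 1.0 if region.event == 1 else -1.0 if region.event == 0 else 0.0
        truth[idx] += sign * float(np.mean(list(region.amplitude.values())))
    return truth


def events_to_Z(events: pd.DataFrame) -> np.ndarray:
    """Rebuild the one-hot performance matrix from an events table."""
    Z = np.zeros((len(events), 4), dtype=np.int8)
    for j, name in enumerate(OUTCOME_COLUMNS):
        Z[events["outcome"].to_numpy() == name, j] = 1
    return Z


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectDataset], dict]:
    """Load a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    cohort = []
    for e in manifest["subjects"]:
        bold = np.asarray(nib.load(root / e["bold"]).dataobj, dtype=float)
        truth = np.asarray(nib.load(root / e["truth"]).dataobj, dtype=float)
        events = pd.read_csv(root / e["events"], sep="\t")
        motion = pd.read_csv(root / e["motion"], sep="\t").to_numpy()
        cohort.append(SubjectDataset(
            bold=bold, Z=events_to_Z(events), motion=motion,
            group=e["group"], truth=truth, subject_id=e["subject_id"],
        ))
    return cohort, manifest
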