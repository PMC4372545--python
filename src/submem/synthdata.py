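"""Synthetic participants: trial schedules, behavior, ground truth, and BOLD.

The generator emulates the delayed match-to-sample acquisition (TR = 2 s,
8 runs of 144 volumes, 12 trials/run of 2 s sample + 10 s delay + 2 s test,
ITIs balanced over {6, 10, 14} s) and a brain-behavior link in which the
per-trial neural amplitude in effect voxels is affine in the trial's later
memory-strength code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import designmat
from .designmat import HRFParams, MOTION_CHANNELS
from .grouplevel import RATING_ORDER, strength_code

__all__ = [
    "AcquisitionSpec",
    "GroundTruth",
    "Behavior",
    "SubjectData",
    "generate_schedule",
    "simulate_behavior",
    "simulate_motion",
    "simulate_bold",
    "simulate_subject",
    "make_roi_labels",
    "write_dataset",
    "ROI_LABELS",
]

#: Medial-temporal ROI label values used in the synthetic label volume.
ROI_LABELS = {
    "PHC": 1,
    "PrC": 2,
    "EC": 3,
    "CA1": 4,
    "CA3DG": 5,
    "SUB": 6,
}


class ConfigurationError(ValueError):
    """Acquisition parameters inconsistent with the trial schedule."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan geometry and timing of one synthetic session."""

    tr: float = 2.0
    n_runs: int = 8
    volumes_per_run: int = 144
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size: float = 1.5
    trials_per_run: int = 12
    sample_duration: float = 2.0
    delay_duration: float = 10.0
    test_duration: float = 2.0
    itis: tuple[float, ...] = (6.0, 10.0, 14.0)

    def __post_init__(self):
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")

    @property
    def trial_duration(self) -> float:
        return self.sample_duration + self.delay_duration + self.test_duration

    @property
    def run_duration(self) -> float:
        return self.volumes_per_run * self.tr

    @property
    def n_volumes(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        return aff

    def validate_schedule_arithmetic(self) -> None:
        """Check that balanced ITIs fill the run exactly."""
        if self.trials_per_run % len(self.itis) != 0:
            raise ConfigurationError(
                "trials_per_run must be divisible by the number of ITI levels"
            )
        total = self.trials_per_run * (self.trial_duration + float(np.mean(self.itis)))
        if abs(total - self.run_duration) > 1e-9:
            raise ConfigurationError(
                f"schedule spans {total}s per run but volumes_per_run x tr = "
                f"{self.run_duration}s"
            )


@dataclass
class GroundTruth:
    """Generative parameters of one synthetic subject.

    The neural amplitude of each trial in effect voxels is
    ``gamma0 + gamma1 * strength_code(smt_rating)``, shaped by the
    ``generative_model`` encoding kernel and convolved with the analysis HRF.
    """

    generative_model: str = "decay"
    gamma0: float = 2.0
    gamma1: float = 0.5
    test_amplitude: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    effect_voxels: np.ndarray = None  # (k, 3) int voxel indices
    drift_coeffs: np.ndarray = None  # (n_runs, 3)
    motion_loading_sd: float = 0.0
    rating_thresholds: tuple[float, ...] = (-1.6, -0.8, 0.0, 1.0)
    mu_old: float = 0.3
    mu_lure: float = -1.0
    p_dms: float = 0.95
    n_lures: int = 144
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        th = np.asarray(self.rating_thresholds, dtype=float)
        if th.shape != (4,) or np.any(np.diff(th) <= 0):
            raise ValueError("rating_thresholds must be 4 strictly increasing values")
        if self.generative_model not in designmat.ENCODING_MODELS:
            raise ValueError(f"unknown generative model {self.generative_model!r}")

    def validate_grid(self, spec: AcquisitionSpec) -> None:
        if self.effect_voxels is None:
            return
        ev = np.asarray(self.effect_voxels)
        if ev.size and (np.any(ev < 0) or np.any(ev >= np.array(spec.grid_shape))):
            raise ValueError("effect_voxels fall outside the acquisition grid")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_voxels"] = (
            None if self.effect_voxels is None else np.asarray(self.effect_voxels).tolist()
        )
        d["drift_coeffs"] = (
            None if self.drift_coeffs is None else np.asarray(self.drift_coeffs).tolist()
        )
        d["rating_thresholds"] = list(self.rating_thresholds)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        if d.get("effect_voxels") is not None:
            d["effect_voxels"] = np.asarray(d["effect_voxels"], dtype=int)
        if d.get("drift_coeffs") is not None:
            d["drift_coeffs"] = np.asarray(d["drift_coeffs"], dtype=float)
        d["rating_thresholds"] = tuple(d["rating_thresholds"])
        return cls(**d)


def default_ground_truth(
    spec: AcquisitionSpec,
    generative_model: str = "decay",
    seed: int = 0,
    **overrides,
) -> GroundTruth:
    """Ground truth with a central cubic block of effect voxels and mild drift."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    half = max(1, min(nx, ny, nz) // 6)
    block = [
        (i, j, k)
        for i in range(cx - half, cx + half)
        for j in range(cy - half, cy + half)
        for k in range(cz - half, cz + half)
    ]
    overrides.setdefault("effect_voxels", np.asarray(block, dtype=int))
    overrides.setdefault(
        "drift_coeffs",
        rng.normal(0.0, [5e-3, 5e-5, 5e-7], size=(spec.n_runs, 3)),
    )
    return GroundTruth(generative_model=generative_model, seed=seed, **overrides)


@dataclass
class Behavior:
    """Per-trial task records plus per-lure subsequent-memory ratings."""

    trials: pd.DataFrame
    lures: pd.DataFrame

    @property
    def categories_used(self) -> list[str]:
        present = set(self.trials["smt_rating"].astype(str))
        return [c for c in RATING_ORDER if c in present]


@dataclass
class SubjectData:
    """Everything generated for one synthetic participant."""

    subject_id: str
    spec: AcquisitionSpec
    truth: GroundTruth
    schedule: pd.DataFrame
    behavior: Behavior
    bold: np.ndarray  # (nx, ny, nz, t)
    motion: pd.DataFrame  # n_volumes x (run + 6 channels)
    roi_labels: np.ndarray


def generate_schedule(spec: AcquisitionSpec, seed: int) -> pd.DataFrame:
    """Generate a full-session trial schedule.

    Each run holds ``trials_per_run`` trials with balanced ITIs (equal counts
    of each level, shuffled) so the run spans exactly
    ``volumes_per_run * tr`` seconds.  Match/non-match conditions are split
    evenly within a run and pseudo-randomized.

    Returns
    -------
    DataFrame
        Columns: run, trial, sample_onset, delay_onset, test_onset,
        iti_after, condition.  Onsets are seconds from run start.
    """
    spec.validate_schedule_arithmetic()
    if spec.trials_per_run % 2 != 0:
        raise ConfigurationError("trials_per_run must be even for a match/non-match split")
    rng = np.random.default_rng(seed)
    reps = spec.trials_per_run // len(spec.itis)
    half = spec.trials_per_run // 2
    rows = []
    for run in range(spec.n_runs):
        itis = rng.permutation(np.repeat(spec.itis, reps))
        conds = rng.permutation(["match"] * half + ["nonmatch"] * half)
        t = 0.0
        for trial in range(spec.trials_per_run):
            rows.append(
                {
                    "run": run,
                    "trial": trial,
                    "sample_onset": t,
                    "delay_onset": t + spec.sample_duration,
                    "test_onset": t + spec.sample_duration + spec.delay_duration,
                    "iti_after": float(itis[trial]),
                    "condition": conds[trial],
                }
            )
            t += spec.trial_duration + itis[trial]
        if abs(t - spec.run_duration) > 1e-9:
            raise ConfigurationError(
                f"run {run} spans {t}s, expected {spec.run_duration}s"
            )
    return pd.DataFrame(rows)


def _ratings_from_latent(latent: np.ndarray, thresholds) -> np.ndarray:
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), latent)
    return np.asarray(RATING_ORDER)[idx]


def simulate_behavior(
    schedule: pd.DataFrame, truth: GroundTruth, seed: int
) -> Behavior:
    """Simulate DMS responses and subsequent-memory ratings.

    A Gaussian latent memory strength per studied scene is cut at
    ``truth.rating_thresholds`` to produce the ordinal 1/2/3/4/R rating;
    lures are drawn from a lower-mean latent.  DMS correctness is Bernoulli
    with probability ``truth.p_dms``.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    latent = rng.normal(truth.mu_old, 1.0, size=n)
    ratings = _ratings_from_latent(latent, truth.rating_thresholds)
    correct = rng.random(n) < truth.p_dms
    is_match = schedule["condition"].to_numpy() == "match"
    response = np.where(is_match == correct, "yes", "no")
    trials = pd.DataFrame(
        {
            "run": schedule["run"].to_numpy(),
            "trial": schedule["trial"].to_numpy(),
            "condition": schedule["condition"].to_numpy(),
            "latent_strength": latent,
            "dms_response": response,
            "dms_correct": correct,
            "smt_rating": ratings,
        }
    )
    lure_latent = rng.normal(truth.mu_lure, 1.0, size=truth.n_lures)
    lures = pd.DataFrame(
        {
            "latent_strength": lure_latent,
            "smt_rating": _ratings_from_latent(lure_latent, truth.rating_thresholds),
        }
    )
    return Behavior(trials=trials, lures=lures)


def simulate_motion(spec: AcquisitionSpec, seed: int, scale: float = 0.05,
                    phi: float = 0.98) -> pd.DataFrame:
    """Six smooth AR(1) motion channels, restarted at each run boundary."""
    rng = np.random.default_rng(seed)
    out = np.zeros((spec.n_volumes, 6))
    innov_sd = scale * np.sqrt(1 - phi**2)
    for r in range(spec.n_runs):
        x = np.zeros(6)
        for t in range(spec.volumes_per_run):
            x = phi * x + rng.normal(0.0, innov_sd, size=6)
            out[r * spec.volumes_per_run + t] = x
    df = pd.DataFrame(out, columns=list(MOTION_CHANNELS))
    df.insert(0, "run", np.repeat(np.arange(spec.n_runs), spec.volumes_per_run))
    return df


def _drift_basis(spec: AcquisitionSpec) -> np.ndarray:
    n = spec.volumes_per_run
    lin = np.arange(n, dtype=float) - (n - 1) / 2.0
    basis = np.column_stack([lin, lin**2 - (lin**2).mean(), lin**3 - (lin**3).mean()])
    return basis


def simulate_bold(
    schedule: pd.DataFrame,
    behavior: Behavior,
    truth: GroundTruth,
    spec: AcquisitionSpec,
    seed: int,
    motion: pd.DataFrame | None = None,
    hrf_params: HRFParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate the 4D BOLD volume and its motion table.

    Effect voxels receive the encoding signal: per trial, amplitude
    ``gamma0 + gamma1 * strength_code(rating)`` under the generative
    encoding kernel, plus a fixed-amplitude test response, convolved with
    the canonical HRF.  All voxels receive per-run baseline, cubic drift,
    motion leakage, and i.i.d. Gaussian noise.
    """
    truth.validate_grid(spec)
    rng = np.random.default_rng(seed)
    if motion is None:
        motion = simulate_motion(spec, seed=rng.integers(2**31))

    interest, names = designmat.interest_regressors(
        schedule, behavior.trials, truth.generative_model, hrf_params, spec
    )
    amps = np.array(
        [
            truth.gamma0 + truth.gamma1 * strength_code(nm.split("_", 1)[1])
            if nm.startswith("encoding_")
            else truth.test_amplitude
            for nm in names
        ]
    )
    signal = interest @ amps  # (n_volumes,)

    n_vox, n_vol = spec.n_voxels, spec.n_volumes
    run_of_row = np.repeat(np.arange(spec.n_runs), spec.volumes_per_run)
    drift = np.zeros(n_vol)
    if truth.drift_coeffs is not None:
        basis = _drift_basis(spec)
        for r in range(spec.n_runs):
            drift[run_of_row == r] = basis @ np.asarray(truth.drift_coeffs)[r]

    data = np.full((n_vox, n_vol), truth.baseline)
    data += drift[None, :]
    if truth.motion_loading_sd > 0:
        loadings = rng.normal(0.0, truth.motion_loading_sd, size=(n_vox, 6))
        data += loadings @ np.asarray(motion[list(MOTION_CHANNELS)]).T
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, size=(n_vox, n_vol))
    if truth.effect_voxels is not None and len(truth.effect_voxels):
        flat = np.ravel_multi_index(np.asarray(truth.effect_voxels).T, spec.grid_shape)
        data[flat] += signal[None, :]
    bold = data.reshape(*spec.grid_shape, n_vol)
    return bold, motion


def make_roi_labels(spec: AcquisitionSpec) -> np.ndarray:
    """Integer ROI label volume partitioning the grid into six x-slabs."""
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    nx = spec.grid_shape[0]
    edges = np.linspace(0, nx, len(ROI_LABELS) + 1).astype(int)
    for value, (lo, hi) in zip(ROI_LABELS.values(), zip(edges[:-1], edges[1:])):
        labels[lo:hi] = value
    return labels


def simulate_subject(
    spec: AcquisitionSpec,
    truth: GroundTruth | None = None,
    seed: int = 0,
    subject_id: str | None = None,
    hrf_params: HRFParams | None = None,
) -> SubjectData:
    """Generate one complete synthetic participant from a single seed."""
    if truth is None:
        truth = default_ground_truth(spec, seed=seed)
    truth = dataclasses.replace(truth, seed=seed)
    schedule = generate_schedule(spec, seed=seed)
    behavior = simulate_behavior(schedule, truth, seed=seed + 1)
    motion = simulate_motion(spec, seed=seed + 2)
    bold, motion = simulate_bold(
        schedule, behavior, truth, spec, seed=seed + 3, motion=motion,
        hrf_params=hrf_params,
    )
    return SubjectData(
        subject_id=subject_id or f"sub-{seed:02d}",
        spec=spec,
        truth=truth,
        schedule=schedule,
        behavior=behavior,
        bold=bold,
        motion=motion,
        roi_labels=make_roi_labels(spec),
    )


def events_frame(subject: SubjectData) -> pd.DataFrame:
    """BIDS-style long event table: one row per trial phase."""
    rows = []
    beh = subject.behavior.trials
    for (_, sched), (_, b) in zip(subject.schedule.iterrows(), beh.iterrows()):
        for phase, onset, duration in (
            ("sample", sched["sample_onset"], subject.spec.sample_duration),
            ("delay", sched["delay_onset"], subject.spec.delay_duration),
            ("test", sched["test_onset"], subject.spec.test_duration),
        ):
            rows.append(
                {
                    "onset": onset,
                    "duration": duration,
                    "trial_type": phase,
                    "run": int(sched["run"]),
                    "condition": sched["condition"],
                    "dms_correct": bool(b["dms_correct"]),
                    "smt_rating": b["smt_rating"],
                }
            )
    return pd.DataFrame(rows)


def write_dataset(subject: SubjectData, directory) -> dict[str, Path]:
    """Write one subject's files (NIfTI volumes, TSV tables, truth JSON).

    Returns a name -> path mapping of everything written.
    """
    import nibabel as nib

    directory = Path(directory) / subject.subject_id
    try:
        directory.mkdir(parents=True, exist_ok=True)
        affine = subject.spec.affine
        paths = {}

        def _save_nii(name, data):
            p = directory / f"{subject.subject_id}_{name}.nii"
            nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), p)
            paths[name] = p

        _save_nii("bold", subject.bold)
        _save_nii("roi-labels", subject.roi_labels.astype(np.float64))

        def _save_tsv(name, frame):
            p = directory / f"{subject.subject_id}_{name}.tsv"
            frame.to_csv(p, sep="\t", index=False)
            paths[name] = p

        _save_tsv("events", events_frame(subject))
        _save_tsv("motion", subject.motion)
        _save_tsv("behavior", subject.behavior.trials)
        _save_tsv("lures", subject.behavior.lures)
        _save_tsv("schedule", subject.schedule)

        p = directory / f"{subject.subject_id}_truth.json"
        payload = {
            "spec": dataclasses.asdict(subject.spec),
            "truth": subject.truth.to_json_dict(),
        }
        p.write_text(json.dumps(payload, indent=2))
        paths["truth"] = p
        return paths
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
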