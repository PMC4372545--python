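"""Posterior-predictive model checking on trial-locked ROI time courses.

Observed and model-simulated sphere-averaged signals are z-scored within
participant, epoched at sample onsets, averaged per response category, and
compared pointwise: time points where the observed mean falls outside the
replicate envelope mark model misfit, and a scalar misfit (mean squared
standardized distance from the replicate mean) ranks competing encoding
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import designmat
from .firstlevel import FirstLevelResult, fit_voxelwise
from .grouplevel import RATING_ORDER

__all__ = [
    "RoiSphere",
    "TrialTimeCourse",
    "PpcResult",
    "sphere_voxels",
    "extract_sphere_signal",
    "trial_average",
    "posterior_predictive_simulate",
    "ppc_discrepancy",
    "compare_models",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


@dataclass
class RoiSphere:
    """Voxels within a world-coordinate radius of a center voxel."""

    center: tuple[int, int, int]
    radius: float
    members: np.ndarray  # (k, 3) voxel indices


@dataclass
class TrialTimeCourse:
    """Trial-locked, z-scored, category-averaged signal with +/- 2 SE band."""

    offsets: np.ndarray  # seconds relative to sample onset
    categories: list[str]
    mean: dict[str, np.ndarray]
    band: dict[str, np.ndarray]  # half-width = 2 * SE; NaN when n < 2
    n_trials: dict[str, int]
    n_dropped: int = 0


@dataclass
class PpcResult:
    """Pointwise envelope flags and scalar misfit for one model."""

    n_sim: int
    sim_mean: dict[str, np.ndarray]
    envelope_low: dict[str, np.ndarray]
    envelope_high: dict[str, np.ndarray]
    flags: dict[str, np.ndarray]
    misfit: float


def sphere_voxels(
    center: tuple[int, int, int],
    radius: float,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> RoiSphere:
    """Enumerate grid voxels whose world coordinates lie within ``radius`` mm
    of the center voxel's world coordinates."""
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= np.asarray(grid_shape)):
        raise ValueError(f"sphere center {tuple(center)} outside grid {grid_shape}")
    A, t = affine[:3, :3], affine[:3, 3]
    c_world = A @ center + t
    # conservative voxel-space bounding box
    step = np.abs(np.linalg.inv(A)) @ np.full(3, radius)
    lo = np.maximum(np.floor(center - step).astype(int), 0)
    hi = np.minimum(np.ceil(center + step).astype(int), np.asarray(grid_shape) - 1)
    ii, jj, kk = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = pts @ A.T + t
    keep = np.linalg.norm(world - c_world, axis=1) <= radius + 1e-9
    members = pts[keep]
    if len(members) == 0:
        raise ValueError("sphere contains no voxels")
    return RoiSphere(center=tuple(center), radius=radius, members=members)


def extract_sphere_signal(
    bold: np.ndarray,
    center: tuple[int, int, int],
    radius: float,
    affine: np.ndarray,
) -> np.ndarray:
    """Mean time series over a sphere of voxels in one 4D volume."""
    sphere = sphere_voxels(center, radius, affine, bold.shape[:3])
    return bold[tuple(sphere.members.T)].mean(axis=0)


def _zscore(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    sd = series.std()
    if sd < _VAR_FLOOR:
        return np.zeros_like(series)
    return (series - series.mean()) / sd


def _as_list(x):
    return x if isinstance(x, (list, tuple)) else [x]


def trial_average(
    series,
    schedule,
    behavior,
    spec,
    window: tuple[float, float] = (-4.0, 24.0),
    zscore: bool = True,
) -> TrialTimeCourse:
    """Trial-locked category averages of one or more participants' series.

    Each participant's whole series is z-scored first, then epoched at
    sample onsets on the TR grid over ``window`` (seconds relative to sample
    onset).  Epochs crossing a run boundary are dropped and counted.
    Trials are pooled across participants within each response category;
    the band half-width is 2 * SD / sqrt(n) over pooled trials.
    """
    series_list = _as_list(series)
    sched_list = _as_list(schedule)
    beh_list = _as_list(behavior)
    if not len(series_list) == len(sched_list) == len(beh_list):
        raise ValueError("series, schedule and behavior lists must align")
    tr = spec.tr
    offs_idx = np.arange(
        int(round(window[0] / tr)), int(round(window[1] / tr)) + 1
    )
    offsets = offs_idx * tr
    epochs: dict[str, list[np.ndarray]] = {c: [] for c in RATING_ORDER}
    n_dropped = 0
    for ser, sched, beh in zip(series_list, sched_list, beh_list):
        z = _zscore(ser) if zscore else np.asarray(ser, dtype=float)
        trials = beh.trials if hasattr(beh, "trials") else beh
        ratings = trials["smt_rating"].astype(str).to_numpy()
        runs = sched["run"].to_numpy()
        onsets = sched["sample_onset"].to_numpy()
        for i in range(len(sched)):
            base = runs[i] * spec.volumes_per_run + int(round(onsets[i] / tr))
            idx = base + offs_idx
            lo, hi = runs[i] * spec.volumes_per_run, (runs[i] + 1) * spec.volumes_per_run
            if idx[0] < lo or idx[-1] >= hi:
                n_dropped += 1
                continue
            epochs[ratings[i]].append(z[idx])
    if n_dropped:
        logger.debug("dropped %d partial epochs at run boundaries", n_dropped)
    cats = [c for c in RATING_ORDER if epochs[c]]
    mean, band, n_trials = {}, {}, {}
    for c in cats:
        arr = np.asarray(epochs[c])
        mean[c] = arr.mean(axis=0)
        n = arr.shape[0]
        band[c] = (
            2.0 * arr.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.full(arr.shape[1], np.nan)
        )
        n_trials[c] = n
    return TrialTimeCourse(
        offsets=offsets, categories=cats, mean=mean, band=band,
        n_trials=n_trials, n_dropped=n_dropped,
    )


def posterior_predictive_simulate(
    fit: FirstLevelResult,
    design,
    n_sim: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Draw replicate series from the fitted linear model's posterior.

    Per replicate: residual variance is drawn from its scaled inverse
    chi-square posterior, coefficients from their conditional normal
    (noninformative prior), and a replicate series ``X beta + noise`` is
    generated.  A zero residual variance reproduces the fitted values
    exactly.

    Returns
    -------
    ndarray of shape (n_sim, n_time, n_voxels).
    """
    if fit.df <= 0:
        raise ValueError("fit must have positive residual df")
    rng = np.random.default_rng(seed)
    X = design.values
    n_time, p = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    xtx_inv = (xtx_inv + xtx_inv.T) / 2
    # eigen square root: robust to the wide column scales of drift regressors
    vals, vecs = np.linalg.eigh(xtx_inv)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    out = np.empty((n_sim, n_time, fit.n_voxels))
    for v in range(fit.n_voxels):
        s2_hat = fit.sigma2[v]
        for r in range(n_sim):
            if s2_hat <= 0:
                out[r, :, v] = X @ fit.beta[v]
                continue
            s2 = fit.df * s2_hat / stats.chi2.rvs(fit.df, random_state=rng)
            beta = fit.beta[v] + np.sqrt(s2) * (L @ rng.normal(size=p))
            out[r, :, v] = X @ beta + rng.normal(0.0, np.sqrt(s2), size=n_time)
    return out


def ppc_discrepancy(
    observed: TrialTimeCourse,
    replicates: list[TrialTimeCourse],
    envelope: str = "minmax",
) -> PpcResult:
    """Compare an observed time course against replicate time courses.

    Flags mark time points where the observed mean lies outside the
    replicate envelope (pointwise min-max by default, or a central 95%
    interval).  The scalar misfit is the mean over categories and time
    points of the squared standardized distance from the replicate mean.
    """
    if envelope not in ("minmax", "central95"):
        raise ValueError("envelope must be 'minmax' or 'central95'")
    cats = observed.categories
    sim_mean, lo, hi, flags = {}, {}, {}, {}
    sq = []
    for c in cats:
        curves = []
        for rep in replicates:
            if c not in rep.mean:
                continue
            if len(rep.offsets) != len(observed.offsets) or not np.allclose(
                rep.offsets, observed.offsets
            ):
                raise ValueError("replicate time grid does not match observed grid")
            curves.append(rep.mean[c])
        if not curves:
            continue
        arr = np.asarray(curves)
        sim_mean[c] = arr.mean(axis=0)
        if envelope == "minmax":
            lo[c], hi[c] = arr.min(axis=0), arr.max(axis=0)
        else:
            lo[c], hi[c] = np.quantile(arr, [0.025, 0.975], axis=0)
        flags[c] = (observed.mean[c] < lo[c]) | (observed.mean[c] > hi[c])
        sd = np.maximum(arr.std(axis=0, ddof=1) if len(arr) > 1 else np.ones_like(arr[0]),
                        np.sqrt(_VAR_FLOOR))
        sq.append(((observed.mean[c] - sim_mean[c]) / sd) ** 2)
    misfit = float(np.mean(np.concatenate(sq))) if sq else float("nan")
    return PpcResult(
        n_sim=len(replicates),
        sim_mean=sim_mean,
        envelope_low=lo,
        envelope_high=hi,
        flags=flags,
        misfit=misfit,
    )


def compare_models(
    series,
    schedule,
    behavior,
    motion,
    spec,
    models: list[str] | None = None,
    hrf_params=None,
    n_sim: int = 20,
    seed: int = 0,
    window: tuple[float, float] = (-4.0, 24.0),
) -> pd.DataFrame:
    """Fit competing encoding models to ROI series and rank them by PPC misfit.

    Accepts one participant's sphere-averaged series (with its schedule,
    behavior, and motion table) or aligned lists for a cohort.  For each
    model, each participant's series is fit with that model's design,
    ``n_sim`` posterior-predictive replicates are drawn, pooled through the
    same trial-averaging pipeline as the observed data, and scored.

    Returns
    -------
    DataFrame with columns ``model``, ``misfit``, ``n_flagged``, ``rank``,
    sorted best first.
    """
    if models is None:
        models = list(designmat.ENCODING_MODELS)
    if len(models) < 1:
        raise ValueError("at least one model required")
    series_list = _as_list(series)
    sched_list = _as_list(schedule)
    beh_list = _as_list(behavior)
    motion_list = _as_list(motion)
    observed = trial_average(series_list, sched_list, beh_list, spec, window)
    rows = []
    for mi, model in enumerate(models):
        rep_series = [[] for _ in range(n_sim)]
        for si, (ser, sched, beh, mot) in enumerate(
            zip(series_list, sched_list, beh_list, motion_list)
        ):
            trials = beh.trials if hasattr(beh, "trials") else beh
            design = designmat.build_design(
                sched, trials, mot, model, spec, hrf_params
            )
            fit = fit_voxelwise(np.asarray(ser, dtype=float)[:, None], design)
            reps = posterior_predictive_simulate(
                fit, design, n_sim=n_sim, seed=seed + 1000 * mi + si
            )
            for r in range(n_sim):
                rep_series[r].append(reps[r, :, 0])
        replicates = [
            trial_average(rep_series[r], sched_list, beh_list, spec, window)
            for r in range(n_sim)
        ]
        ppc = ppc_discrepancy(observed, replicates)
        rows.append(
            {
                "model": model,
                "misfit": ppc.misfit,
                "n_flagged": int(sum(f.sum() for f in ppc.flags.values())),
            }
        )
    out = pd.DataFrame(rows).sort_values("misfit", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def timecourse_frame(tc: TrialTimeCourse, ppc: PpcResult | None = None) -> pd.DataFrame:
    """Long-format table of a trial time course (for TSV export)."""
    rows = []
    for c in tc.categories:
        for i, off in enumerate(tc.offsets):
            row = {
                "category": c,
                "offset_s": float(off),
                "mean": float(tc.mean[c][i]),
                "band": float(tc.band[c][i]),
                "n_trials": tc.n_trials[c],
            }
            if ppc is not None and c in ppc.sim_mean:
                row.update(
                    sim_mean=float(ppc.sim_mean[c][i]),
                    env_low=float(ppc.envelope_low[c][i]),
                    env_high=float(ppc.envelope_high[c][i]),
                    flagged=bool(ppc.flags[c][i]),
                )
            rows.append(row)
    return pd.DataFrame(rows)
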