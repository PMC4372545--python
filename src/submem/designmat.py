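"""First-level design matrix construction.

Regressors of interest are built per subsequent-memory response category:
one encoding regressor (an encoding-model kernel placed at each sample
onset) and one test regressor (a boxcar over the test phase), both convolved
with a canonical double-gamma HRF.  Nuisance regressors carry run baselines,
per-run motion copies, and per-run cubic drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grouplevel import RATING_ORDER

__all__ = [
    "HRFParams",
    "ENCODING_MODELS",
    "DesignMatrix",
    "double_gamma_hrf",
    "encoding_kernel",
    "interest_regressors",
    "nuisance_regressors",
    "assemble",
    "build_design",
]

ENCODING_MODELS = ("sample_only", "sample_plus_delay", "decay")

MOTION_CHANNELS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds unless noted)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def validate(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "kernel_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named, partitioned columns."""

    values: np.ndarray
    column_names: list[str]
    interest_columns: list[str]
    run_of_row: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def nuisance_columns(self) -> list[str]:
        interest = set(self.interest_columns)
        return [c for c in self.column_names if c not in interest]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.column_names.index(name)]
        except ValueError:
            raise KeyError(f"no design column named {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def double_gamma_hrf(
    params: HRFParams | None = None, tr: float = 2.0, oversampling: int = 1
) -> np.ndarray:
    """Sample the canonical double-gamma HRF.

    The kernel is the difference of two gamma densities (the second scaled
    by ``1/undershoot_ratio``), truncated at ``kernel_length`` and
    peak-normalized to 1.

    Parameters
    ----------
    params : HRFParams, optional
    tr : float
        Repetition time (s).
    oversampling : int
        Samples per TR (>= 1).

    Returns
    -------
    ndarray
        Kernel sampled at ``tr / oversampling`` from t = 0.
    """
    params = params or HRFParams()
    params.validate()
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    dt = tr / oversampling
    t = np.arange(0.0, params.kernel_length + dt / 2, dt)
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    kernel = peak - under / params.undershoot_ratio
    return kernel / kernel.max()


def encoding_kernel(model: str, n_sample_tp: int = 1, n_delay_tp: int = 5) -> np.ndarray:
    """Pre-convolution weights of an encoding model on the TR grid.

    ``sample_only`` loads only the sample time point; ``sample_plus_delay``
    is a unit boxcar over sample and delay; ``decay`` assigns weight n**-2
    to the n-th time point after (and including) sample onset.
    """
    if n_sample_tp <= 0 or n_delay_tp < 0:
        raise ValueError("time point counts must be positive")
    n_total = n_sample_tp + n_delay_tp
    if model == "sample_only":
        return np.ones(n_sample_tp)
    if model == "sample_plus_delay":
        return np.ones(n_total)
    if model == "decay":
        n = np.arange(1, n_total + 1, dtype=float)
        return n**-2
    raise ValueError(f"unknown encoding model {model!r}; expected one of {ENCODING_MODELS}")


def _categories_used(ratings) -> list[str]:
    present = set(str(r) for r in ratings)
    return [c for c in RATING_ORDER if c in present]


def interest_regressors(
    schedule: pd.DataFrame,
    behavior: pd.DataFrame,
    model: str,
    hrf_params: HRFParams | None,
    spec,
    oversampling: int = 16,
) -> tuple[np.ndarray, list[str]]:
    """Build HRF-convolved regressors of interest.

    One encoding column and one test column per response category present in
    ``behavior`` (trials pooled across match/non-match and DMS correctness).
    Columns are constructed per run on an oversampled grid, convolved, then
    decimated back to the TR grid.

    Returns
    -------
    (matrix, names)
        ``matrix`` has ``n_runs * volumes_per_run`` rows; names are
        ``encoding_<cat>`` then ``test_<cat>`` in rating order.
    """
    if len(schedule) != len(behavior):
        raise ValueError("schedule and behavior must have one row per trial")
    tr, osf = spec.tr, int(oversampling)
    dt = tr / osf
    n_hi = spec.volumes_per_run * osf
    run_len = spec.volumes_per_run * tr
    hrf = double_gamma_hrf(hrf_params, tr, osf)
    n_sample_tp = int(round(spec.sample_duration / tr))
    n_delay_tp = int(round(spec.delay_duration / tr))
    kernel = encoding_kernel(model, n_sample_tp, n_delay_tp)

    cats = _categories_used(behavior["smt_rating"])
    names = [f"encoding_{c}" for c in cats] + [f"test_{c}" for c in cats]
    if not cats:
        return np.zeros((spec.n_runs * spec.volumes_per_run, 0)), []
    cat_idx = {c: i for i, c in enumerate(cats)}

    columns = []
    ratings = behavior["smt_rating"].astype(str).to_numpy()
    for run in range(spec.n_runs):
        in_run = schedule["run"].to_numpy() == run
        neural = np.zeros((2 * len(cats), n_hi))  # encoding rows then test rows
        for trial_pos in np.flatnonzero(in_run):
            row = schedule.iloc[trial_pos]
            ci = cat_idx[ratings[trial_pos]]
            s0 = float(row["sample_onset"])
            t0 = float(row["test_onset"])
            if s0 < 0 or t0 + spec.test_duration > run_len:
                raise ValueError(
                    f"trial at sample onset {s0}s extends outside run {run}"
                )
            for j, wj in enumerate(kernel):
                a = int(round((s0 + j * tr) / dt))
                neural[ci, a : a + osf] += wj
            a = int(round(t0 / dt))
            b = int(round((t0 + spec.test_duration) / dt))
            neural[len(cats) + ci, a:b] += 1.0
        conv = np.array([np.convolve(row, hrf)[:n_hi] for row in neural])
        columns.append(conv[:, ::osf].T)
    mat = np.vstack(columns)
    # reorder rows-of-interest blocks into the declared name order
    order = list(range(len(cats))) + [len(cats) + i for i in range(len(cats))]
    return mat[:, order], names


def nuisance_regressors(
    motion: np.ndarray | pd.DataFrame, spec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the nuisance block: run baselines, motion x run, drift x run.

    Motion-by-run interactions use cell-means coding (a per-run copy of each
    motion channel).  Drift columns are a centered unit-step sequence per run
    with its square and cube, each re-centered so every drift column sums to
    zero within its run.

    Returns
    -------
    (matrix, names, dropped)
        ``dropped`` lists all-zero columns (e.g. a motionless channel) that
        were flagged and removed.
    """
    motion = np.asarray(
        motion[list(MOTION_CHANNELS)] if isinstance(motion, pd.DataFrame) else motion,
        dtype=float,
    )
    n_vol = spec.n_runs * spec.volumes_per_run
    if motion.shape != (n_vol, 6):
        raise ValueError(
            f"motion table must be {n_vol} x 6, got {motion.shape}"
        )
    run_of_row = np.repeat(np.arange(spec.n_runs), spec.volumes_per_run)
    n = spec.volumes_per_run
    lin = np.arange(n, dtype=float) - (n - 1) / 2.0

    cols, names = [], []
    for r in range(spec.n_runs):
        cols.append((run_of_row == r).astype(float))
        names.append(f"run_{r}")
    for r in range(spec.n_runs):
        sel = run_of_row == r
        for ci, ch in enumerate(MOTION_CHANNELS):
            col = np.zeros(n_vol)
            col[sel] = motion[sel, ci]
            cols.append(col)
            names.append(f"motion_{ch}_run_{r}")
    for r in range(spec.n_runs):
        sel = run_of_row == r
        for p in (1, 2, 3):
            basis = lin**p
            basis = basis - basis.mean()
            col = np.zeros(n_vol)
            col[sel] = basis
            cols.append(col)
            names.append(f"drift{p}_run_{r}")

    mat = np.column_stack(cols)
    keep = np.any(mat != 0, axis=0)
    dropped = [nm for nm, k in zip(names, keep) if not k]
    return mat[:, keep], [nm for nm, k in zip(names, keep) if k], dropped


def assemble(
    interest: tuple[np.ndarray, list[str]],
    nuisance: tuple[np.ndarray, list[str]],
    spec,
) -> DesignMatrix:
    """Concatenate interest and nuisance blocks, with a full-rank check.

    Raises
    ------
    ValueError
        If the assembled matrix is rank deficient; the message names the
        columns implicated (via pivoted QR).
    """
    i_mat, i_names = interest[0], list(interest[1])
    n_mat, n_names = nuisance[0], list(nuisance[1])
    if i_mat.shape[1] and i_mat.shape[0] != n_mat.shape[0]:
        raise ValueError("interest and nuisance blocks disagree on row count")
    values = np.hstack([i_mat, n_mat]) if i_mat.shape[1] else n_mat
    names = i_names + n_names
    rank = np.linalg.matrix_rank(values)
    if rank < values.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(values, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(values.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(names)) if i >= rank or diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    run_of_row = np.repeat(np.arange(spec.n_runs), spec.volumes_per_run)
    return DesignMatrix(
        values=values,
        column_names=names,
        interest_columns=i_names,
        run_of_row=run_of_row,
    )


def build_design(
    schedule: pd.DataFrame,
    behavior: pd.DataFrame,
    motion,
    model: str,
    spec,
    hrf_params: HRFParams | None = None,
    oversampling: int = 16,
) -> DesignMatrix:
    """Convenience wrapper: interest + nuisance + assembly."""
    interest = interest_regressors(schedule, behavior, model, hrf_params, spec, oversampling)
    nui_mat, nui_names, _ = nuisance_regressors(motion, spec)
    return assemble(interest, (nui_mat, nui_names), spec)
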