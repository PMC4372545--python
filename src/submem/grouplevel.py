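"""Group-level weighted least squares on first-level encoding coefficients.

The group model relates each subject's per-category encoding coefficients to
a linear memory-strength code (ratings 1..4, R mapped to -2..+2), with one
intercept factor per subject.  Rows are weighted by the inverse of the
first-level coefficient variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RATING_ORDER",
    "STRENGTH_CODE",
    "strength_code",
    "StackedGroupData",
    "GroupFit",
    "stack_group_data",
    "fit_wls",
]

#: Subsequent-memory confidence ratings, weakest to strongest.
RATING_ORDER: tuple[str, ...] = ("1", "2", "3", "4", "R")

#: Linear memory-strength code: -2 for "1", +2 for "R", unit steps between.
STRENGTH_CODE: dict[str, int] = {"1": -2, "2": -1, "3": 0, "4": 1, "R": 2}

#: Default cap on inverse-variance weights (guards noiseless synthetic data).
DEFAULT_MAX_WEIGHT = 1e8


def strength_code(rating: str) -> int:
    """Map a subsequent-memory rating to its linear memory-strength code.

    Parameters
    ----------
    rating : str
        One of ``"1", "2", "3", "4", "R"``.

    Returns
    -------
    int
        Code in ``{-2, -1, 0, 1, 2}``.
    """
    try:
        return STRENGTH_CODE[str(rating)]
    except KeyError:
        raise ValueError(
            f"unknown rating {rating!r}; expected one of {RATING_ORDER}"
        ) from None


@dataclass
class StackedGroupData:
    """Per-voxel group regression rows stacked across subjects.

    One row per (subject, used response category).  ``y`` and ``weight`` are
    (n_rows, n_voxels) arrays; ``subject_index`` and ``code`` are shared
    across voxels (the row layout is voxel-invariant).
    """

    y: np.ndarray
    weight: np.ndarray
    subject_index: np.ndarray
    code: np.ndarray
    subjects: list[str]
    categories: list[str]

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.y.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def design(self, code: np.ndarray | None = None) -> np.ndarray:
        """Subject-indicator columns plus the strength-code column."""
        code = self.code if code is None else np.asarray(code, dtype=float)
        X = np.zeros((self.n_rows, self.n_subjects + 1))
        X[np.arange(self.n_rows), self.subject_index] = 1.0
        X[:, -1] = code
        return X

    def to_frame(self, voxel: int = 0) -> pd.DataFrame:
        """Long-format table for one voxel (for TSV export)."""
        return pd.DataFrame(
            {
                "subject": [self.subjects[i] for i in self.subject_index],
                "category": self.categories,
                "code": self.code.astype(int),
                "y": self.y[:, voxel],
                "weight": self.weight[:, voxel],
            }
        )


@dataclass
class GroupFit:
    """Per-voxel slope of BOLD change on the memory-strength scale."""

    slope: np.ndarray
    slope_se: np.ndarray
    t_stat: np.ndarray
    df: int
    n_points: int
    subject_effects: np.ndarray = field(repr=False, default=None)


def stack_group_data(
    tables: dict[str, pd.DataFrame],
    max_weight: float = DEFAULT_MAX_WEIGHT,
) -> StackedGroupData:
    """Stack per-subject encoding-coefficient tables into group rows.

    Parameters
    ----------
    tables : dict
        Maps subject id to a table with columns ``voxel``, ``category``,
        ``beta``, ``beta_var`` (one row per voxel x used category).  All
        subjects must cover the same voxel set.
    max_weight : float
        Cap applied to inverse-variance weights so that zero-variance
        (noiseless) inputs yield finite weights.

    Returns
    -------
    StackedGroupData
    """
    if len(tables) < 2:
        raise ValueError("group model requires at least 2 subjects")
    subjects = sorted(tables)
    voxels = None
    rows_y, rows_w, subj_idx, codes, cats = [], [], [], [], []
    for si, sid in enumerate(subjects):
        tab = tables[sid]
        used = [c for c in RATING_ORDER if c in set(tab["category"].astype(str))]
        if len(used) < 2:
            raise ValueError(f"subject {sid!r} uses fewer than 2 categories")
        for cat in used:
            sub = tab[tab["category"].astype(str) == cat].sort_values("voxel")
            vox = sub["voxel"].to_numpy()
            if voxels is None:
                voxels = vox
            elif not np.array_equal(vox, voxels):
                raise ValueError(f"subject {sid!r} voxel set differs from the first")
            var = sub["beta_var"].to_numpy(dtype=float)
            if np.any(var < 0):
                raise ValueError("negative coefficient variance")
            with np.errstate(divide="ignore"):
                w = np.where(var > 0, 1.0 / np.where(var > 0, var, 1.0), np.inf)
            rows_y.append(sub["beta"].to_numpy(dtype=float))
            rows_w.append(np.minimum(w, max_weight))
            subj_idx.append(si)
            codes.append(strength_code(cat))
            cats.append(cat)
    return StackedGroupData(
        y=np.asarray(rows_y),
        weight=np.asarray(rows_w),
        subject_index=np.asarray(subj_idx, dtype=int),
        code=np.asarray(codes, dtype=float),
        subjects=subjects,
        categories=cats,
    )


def _check_rank(subject_index: np.ndarray, code: np.ndarray, n_subjects: int) -> None:
    for si in range(n_subjects):
        if len(np.unique(code[subject_index == si])) < 2:
            raise ValueError(
                f"subject index {si} has a constant strength code; "
                "the group design is rank deficient"
            )


def fit_wls(
    stacked: StackedGroupData,
    rescale_variance: bool = True,
    code: np.ndarray | None = None,
) -> GroupFit:
    """Fit the weighted least squares group model at every voxel.

    Parameters
    ----------
    stacked : StackedGroupData
    rescale_variance : bool
        If True (default) the coefficient covariance is rescaled by the
        weighted residual variance; if False, weights are taken as exact
        inverse variances (fixed-weights WLS).
    code : array, optional
        Replacement strength-code vector (used by permutation refits).

    Returns
    -------
    GroupFit
    """
    code_vec = stacked.code if code is None else np.asarray(code, dtype=float)
    _check_rank(stacked.subject_index, code_vec, stacked.n_subjects)
    X = stacked.design(code_vec)
    n_rows, n_par = X.shape
    df = n_rows - n_par
    if df <= 0:
        raise ValueError(f"non-positive residual df ({n_rows} rows, {n_par} params)")
    w, y = stacked.weight, stacked.y
    # Batched weighted normal equations; X is shared across voxels.
    A = np.einsum("rv,rp,rq->vpq", w, X, X, optimize=True)
    b = np.einsum("rv,rp->vp", w * y, X)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    fitted = X @ beta.T
    rss_w = np.sum(w * (y - fitted) ** 2, axis=0)
    Ainv = np.linalg.inv(A)
    slope = beta[:, -1]
    scale = rss_w / df if rescale_variance else np.ones_like(rss_w)
    slope_var = scale * Ainv[:, -1, -1]
    slope_se = np.sqrt(slope_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(slope_se > 0, slope / slope_se, 0.0)
    return GroupFit(
        slope=slope,
        slope_se=slope_se,
        t_stat=t,
        df=df,
        n_points=n_rows,
        subject_effects=beta[:, :-1],
    )


def wls_t_stats(stacked: StackedGroupData, code: np.ndarray) -> np.ndarray:
    """Slope t-statistics for a given code vector, via the partialled form.

    Algebraically identical to :func:`fit_wls` with ``rescale_variance=True``
    (the subject factors are projected out in closed form), but much faster
    inside permutation loops.
    """
    code = np.asarray(code, dtype=float)
    w, y = stacked.weight, stacked.y
    si = stacked.subject_index
    n_sub = stacked.n_subjects
    df = stacked.n_rows - (n_sub + 1)
    # Weighted per-subject means of code and response, per voxel.
    S = np.zeros((stacked.n_rows, n_sub))
    S[np.arange(stacked.n_rows), si] = 1.0
    sw = S.T @ w                                  # (n_sub, V)
    swc = S.T @ (w * code[:, None])               # (n_sub, V)
    swy = S.T @ (w * y)                           # (n_sub, V)
    c_tilde = code[:, None] - (swc / sw)[si]
    y_tilde = y - (swy / sw)[si]
    denom = np.sum(w * c_tilde**2, axis=0)
    slope = np.sum(w * c_tilde * y_tilde, axis=0) / denom
    rss_w = np.sum(w * (y_tilde - slope[None] * c_tilde) ** 2, axis=0)
    se = np.sqrt(rss_w / df / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, slope / se, 0.0)
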