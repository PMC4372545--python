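"""Voxel-wise ordinary least squares on BOLD time series.

The design matrix is voxel-invariant within a subject, so the whole-brain
fit reduces to one orthogonal decomposition shared across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designmat import DesignMatrix

__all__ = ["FirstLevelResult", "fit_voxelwise", "encoding_coefficients"]


@dataclass
class FirstLevelResult:
    """Per-voxel coefficients and variances from a shared design.

    ``beta`` and ``beta_var`` are (n_voxels, n_columns); ``sigma2`` is the
    per-voxel residual variance (RSS / df) with ``df = rows - rank(X)``.
    ``voxel_index`` holds flat grid indices when a mask was applied.
    """

    beta: np.ndarray
    beta_var: np.ndarray
    sigma2: np.ndarray
    df: int
    column_names: list[str]
    interest_columns: list[str]
    voxel_index: np.ndarray
    grid_shape: tuple[int, ...] | None = None

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[0]

    @property
    def categories_used(self) -> list[str]:
        return [c.split("_", 1)[1] for c in self.interest_columns
                if c.startswith("encoding_")]


def fit_voxelwise(
    bold: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None
) -> FirstLevelResult:
    """Least-squares fit of the design at every (masked) voxel.

    Parameters
    ----------
    bold : ndarray
        Either a 4D volume (x, y, z, t) or a (t, n_voxels) matrix.
    design : DesignMatrix
    mask : ndarray of bool, optional
        3D voxel mask (4D input only); default all voxels.

    Returns
    -------
    FirstLevelResult
    """
    X = design.values
    grid_shape = None
    if bold.ndim == 4:
        grid_shape = bold.shape[:3]
        Y = bold.reshape(-1, bold.shape[3]).T
        if mask is not None:
            if mask.shape != grid_shape:
                raise ValueError("mask shape does not match the volume grid")
            voxel_index = np.flatnonzero(mask.reshape(-1))
        else:
            voxel_index = np.arange(Y.shape[1])
        Y = Y[:, voxel_index]
    elif bold.ndim == 2:
        Y = bold
        voxel_index = np.arange(Y.shape[1])
    else:
        raise ValueError("bold must be 4D (x,y,z,t) or 2D (t, voxels)")
    if Y.shape[0] != design.n_rows:
        raise ValueError(
            f"bold has {Y.shape[0]} volumes but the design has {design.n_rows} rows"
        )

    Xp = np.linalg.pinv(X)
    rank = np.linalg.matrix_rank(X)
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    beta = (Xp @ Y).T
    resid = Y - X @ beta.T
    rss = np.einsum("tv,tv->v", resid, resid)
    sigma2 = rss / df
    # full column rank (checked at assembly): (X'X)^-1 = Xp Xp'
    xtx_inv_diag = np.einsum("pt,pt->p", Xp, Xp)
    beta_var = sigma2[:, None] * xtx_inv_diag[None, :]
    return FirstLevelResult(
        beta=beta,
        beta_var=beta_var,
        sigma2=sigma2,
        df=int(df),
        column_names=list(design.column_names),
        interest_columns=list(design.interest_columns),
        voxel_index=voxel_index,
        grid_shape=grid_shape,
    )


def encoding_coefficients(result: FirstLevelResult) -> pd.DataFrame:
    """Per-(voxel, category) encoding coefficients and variances.

    Returns a long table with columns ``voxel``, ``category``, ``beta``,
    ``beta_var``; categories with no encoding column are absent.
    """
    frames = []
    for cat in result.categories_used:
        name = f"encoding_{cat}"
        if name not in result.column_names:
            raise KeyError(f"no encoding column for category {cat!r}")
        j = result.column_names.index(name)
        frames.append(
            pd.DataFrame(
                {
                    "voxel": result.voxel_index,
                    "category": cat,
                    "beta": result.beta[:, j],
                    "beta_var": result.beta_var[:, j],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["voxel", "category", "beta", "beta_var"])
    return pd.concat(frames, ignore_index=True)
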