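"""Thresholding, cluster labeling, and permutation max-|t| FWE inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grouplevel import StackedGroupData, fit_wls, wls_t_stats

__all__ = [
    "ThresholdResult",
    "PermutationNull",
    "threshold_map",
    "label_clusters",
    "permutation_fwe",
    "count_exceedances",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ThresholdResult:
    """Signed suprathreshold map at an uncorrected two-tailed alpha."""

    signed_map: np.ndarray  # +1 / -1 / 0
    critical_value: float
    n_positive: int
    n_negative: int

    @property
    def n_flagged(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class PermutationNull:
    """Null distribution of the image-wise maximum |t|."""

    max_abs_t: np.ndarray
    B: int
    scheme: str
    seed: int
    n_redrawn: int = 0
    null_abs_t: np.ndarray | None = None  # (B, V), kept only on request


def threshold_map(t_map: np.ndarray, df: int, alpha: float = 0.01) -> ThresholdResult:
    """Two-tailed uncorrected threshold of a t-map.

    A voxel is flagged when |t| exceeds the two-tailed Student-t critical
    value at ``alpha`` with ``df`` degrees of freedom; positive and negative
    exceedances are counted separately.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df <= 0:
        raise ValueError("df must be positive")
    crit = float(stats.t.ppf(1 - alpha / 2, df))
    t_map = np.asarray(t_map)
    signed = np.zeros(t_map.shape, dtype=np.int8)
    signed[t_map > crit] = 1
    signed[t_map < -crit] = -1
    return ThresholdResult(
        signed_map=signed,
        critical_value=crit,
        n_positive=int(np.sum(signed == 1)),
        n_negative=int(np.sum(signed == -1)),
    )


def label_clusters(
    signed_map: np.ndarray,
    t_map: np.ndarray,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Connected-component clusters of a signed suprathreshold map.

    Components are labeled separately per sign.  Returns one row per
    cluster with its size ``k``, peak |t| voxel, peak coordinate (world
    coordinates when an affine is given), peak t, and sign, sorted by
    descending size.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    rows = []
    for sign in (1, -1):
        labeled, n = ndimage.label(signed_map == sign, structure=structure)
        for lab in range(1, n + 1):
            members = np.argwhere(labeled == lab)
            ts = t_map[tuple(members.T)]
            peak = members[np.argmax(np.abs(ts))]
            coord = peak.astype(float)
            if affine is not None:
                coord = (affine @ np.append(peak, 1.0))[:3]
            rows.append(
                {
                    "sign": sign,
                    "k": len(members),
                    "peak_i": int(peak[0]),
                    "peak_j": int(peak[1]),
                    "peak_k": int(peak[2]),
                    "peak_x": coord[0],
                    "peak_y": coord[1],
                    "peak_z": coord[2],
                    "peak_t": float(ts[np.argmax(np.abs(ts))]),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sign", "k", "peak_i", "peak_j", "peak_k",
            "peak_x", "peak_y", "peak_z", "peak_t",
        ],
    )
    return frame.sort_values("k", ascending=False, ignore_index=True)


def _permute_codes(
    rng: np.random.Generator, stacked: StackedGroupData, scheme: str
) -> np.ndarray:
    code = stacked.code
    if scheme == "global":
        return code[rng.permutation(len(code))]
    if scheme == "within_subject":
        out = code.copy()
        for si in range(stacked.n_subjects):
            idx = np.flatnonzero(stacked.subject_index == si)
            out[idx] = code[idx[rng.permutation(len(idx))]]
        return out
    raise ValueError("scheme must be 'global' or 'within_subject'")


def _valid_permutation(stacked: StackedGroupData, code: np.ndarray) -> bool:
    for si in range(stacked.n_subjects):
        if len(np.unique(code[stacked.subject_index == si])) < 2:
            return False
    return True


def permutation_fwe(
    stacked: StackedGroupData,
    B: int = 1000,
    scheme: str = "global",
    seed: int = 0,
    p_definition: str = "greater",
    keep_null_t: bool = False,
    max_redraws: int = 1000,
) -> tuple[PermutationNull, np.ndarray]:
    """Max-|t| permutation FWE correction of the group slope t-map.

    Per permutation the strength-code vector is shuffled (globally across
    all rows, or within subject), the group model refit at every voxel with
    the same permuted order, and the image-wise maximum |t| recorded.

    Parameters
    ----------
    p_definition : {'greater', 'add_one'}
        'greater': corrected p = proportion of null maxima strictly greater
        than the observed |t| (can be exactly 0).  'add_one': the
        (b + 1) / (B + 1) estimator with weak inequality.

    Returns
    -------
    (PermutationNull, ndarray)
        The null distribution and the per-voxel corrected p-values.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if p_definition not in ("greater", "add_one"):
        raise ValueError("p_definition must be 'greater' or 'add_one'")
    observed = fit_wls(stacked)
    t_obs = np.abs(observed.t_stat)
    rng = np.random.default_rng(seed)
    max_abs = np.empty(B)
    null_t = np.empty((B, stacked.n_voxels)) if keep_null_t else None
    n_redrawn = 0
    for b in range(B):
        for _ in range(max_redraws):
            code = _permute_codes(rng, stacked, scheme)
            if _valid_permutation(stacked, code):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a rank-preserving permutation")
        abs_t = np.abs(wls_t_stats(stacked, code))
        max_abs[b] = abs_t.max()
        if keep_null_t:
            null_t[b] = abs_t
    if p_definition == "greater":
        p = np.mean(max_abs[None, :] > t_obs[:, None], axis=1)
    else:
        p = (np.sum(max_abs[None, :] >= t_obs[:, None], axis=1) + 1) / (B + 1)
    null = PermutationNull(
        max_abs_t=max_abs, B=B, scheme=scheme, seed=seed,
        n_redrawn=n_redrawn, null_abs_t=null_t,
    )
    return null, p


def count_exceedances(
    p_map: np.ndarray, level: float, null: PermutationNull
) -> tuple[int, float | None]:
    """Count voxels at corrected p <= level, with a chance probability.

    The Monte-Carlo probability of observing at least that many labeled
    voxels under permuted data requires the per-permutation |t| maps
    (``keep_null_t=True``); otherwise only the count is returned.
    """
    count = int(np.sum(np.asarray(p_map) <= level))
    if null.null_abs_t is None:
        return count, None
    if count == 0:
        return count, 1.0
    # threshold at which a voxel attains corrected p <= level
    q = np.quantile(null.max_abs_t, 1 - level, method="higher")
    null_counts = np.sum(null.null_abs_t > q, axis=1)
    return count, float(np.mean(null_counts >= count))
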