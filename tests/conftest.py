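import numpy as np
import pandas as pd
import pytest

from submem.designmat import build_design
from submem.firstlevel import encoding_coefficients, fit_voxelwise
from submem.grouplevel import RATING_ORDER
from submem.synthdata import AcquisitionSpec, GroundTruth, simulate_subject

SMALL_GRID = (6, 6, 4)
EFFECT_VOXEL = (2, 2, 1)


def small_spec_factory(**kw):
    kw.setdefault("grid_shape", SMALL_GRID)
    return AcquisitionSpec(**kw)


def effect_block():
    return np.array(
        [[i, j, k] for i in (2, 3) for j in (2, 3) for k in (1, 2)], dtype=int
    )


def make_truth(**kw):
    kw.setdefault("generative_model", "decay")
    kw.setdefault("gamma0", 2.0)
    kw.setdefault("gamma1", 0.5)
    kw.setdefault("noise_sd", 1.0)
    kw.setdefault("effect_voxels", effect_block())
    kw.setdefault("drift_coeffs", np.zeros((8, 3)))
    return GroundTruth(**kw)


@pytest.fixture(scope="session")
def default_spec():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def small_spec():
    return small_spec_factory()


@pytest.fixture(scope="session")
def small_subject(small_spec):
    """One noisy decay-model subject on the small grid (shared, read-only)."""
    return simulate_subject(small_spec, make_truth(), seed=11)


@pytest.fixture(scope="session")
def noiseless_subject(small_spec):
    return simulate_subject(
        small_spec, make_truth(noise_sd=0.0, motion_loading_sd=0.0), seed=7
    )


@pytest.fixture(scope="session")
def small_subject_fit(small_spec, small_subject):
    design = build_design(
        small_subject.schedule,
        small_subject.behavior.trials,
        small_subject.motion,
        "decay",
        small_spec,
    )
    return design, fit_voxelwise(small_subject.bold, design)


def synthetic_coefficient_tables(
    n_subjects: int,
    n_voxels: int,
    seed: int,
    slope: float = 0.0,
    missing: dict[int, list[str]] | None = None,
    var_range: tuple[float, float] = (0.5, 2.0),
):
    """Group-level coefficient tables generated directly (no imaging step).

    y = subject effect + slope * code + noise with per-row variance drawn
    from ``var_range``; heterogeneous variances feed the WLS weights.
    """
    from submem.grouplevel import strength_code

    rng = np.random.default_rng(seed)
    missing = missing or {}
    tables = {}
    for s in range(n_subjects):
        subj_eff = rng.normal(0.0, 1.0)
        cats = [c for c in RATING_ORDER if c not in missing.get(s, [])]
        rows = []
        for c in cats:
            var = rng.uniform(*var_range)
            noise = rng.normal(0.0, np.sqrt(var), size=n_voxels)
            y = subj_eff + slope * strength_code(c) + noise
            for v in range(n_voxels):
                rows.append(
                    {"voxel": v, "category": c, "beta": y[v], "beta_var": var}
                )
        tables[f"sub-{s + 1:02d}"] = pd.DataFrame(rows)
    return tables
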