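import numpy as np
import pandas as pd
import pytest

from punctascreen import (
    Acquisition,
    PhenotypeParams,
    ScreenMatrix,
    extract_profile,
    generate_field,
)


def make_matrix(values, roles=None, plate="plate_01", columns=None) -> ScreenMatrix:
    """Small helper: wrap a 2D array into a ScreenMatrix."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    index = pd.Index([f"s{i:04d}" for i in range(n)], name="strain_id")
    columns = columns if columns is not None else [f"f{j}" for j in range(p)]
    roles = roles if roles is not None else ["reference"] * min(2, n) + ["inlier"] * max(0, n - 2)
    meta = pd.DataFrame({"plate_id": plate, "role": roles}, index=index)
    return ScreenMatrix(features=pd.DataFrame(values, index=index, columns=columns), meta=meta)


@pytest.fixture(scope="session")
def small_acq() -> Acquisition:
    return Acquisition(field_px=256)


@pytest.fixture(scope="session")
def clean_params() -> PhenotypeParams:
    """Noise-free field with well-separated, fixed-count puncta."""
    return PhenotypeParams(
        cells_per_field=8,
        puncta_per_cell=3,
        puncta_radius_px=(1.5, 0.1),
        min_separation_px=14.0,
        diffuse_fraction=0.0,
        photon_noise=False,
        read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_field(clean_params, small_acq):
    return generate_field(clean_params, small_acq, seed=42)


@pytest.fixture(scope="session")
def noisy_profile(small_acq):
    params = PhenotypeParams(cells_per_field=8)
    stack, _ = generate_field(params, small_acq, seed=7)
    return extract_profile(stack, strain_id="s0001", plate_id="plate_01")
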