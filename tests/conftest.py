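"""Shared fixtures: small synthetic datasets reused across test modules.

Session scope keeps the profile-spectrum pipeline (the slowest stage) to a
single run for all tests that inspect its output.
"""

import numpy as np
import pandas as pd
import pytest

from chordomics.references import nedc_principal_mz
from chordomics.synthetic import generate_geomx, generate_msi, generate_msi_cohort
from chordomics.geomx_preprocess import preprocess_geomx
from chordomics.msi_preprocess import preprocess_msi


@pytest.fixture(scope="session")
def geomx_small():
    pcm, meta, gt = generate_geomx(n_samples=10, n_genes=800, seed=7)
    return pcm, meta, gt


@pytest.fixture(scope="session")
def geomx_processed(geomx_small):
    pcm, meta, gt = geomx_small
    return preprocess_geomx(pcm, meta), gt


@pytest.fixture(scope="session")
def msi_small():
    """16x16 grid, 12 species, planted affine drift (5 + 0.01*m ppm)."""
    ds, gt = generate_msi(grid_w=16, grid_h=16, n_species=12,
                          drift_ppm=(5.0, 0.01), noise_sd=1.0, seed=3)
    return ds, gt


@pytest.fixture(scope="session")
def msi_processed(msi_small):
    ds, gt = msi_small
    refs = np.array([sp["mz"] for sp in gt.lipid_species])
    res = preprocess_msi(ds, calibration_refs=refs,
                         principal_mz=nedc_principal_mz(), seed=0)
    return res, gt


@pytest.fixture(scope="session")
def msi_cohort():
    mats, pmeta, gt = generate_msi_cohort(seed=5)
    return mats, pmeta, gt


@pytest.fixture(scope="session")
def cohort_region_means(msi_cohort):
    from chordomics.msi_analysis import region_means

    mats, pmeta, gt = msi_cohort
    big = pd.concat(mats)
    return region_means(big, pmeta["sample_id"], pmeta["region"]), pmeta, gt
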