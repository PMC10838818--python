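import sys
from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage

sys.path.insert(0, str(Path(__file__).parent))

from hepavess import (
    Mask,
    PhantomParams,
    Volume,
    generate_case,
    run_wang_pipeline,
)

# study conditions for the pipeline phantoms: anisotropic clinical-like
# grid, mild noise, mild blur (a "clean" arterial-phase scan)
CLEAN = dict(shape=(64, 64, 48), spacing=(1.0, 1.0, 2.0),
             noise_sigma=2.0, blur_fwhm=1.0)


@pytest.fixture(scope="session")
def clean_case():
    return generate_case(PhantomParams(seed=5, **CLEAN))


@pytest.fixture(scope="session")
def vein_case():
    return generate_case(PhantomParams(seed=5, confounders=("vein",), **CLEAN))


@pytest.fixture(scope="session")
def wang_mask_clean(clean_case):
    """One full classical-pipeline run, shared by the slow tests."""
    return run_wang_pipeline(clean_case.image)


@pytest.fixture(scope="session")
def wang_mask_vein(vein_case):
    return run_wang_pipeline(vein_case.image)


def soft_maps(case, sigma_vox=0.7):
    """Ground-truth-derived fine/coarse probability maps for a phantom."""
    from hepavess import resample

    fine = Volume(
        ndimage.gaussian_filter(
            case.vessel_mask.data.astype(np.float32), sigma_vox
        ),
        case.vessel_mask.spacing,
    )
    coarse = resample(fine, 2.0, order=1)
    return fine, coarse


def n_components_26(mask: Mask) -> int:
    _, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    return int(n)
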