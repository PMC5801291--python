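import numpy as np
import pytest

from ppmcompare import (
    BrainMask,
    StatVolume,
    SubjectImageSet,
    SyntheticSpec,
    VolumeGrid,
    generate_subject_images,
)


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid.from_spacing((12, 12, 10), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def strong_blob_images():
    """A small dataset with a strong dense effect: every inference method
    (including Bayes at tau = 5) produces a nonempty activation."""
    grid = VolumeGrid.from_spacing((20, 20, 16), (2.0, 2.0, 2.0))
    spec = SyntheticSpec(
        grid=grid,
        n_subjects=16,
        smooth_fwhm_voxels=3.0,
        blobs=({"center_voxel": (10, 10, 8), "radius_voxels": 5.0, "d_true": 2.5},),
        mask_shape="ellipsoid",
        seed=7,
    )
    images, truth = generate_subject_images(spec)
    return images, truth


def glm_from_arrays(beta, var, n, grid=None, mask=None):
    """Build a GroupGLMResult directly from chosen per-voxel moments."""
    from ppmcompare.classical import GroupGLMResult

    beta = np.asarray(beta, dtype=float)
    var = np.asarray(var, dtype=float)
    if grid is None:
        grid = VolumeGrid.from_spacing(beta.shape, (1.0, 1.0, 1.0))
    if mask is None:
        mask = BrainMask(grid, np.ones(beta.shape, bool))
    t = np.zeros_like(beta)
    ok = var > 0
    t[ok] = beta[ok] / np.sqrt(var[ok] / n)
    return GroupGLMResult(
        beta_hat=StatVolume(grid, beta, "contrast"),
        resid_var=StatVolume(grid, var, "contrast"),
        tmap=StatVolume(grid, t, "t"),
        df=n - 1,
        n=n,
        mask=mask,
    )
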