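"""Shared fixtures: synthetic image fixtures and printed reference data."""

import numpy as np
import pytest

import scaffdeg as sd

#: Published confusion matrix of the pixel classifier on a labelled
#: micrograph, rows/columns in (collagen, ECM, nuclei, background) order.
TABLE2_PAPER_ORDER = np.array([
    [5727, 220, 25, 10],
    [92, 5630, 36, 16],
    [7, 90, 1073, 4],
    [1, 7, 9, 6361],
])

def table2_package_order() -> np.ndarray:
    """Reindex the printed counts into the package label encoding."""
    # paper order -> package label of each paper row/column
    paper_labels = [sd.LABEL_COLLAGEN, sd.LABEL_ECM, sd.LABEL_NUCLEI,
                    sd.LABEL_BACKGROUND]
    out = np.zeros((4, 4), dtype=np.int64)
    for i, li in enumerate(paper_labels):
        for j, lj in enumerate(paper_labels):
            out[li, lj] = TABLE2_PAPER_ORDER[i, j]
    return out


#: Two-component logistic mixture estimates published for the
#: osteogenic-medium (CCO) and plain-medium (CCT) groups:
#: (A1, mu1, scal1, A2, mu2, scal2) in % and days.
CCO_THETA = (50.223, 1.7340, 1.0000, 23.463, 16.261, 1.3233)
CCT_THETA = (52.502, 2.4768, 1.1546, 21.653, 16.881, 3.6554)

#: Published multivariate mass-loss model coefficients (CCO reference).
TABLE4_COEFFS = {
    "intercept": -17.0396, "CCT": -0.215, "CO": -2.1751,
    "ln_circularity": -0.0599, "ln_mode": 3.7804, "ln_area": 0.1760,
}


def noiseless_textures():
    """Four flat, well-separated class colours (no texture noise)."""
    return tuple(sd.synthetic.ClassTexture(c, noise_sd=0.0)
                 for c in ((245.0, 245.0, 245.0), (230.0, 150.0, 180.0),
                           (170.0, 110.0, 200.0), (70.0, 45.0, 120.0)))


@pytest.fixture(scope="session")
def noiseless_fixture():
    """A texture-noise-free micrograph: classes are flat colours, hence
    exactly separable by intensity."""
    params = sd.SyntheticImageParams(
        width_px=96, height_px=96, seed=11,
        class_fractions=(0.2, 0.35, 0.35, 0.1),
        textures=noiseless_textures())
    micro, mask = sd.generate_micrograph(params)
    return micro, mask


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_fixture):
    micro, _ = noiseless_fixture
    return sd.build_feature_stack(micro)


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard textured fixture: default H&E-like palette, whose
    class luma ranges overlap — thresholding cannot fully separate them."""
    params = sd.SyntheticImageParams(width_px=96, height_px=96, seed=7,
                                     class_fractions=(0.2, 0.35, 0.35, 0.1))
    micro, mask = sd.generate_micrograph(params)
    return micro, mask


@pytest.fixture(scope="session")
def standard_stack(standard_fixture):
    micro, _ = standard_fixture
    return sd.build_feature_stack(micro)


#: Threshold cut points at the midpoints of the default palette's class
#: luma levels, bands mapped dark->bright as nuclei, ECM, collagen,
#: background.
STANDARD_CUTS = (115.0, 170.0, 213.0)
STANDARD_BAND_LABELS = (sd.LABEL_NUCLEI, sd.LABEL_ECM, sd.LABEL_COLLAGEN,
                        sd.LABEL_BACKGROUND)
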