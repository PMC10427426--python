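import numpy as np
import pytest

from trialomics import her2_spatial as hs
from trialomics import synthetic_data as sd


@pytest.fixture(scope="session")
def small_ihc_cohort():
    """A reduced two-group slide cohort (4 slides) shared by
    image-pipeline tests.  Slides keep the full 512 px size: the
    tissue detector's minimum-area rule (1,500 downsampled px) makes
    smaller rasters degenerate by construction."""
    cfg = sd.SyntheticCohortConfig(n_slides_per_group=2)
    return sd.gen_ihc_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_cohort_patches(small_ihc_cohort):
    """Patches and per-patch planted class for the reduced cohort."""
    patches, true_class = [], []
    for slide in small_ihc_cohort.slides:
        mask = hs.detect_tissue(slide)
        ps = hs.extract_patches(slide, mask)
        truth = small_ihc_cohort.truths[slide.slide_id]
        patches.extend(ps)
        true_class.extend(truth.class_of_patch(p.origin) for p in ps)
    return patches, np.asarray(true_class)


@pytest.fixture(scope="session")
def variant_cohort():
    return sd.gen_paired_variants(seed=11)


def textured_disc_slide(seed=0, size=1024, radius=200, sd_tex=12.0, speck=None):
    """A brightfield-like slide with one textured disc of tissue on a
    blank background; texture is spatially correlated at nucleus scale
    so it survives the x8 downsample.  ``speck`` optionally adds a
    second textured disc of the given full-resolution radius."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    disc = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    tex = ndimage.gaussian_filter(rng.standard_normal((size, size)), 5)
    tex *= sd_tex / tex.std()
    img = np.full((size, size), 200.0)
    img[disc] += tex[disc]
    if speck is not None:
        sp = (yy - 60) ** 2 + (xx - 60) ** 2 <= speck**2
        img[sp] += tex[sp] * 3.0
        disc_sp = sp
    else:
        disc_sp = None
    img += rng.standard_normal((size, size))
    rgb = np.clip(img, 0, 255).astype(np.uint8)[..., None].repeat(3, axis=2)
    slide = hs.SlideImage(pixels=rgb, slide_id="disc")
    return slide, disc, disc_sp
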