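"""Whole-slide HER2 IHC patch pipeline.

Stages, in running order: texture-based tissue detection on a x8
downsample of the slide; extraction of non-overlapping, grid-aligned
64 x 64 px patches inside tissue (and inside annotated regions of
interest when provided) with black/white patch filtering; per-patch
appearance descriptors (a handcrafted stain/texture/nuclei descriptor
by default, with a pluggable interface for CNN embeddings);
mini-batch k-means over all slides' patches with Davies-Bouldin model
selection across a range of cluster counts; per-slide cluster
proportion vectors; and a per-cluster Mann-Whitney U association of
those proportions with binary response, Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Protocol, Sequence

import numpy as np
from scipy import ndimage, stats
from shapely.geometry import Polygon, box
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import davies_bouldin_score
from statsmodels.stats.multitest import multipletests

from .nuclei_morphometrics import (
    DEFAULT_BASIS,
    SegmentationConfig,
    StainBasis,
    deconvolve,
    segment_nuclei,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SlideImage",
    "TissueMask",
    "Patch",
    "PatchFeatureMatrix",
    "ClusterModel",
    "SlideClusterProfile",
    "ClusterAssociation",
    "TissueConfig",
    "HandcraftedDescriptor",
    "detect_tissue",
    "extract_patches",
    "compute_descriptors",
    "fit_clusters",
    "select_k",
    "slide_profile",
    "associate_clusters",
    "benjamini_hochberg",
    "PATCH_SIZE",
]

PATCH_SIZE = 64

# Law's 1-D texture kernels (level, edge, spot); the tissue detector
# uses the separable spot-spot combination.
LAW_L5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
LAW_E5 = np.array([-1.0, -2.0, 0.0, 2.0, 1.0])
LAW_S5 = np.array([-1.0, 0.0, 2.0, 0.0, -1.0])


@dataclass
class SlideImage:
    """An RGB brightfield slide with physical scale and optional ROIs.

    ``rois`` is a list of polygons, each a sequence of (x, y) pixel
    vertices at full resolution.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    microns_per_pixel: float = 0.325
    slide_id: str = ""
    rois: Optional[list[Sequence[tuple[float, float]]]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 RGB raster")
        if min(self.pixels.shape[:2]) < 64:
            raise ValueError("slide must be at least 64 px on each side")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")


@dataclass
class TissueMask:
    mask: np.ndarray  # boolean, downsampled grid
    downsample_factor: int = 8


@dataclass
class Patch:
    slide_id: str
    origin: tuple[int, int]  # (row, col), full resolution, 0-based
    pixels: np.ndarray  # PATCH_SIZE x PATCH_SIZE x 3
    size: int = PATCH_SIZE


@dataclass
class PatchFeatureMatrix:
    """Z-scored descriptor rows, one per retained patch (all slides).

    ``slide_ids`` aligns rows to slides; ``feature_mean``/``feature_sd``
    record the normalisation applied; near-constant features
    (s.d. < 1e-12) are dropped, and ``kept_features`` indexes the
    surviving columns of the raw descriptor.
    """

    features: np.ndarray
    slide_ids: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    kept_features: np.ndarray


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    seed: int
    db_index: float
    labels: np.ndarray
    degenerate: bool = False
    estimator: Optional[MiniBatchKMeans] = None


@dataclass
class SlideClusterProfile:
    """Per-slide vector of cluster proportions V with V[c] the fraction
    of the slide's patches assigned label c."""

    slide_id: str
    v: np.ndarray
    n_patches: int


@dataclass
class ClusterAssociation:
    cluster: int
    p_value: float
    q_value: float
    direction: int  # sign of median(responders) - median(non-responders)


@dataclass(frozen=True)
class TissueConfig:
    """Parameters of the texture-based tissue detector."""

    downsample: int = 8
    mean_window: int = 30
    energy_window: int = 15
    energy_threshold: float = 20.0
    min_area: int = 1500


def _grayscale(rgb: np.ndarray) -> np.ndarray:
    """Rec.601 luma from 8-bit RGB."""
    rgb = np.asarray(rgb, dtype=float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _block_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean over factor x factor blocks, edge-padding to a multiple of
    the factor so output dims are ceil(dims / factor)."""
    h, w = img.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    h2, w2 = img.shape
    return img.reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))


def _law_energy(img: np.ndarray, k_row: np.ndarray, k_col: np.ndarray, window: int) -> np.ndarray:
    """Law's texture energy: separable convolution followed by a local
    average of absolute responses."""
    resp = ndimage.convolve1d(img, k_row, axis=0, mode="reflect")
    resp = ndimage.convolve1d(resp, k_col, axis=1, mode="reflect")
    return ndimage.uniform_filter(np.abs(resp), size=window, mode="reflect")


def detect_tissue(slide: SlideImage, config: TissueConfig = TissueConfig()) -> TissueMask:
    """Texture-based tissue detection.

    Downsample x8 -> grayscale -> subtract the 30 x 30 local mean ->
    Law's spot (S5'S5) texture energy with 15 x 15 averaging ->
    threshold energy > 20 -> fill interior holes (4-connected) -> drop
    components with area <= 1500 downsampled pixels.
    """
    gray = _grayscale(slide.pixels)
    small = _block_downsample(gray, config.downsample)
    if min(small.shape) < config.mean_window:
        raise ValueError("slide smaller than the local-mean window after downsampling")
    centered = small - ndimage.uniform_filter(small, size=config.mean_window, mode="reflect")
    energy = _law_energy(centered, LAW_S5, LAW_S5, config.energy_window)
    binary = energy > config.energy_threshold
    binary = ndimage.binary_fill_holes(binary)  # 4-connected structure by default
    labels, n = ndimage.label(binary)  # 4-connectivity
    if n:
        areas = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = areas[1:] > config.min_area
        binary = keep[labels]
    return TissueMask(mask=binary, downsample_factor=config.downsample)


def _roi_fraction(origin: tuple[int, int], size: int, polys: list[Polygon]) -> float:
    r, c = origin
    patch_box = box(c, r, c + size, r + size)
    inter = sum(p.intersection(patch_box).area for p in polys)
    return min(inter / patch_box.area, 1.0)


def extract_patches(
    slide: SlideImage,
    mask: TissueMask,
    tissue_fraction: float = 0.5,
    black_level: int = 2,
    white_level: int = 250,
    black_fraction: float = 0.70,
    white_fraction: float = 0.80,
) -> list[Patch]:
    """Grid-aligned non-overlapping 64 x 64 patches inside tissue.

    A patch is kept when at least ``tissue_fraction`` of its footprint
    maps into the tissue mask (and into the ROI polygons when the slide
    carries any), then discarded when strictly more than 70% of its RGB
    values (all three channels jointly) are below 2 (black patch) or
    strictly more than 80% are above 250 (white patch).
    """
    h, w = slide.pixels.shape[:2]
    f = mask.downsample_factor
    polys = None
    if slide.rois:
        polys = [Polygon(ring) for ring in slide.rois]
    patches: list[Patch] = []
    for r in range(0, h - PATCH_SIZE + 1, PATCH_SIZE):
        for c in range(0, w - PATCH_SIZE + 1, PATCH_SIZE):
            sub = mask.mask[r // f : (r + PATCH_SIZE) // f, c // f : (c + PATCH_SIZE) // f]
            if sub.size == 0 or sub.mean() < tissue_fraction:
                continue
            if polys is not None and _roi_fraction((r, c), PATCH_SIZE, polys) < tissue_fraction:
                continue
            tile = slide.pixels[r : r + PATCH_SIZE, c : c + PATCH_SIZE]
            frac_black = np.mean(tile < black_level)
            frac_white = np.mean(tile > white_level)
            if frac_black > black_fraction or frac_white > white_fraction:
                continue
            patches.append(Patch(slide_id=slide.slide_id, origin=(r, c), pixels=tile))
    return patches


class DescriptorExtractor(Protocol):
    """Deterministic fixed-dimension patch descriptor.

    The CNN embedding of the original analysis (1,024-d truncated
    ResNet50 features) plugs in through this interface; the package
    ships a handcrafted stain/texture/nuclei descriptor as default.
    """

    dim: int

    def __call__(self, pixels: np.ndarray) -> np.ndarray: ...


_DAB_QUANTS = (0.1, 0.25, 0.5, 0.75, 0.9)


class HandcraftedDescriptor:
    """Handcrafted per-patch descriptor (14 dimensions).

    Concatenates DAB optical-density statistics (mean, s.d. and five
    quantiles), hematoxylin OD mean and s.d., two Law's texture
    energies (S5S5 spot and E5E5 edge) of the centred grayscale tile,
    and a nuclei block from the classical segmenter: the square root
    of the nucleus count (variance-stabilised), the square root of the
    mean nucleus area (a size axis), and the mean within-nucleus DAB
    tile OD (the patch DAB mean stands in when no nucleus was found,
    keeping the feature continuous).
    """

    def __init__(
        self,
        basis: StainBasis = DEFAULT_BASIS,
        seg_config: Optional[SegmentationConfig] = None,
        include_nuclei: bool = True,
    ) -> None:
        self.basis = basis
        self.seg_config = seg_config or SegmentationConfig()
        self.include_nuclei = include_nuclei
        self.dim = (2 + len(_DAB_QUANTS)) + 2 + 2 + (3 if include_nuclei else 0)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        h_od, d_od = deconvolve(pixels, self.basis)
        feats: list[float] = [float(d_od.mean()), float(d_od.std())]
        feats.extend(float(q) for q in np.quantile(d_od, _DAB_QUANTS))
        feats.append(float(h_od.mean()))
        feats.append(float(h_od.std()))
        gray = _grayscale(pixels)
        centered = gray - gray.mean()
        for kr, kc in ((LAW_S5, LAW_S5), (LAW_E5, LAW_E5)):
            resp = ndimage.convolve1d(centered, kr, axis=0, mode="reflect")
            resp = ndimage.convolve1d(resp, kc, axis=1, mode="reflect")
            feats.append(float(np.abs(resp).mean()))
        if self.include_nuclei:
            nuclei = segment_nuclei(h_od, self.seg_config, dab_od=d_od)
            if nuclei:
                feats.append(math.sqrt(len(nuclei)))
                feats.append(math.sqrt(float(np.mean([n.area for n in nuclei]))))
                feats.append(float(np.mean([n.dab_tile_mean for n in nuclei])))
            else:
                feats.extend([0.0, 0.0, float(d_od.mean())])
        return np.asarray(feats, dtype=float)


def compute_descriptors(
    patches: Sequence[Patch],
    extractor: Optional[DescriptorExtractor] = None,
    sd_floor: float = 1e-12,
) -> PatchFeatureMatrix:
    """Descriptor matrix over all patches of all slides, z-scored
    per feature; near-constant features are dropped (and logged)
    rather than divided by a vanishing s.d."""
    if not patches:
        raise ValueError("need at least one patch")
    if extractor is None:
        extractor = HandcraftedDescriptor()
    # canonical row order makes the whole pipeline invariant to the
    # order slides (and their patches) arrive in
    patches = sorted(patches, key=lambda p: (p.slide_id, p.origin))
    rows = []
    for p in patches:
        row = np.asarray(extractor(p.pixels), dtype=float)
        if row.shape != (extractor.dim,):
            raise ValueError(
                f"descriptor dimension mismatch: got {row.shape}, expected ({extractor.dim},)"
            )
        rows.append(row)
    raw = np.stack(rows)
    if not np.isfinite(raw).all():
        raise ValueError("descriptor produced non-finite values")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    kept = np.flatnonzero(sd >= sd_floor)
    if kept.size < raw.shape[1]:
        logger.info("dropping %d near-constant feature(s)", raw.shape[1] - kept.size)
    feats = (raw[:, kept] - mean[kept]) / sd[kept]
    return PatchFeatureMatrix(
        features=feats,
        slide_ids=[p.slide_id for p in patches],
        feature_mean=mean,
        feature_sd=sd,
        kept_features=kept,
    )


def fit_clusters(
    features: PatchFeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    batch_size: int = 1024,
    max_iter: int = 100,
    n_init: int = 10,
) -> ClusterModel:
    """Mini-batch k-means with k-means++ init and a fixed seed."""
    x = features.features if isinstance(features, PatchFeatureMatrix) else np.asarray(features)
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.shape[0] < k:
        raise ValueError(f"k={k} exceeds number of rows {x.shape[0]}")
    est = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        max_iter=max_iter,
        n_init=n_init,
        init="k-means++",
    )
    labels = est.fit_predict(x)
    degenerate = len(np.unique(labels)) < k
    if degenerate:
        db = float("inf")
        logger.warning("degenerate fit: only %d distinct labels for k=%d",
                       len(np.unique(labels)), k)
    else:
        db = float(davies_bouldin_score(x, labels))
    return ClusterModel(
        k=k, centroids=est.cluster_centers_, seed=seed, db_index=db,
        labels=labels, degenerate=degenerate, estimator=est,
    )


def select_k(
    features: PatchFeatureMatrix | np.ndarray,
    k_range: Sequence[int] = range(7, 13),
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, ClusterModel]:
    """Fit every k in ``k_range`` and return the fit minimising the
    Davies-Bouldin index, ties broken toward the smaller k."""
    best: Optional[ClusterModel] = None
    for k in k_range:
        model = fit_clusters(features, k, seed=seed, **fit_kwargs)
        if best is None or model.db_index < best.db_index:
            best = model
    if best is None:
        raise ValueError("empty k_range")
    return best.k, best


def slide_profile(labels: Sequence[int], k: int, slide_id: str = "") -> SlideClusterProfile:
    """Proportion of a slide's patches carrying each cluster label:
    V[c] = (1/N) sum 1{L == c}."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("slide has no patches")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("labels must lie in {0..k-1}")
    counts = np.bincount(labels, minlength=k)
    return SlideClusterProfile(slide_id=slide_id, v=counts / labels.size, n_patches=labels.size)


def profiles_from_labels(
    labels: np.ndarray, slide_ids: Sequence[str], k: int
) -> list[SlideClusterProfile]:
    """Group pooled patch labels by slide into cluster profiles,
    ordered by first appearance of each slide."""
    seen: dict[str, list[int]] = {}
    for lab, sid in zip(labels, slide_ids):
        seen.setdefault(sid, []).append(int(lab))
    return [slide_profile(v, k, slide_id=sid) for sid, v in seen.items()]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have at most ``exact_max``
    observations and the data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max and len(y) <= exact_max and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def associate_clusters(
    profiles: Sequence[SlideClusterProfile],
    response: dict[str, bool] | Sequence[bool],
) -> list[ClusterAssociation]:
    """Per-cluster association between cluster proportion and response.

    For each cluster, a two-sided Mann-Whitney U compares that
    cluster's slide proportions between responders and non-responders;
    p-values are Benjamini-Hochberg adjusted across the k clusters, and
    the direction is the sign of median(responders) minus
    median(non-responders).
    """
    if isinstance(response, dict):
        resp = np.array([bool(response[p.slide_id]) for p in profiles])
    else:
        resp = np.asarray(response, dtype=bool)
        if resp.size != len(profiles):
            raise ValueError("response labels must align with profiles")
    if resp.sum() < 2 or (~resp).sum() < 2:
        raise ValueError("need at least two slides per response group")
    v = np.stack([p.v for p in profiles])
    k = v.shape[1]
    ps = []
    dirs = []
    for c in range(k):
        a = v[resp, c]
        b = v[~resp, c]
        if np.ptp(v[:, c]) < 1e-15:
            ps.append(1.0)
        else:
            _, p = mann_whitney_u(a, b)
            ps.append(p)
        dirs.append(int(np.sign(np.median(a) - np.median(b))))
    qs = benjamini_hochberg(ps)
    return [
        ClusterAssociation(cluster=c, p_value=ps[c], q_value=float(qs[c]), direction=dirs[c])
        for c in range(k)
    ]
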