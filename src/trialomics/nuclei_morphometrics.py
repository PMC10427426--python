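"""Stain deconvolution and classical nuclei morphometrics for
brightfield IHC (hematoxylin counterstain + DAB chromogen).

The deconvolution converts RGB transmittance to optical density (OD)
per Beer-Lambert and unmixes it onto a two-stain basis by least
squares.  Nuclei are segmented classically: Otsu threshold on the
hematoxylin OD map, watershed split on the distance transform, then
shape filters on perimeter and circularity.  A greedy centroid
deduplication drops any nucleus detected within 20 px of an already
kept one, and per-nucleus shape/intensity features are averaged within
the 64 px analysis patches that contain each centroid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "StainBasis",
    "Nucleus",
    "PatchNucleiSummary",
    "SegmentationConfig",
    "deconvolve",
    "segment_nuclei",
    "dedup_nuclei",
    "summarize_patches",
    "DEFAULT_BASIS",
]


class CollinearBasisError(ValueError):
    """Stain vectors too close to collinear to unmix."""


@dataclass(frozen=True)
class StainBasis:
    """Unit optical-density vectors of the two stains in RGB space.

    Defaults are the classical hematoxylin / DAB vectors of
    Ruifrok-Johnston colour deconvolution; ``i0`` is the background
    (blank glass) transmitted intensity per channel.
    """

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    dab: tuple[float, float, float] = (0.268, 0.570, 0.776)
    i0: float = 255.0

    def matrix(self) -> np.ndarray:
        h = np.asarray(self.hematoxylin, dtype=float)
        d = np.asarray(self.dab, dtype=float)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        cosang = abs(float(np.dot(h, d)))
        if cosang > math.cos(math.radians(10.0)):
            raise CollinearBasisError("stain vectors are within 10 degrees of collinear")
        return np.stack([h, d], axis=1)  # 3 x 2


DEFAULT_BASIS = StainBasis()


@dataclass
class Nucleus:
    """A segmented nucleus with shape and DAB-intensity features.

    ``circularity`` is 4*pi*area / perimeter**2 (1 for a perfect disc);
    ``dab_tile_mean`` is the mean DAB OD within a 30 um diameter disc
    centred on the centroid (NaN when no DAB map was supplied).
    """

    centroid: tuple[float, float]  # (row, col) pixels
    area: float
    perimeter: float
    circularity: float
    dab_tile_mean: float = float("nan")
    mask: Optional[np.ndarray] = None
    label: int = 0


@dataclass
class PatchNucleiSummary:
    """Nuclei statistics aggregated over one 64 px analysis patch."""

    origin: tuple[int, int]  # (row, col) of the patch's top-left pixel
    nuclei_count: int
    mean_area: float = float("nan")
    mean_perimeter: float = float("nan")
    mean_circularity: float = float("nan")
    mean_dab_tile: float = float("nan")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the classical segmenter and its post-filters.

    The perimeter bounds and circularity floor mirror the artifact
    filters applied downstream of segmentation; they are configurable
    because no canonical values exist, and the values used are logged
    on every call.
    """

    min_perimeter: float = 8.0
    max_perimeter: float = 300.0
    min_circularity: float = 0.25
    min_area: int = 12
    min_peak_distance: int = 4
    microns_per_pixel: float = 0.325
    dedup_radius_px: float = 20.0


def deconvolve(
    pixels: np.ndarray, basis: StainBasis = DEFAULT_BASIS
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB image into (hematoxylin OD, DAB OD) maps.

    OD = -log10((I + eps) / I0) per channel with eps = 1 (8-bit
    counts), projected onto the stain basis by least squares; negative
    stain amounts are clipped to zero.
    """
    m = basis.matrix()
    img = np.asarray(pixels, dtype=float)
    od = -np.log10((img + 1.0) / basis.i0)
    flat = od.reshape(-1, 3)
    # least-squares projection onto the two stain vectors
    coeffs, *_ = np.linalg.lstsq(m, flat.T, rcond=None)
    coeffs = np.clip(coeffs, 0.0, None)
    h = coeffs[0].reshape(img.shape[:2])
    d = coeffs[1].reshape(img.shape[:2])
    return h, d


def _disc_mean(img: np.ndarray, center: tuple[float, float], radius_px: float) -> float:
    """Mean of ``img`` over a disc clipped at the image borders."""
    r0, c0 = center
    rad = int(math.ceil(radius_px))
    rlo, rhi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    if rlo >= rhi or clo >= chi:
        return float("nan")
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    if not inside.any():
        return float("nan")
    return float(img[rlo:rhi, clo:chi][inside].mean())


def segment_nuclei(
    hematoxylin_od: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    dab_od: Optional[np.ndarray] = None,
) -> list[Nucleus]:
    """Segment nuclei on a hematoxylin OD map.

    Pipeline: Otsu threshold on the OD -> connected components ->
    watershed split on the distance transform -> perimeter bounds and
    circularity floor.  When a DAB OD map is supplied, each nucleus
    also gets the mean DAB OD within a 30 um diameter disc around its
    centroid (diameter rounded to the nearest odd pixel count).
    """
    od = np.asarray(hematoxylin_od, dtype=float)
    if not np.isfinite(od).all():
        raise ValueError("hematoxylin OD map contains non-finite values")
    logger.debug(
        "segment_nuclei filters: perimeter in [%g, %g], circularity >= %g",
        config.min_perimeter, config.max_perimeter, config.min_circularity,
    )
    if od.max() <= 0 or np.ptp(od) < 1e-9:
        return []
    thr = threshold_otsu(od)
    fg = od > thr
    if not fg.any():
        return []
    fg = ndimage.binary_fill_holes(fg)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=config.min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(od, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndimage.label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)

    # 30 um disc radius in pixels, odd-diameter rounding
    diam_px = 30.0 / config.microns_per_pixel
    diam_px = 2 * round((diam_px - 1) / 2) + 1
    radius_px = diam_px / 2.0

    nuclei: list[Nucleus] = []
    for prop in regionprops(labels):
        if prop.area < config.min_area:
            continue
        perim = float(prop.perimeter)
        if perim <= 0 or not (config.min_perimeter <= perim <= config.max_perimeter):
            continue
        circ = min(4.0 * math.pi * prop.area / perim**2, 1.0 + 1e-6)
        if circ < config.min_circularity:
            continue
        dab_mean = float("nan")
        if dab_od is not None:
            dab_mean = _disc_mean(np.asarray(dab_od, float), prop.centroid, radius_px)
        nuclei.append(
            Nucleus(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=float(prop.area),
                perimeter=perim,
                circularity=float(circ),
                dab_tile_mean=dab_mean,
                label=int(prop.label),
            )
        )
    return nuclei


def dedup_nuclei(
    nuclei: Sequence[Nucleus], radius_px: float = 20.0, presorted: bool = False
) -> list[Nucleus]:
    """Greedy centroid deduplication.

    Nuclei are processed in a deterministic order (descending area,
    then raster order of centroids, unless ``presorted``); a nucleus is
    dropped when its centroid lies strictly within ``radius_px``
    (Euclidean) of any previously kept centroid.
    """
    if presorted:
        ordered = list(nuclei)
    else:
        ordered = sorted(nuclei, key=lambda n: (-n.area, n.centroid[0], n.centroid[1]))
    kept: list[Nucleus] = []
    r2 = radius_px**2
    for nuc in ordered:
        y, x = nuc.centroid
        if any((y - k.centroid[0]) ** 2 + (x - k.centroid[1]) ** 2 < r2 for k in kept):
            continue
        kept.append(nuc)
    return kept


def summarize_patches(
    nuclei: Iterable[Nucleus],
    patch_origins: Sequence[tuple[int, int]],
    patch_size: int = 64,
) -> list[PatchNucleiSummary]:
    """Aggregate nuclei features over grid-aligned patches.

    Each nucleus is assigned to the unique patch whose half-open
    footprint ``[origin, origin + patch_size)`` contains its centroid;
    per-patch means cover area, perimeter, circularity and the DAB tile
    mean.  Patches with no nuclei report count 0 and NaN features.
    """
    by_origin: dict[tuple[int, int], list[Nucleus]] = {tuple(o): [] for o in patch_origins}
    for nuc in nuclei:
        r = int(nuc.centroid[0] // patch_size) * patch_size
        c = int(nuc.centroid[1] // patch_size) * patch_size
        key = (r, c)
        if key in by_origin:
            by_origin[key].append(nuc)
    out: list[PatchNucleiSummary] = []
    for origin in patch_origins:
        group = by_origin[tuple(origin)]
        if not group:
            out.append(PatchNucleiSummary(origin=tuple(origin), nuclei_count=0))
            continue
        dabs = [n.dab_tile_mean for n in group if not math.isnan(n.dab_tile_mean)]
        out.append(
            PatchNucleiSummary(
                origin=tuple(origin),
                nuclei_count=len(group),
                mean_area=float(np.mean([n.area for n in group])),
                mean_perimeter=float(np.mean([n.perimeter for n in group])),
                mean_circularity=float(np.mean([n.circularity for n in group])),
                mean_dab_tile=float(np.mean(dabs)) if dabs else float("nan"),
            )
        )
    return out
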