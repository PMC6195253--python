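"""Dual-channel worm counting from paired brightfield / GFP well images.

A simplified re-implementation of the image-analysis counting route:

1. correct the radially uneven well illumination (edges dark, center
   bright) by dividing out a heavily smoothed background estimate;
2. optionally crop the image border, which removes the edge region where
   illumination artefacts and debris produce false-positive worm objects;
3. segment putative worms from the corrected brightfield by global
   thresholding (Otsu) and connected components, filtering components by
   area; components much larger than a single worm are taken to be clumps
   of touching worms and resolved by area quantization (multiplicity =
   round(area / reference worm area));
4. threshold the fluorescence channel and assign each fluorescent connected
   component ("GFP child") to the worm object containing its centroid;
5. a worm object with no GFP child is called focal, with >= 1 child it is
   called competitor; clump objects contribute min(children, multiplicity)
   GFP worms.

Area quantization replaces probabilistic worm-shape untangling: it needs no
training and is adequate for mild clumping, at the cost of occasional
off-by-one multiplicities in dense clumps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

from .metrics import FitnessEstimate, fitness_estimate
from .render import WellImagePair

__all__ = [
    "SegmentationParams",
    "ObjectRecord",
    "CountResult",
    "correct_illumination",
    "crop_well",
    "segment_worms",
    "detect_gfp_children",
    "count_image_pair",
]


@dataclass(frozen=True)
class SegmentationParams:
    """All tunables of the counting pipeline, echoed into every result."""

    crop_fraction: float = 0.0
    illumination_sigma: float | None = None  # default: image size / 20
    illumination_mode: str = "divide"  # or "subtract"
    illumination_iterations: int = 3
    min_area: int = 100
    max_area: int | None = None  # default: 20 x reference worm area
    reference_worm_area: float | None = None  # default: per-image median
    max_single_frac: float = 1.6  # areas above this x reference are clumps
    max_foreground_frac: float = 0.45  # larger => declare no real foreground
    min_gfp_area: int = 8
    max_gfp_foreground_frac: float = 0.05


@dataclass(frozen=True)
class ObjectRecord:
    label: int
    area: int
    multiplicity: int
    gfp_children: int
    centroid: tuple[float, float]


@dataclass
class CountResult:
    """Outcome of counting one well image pair."""

    n_total: int
    n_gfp: int
    objects: list[ObjectRecord]
    n_unassigned_gfp: int
    reference_worm_area: float
    params: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return len(self.objects)


def correct_illumination(
    image: np.ndarray,
    sigma: float | None = None,
    mode: str = "divide",
    iterations: int = 3,
) -> np.ndarray:
    """Remove smooth uneven illumination from an image.

    The background is estimated by heavy Gaussian smoothing (default scale:
    one twentieth of the smaller image dimension) and divided out (or
    subtracted, ``mode="subtract"``).  A single pass leaves a residual of
    order ``sigma^2`` times the field's curvature, so the division is
    iterated (3 passes by default), after which a smooth radial field is
    flat to within a couple of percent.  The output is rescaled to preserve
    the input's mean; rank order within local neighborhoods is preserved
    because the background varies slowly.  A constant image is returned
    unchanged with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D raster")
    if np.ptp(img) == 0.0:
        warnings.warn("constant image: no illumination to correct", stacklevel=2)
        return img.copy()
    if mode not in ("divide", "subtract"):
        raise ValueError("mode must be 'divide' or 'subtract'")
    if sigma is None:
        sigma = min(img.shape) / 20.0
    out = img
    for _ in range(max(iterations, 1)):
        bg = gaussian(out, sigma=sigma, mode="nearest", preserve_range=True)
        if mode == "divide":
            floor = 1e-6 * float(np.max(np.abs(bg)) or 1.0)
            out = out / np.maximum(bg, floor)
        else:
            out = out - bg
    src_mean = float(img.mean())
    out_mean = float(out.mean())
    if mode == "divide" and out_mean != 0:
        out = out * (src_mean / out_mean)
    else:
        out = out + src_mean
    return out


def crop_well(image: np.ndarray, crop_fraction: float) -> np.ndarray:
    """Remove a border of ``crop_fraction x min(height, width)`` per side."""
    if not 0.0 <= crop_fraction < 0.5:
        raise ValueError("crop_fraction must lie in [0, 0.5)")
    if crop_fraction == 0.0:
        return image
    h, w = image.shape[:2]
    b = int(round(crop_fraction * min(h, w)))
    if h - 2 * b < 1 or w - 2 * b < 1:
        raise ValueError("crop_fraction removes the whole image")
    return image[b : h - b, b : w - b]


def _threshold_foreground(
    image: np.ndarray, dark_objects: bool, max_frac: float
) -> np.ndarray:
    """Otsu threshold with a guard against thresholding pure background.

    Otsu always splits the histogram, so an image with no real objects would
    yield a huge spurious foreground; if the foreground fraction exceeds
    ``max_frac`` the image is declared object-free.  The rule depends only
    on intensity ranks, so counting is invariant to global rescaling.
    """
    if np.ptp(image) == 0.0:
        return np.zeros(image.shape, dtype=bool)
    t = threshold_otsu(image)
    fg = image < t if dark_objects else image > t
    if fg.mean() > max_frac:
        return np.zeros(image.shape, dtype=bool)
    return fg


def segment_worms(
    brightfield: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[ObjectRecord], float]:
    """Segment worm objects from an illumination-corrected brightfield image.

    Returns ``(labels, objects, reference_worm_area)``.  Worms are dark on a
    bright background.  Components outside ``[min_area, max_area]`` are
    discarded; components larger than ``max_single_frac x`` the reference
    worm area get clump multiplicity ``round(area / reference)``.  The
    reference area defaults to the median area of single-sized components in
    this image.  An image with no foreground yields zero objects, not an
    error.
    """
    p = params or SegmentationParams()
    fg = _threshold_foreground(
        np.asarray(brightfield, dtype=float), True, p.max_foreground_frac
    )
    labels, n_lab = ndimage.label(fg)
    if n_lab == 0:
        return labels, [], float(p.reference_worm_area or 0.0)

    areas = ndimage.sum_labels(fg, labels, index=np.arange(1, n_lab + 1))
    keep = areas >= p.min_area
    if p.max_area is not None:
        keep &= areas <= p.max_area

    kept_areas = areas[keep]
    if p.reference_worm_area is not None:
        ref = float(p.reference_worm_area)
    elif kept_areas.size:
        # reference = median area of components that look single-sized;
        # iterate once so an image of mostly clumps still gets a sane ref
        ref0 = float(np.median(kept_areas))
        singles = kept_areas[kept_areas <= p.max_single_frac * ref0]
        ref = float(np.median(singles)) if singles.size else ref0
    else:
        ref = 0.0
    if p.max_area is None and ref > 0:
        keep &= areas <= 20.0 * ref

    out_labels = np.zeros_like(labels)
    objects: list[ObjectRecord] = []
    centroids = ndimage.center_of_mass(fg, labels, index=np.arange(1, n_lab + 1))
    new_lab = 0
    for i in np.flatnonzero(keep):
        new_lab += 1
        area = int(areas[i])
        out_labels[labels == i + 1] = new_lab
        if ref > 0 and area > p.max_single_frac * ref:
            mult = max(int(round(area / ref)), 1)
        else:
            mult = 1
        objects.append(
            ObjectRecord(
                label=new_lab,
                area=area,
                multiplicity=mult,
                gfp_children=0,
                centroid=(float(centroids[i][0]), float(centroids[i][1])),
            )
        )
    return out_labels, objects, ref


def detect_gfp_children(
    labels: np.ndarray,
    objects: list[ObjectRecord],
    fluorescence: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[list[ObjectRecord], int]:
    """Count fluorescent child objects per worm object.

    The fluorescence channel is thresholded (Otsu, with the same
    no-foreground guard); each fluorescent connected component of at least
    ``min_gfp_area`` pixels is assigned to the worm object containing its
    centroid.  Components whose centroid lies on background are reported as
    unassigned.
    """
    p = params or SegmentationParams()
    fl = np.asarray(fluorescence, dtype=float)
    if fl.shape != labels.shape:
        raise ValueError(
            f"fluorescence frame {fl.shape} does not match labels {labels.shape}"
        )
    fg = _threshold_foreground(fl, False, p.max_gfp_foreground_frac)
    child_lab, n_child = ndimage.label(fg)
    counts = {o.label: 0 for o in objects}
    unassigned = 0
    if n_child:
        areas = ndimage.sum_labels(fg, child_lab, index=np.arange(1, n_child + 1))
        cents = ndimage.center_of_mass(fg, child_lab, index=np.arange(1, n_child + 1))
        for a, (cy, cx) in zip(areas, cents):
            if a < p.min_gfp_area:
                continue
            owner = int(labels[int(round(cy)), int(round(cx))])
            if owner in counts:
                counts[owner] += 1
            else:
                unassigned += 1
    updated = [
        ObjectRecord(
            label=o.label,
            area=o.area,
            multiplicity=o.multiplicity,
            gfp_children=counts[o.label],
            centroid=o.centroid,
        )
        for o in objects
    ]
    return updated, unassigned


def count_image_pair(
    pair: WellImagePair, params: SegmentationParams | None = None
) -> tuple[CountResult, FitnessEstimate | None]:
    """End-to-end counting of one well: correct, crop, segment, classify.

    ``n_total`` sums clump multiplicities; ``n_gfp`` sums
    ``min(gfp_children, multiplicity)`` per object.  Returns the count
    result plus the fitness estimate (None for an empty well, where p is
    undefined).
    """
    p = params or SegmentationParams()
    bf = correct_illumination(
        pair.brightfield,
        sigma=p.illumination_sigma,
        mode=p.illumination_mode,
        iterations=p.illumination_iterations,
    )
    fl = np.asarray(pair.fluorescence, dtype=float)
    if p.crop_fraction > 0:
        bf = crop_well(bf, p.crop_fraction)
        fl = crop_well(fl, p.crop_fraction)

    labels, objects, ref = segment_worms(bf, p)
    objects, unassigned = detect_gfp_children(labels, objects, fl, p)

    n_total = sum(o.multiplicity for o in objects)
    n_gfp = sum(min(o.gfp_children, o.multiplicity) for o in objects)
    result = CountResult(
        n_total=n_total,
        n_gfp=n_gfp,
        objects=objects,
        n_unassigned_gfp=unassigned,
        reference_worm_area=ref,
        params=asdict(p),
    )
    est = fitness_estimate(n_total, n_gfp) if n_total > 0 else None
    return result, est
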