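"""Renderer for synthetic paired brightfield / GFP well images.

Produces the kind of image the counting pipeline consumes: worms drawn as
smooth random-curvature tubes inside a circular well, imaged dark on a
bright background under a radially uneven illumination field (well centers
bright, edges dark), with optional dark debris specks concentrated near the
well edge; the fluorescence channel carries one bright compact GFP locus
placed head-proximally inside each marked worm.  Ground truth (centerlines,
centroids, GFP flags) is embedded in the returned pair, so counting accuracy
can be scored exactly.

The worm/GFP appearance model is deliberately simple — this is plumbing for
validating the counting pipeline, not a microscopy simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RenderConfig", "WormTruth", "WellImagePair", "render_well_image"]


@dataclass(frozen=True)
class WormTruth:
    """Ground truth for one rendered worm."""

    centerline: np.ndarray  # (k, 2) row/col points
    centroid: tuple[float, float]
    is_gfp: bool
    gfp_point: tuple[float, float] | None


@dataclass
class WellImagePair:
    """Paired brightfield + fluorescence rasters with embedded ground truth."""

    brightfield: np.ndarray
    fluorescence: np.ndarray
    truth: list[WormTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError("channel rasters must share dimensions")

    def truth_counts(self, crop_fraction: float = 0.0) -> tuple[int, int]:
        """(n_total, n_gfp) among worms whose centroid survives the crop."""
        h, w = self.brightfield.shape
        b = int(round(crop_fraction * min(h, w)))
        tot = gfp = 0
        for t in self.truth:
            r, c = t.centroid
            if b <= r < h - b and b <= c < w - b:
                tot += 1
                gfp += int(t.is_gfp)
        return tot, gfp


@dataclass(frozen=True)
class RenderConfig:
    """Geometry, optics and nuisance parameters of the renderer."""

    image_size: int = 512
    placement_radius_frac: float = 0.88  # worms stay inside this frac of N/2
    worm_length_px: float = 55.0
    worm_length_jitter: float = 0.12  # relative SD of length
    worm_width_px: float = 5.0
    step_px: float = 3.0
    curvature_sd: float = 0.22  # radians of heading change per step
    background_level: float = 0.85
    worm_attenuation: float = 0.55  # worm pixels are (1 - this) x background
    illum_corner_level: float = 0.35  # illumination at image corner vs center 1.0
    noise_sd: float = 0.01
    # debris: dark specks, preferentially in the dark border region
    n_debris: int = 8
    debris_radius_lo: float = 2.0
    debris_radius_hi: float = 4.0
    debris_band: tuple[float, float] = (0.55, 0.95)  # corner-normalized radius
    # clumping: chance a worm is seeded adjacent to an existing worm
    clump_prob: float = 0.1
    min_separation_px: float = 3.0
    # fluorescence
    gfp_radius_px: float = 3.5
    gfp_intensity: float = 1.0
    gfp_background: float = 0.02
    gfp_noise_sd: float = 0.005
    gfp_head_frac: float = 0.12  # GFP locus position along the centerline
    max_placement_attempts: int = 200


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    r0, c0 = center
    rlo = max(int(r0 - radius) - 1, 0)
    rhi = min(int(r0 + radius) + 2, shape[0])
    clo = max(int(c0 - radius) - 1, 0)
    chi = min(int(c0 + radius) + 2, shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    sub = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return (slice(rlo, rhi), slice(clo, chi)), sub


def _stamp_disk(canvas: np.ndarray, center, radius) -> None:
    sl, sub = _disk_mask(canvas.shape, center, radius)
    canvas[sl][sub] = True


def _worm_centerline(
    start: np.ndarray, heading: float, n_steps: int, cfg: RenderConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    pts = [start.copy()]
    pos = start.astype(float)
    for _ in range(n_steps):
        heading += rng.normal(0.0, cfg.curvature_sd)
        pos = pos + cfg.step_px * np.array([math.sin(heading), math.cos(heading)])
        pts.append(pos.copy())
    return np.array(pts)


def render_well_image(
    n_worms: int,
    gfp_fraction: float,
    config: RenderConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> WellImagePair:
    """Render one paired brightfield/fluorescence well image.

    Exactly ``round(n_worms * gfp_fraction)`` worms carry a GFP locus.  With
    ``clump_prob = 0`` worms keep at least ``min_separation_px`` apart, so a
    connected-component counter can recover the truth exactly; with clumping
    on, some worms are seeded touching an existing worm.

    Raises if repeated placement attempts fail (well too crowded).
    """
    cfg = config or RenderConfig()
    if n_worms < 0:
        raise ValueError("n_worms must be non-negative")
    if not 0.0 <= gfp_fraction <= 1.0:
        raise ValueError("gfp_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator
    ) else rng

    N = cfg.image_size
    center = (N - 1) / 2.0
    R = cfg.placement_radius_frac * N / 2.0
    rr, cc = np.mgrid[0:N, 0:N]
    dist = np.hypot(rr - center, cc - center)
    corner_dist = center * math.sqrt(2.0)

    worm_mask = np.zeros((N, N), dtype=bool)
    sep_mask = np.zeros((N, N), dtype=bool)  # worms + separation halo
    truths: list[WormTruth] = []
    n_gfp = int(round(n_worms * gfp_fraction))
    half_w = cfg.worm_width_px / 2.0

    for i in range(n_worms):
        placed = False
        for _ in range(cfg.max_placement_attempts):
            length = max(
                cfg.worm_length_px
                * (1.0 + rng.normal(0.0, cfg.worm_length_jitter)),
                3 * cfg.step_px,
            )
            n_steps = max(int(length / cfg.step_px), 3)
            clumped = truths and rng.random() < cfg.clump_prob
            if clumped:
                host = truths[rng.integers(len(truths))]
                anchor = host.centerline[
                    rng.integers(len(host.centerline))
                ]
                start = anchor + rng.normal(0.0, cfg.worm_width_px, size=2)
            else:
                # rejection-sample a start point inside the placement margin
                theta = rng.uniform(0, 2 * math.pi)
                rad = R * 0.9 * math.sqrt(rng.uniform())
                start = np.array(
                    [center + rad * math.sin(theta), center + rad * math.cos(theta)]
                )
            heading = rng.uniform(0, 2 * math.pi)
            line = _worm_centerline(start, heading, n_steps, cfg, rng)
            d = np.hypot(line[:, 0] - center, line[:, 1] - center)
            if np.any(d > R - half_w - 2):
                continue
            cand = np.zeros((N, N), dtype=bool)
            for pt in line:
                _stamp_disk(cand, (pt[0], pt[1]), half_w)
            if not clumped and np.any(cand & sep_mask):
                continue
            worm_mask |= cand
            halo = np.zeros((N, N), dtype=bool)
            for pt in line:
                _stamp_disk(halo, (pt[0], pt[1]), half_w + cfg.min_separation_px)
            sep_mask |= halo
            ys, xs = np.nonzero(cand)
            is_gfp = i < n_gfp
            gfp_pt = None
            if is_gfp:
                k = max(int(cfg.gfp_head_frac * len(line)), 0)
                gfp_pt = (float(line[k, 0]), float(line[k, 1]))
            truths.append(
                WormTruth(
                    centerline=line,
                    centroid=(float(ys.mean()), float(xs.mean())),
                    is_gfp=is_gfp,
                    gfp_point=gfp_pt,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place worm {i + 1}/{n_worms}: well too crowded, "
                "reduce n_worms or enlarge the image"
            )

    debris_mask = np.zeros((N, N), dtype=bool)
    placed_debris = 0
    while placed_debris < cfg.n_debris:
        theta = rng.uniform(0, 2 * math.pi)
        rad = corner_dist * rng.uniform(*cfg.debris_band)
        pos = (center + rad * math.sin(theta), center + rad * math.cos(theta))
        if not (0 <= pos[0] < N and 0 <= pos[1] < N):
            continue  # band radius can exceed the frame off the diagonals
        _stamp_disk(
            debris_mask,
            pos,
            rng.uniform(cfg.debris_radius_lo, cfg.debris_radius_hi),
        )
        placed_debris += 1

    # brightfield: (background x object attenuation) x smooth radial
    # illumination (center bright, edges/corners dark) + noise
    illum = 1.0 - (1.0 - cfg.illum_corner_level) * (dist / corner_dist) ** 2
    dark = worm_mask | debris_mask
    bf = cfg.background_level * np.where(dark, 1.0 - cfg.worm_attenuation, 1.0)
    bf = bf * illum
    bf = np.clip(bf + rng.normal(0.0, cfg.noise_sd, size=bf.shape), 0.0, None)

    fl = np.full((N, N), cfg.gfp_background)
    for t in truths:
        if t.gfp_point is not None:
            blob = np.zeros((N, N), dtype=bool)
            _stamp_disk(blob, t.gfp_point, cfg.gfp_radius_px)
            fl[blob] = cfg.gfp_intensity
    fl = np.clip(fl + rng.normal(0.0, cfg.gfp_noise_sd, size=fl.shape), 0.0, None)

    return WellImagePair(brightfield=bf, fluorescence=fl, truth=truths)
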