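"""Synthetic en-face angiogram scenes with exact ground truth.

The generator grows random branching vessel trees from the image border
toward the center, skirting a central avascular disc (the FAZ), and renders
them as bright curvilinear structures on a dark speckled background — the
geometry the quantification pipeline is designed for.  Because every vessel
segment is rasterized from a known polyline and caliber, the true vessel
area, centerline length and mean caliber are available by construction,
which lets VAD/VSD/VDI recovery be tested without any real scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from .io import EnFaceImage
from .metrics import PerfusionMetrics


@dataclass(frozen=True)
class VesselSegment:
    """A single vessel branch: a polyline with constant caliber and intensity."""

    polyline: np.ndarray  # (n, 2) float (row, col) control points, n >= 2
    caliber_px: float
    intensity: float = 200.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.polyline, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("polyline must be an (n>=2, 2) array of (row, col) points")
        if self.caliber_px < 1:
            raise ValueError("caliber_px must be >= 1")
        object.__setattr__(self, "polyline", pts)


@dataclass(frozen=True)
class SceneParams:
    """Conditions of a synthetic scan.

    Defaults emulate the nominal study scan: a 586 x 585 px grid over
    3 x 3 mm, a vessel-free central disc of radius 0.276 mm (area ~0.24 mm^2,
    a typical FAZ), vessel calibers 3-8 px (~15-40 um) and a whole-image
    vessel area fraction around 0.4.
    """

    shape: tuple[int, int] = (586, 585)
    extent_mm: tuple[float, float] = (3.0, 3.0)
    faz_radius_mm: float = 0.276
    target_vad: float = 0.4
    caliber_range_px: tuple[float, float] = (3.0, 8.0)
    intensity_range: tuple[float, float] = (100.0, 230.0)
    background: float = 80.0
    noise: tuple = ("gaussian", 12.0)  # ("none",) | ("gaussian", sigma) | ("speckle", sigma)
    #: illumination falls off linearly to (1 - shading) across the scan in a
    #: random direction, as in vignetted or decentered acquisitions
    shading: float = 0.35
    branch_prob_per_px: float = 0.02
    curvature_jitter: float = 0.15  # rad per step
    step_px: float = 2.0
    blur_sigma_px: float = 0.5
    max_trees: int = 6000
    plexus: str = "SCP"

    def __post_init__(self) -> None:
        h, w = self.shape
        if self.caliber_range_px[1] > min(h, w):
            raise ValueError("caliber exceeds image size")
        if not 0 <= self.target_vad < 1:
            raise ValueError("target_vad must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Exact truth for a rendered scene, consistent with its segments.

    ``truth_mean_caliber_px`` is total vessel area / total centerline length
    — the same area-over-length construction as VDI, i.e. the mean caliber
    weighted by centerline length.  ``mean_caliber_area_weighted_px``
    weights each branch's caliber by its area instead (wider vessels count
    more); both are reported.
    """

    truth_mask: np.ndarray
    centerline_mask: np.ndarray
    segments: tuple[VesselSegment, ...]
    faz_radius_mm: float
    faz_center_px: tuple[float, float]

    @property
    def truth_skeleton_px(self) -> int:
        return int(self.centerline_mask.sum())

    @property
    def truth_vad(self) -> float:
        return float(self.truth_mask.sum()) / self.truth_mask.size

    @property
    def truth_vsd(self) -> float:
        return float(self.centerline_mask.sum()) / self.centerline_mask.size

    @property
    def truth_mean_caliber_px(self) -> float:
        n_center = self.centerline_mask.sum()
        if n_center == 0:
            raise ValueError("empty scene: mean caliber undefined")
        return float(self.truth_mask.sum()) / float(n_center)

    @property
    def mean_caliber_area_weighted_px(self) -> float:
        areas = np.array([s.caliber_px * _polyline_length(s.polyline) for s in self.segments])
        if areas.sum() == 0:
            raise ValueError("empty scene: mean caliber undefined")
        calibers = np.array([s.caliber_px for s in self.segments])
        return float((calibers * areas).sum() / areas.sum())


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def _fill_tiny_holes(mask: np.ndarray, max_px: int = 2) -> np.ndarray:
    """Fill background pockets of at most ``max_px`` pixels.

    Unioning per-segment discs can leave 1-2 px holes where tubes run
    tangent; real vessels are solid, and such pinholes are topological
    obstructions that no thinning can reduce to unit width."""
    labels, n = ndimage.label(~mask)  # 4-connected background
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    tiny = np.zeros(n + 1, dtype=bool)
    tiny[1:] = sizes[1:] <= max_px
    return mask | tiny[labels]


def rasterize_segment(segment: VesselSegment, shape: tuple[int, int]):
    """Rasterize one segment onto a grid.

    Returns ``(area_mask, centerline_mask)``: the area mask sets every pixel
    whose center lies within ``caliber/2`` of the drawn centerline; the
    centerline mask holds the Bresenham trace of the polyline.  A
    degenerate zero-length polyline yields a disc of diameter ``caliber``.
    """
    h, w = shape
    center = np.zeros(shape, dtype=bool)
    pts = np.rint(segment.polyline).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        center[rr[ok], cc[ok]] = True
    if not center.any():
        return np.zeros(shape, dtype=bool), center

    r = segment.caliber_px / 2.0
    pad = int(math.ceil(r)) + 1
    rows, cols = np.nonzero(center)
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, h)
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, w)
    dist = ndimage.distance_transform_edt(~center[r0:r1, c0:c1])
    area = np.zeros(shape, dtype=bool)
    area[r0:r1, c0:c1] = dist <= r
    return area, center


#: minimum rendered gap (px) kept between distinct vessels so the Gaussian
#: point-spread blur cannot fuse neighbouring tubes into one
_CLEARANCE_PX = 3.0


def _spawn_root(params: SceneParams, rng: np.random.Generator):
    """Root walker: from a random border pixel heading inward, or (once the
    border crowds up) from a random interior point — capillaries dive in and
    out of the plexus, so interior origins are plausible."""
    h, w = params.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if rng.random() < 0.5:
        side = rng.integers(4)
        if side == 0:
            pos = np.array([0.0, rng.uniform(0, w - 1)])
        elif side == 1:
            pos = np.array([h - 1.0, rng.uniform(0, w - 1)])
        elif side == 2:
            pos = np.array([rng.uniform(0, h - 1), 0.0])
        else:
            pos = np.array([rng.uniform(0, h - 1), w - 1.0])
        angle = math.atan2(cy - pos[0], cx - pos[1]) + rng.normal(0, 0.4)
    else:
        pos = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        angle = rng.uniform(0, 2 * math.pi)
    caliber = rng.uniform(*params.caliber_range_px)
    intensity = rng.uniform(*params.intensity_range)
    return pos, angle, caliber, intensity


def _walk(params, rng, pos, angle, caliber, forbidden, grace):
    """Advance one walker until it leaves the image, reaches the FAZ rim,
    runs into the clearance zone of an existing vessel, or exhausts its
    length budget.  Returns (polyline points, spawned branch states).

    ``forbidden`` marks existing vessel area plus a clearance margin; the
    walker tries mild deflections before giving up, so meshes fill space
    without tubes fusing.  ``grace`` px of initial travel ignore the mask
    (branches start on their parent vessel).
    """
    h, w = params.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    pitch_mm = params.extent_mm[0] / h
    faz_r_px = params.faz_radius_mm / pitch_mm
    max_len = 1.5 * max(h, w)

    points = [pos.copy()]
    branches = []
    travelled = 0.0
    while travelled < max_len:
        angle += rng.normal(0, params.curvature_jitter)
        step = params.step_px
        chosen = None
        for delta in (0.0, 0.35, -0.35, 0.7, -0.7):
            cand_angle = angle + delta
            nxt = pos + step * np.array([math.sin(cand_angle), math.cos(cand_angle)])
            if not (0 <= nxt[0] < h and 0 <= nxt[1] < w):
                continue
            if np.hypot(nxt[0] - cy, nxt[1] - cx) < faz_r_px + caliber / 2.0:
                continue
            ri = min(int(round(nxt[0])), h - 1)
            ci = min(int(round(nxt[1])), w - 1)
            if travelled <= grace or not forbidden[ri, ci]:
                chosen = (cand_angle, nxt)
                break
        if chosen is None:
            break
        angle, pos = chosen
        points.append(pos.copy())
        travelled += step
        # thick vessels branch less often (rate nominal at 3 px caliber)
        if rng.random() < params.branch_prob_per_px * step * 3.0 / caliber:
            sign = 1 if rng.random() < 0.5 else -1
            b_angle = angle + sign * rng.uniform(0.4, 1.0)
            # launch from the parent's edge so the child's centerline does not
            # run inside the parent tube (it would vanish under thinning)
            b_pos = pos + (caliber / 2.0) * np.array([math.sin(b_angle), math.cos(b_angle)])
            branches.append((b_pos, b_angle, caliber))
    return points, branches


def render_scene(
    segments: Sequence[VesselSegment],
    params: SceneParams,
    seed: int = 0,
) -> tuple[EnFaceImage, SyntheticGroundTruth]:
    """Rasterize and render a fixed set of segments under the given conditions.

    Ground truth (area and centerline masks) is taken before blurring and
    noise; the rendered image applies a Gaussian point-spread blur, the
    chosen noise model, and 8-bit clipping.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    truth = np.zeros((h, w), dtype=bool)
    centerline = np.zeros((h, w), dtype=bool)
    img = np.full((h, w), params.background, dtype=np.float64)

    for seg in segments:
        area, center = rasterize_segment(seg, (h, w))
        truth |= area
        centerline |= center
        img = np.where(area, np.maximum(img, seg.intensity), img)
    truth = _fill_tiny_holes(truth)

    if params.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma_px)

    if params.shading > 0:
        theta = rng.uniform(0, 2 * np.pi)
        proj = (np.arange(h)[:, None] * math.sin(theta)
                + np.arange(w)[None, :] * math.cos(theta))
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
        img = img * (1.0 - params.shading * proj)

    kind = params.noise[0]
    if kind == "gaussian":
        img = img + rng.normal(0, params.noise[1], img.shape)
    elif kind == "speckle":
        img = img * (1.0 + rng.normal(0, params.noise[1], img.shape))
    elif kind != "none":
        raise ValueError(f"unknown noise model {params.noise!r}")

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = EnFaceImage(
        pixels=pixels,
        extent_mm=params.extent_mm,
        plexus=params.plexus,
        quality_score=None,
        eye_id="synthetic",
        visit="sim",
    )
    gt = SyntheticGroundTruth(
        truth_mask=truth,
        centerline_mask=centerline,
        segments=tuple(segments),
        faz_radius_mm=params.faz_radius_mm,
        faz_center_px=((h - 1) / 2.0, (w - 1) / 2.0),
    )
    return image, gt


def generate_scene(
    params: SceneParams = SceneParams(), seed: int = 0
) -> tuple[EnFaceImage, SyntheticGroundTruth]:
    """Generate a random branching-tree scene with exact ground truth.

    Trees are grown from border seeds until the true vessel area fraction
    reaches ``params.target_vad`` (or the tree budget is exhausted).  All
    randomness — layout, rendering noise — comes from one generator stream,
    so a seed fully determines the output.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    target_px = params.target_vad * h * w
    segments: list[VesselSegment] = []
    truth = np.zeros((h, w), dtype=bool)
    # vessel area dilated by a clearance margin: walkers may not enter, so
    # distinct tubes keep a visible gap and never fuse after blurring
    forbidden = np.zeros((h, w), dtype=bool)
    c_mean = 0.5 * (params.caliber_range_px[0] + params.caliber_range_px[1])
    vessel_px = 0

    queue: list = []  # pending walkers (LIFO keeps growth depth-first and deterministic)
    spawns = 0
    stalled = 0
    while vessel_px < target_px and spawns < params.max_trees:
        if queue:
            pos, angle, caliber, intensity, grace = queue.pop()
        else:
            pos, angle, caliber, intensity = _spawn_root(params, rng)
            grace = 0.0
            spawns += 1
        points, branches = _walk(params, rng, pos, angle, caliber, forbidden, grace)
        branch_grace = c_mean / 2.0 + _CLEARANCE_PX + params.step_px
        queue.extend((p, a, c, intensity, branch_grace) for p, a, c in branches)
        if len(points) < 5:  # too short to be a credible vessel
            stalled += 1
            if stalled > 10 * params.max_trees:
                break
            continue
        seg = VesselSegment(polyline=np.array(points), caliber_px=caliber, intensity=intensity)
        area, _ = rasterize_segment(seg, (h, w))
        margin, _ = rasterize_segment(
            VesselSegment(polyline=seg.polyline,
                          caliber_px=seg.caliber_px + c_mean + 2 * _CLEARANCE_PX,
                          intensity=intensity),
            (h, w),
        )
        new_px = int((area & ~truth).sum())
        truth |= area
        forbidden |= margin
        vessel_px += new_px
        segments.append(seg)

    render_seed = int(rng.integers(2**31 - 1))
    return render_scene(segments, params, seed=render_seed)


def truth_metrics(ground_truth: SyntheticGroundTruth, roi) -> PerfusionMetrics:
    """Metrics computed from ground truth alone (no image processing)."""
    roi = np.asarray(roi.mask if hasattr(roi, "mask") else roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    vad = float((ground_truth.truth_mask & roi).sum()) / n_roi
    n_sk = int((ground_truth.centerline_mask & roi).sum())
    vsd = float(n_sk) / n_roi
    vdi_px = (float((ground_truth.truth_mask & roi).sum()) / n_sk) if n_sk else None
    return PerfusionMetrics(vad=vad, vsd=vsd, vdi_px=vdi_px, vdi_um=None, region="whole")


def faz_contour_mm(radius_mm: float, n_vertices: int = 64, center_mm=(0.0, 0.0)) -> np.ndarray:
    """Regular polygon tracing the synthetic FAZ rim, in mm coordinates."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [center_mm[0] + radius_mm * np.cos(theta), center_mm[1] + radius_mm * np.sin(theta)]
    )
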