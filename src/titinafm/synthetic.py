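"""Synthetic AFM topographs of titin oligomers and M-complexes.

Ground-truth molecule layouts — globular M-complex blobs with titin
filaments radiating out of them, optionally interlinked into M-complex
arrays — are rendered into height maps the way an AFM sees them: the true
surface is morphologically dilated by a spherical probe (tip convolution)
and corrupted with per-scan-line tilt, Gaussian roughness, and a
multiplicative inter-scan gain.  Because every generated image carries its
exact geometric ground truth, each downstream analysis stage can be tested
as a parameter-recovery problem.

Geometry conventions: continuous nm coordinates, origin at the centre of
the top-left pixel, x rightward, y downward.  M-complexes render as
spherical caps (stated sphere radius, stated peak height), filaments as
circular-segment ridges whose apex equals the stated peak height
(reproducing the sub-nm apparent heights of dried titin); overlapping
features combine by per-pixel maximum.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .exceptions import LayoutError
from .heightmap import HeightMap
from .models import SigmoidParams, ThinPlateParams, eval_sigmoid, eval_thin_plate

__all__ = [
    "Blob",
    "Filament",
    "ManipulationEvent",
    "ScanArtifacts",
    "MoleculeLayout",
    "LayoutConfig",
    "generate_layout",
    "apply_manipulation",
    "render_true_surface",
    "dilate_with_tip",
    "add_scan_artifacts",
    "make_scan_pair",
    "cap_volume",
    "cap_support_radius",
    "polyline_arc_length",
    "point_at_arc",
]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def cap_volume(radius: float, peak: float) -> float:
    """Analytic volume of a spherical cap of apex height ``peak`` cut from
    a sphere of radius ``radius``: V = pi*h^2*(3R - h)/3."""
    return math.pi * peak**2 * (3.0 * radius - peak) / 3.0


def cap_support_radius(radius: float, peak: float) -> float:
    """Base radius of the cap's footprint on the substrate."""
    return math.sqrt(radius**2 - (radius - peak) ** 2)


def polyline_arc_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def point_at_arc(points: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc position ``s`` along a polyline."""
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum[1:], s, side="left"))
    i = min(i, len(seg) - 1)
    frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
    tangent = seg[i] / seg_len[i]
    return pts[i] + frac * seg[i], tangent


def _nearest_on_polyline(points: np.ndarray, xy: np.ndarray) -> tuple[float, float]:
    """(distance, arc position) of the closest point on a polyline to xy."""
    pts = np.asarray(points, dtype=float)
    xy = np.asarray(xy, dtype=float)
    best = (np.inf, 0.0)
    arc = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        L = float(np.hypot(*ab))
        if L == 0:
            continue
        t = float(np.clip(np.dot(xy - a, ab) / L**2, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.hypot(*(xy - proj)))
        if d < best[0]:
            best = (d, arc + t * L)
        arc += L
    return best


# ---------------------------------------------------------------------------
# Layout types
# ---------------------------------------------------------------------------


@dataclass
class Blob:
    """Globular M-complex: spherical cap with given sphere radius and
    apex (peak) height."""

    center: tuple[float, float]
    radius: float
    peak_height: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise LayoutError(f"blob radius must be > 0, got {self.radius}")
        if not 0 < self.peak_height <= 2 * self.radius:
            raise LayoutError(
                f"blob peak height must lie in (0, 2*radius], got {self.peak_height}"
            )

    @property
    def volume(self) -> float:
        return cap_volume(self.radius, self.peak_height)

    @property
    def support_radius(self) -> float:
        return cap_support_radius(self.radius, self.peak_height)


@dataclass
class Filament:
    """Titin filament: circular-segment ridge along a polyline.

    ``axial_heights`` optionally gives a per-vertex apex height (linearly
    interpolated along the contour); otherwise the ridge has the uniform
    ``peak_height``.
    """

    points: np.ndarray
    tube_radius: float
    peak_height: float
    axial_heights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise LayoutError("filament polyline needs >= 2 points")
        seg = np.hypot(*np.diff(self.points, axis=0).T)
        if np.any(seg == 0):
            raise LayoutError("consecutive polyline points must be distinct")
        if not self.tube_radius > 0:
            raise LayoutError("tube_radius must be > 0")
        if not self.peak_height > 0:
            raise LayoutError("peak_height must be > 0")
        if self.peak_height > self.tube_radius * 2:
            raise LayoutError("peak_height cannot exceed the tube diameter")
        if self.axial_heights is not None:
            self.axial_heights = np.asarray(self.axial_heights, dtype=float)
            if self.axial_heights.shape != (self.points.shape[0],):
                raise LayoutError("axial_heights must match the vertex count")

    @property
    def arc_length(self) -> float:
        return polyline_arc_length(self.points)


@dataclass
class ManipulationEvent:
    """A single nanosurgical tip drag.

    The tip is pressed onto the molecule at ``start_xy`` and moved
    ``distance`` nm along ``direction``; ``speed_class`` distinguishes
    slow (~10 nm/s, long dislodged segment, lower strain) from fast
    (~1000 nm/s) drags.  ``loop_params`` prescribes the thin-plate loop a
    filament drag produces; ``volume_increment`` the expansion a drag
    through an M-complex causes; ``pulled_sigmoid``/``pulled_length`` the
    axial height decay of a strand pulled out of an M-complex.
    """

    start_xy: tuple[float, float]
    direction: tuple[float, float]
    distance: float
    speed_class: Literal["slow", "fast"] = "slow"
    loop_params: Optional[ThinPlateParams] = None
    strand_height_after: float = 0.2
    volume_increment: float = 0.0
    pulled_sigmoid: Optional[SigmoidParams] = None
    pulled_length: Optional[float] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = float(np.hypot(*d))
        if norm == 0:
            raise LayoutError("direction must be a nonzero vector")
        self.direction = tuple(d / norm)
        if self.distance != 0 and not (10.0 <= self.distance <= 300.0):
            raise LayoutError(
                f"manipulation distance must be 0 (no-op) or in [10, 300] nm, "
                f"got {self.distance}"
            )
        if self.volume_increment < 0:
            raise LayoutError("volume_increment must be >= 0")


@dataclass
class ScanArtifacts:
    """Scan-corruption model: per-line linear background with slope scale
    ``per_line_tilt_sd`` (nm across the scan width), i.i.d. Gaussian
    roughness ``noise_sd`` (nm), and a multiplicative calibration
    ``gain`` applied to the whole frame."""

    noise_sd: float = 0.0
    per_line_tilt_sd: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise LayoutError("noise_sd must be >= 0")
        if not self.gain > 0:
            raise LayoutError("gain must be > 0")


@dataclass
class MoleculeLayout:
    """Ground-truth geometric description of one field of molecules."""

    field_size: tuple[float, float]
    blobs: list = field(default_factory=list)
    filaments: list = field(default_factory=list)
    manipulation_events: list = field(default_factory=list)
    array_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        w, h = self.field_size
        if not (w > 0 and h > 0):
            raise LayoutError("field_size must be positive")
        for blob in self.blobs:
            x, y = blob.center
            if not (0 <= x <= w and 0 <= y <= h):
                raise LayoutError(f"blob center {blob.center} outside field")
        for fil in self.filaments:
            if np.any(fil.points[:, 0] < 0) or np.any(fil.points[:, 0] > w) or \
               np.any(fil.points[:, 1] < 0) or np.any(fil.points[:, 1] > h):
                raise LayoutError("filament polyline leaves the field")

    def copy(self) -> "MoleculeLayout":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        """JSON-serializable ground-truth record."""
        return {
            "field_size": list(self.field_size),
            "array_spacing": self.array_spacing,
            "blobs": [
                {
                    "center": list(b.center),
                    "radius": b.radius,
                    "peak_height": b.peak_height,
                    "volume": b.volume,
                }
                for b in self.blobs
            ],
            "filaments": [
                {
                    "points": f.points.tolist(),
                    "tube_radius": f.tube_radius,
                    "peak_height": f.peak_height,
                    "axial_heights": None
                    if f.axial_heights is None
                    else f.axial_heights.tolist(),
                    "arc_length": f.arc_length,
                }
                for f in self.filaments
            ],
            "n_events": len(self.manipulation_events),
        }


# ---------------------------------------------------------------------------
# Layout generation
# ---------------------------------------------------------------------------


class LayoutConfig(BaseModel):
    """Distributional description of a synthetic field of titin oligomers.

    Defaults emulate dried titin preparations: M-complex blobs ~4.4 nm
    high, titin filaments ~0.3 nm high, inter-blob (M-complex array)
    spacing ~30 nm, inter-filament spacing ~20 nm in the oriented
    (meniscus-stretched) mode.
    """

    field_size: tuple[float, float] = (1000.0, 1000.0)
    n_blobs: int = Field(default=1, ge=1)
    blob_spacing_mean: Optional[float] = 29.37
    blob_spacing_sd: float = Field(default=7.12, ge=0)
    blob_radius: float = Field(default=12.0, gt=0)
    blob_peak_mean: float = Field(default=4.4, gt=0)
    blob_peak_sd: float = Field(default=0.0, ge=0)
    n_filaments: int = Field(default=6, ge=0)
    filament_length_mean: float = Field(default=120.0, gt=0)
    filament_length_sd: float = Field(default=25.0, ge=0)
    filament_height: float = Field(default=0.3, gt=0)
    filament_tube_radius: float = Field(default=3.0, gt=0)
    oriented: bool = False
    orientation_deg: float = 0.0
    filament_spacing_mean: float = Field(default=20.14, gt=0)
    filament_spacing_sd: float = Field(default=7.12, ge=0)

    @model_validator(mode="after")
    def _check_field(self):
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field_size must be positive")
        return self


def generate_layout(config: LayoutConfig, seed: int) -> MoleculeLayout:
    """Draw a ground-truth layout from the configured distributions.

    Reproducible for a given seed.  Blobs are placed along a horizontal
    array through the field centre with gaps drawn from
    N(blob_spacing_mean, blob_spacing_sd) when a spacing is configured,
    or uniformly at random otherwise; filaments radiate from the blobs
    (round-robin) at uniform random angles, or parallel to
    ``orientation_deg`` in the oriented (meniscus-stretched) mode.

    Raises
    ------
    LayoutError
        If the configured geometry cannot fit inside the field.
    """
    rng = np.random.default_rng(seed)
    w, h = config.field_size
    cx, cy = w / 2.0, h / 2.0
    margin = config.blob_radius

    # --- blob centres -----------------------------------------------------
    if config.n_blobs == 1:
        centers = [np.array([cx, cy])]
    elif config.blob_spacing_mean is not None:
        gaps = rng.normal(config.blob_spacing_mean, config.blob_spacing_sd,
                          size=config.n_blobs - 1)
        gaps = np.clip(gaps, 2.0, None)
        xs = np.concatenate([[0.0], np.cumsum(gaps)])
        span = xs[-1]
        if span + 2 * margin > w:
            raise LayoutError(
                f"blob array span {span:.1f} nm + margins exceeds field width {w} nm"
            )
        xs = xs - span / 2.0 + cx
        centers = [np.array([x, cy]) for x in xs]
    else:
        centers = []
        min_sep = 4.0 * config.blob_radius
        for _ in range(config.n_blobs):
            for _attempt in range(1000):
                cand = rng.uniform([margin, margin], [w - margin, h - margin])
                if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
                    centers.append(cand)
                    break
            else:
                raise LayoutError(
                    f"could not place {config.n_blobs} blobs with separation "
                    f">= {min_sep:.0f} nm in a {w} x {h} nm field"
                )

    peaks = rng.normal(config.blob_peak_mean, config.blob_peak_sd,
                       size=len(centers))
    peaks = np.clip(peaks, 0.05, 2 * config.blob_radius)
    blobs = [
        Blob(center=(float(c[0]), float(c[1])), radius=config.blob_radius,
             peak_height=float(p))
        for c, p in zip(centers, peaks)
    ]

    # --- filaments --------------------------------------------------------
    filaments = []
    theta0 = math.radians(config.orientation_deg)
    if config.oriented and config.n_filaments > 0:
        # parallel filaments offset perpendicular to the common axis
        gaps = rng.normal(config.filament_spacing_mean,
                          config.filament_spacing_sd,
                          size=max(config.n_filaments - 1, 0))
        gaps = np.clip(gaps, 2.0, None)
        offsets = np.concatenate([[0.0], np.cumsum(gaps)])
        offsets -= offsets.mean()
        axis = np.array([math.cos(theta0), math.sin(theta0)])
        perp = np.array([-axis[1], axis[0]])
        anchor = np.array(blobs[0].center)
        for off in offsets:
            length = max(rng.normal(config.filament_length_mean,
                                    config.filament_length_sd), 10.0)
            start = anchor + off * perp
            end = start + length * axis
            start, end = _clip_to_field(start, end, w, h)
            filaments.append(Filament(points=np.array([start, end]),
                                      tube_radius=config.filament_tube_radius,
                                      peak_height=config.filament_height))
    else:
        for i in range(config.n_filaments):
            blob = blobs[i % len(blobs)]
            angle = rng.uniform(0, 2 * math.pi)
            length = max(rng.normal(config.filament_length_mean,
                                    config.filament_length_sd), 10.0)
            start = np.array(blob.center)
            end = start + length * np.array([math.cos(angle), math.sin(angle)])
            start, end = _clip_to_field(start, end, w, h)
            filaments.append(Filament(points=np.array([start, end]),
                                      tube_radius=config.filament_tube_radius,
                                      peak_height=config.filament_height))

    return MoleculeLayout(
        field_size=(w, h),
        blobs=blobs,
        filaments=filaments,
        array_spacing=config.blob_spacing_mean if config.n_blobs > 1 else None,
    )


def _clip_to_field(start: np.ndarray, end: np.ndarray, w: float, h: float,
                   pad: float = 2.0):
    """Shorten a segment so both endpoints stay inside the field."""
    lo = np.array([pad, pad])
    hi = np.array([w - pad, h - pad])
    start = np.clip(start, lo, hi)
    direction = end - start
    t = 1.0
    for dim in range(2):
        if direction[dim] > 0:
            t = min(t, (hi[dim] - start[dim]) / direction[dim])
        elif direction[dim] < 0:
            t = min(t, (lo[dim] - start[dim]) / direction[dim])
    end = start + max(t, 1e-3) * direction
    return start, end


# ---------------------------------------------------------------------------
# Nanosurgical manipulation of a layout
# ---------------------------------------------------------------------------


def apply_manipulation(
    layout: MoleculeLayout,
    event: ManipulationEvent,
    sample_step: float = 1.0,
) -> MoleculeLayout:
    """Impose the geometric outcome of one nanosurgical drag on a layout.

    A drag across a filament replaces the targeted segment (half-extent
    ``r0`` of ``event.loop_params``) by a two-strand loop whose transverse
    displacement samples the tip-shifted thin-plate profile on
    ``|r| in (d, r0]`` at ``sample_step`` resolution — the excluded
    ``|r| <= d`` region leaves the characteristic gap between the strands
    at the loop vertex — with the strand apex height reduced to
    ``event.strand_height_after`` (partial domain unfolding thins the
    strand).  A drag through an M-complex blob expands it isotropically by
    ``event.volume_increment`` and, when ``pulled_length`` is set, appends
    a pulled-out strand whose axial height follows ``event.pulled_sigmoid``.

    Everything not targeted by the event is conserved exactly.
    """
    if event.distance == 0:
        return layout.copy()

    start = np.asarray(event.start_xy, dtype=float)
    w, h = layout.field_size
    if not (0 <= start[0] <= w and 0 <= start[1] <= h):
        raise LayoutError(f"event start {event.start_xy} outside field")

    # blob target?
    for bi, blob in enumerate(layout.blobs):
        if np.hypot(*(start - np.array(blob.center))) <= blob.support_radius:
            return _manipulate_blob(layout, bi, event, sample_step)

    # filament target?
    best = (np.inf, -1, 0.0)
    for fi, fil in enumerate(layout.filaments):
        d, s = _nearest_on_polyline(fil.points, start)
        if d < best[0]:
            best = (d, fi, s)
    dist, fi, s_star = best
    if fi < 0 or dist > 2.0 * layout.filaments[fi].tube_radius + 2.0:
        raise LayoutError(
            f"event start {event.start_xy} is not on or near any molecule"
        )
    return _manipulate_filament(layout, fi, s_star, event, sample_step)


def _manipulate_filament(layout, fi, s_star, event, sample_step):
    if event.loop_params is None:
        raise LayoutError("filament manipulation requires loop_params")
    params = event.loop_params
    fil = layout.filaments[fi]
    total = fil.arc_length
    if s_star - params.r0 < -1e-9 or s_star + params.r0 > total + 1e-9:
        raise LayoutError(
            f"loop half-extent r0={params.r0} nm extends beyond the filament "
            f"(target arc {s_star:.1f} of {total:.1f} nm)"
        )
    direction = np.asarray(event.direction, dtype=float)

    # signed arc offsets sampled on (d, r0], mirrored to the negative side
    n_samp = max(int(math.floor((params.r0 - params.d) / sample_step)), 2)
    r_pos = params.d + np.arange(1, n_samp + 1) * (
        (params.r0 - params.d) / n_samp
    )
    u_pos = eval_thin_plate(params, r_pos)

    def strand(signed_r, u_vals):
        pts = []
        for r, u in zip(signed_r, u_vals):
            base, _ = point_at_arc(fil.points, s_star + r)
            pts.append(base + u * direction)
        return np.asarray(pts)

    strand_neg = strand(-r_pos[::-1], u_pos[::-1])  # from -r0 toward the apex
    strand_pos = strand(r_pos, u_pos)

    for pts in (strand_neg, strand_pos):
        wf, hf = layout.field_size
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > wf) or \
           np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > hf):
            raise LayoutError("manipulated loop extends beyond the field")

    new_filaments = [f for i, f in enumerate(layout.filaments) if i != fi]
    # untargeted portions of the targeted filament, conserved exactly
    for lo, hi_ in ((0.0, s_star - params.r0), (s_star + params.r0, total)):
        if hi_ - lo > sample_step / 2:
            new_filaments.append(
                Filament(points=_sub_polyline(fil.points, lo, hi_),
                         tube_radius=fil.tube_radius,
                         peak_height=fil.peak_height)
            )
    for pts in (strand_neg, strand_pos):
        new_filaments.append(
            Filament(points=pts, tube_radius=fil.tube_radius,
                     peak_height=event.strand_height_after)
        )
    out = MoleculeLayout(
        field_size=layout.field_size,
        blobs=copy.deepcopy(layout.blobs),
        filaments=new_filaments,
        manipulation_events=list(layout.manipulation_events) + [event],
        array_spacing=layout.array_spacing,
    )
    return out


def _sub_polyline(points: np.ndarray, s_lo: float, s_hi: float) -> np.ndarray:
    """Portion of a polyline between two arc positions, original vertices
    preserved exactly."""
    pts = np.asarray(points, dtype=float)
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    p_lo, _ = point_at_arc(pts, s_lo)
    p_hi, _ = point_at_arc(pts, s_hi)
    inner = pts[(cum > s_lo + 1e-9) & (cum < s_hi - 1e-9)]
    out = [p_lo, *inner, p_hi]
    # drop duplicated consecutive points
    cleaned = [out[0]]
    for p in out[1:]:
        if np.hypot(*(p - cleaned[-1])) > 1e-9:
            cleaned.append(p)
    return np.asarray(cleaned)


def _manipulate_blob(layout, bi, event, sample_step):
    blob = layout.blobs[bi]
    new_blobs = copy.deepcopy(layout.blobs)
    if event.volume_increment > 0:
        scale = ((blob.volume + event.volume_increment) / blob.volume) ** (1 / 3)
        new_blobs[bi] = Blob(
            center=blob.center,
            radius=blob.radius * scale,
            peak_height=blob.peak_height * scale,
        )
    new_filaments = copy.deepcopy(layout.filaments)
    if event.pulled_length is not None:
        direction = np.asarray(event.direction, dtype=float)
        n = max(int(event.pulled_length / sample_step), 2)
        arcs = np.linspace(0.0, event.pulled_length, n + 1)
        pts = np.array(blob.center) + np.outer(arcs, direction)
        wf, hf = layout.field_size
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > wf) or \
           np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > hf):
            raise LayoutError("pulled strand extends beyond the field")
        if event.pulled_sigmoid is not None:
            heights = eval_sigmoid(event.pulled_sigmoid, arcs)
        else:
            heights = np.full(len(arcs), event.strand_height_after)
        tube = max(new_filaments[0].tube_radius if new_filaments else 3.0,
                   heights.max() / 2 + 1e-6)
        new_filaments.append(
            Filament(points=pts, tube_radius=tube,
                     peak_height=float(heights.max()),
                     axial_heights=heights)
        )
    return MoleculeLayout(
        field_size=layout.field_size,
        blobs=new_blobs,
        filaments=new_filaments,
        manipulation_events=list(layout.manipulation_events) + [event],
        array_spacing=layout.array_spacing,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_true_surface(layout: MoleculeLayout, pixel_size: float) -> HeightMap:
    """Rasterize a layout into a noiseless, tip-free height map.

    Blobs render as spherical caps, filaments as circular-segment ridges;
    overlapping features combine by per-pixel maximum.
    """
    if not pixel_size > 0:
        raise LayoutError("pixel_size must be > 0")
    w, h = layout.field_size
    cols = max(int(round(w / pixel_size)), 1)
    rows = max(int(round(h / pixel_size)), 1)
    if rows * cols > 16_000_000:
        raise LayoutError(
            f"{rows} x {cols} pixels exceeds the pixel budget; "
            "increase pixel_size"
        )
    z = np.zeros((rows, cols))
    xs = np.arange(cols) * pixel_size
    ys = np.arange(rows) * pixel_size

    for blob in layout.blobs:
        bx, by = blob.center
        a = blob.support_radius
        j0 = max(int((bx - a) / pixel_size) - 1, 0)
        j1 = min(int((bx + a) / pixel_size) + 2, cols)
        i0 = max(int((by - a) / pixel_size) - 1, 0)
        i1 = min(int((by + a) / pixel_size) + 2, rows)
        if j0 >= j1 or i0 >= i1:
            continue
        xg, yg = np.meshgrid(xs[j0:j1], ys[i0:i1])
        rho2 = (xg - bx) ** 2 + (yg - by) ** 2
        inside = rho2 <= blob.radius**2
        cap = np.zeros_like(xg)
        cap[inside] = np.sqrt(blob.radius**2 - rho2[inside]) - (
            blob.radius - blob.peak_height
        )
        np.maximum(z[i0:i1, j0:j1], np.clip(cap, 0, None), out=z[i0:i1, j0:j1])

    for fil in layout.filaments:
        _render_filament(z, fil, pixel_size, xs, ys)

    return HeightMap(z, pixel_size,
                     metadata={"synthetic": True, "true_surface": True})


def _render_filament(z, fil: Filament, px: float, xs, ys) -> None:
    pts = fil.points
    rt = fil.tube_radius
    seg_len = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if fil.axial_heights is not None:
        h_at = lambda s: np.interp(s, cum, fil.axial_heights)  # noqa: E731
        hmax = float(fil.axial_heights.max())
    else:
        h_at = lambda s: np.full_like(np.asarray(s, dtype=float),  # noqa: E731
                                      fil.peak_height)
        hmax = fil.peak_height
    support = cap_support_radius(rt, min(hmax, rt))
    pad = support + px
    rows, cols = z.shape
    for k, (a, b) in enumerate(zip(pts[:-1], pts[1:])):
        L = seg_len[k]
        if L == 0:
            continue
        lo = np.minimum(a, b) - pad
        hi = np.maximum(a, b) + pad
        j0 = max(int(lo[0] / px) - 1, 0)
        j1 = min(int(hi[0] / px) + 2, cols)
        i0 = max(int(lo[1] / px) - 1, 0)
        i1 = min(int(hi[1] / px) + 2, rows)
        if j0 >= j1 or i0 >= i1:
            continue
        xg, yg = np.meshgrid(xs[j0:j1], ys[i0:i1])
        ab = (b - a) / L
        dx = xg - a[0]
        dy = yg - a[1]
        s_proj = np.clip(dx * ab[0] + dy * ab[1], 0.0, L)
        t2 = (dx - s_proj * ab[0]) ** 2 + (dy - s_proj * ab[1]) ** 2
        h_loc = np.asarray(h_at(cum[k] + s_proj))
        inside = t2 <= rt**2
        ridge = np.zeros_like(xg)
        ridge[inside] = np.sqrt(rt**2 - t2[inside]) - (rt - h_loc[inside])
        np.maximum(z[i0:i1, j0:j1], np.clip(ridge, 0, None),
                   out=z[i0:i1, j0:j1])


# ---------------------------------------------------------------------------
# Tip convolution and scan artifacts
# ---------------------------------------------------------------------------


def tip_kernel(tip_radius: float, pixel_size: float):
    """Spherical-probe kernel sampled on the pixel grid.

    Returns (structure, footprint): additive apex-relative heights
    ``sqrt(R^2 - rho^2) - R`` (all <= 0, apex exactly 0) and the boolean
    disk of valid offsets.
    """
    kr = int(math.floor(tip_radius / pixel_size))
    offsets = np.arange(-kr, kr + 1) * pixel_size
    dx, dy = np.meshgrid(offsets, offsets)
    rho2 = dx**2 + dy**2
    footprint = rho2 <= tip_radius**2
    structure = np.where(
        footprint, np.sqrt(np.clip(tip_radius**2 - rho2, 0, None)) - tip_radius,
        0.0,
    )
    return structure, footprint


def dilate_with_tip(hmap: HeightMap, tip_radius: float) -> HeightMap:
    """Grayscale (max-plus) morphological dilation by a spherical probe.

    Models tip convolution: the image an AFM records is the dilation of
    the true surface by the probe shape.  ``tip_radius = 0`` returns the
    input unchanged.  Borders use nearest-pixel padding.
    """
    if tip_radius < 0:
        raise LayoutError("tip_radius must be >= 0")
    if tip_radius == 0:
        return hmap.copy()
    structure, footprint = tip_kernel(tip_radius, hmap.pixel_size)
    if not footprint.any() or footprint.sum() == 1:
        return hmap.copy()
    dilated = ndimage.grey_dilation(
        hmap.heights, footprint=footprint, structure=structure, mode="nearest"
    )
    meta = dict(hmap.metadata)
    meta["tip_radius_nm"] = tip_radius
    meta.pop("true_surface", None)
    return HeightMap(dilated, hmap.pixel_size, meta)


def add_scan_artifacts(hmap: HeightMap, artifacts: ScanArtifacts) -> HeightMap:
    """Corrupt a rendered surface with seeded, reproducible scan artifacts.

    Adds a per-scan-line linear background (offset and cross-width ramp
    each drawn N(0, per_line_tilt_sd)), i.i.d. Gaussian roughness
    N(0, noise_sd), then multiplies the whole frame by ``gain``.
    """
    rng = np.random.default_rng(artifacts.seed)
    z = hmap.heights.copy()
    rows, cols = z.shape
    if artifacts.per_line_tilt_sd > 0:
        offsets = rng.normal(0.0, artifacts.per_line_tilt_sd, size=rows)
        ramps = rng.normal(0.0, artifacts.per_line_tilt_sd, size=rows)
        frac = np.linspace(0.0, 1.0, cols)
        z = z + offsets[:, None] + ramps[:, None] * frac[None, :]
    if artifacts.noise_sd > 0:
        z = z + rng.normal(0.0, artifacts.noise_sd, size=z.shape)
    z = z * artifacts.gain
    meta = dict(hmap.metadata)
    meta["scan_gain"] = artifacts.gain
    meta.pop("true_surface", None)
    return HeightMap(z, hmap.pixel_size, meta)


def make_scan_pair(
    before: MoleculeLayout,
    after: MoleculeLayout,
    artifacts_before: ScanArtifacts,
    artifacts_after: ScanArtifacts,
    pixel_size: float = 2.0,
    tip_radius: float = 7.0,
):
    """Render a before/after scan pair the way the AFM would record it.

    Both layouts are rasterized, tip-dilated, and corrupted with their own
    scan artifacts (the two scans may carry different gains — the
    inter-scan bias the volume analysis must correct).  Returns
    ``(image_before, image_after, before, after)`` so recovery tests keep
    the ground truth.
    """
    if tuple(before.field_size) != tuple(after.field_size):
        raise LayoutError(
            f"mismatched fields: {before.field_size} vs {after.field_size}"
        )
    images = []
    for layout, artifacts in ((before, artifacts_before),
                              (after, artifacts_after)):
        img = render_true_surface(layout, pixel_size)
        img = dilate_with_tip(img, tip_radius)
        img = add_scan_artifacts(img, artifacts)
        images.append(img)
    return images[0], images[1], before, after
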