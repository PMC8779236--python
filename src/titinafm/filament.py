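"""Per-molecule measurements on traced filaments.

Traces are operator-supplied polylines in nm coordinates (manual tracing
is the convention for AFM contour analysis); a steepest-ascent ridge
follower is provided as a convenience but never gates any measurement.

Measurements:

* contour length of a trace;
* spacing statistics between topographical peaks along a cross-section
  (inter-M-complex bump spacing ~30 nm, inter-filament spacing ~20 nm);
* strain of a nanosurgically pulled loop, (L1 + L2) / L0, where L0 is the
  contour length of the displaced segment and L1, L2 the two stretched
  strands;
* axial height decay of a strand pulled out of an M-complex (feeds the
  sigmoid fit);
* necking profile: per-axial-station height and width of a strand from a
  least-squares rectangular (top-hat) fit to each perpendicular
  cross-section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import signal

from .exceptions import DomainError
from .heightmap import CrossSection, HeightMap
from .topography import extract_profile

__all__ = [
    "TracePolyline",
    "StrainMeasurement",
    "SpacingStats",
    "NeckProfile",
    "contour_length",
    "peak_spacings",
    "strain",
    "axial_height_decay",
    "neck_profile",
    "fit_top_hat",
    "trace_ridge",
]


@dataclass
class TracePolyline:
    """Ordered (x, y) nm points with a semantic role."""

    points: np.ndarray
    role: Literal["filament", "section_line", "manipulation_path"] = "filament"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise DomainError("trace needs >= 2 points")
        seg = np.hypot(*np.diff(self.points, axis=0).T)
        if np.any(seg == 0):
            raise DomainError("consecutive trace points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StrainMeasurement:
    """Strain of a pulled loop: (L1 + L2) / L0."""

    L0: float
    L1: float
    L2: float

    def __post_init__(self) -> None:
        for name, val in (("L0", self.L0), ("L1", self.L1), ("L2", self.L2)):
            if not val > 0:
                raise DomainError(f"{name} must be > 0, got {val}")

    @property
    def strain(self) -> float:
        return (self.L1 + self.L2) / self.L0


@dataclass
class SpacingStats:
    """Gap statistics between consecutive topographical peaks."""

    peak_positions: np.ndarray
    gaps: np.ndarray

    def __post_init__(self) -> None:
        self.peak_positions = np.asarray(self.peak_positions, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=float)

    @property
    def n(self) -> int:
        return len(self.gaps)

    @property
    def mean(self) -> float:
        return float(np.mean(self.gaps)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.gaps, ddof=1)) if self.n > 1 else float("nan")

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n > 1 else float("nan")


@dataclass
class NeckProfile:
    """Axial height/width series of a strand; NaN width where the top-hat
    fit was degenerate (flat background)."""

    axial_position: np.ndarray
    height: np.ndarray
    width: np.ndarray
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.axial_position = np.asarray(self.axial_position, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if not (len(self.axial_position) == len(self.height) == len(self.width)):
            raise DomainError("neck profile arrays must have equal length")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.height), dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "axial_position_nm": self.axial_position,
                "height_nm": self.height,
                "width_nm": self.width,
                "degenerate": self.degenerate,
            }
        )


# ---------------------------------------------------------------------------


def contour_length(trace) -> float:
    """Sum of Euclidean segment lengths of a trace, in nm."""
    pts = trace.points if isinstance(trace, TracePolyline) else np.asarray(
        trace, dtype=float)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def peak_spacings(profile: CrossSection, min_prominence: float = 0.3,
                  min_separation: float = 10.0) -> SpacingStats:
    """Spacing statistics of local height maxima along a section profile.

    Peaks must rise ``min_prominence`` nm above their surroundings
    (prominence is relative, so a constant offset does not change the
    result) and be at least ``min_separation`` nm apart.  Fewer than two
    peaks yields ``n = 0`` rather than an exception.
    """
    step = profile.step
    total = profile.arc_positions[-1] - profile.arc_positions[0] if len(
        profile) > 1 else 0.0
    if total <= 2 * min_separation:
        raise DomainError(
            f"profile span {total:.1f} nm must exceed twice the minimum "
            f"separation ({min_separation} nm)"
        )
    distance = max(int(round(min_separation / step)), 1) if step > 0 else 1
    idx, _ = signal.find_peaks(profile.heights, prominence=min_prominence,
                               distance=distance)
    positions = profile.arc_positions[idx]
    gaps = np.diff(positions)
    return SpacingStats(peak_positions=positions, gaps=gaps)


def strain(L0: float, L1: float, L2: float) -> StrainMeasurement:
    """Strain of a pulled titin loop: (L1 + L2) / L0.

    Unstretched two-strand limit: L1 = L2 = L0/2 gives strain 1; the
    measure is scale-invariant.
    """
    return StrainMeasurement(L0=L0, L1=L1, L2=L2)


def axial_height_decay(hmap: HeightMap, strand_trace, origin_xy=None
                       ) -> CrossSection:
    """Height along a pulled-out strand versus arc distance from its origin.

    The trace is sampled at pixel_size steps (bilinear interpolation);
    distances are measured from the trace start, which should coincide
    with ``origin_xy`` (the M-complex centre) when given.  The result
    feeds :class:`~titinafm.models.SigmoidModel`.
    """
    pts = strand_trace.points if isinstance(strand_trace, TracePolyline) \
        else np.asarray(strand_trace, dtype=float)
    if origin_xy is not None:
        origin = np.asarray(origin_xy, dtype=float)
        if np.hypot(*(pts[0] - origin)) > np.hypot(*(pts[-1] - origin)):
            pts = pts[::-1].copy()  # orient the trace away from the origin
    profile = extract_profile(hmap, pts, averaging_width=0.0)
    return profile


def fit_top_hat(positions: np.ndarray, heights: np.ndarray,
                height_floor: float = 0.0):
    """Least-squares rectangular ("square function") fit to a cross-section.

    Fits h(x) = H for |x - c| <= W/2, else 0, by exhaustive search of the
    centre ``c`` over the sampling grid and the width ``W`` over the
    half-pixel grid, with ``H`` closed-form (mean of the enclosed heights)
    for each candidate.  Exhaustive search avoids the local minima a
    gradient fit would hit on a discontinuous model.

    Returns ``(c, W, H, degenerate)``; a profile whose maximum does not
    exceed ``height_floor`` is degenerate and reported as (nan, 0, 0, True).
    """
    positions = np.asarray(positions, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if heights.max() <= height_floor:
        return float("nan"), 0.0, 0.0, True
    step = float(np.median(np.diff(positions)))
    n = len(positions)
    total_ss = float(np.sum(heights**2))
    widths = np.arange(1, 2 * n) * (step / 2.0)
    best = (np.inf, positions[int(np.argmax(heights))], step, heights.max())
    # prefix sums for O(1) window statistics
    csum = np.concatenate([[0.0], np.cumsum(heights)])
    csum2 = np.concatenate([[0.0], np.cumsum(heights**2)])
    for ci in range(n):
        c = positions[ci]
        for W in widths:
            lo = np.searchsorted(positions, c - W / 2 - 1e-12)
            hi = np.searchsorted(positions, c + W / 2 + 1e-12)
            m = hi - lo
            if m == 0:
                continue
            s = csum[hi] - csum[lo]
            s2 = csum2[hi] - csum2[lo]
            H = s / m
            # SSE = inside (s2 - m H^2) + outside (total_ss - s2)
            sse = (s2 - m * H * H) + (total_ss - s2)
            if sse < best[0] - 1e-15:
                best = (sse, c, W, H)
    _, c, W, H = best
    return float(c), float(W), float(H), False


def neck_profile(hmap: HeightMap, strand_trace, station_step: float = 4.0,
                 cross_length: float = 30.0,
                 height_floor: float = 0.0) -> NeckProfile:
    """Axial height/width profile of a strand from top-hat cross-section fits.

    At each axial station (every ``station_step`` nm along the trace) a
    perpendicular cross-section of total length ``cross_length`` is
    extracted and fitted with a rectangular function; the fitted plateau
    ``H`` is the local height and ``W`` the local width.  Necking shows up
    as a dip of the width (and height) series at mid-span.  Stations whose
    cross-section leaves the map are skipped with a warning.
    """
    pts = strand_trace.points if isinstance(strand_trace, TracePolyline) \
        else np.asarray(strand_trace, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    stations = np.arange(0.0, total + 1e-9, station_step)
    axial, height, width, degen = [], [], [], []
    for s in stations:
        i = min(int(np.searchsorted(cum[1:], s, side="left")), len(seg) - 1)
        frac = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        pos = pts[i] + frac * seg[i]
        tang = seg[i] / seg_len[i]
        normal = np.array([-tang[1], tang[0]])
        a = pos - normal * cross_length / 2
        b = pos + normal * cross_length / 2
        try:
            section = extract_profile(hmap, np.array([a, b]))
        except DomainError:
            warnings.warn(
                f"neck station at {s:.1f} nm: cross-section leaves the map; "
                "skipped",
                stacklevel=2,
            )
            continue
        c, W, H, is_degen = fit_top_hat(section.arc_positions, section.heights,
                                        height_floor=height_floor)
        axial.append(s)
        height.append(H)
        width.append(W)
        degen.append(is_degen)
    return NeckProfile(
        axial_position=np.array(axial),
        height=np.array(height),
        width=np.array(width),
        degenerate=np.array(degen, dtype=bool),
    )


def trace_ridge(hmap: HeightMap, seed_xy, max_length: float = 500.0,
                step: float | None = None) -> TracePolyline:
    """Convenience steepest-ascent ridge follower (manual traces remain
    the reference input for every measurement).

    From the seed, repeatedly moves one step to the highest neighbouring
    sample while forbidding immediate backtracking; follows the ridge in
    both directions from the seed.
    """
    px = hmap.pixel_size
    step = step or px
    rows, cols = hmap.heights.shape

    def climb(start, first_dir):
        pts = [np.asarray(start, dtype=float)]
        direction = first_dir
        travelled = 0.0
        while travelled < max_length / 2:
            angles = np.linspace(-np.pi / 2, np.pi / 2, 9) + np.arctan2(
                direction[1], direction[0])
            best = None
            for ang in angles:
                cand = pts[-1] + step * np.array([np.cos(ang), np.sin(ang)])
                j, i = cand[0] / px, cand[1] / px
                if not (0 <= i <= rows - 1 and 0 <= j <= cols - 1):
                    continue
                from scipy.ndimage import map_coordinates

                val = float(map_coordinates(hmap.heights, [[i], [j]],
                                            order=1)[0])
                if best is None or val > best[0]:
                    best = (val, cand, ang)
            if best is None:
                break
            _, cand, ang = best
            direction = np.array([np.cos(ang), np.sin(ang)])
            pts.append(cand)
            travelled += step
        return pts

    # initial direction: local gradient of a smoothed neighbourhood
    j0, i0 = seed_xy[0] / px, seed_xy[1] / px
    gy, gx = np.gradient(hmap.heights)
    from scipy.ndimage import map_coordinates

    gdir = np.array([
        float(map_coordinates(gx, [[i0], [j0]], order=1)[0]),
        float(map_coordinates(gy, [[i0], [j0]], order=1)[0]),
    ])
    if np.hypot(*gdir) == 0:
        gdir = np.array([1.0, 0.0])
    gdir = gdir / np.hypot(*gdir)
    forward = climb(seed_xy, gdir)
    backward = climb(seed_xy, -gdir)
    pts = np.array(backward[::-1] + forward[1:])
    # drop duplicate consecutive points
    keep = [0]
    for k in range(1, len(pts)):
        if np.hypot(*(pts[k] - pts[keep[-1]])) > 1e-9:
            keep.append(k)
    return TracePolyline(points=pts[keep], role="filament")
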