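"""Height-map processing: flattening, thresholding, masked volumes, and
cross-sections.

The volume analysis follows the AFM convention: the volume of a feature is
the integral of the surface height over a masked area (sum of masked
heights times the pixel area).  Because consecutive scans of the same
field can differ by a calibration drift, volumes measured in the second
scan are corrected by the volume ratio of an unmanipulated reference
object present in both scans (inter-scan bias correction): with

    bias_ratio = V_ref(before) / V_ref(after)

the corrected volume change of the manipulated target is

    dV = bias_ratio * V_target(after) - V_target(before).

Any multiplicative gain common to the whole after-scan cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DomainError, FlattenError, MaskError
from .heightmap import CrossSection, HeightMap, Mask

__all__ = [
    "VolumeChange",
    "flatten",
    "segment_threshold",
    "integrate_volume",
    "volume_change",
    "sphere_equivalent_diameter",
    "extract_profile",
    "component_mask",
]


@dataclass
class VolumeChange:
    """Paired masked volumes with inter-scan bias correction applied."""

    v_before: float
    v_after: float
    ref_before: float
    ref_after: float

    def __post_init__(self) -> None:
        if self.ref_after == 0 or self.ref_before == 0:
            raise DomainError("reference volume is zero; cannot form bias ratio")
        if self.bias_ratio <= 0:
            raise DomainError(f"bias ratio must be > 0, got {self.bias_ratio}")

    @property
    def bias_ratio(self) -> float:
        return self.ref_before / self.ref_after

    @property
    def dv_corrected(self) -> float:
        return self.bias_ratio * self.v_after - self.v_before

    def to_record(self) -> dict:
        return {
            "v_before_nm3": self.v_before,
            "v_after_nm3": self.v_after,
            "ref_before_nm3": self.ref_before,
            "ref_after_nm3": self.ref_after,
            "bias_ratio": self.bias_ratio,
            "dv_corrected_nm3": self.dv_corrected,
        }


def flatten(hmap: HeightMap, order: int = 1,
            exclude: Mask | None = None) -> HeightMap:
    """Per-scan-line polynomial background removal (flatness-of-field).

    A polynomial of the given order is fitted to the *background* pixels
    of each scan line (row) — pixels under ``exclude`` are treated as
    foreground: subtracted but never fitted — and subtracted from the
    whole line.  ``order = 0`` subtracts the per-line median of the
    background.  The operation is idempotent for a fixed exclude mask.

    Raises
    ------
    FlattenError
        If any line retains fewer than ``order + 1`` background pixels;
        the message identifies the row.
    """
    if order not in (0, 1, 2):
        raise DomainError(f"order must be 0, 1 or 2, got {order}")
    z = hmap.heights
    rows, cols = z.shape
    if exclude is not None:
        exclude.check_congruent(hmap)
        bg = ~exclude.values
    else:
        bg = np.ones_like(z, dtype=bool)
    x = np.arange(cols, dtype=float)
    out = np.empty_like(z)
    for i in range(rows):
        sel = bg[i]
        n_bg = int(sel.sum())
        if n_bg < order + 1:
            raise FlattenError(
                f"row {i} has only {n_bg} background pixels; "
                f"order {order} needs at least {order + 1}"
            )
        if order == 0:
            background = np.full(cols, np.median(z[i, sel]))
        else:
            coeffs = np.polyfit(x[sel], z[i, sel], order)
            background = np.polyval(coeffs, x)
        out[i] = z[i] - background
    meta = dict(hmap.metadata)
    meta["flattened_order"] = order
    return HeightMap(out, hmap.pixel_size, meta)


def segment_threshold(hmap: HeightMap, method: str = "background_sigma",
                      level: float = 3.0, label: str = "") -> Mask:
    """Threshold a height map into a foreground mask.

    ``method='fixed'`` masks pixels above ``level`` nm.
    ``method='background_sigma'`` masks pixels above
    ``median + level * 1.4826 * MAD`` of all pixels (robust SD), which is
    insensitive to the foreground fraction and to residual tilt.

    An empty mask triggers a warning, not an error (legal for blank scans).
    """
    z = hmap.heights
    if method == "fixed":
        threshold = float(level)
    elif method == "background_sigma":
        med = float(np.median(z))
        mad = float(np.median(np.abs(z - med)))
        threshold = med + level * 1.4826 * mad
    else:
        raise DomainError(
            f"method must be 'fixed' or 'background_sigma', got {method!r}"
        )
    values = z > threshold
    if not values.any():
        warnings.warn("segment_threshold produced an empty mask", stacklevel=2)
    return Mask(values, label=label or f"{method}:{level}")


def component_mask(mask: Mask, point_xy, pixel_size: float,
                   label: str = "") -> Mask:
    """Connected component of a mask containing (or nearest to) a point.

    Convenience for selecting the target or reference object out of a
    thresholded scan by its known position (nm coordinates).
    """
    labeled, n = ndimage.label(mask.values)
    if n == 0:
        raise MaskError("mask has no foreground components")
    j = int(round(point_xy[0] / pixel_size))
    i = int(round(point_xy[1] / pixel_size))
    i = np.clip(i, 0, mask.values.shape[0] - 1)
    j = np.clip(j, 0, mask.values.shape[1] - 1)
    lab = labeled[i, j]
    if lab == 0:
        # nearest foreground pixel
        fg = np.argwhere(mask.values)
        k = np.argmin((fg[:, 0] - i) ** 2 + (fg[:, 1] - j) ** 2)
        lab = labeled[tuple(fg[k])]
    return Mask(labeled == lab, label=label)


def integrate_volume(hmap: HeightMap, mask: Mask) -> float:
    """Masked volume in nm³: sum of heights over the mask × pixel area.

    Negative (post-flattening) heights contribute with their sign; they
    are deliberately not clipped, which would bias volumes upward.
    """
    mask.check_congruent(hmap)
    if mask.n_pixels == 0:
        raise MaskError("cannot integrate volume over an empty mask")
    return float(hmap.heights[mask.values].sum() * hmap.pixel_size**2)


def volume_change(
    before: HeightMap,
    after: HeightMap,
    target_before: Mask,
    target_after: Mask,
    reference_before: Mask,
    reference_after: Mask,
) -> VolumeChange:
    """Masked volume change of a manipulated target, corrected for
    inter-scan bias via an unmanipulated reference object.

    The caller asserts that the reference object was not manipulated; the
    masks may differ in shape between the scans (each scan is re-masked,
    no registration is attempted).
    """
    return VolumeChange(
        v_before=integrate_volume(before, target_before),
        v_after=integrate_volume(after, target_after),
        ref_before=integrate_volume(before, reference_before),
        ref_after=integrate_volume(after, reference_after),
    )


def sphere_equivalent_diameter(volume: float) -> float:
    """Diameter of the sphere with the given volume: (6V/pi)^(1/3)."""
    if not volume > 0:
        raise DomainError(f"volume must be > 0, got {volume}")
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def extract_profile(hmap: HeightMap, line, averaging_width: float = 0.0
                    ) -> CrossSection:
    """Sample a height profile along a polyline by bilinear interpolation.

    Samples are taken at ``pixel_size`` steps of arc length.  When
    ``averaging_width > 0`` each sample is the mean over a perpendicular
    segment of that width (sampled at pixel_size steps), emulating the
    width-averaged section tool of AFM software.

    Raises
    ------
    DomainError
        If the line (or its averaging band) leaves the image bounds, or
        has zero length.
    """
    pts = np.asarray(line, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise DomainError("line must be a polyline of >= 2 (x, y) points")
    if averaging_width < 0:
        raise DomainError("averaging_width must be >= 0")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total == 0:
        raise DomainError("zero-length section line")
    px = hmap.pixel_size
    n = int(np.floor(total / px)) + 1
    arc = np.arange(n) * px
    # positions along the polyline
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    xy = np.empty((n, 2))
    tang = np.empty((n, 2))
    idx = np.clip(np.searchsorted(cum[1:], arc, side="left"), 0, len(seg) - 1)
    for k in range(n):
        i = idx[k]
        frac = (arc[k] - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        xy[k] = pts[i] + frac * seg[i]
        tang[k] = seg[i] / seg_len[i]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    if averaging_width > 0:
        n_off = max(int(round(averaging_width / px / 2)), 1)
        offsets = np.arange(-n_off, n_off + 1) * px
    else:
        offsets = np.array([0.0])

    rows, cols = hmap.heights.shape
    heights = np.zeros(n)
    for off in offsets:
        sample_xy = xy + off * normal
        ci = sample_xy[:, 1] / px  # row coordinate
        cj = sample_xy[:, 0] / px  # col coordinate
        if (ci.min() < -1e-9 or cj.min() < -1e-9
                or ci.max() > rows - 1 + 1e-9 or cj.max() > cols - 1 + 1e-9):
            raise DomainError("section line (or averaging band) leaves the image")
        heights += ndimage.map_coordinates(
            hmap.heights, np.vstack([ci, cj]), order=1, mode="nearest"
        )
    heights /= len(offsets)
    return CrossSection(arc_positions=arc, heights=heights,
                        source_line=pts)
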