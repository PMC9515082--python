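"""Outcome quantifiers for contrast-enhanced MRI and H&E histology.

Opening volume: voxels in a treated elliptical ROI whose intensity exceeds
the control-ROI mean by more than three standard deviations, counted per
slice and converted to mm^3; the slice with the largest supra-threshold
count gives the reported volume.  Red-pixel area: HSV red-hue pixel count
inside an ROI times the pixel area.  Includes seeded synthetic generators
for both readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "ROISpec", "OpeningResult", "ellipse_mask",
           "roi_mask", "opening_volume", "synth_mri", "red_pixel_area",
           "lesion_axes_from_pressure", "DEFAULT_SPACING"]

DEFAULT_SPACING = (0.85, 0.85, 1.0)


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar grid with physical voxel spacing in mm (x, y, z=slice)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]


@dataclass(frozen=True)
class ROISpec:
    """An in-plane elliptical region, optionally limited to a slice range.

    ``center`` is in mm (voxel-center coordinates, origin at voxel (0, 0)).
    ``slices`` is a half-open (start, stop) index range; None means all.
    """

    center: tuple[float, float]
    major_axis: float = 19.0
    minor_axis: float = 8.0
    orientation: float = 0.0
    slices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")


def ellipse_mask(shape: tuple[int, int], spacing: tuple[float, float],
                 roi: ROISpec) -> np.ndarray:
    """Boolean in-plane mask: voxel centers inside the rotated ellipse.

    A voxel (i, j) sits at physical (i*dx, j*dy); it is included iff
    (u/a)^2 + (v/b)^2 <= 1 in the ellipse frame, a = major/2, b = minor/2.
    """
    nx, ny = shape
    dx, dy = spacing
    cx, cy = roi.center
    a = roi.major_axis / 2.0
    b = roi.minor_axis / 2.0
    if cx - a < -dx / 2 or cx + a > (nx - 0.5) * dx \
            or cy - a < -dy / 2 or cy + a > (ny - 0.5) * dy:
        raise ValueError("ROI extends outside the image grid")
    x = np.arange(nx)[:, None] * dx - cx
    y = np.arange(ny)[None, :] * dy - cy
    th = np.deg2rad(roi.orientation)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def roi_mask(volume: ImageVolume, roi: ROISpec) -> np.ndarray:
    """3-D boolean mask: the in-plane ellipse over the ROI's slice range."""
    m2 = ellipse_mask(volume.intensities.shape[:2], volume.spacing[:2], roi)
    mask = np.zeros(volume.intensities.shape, dtype=bool)
    if roi.slices is None:
        lo, hi = 0, volume.n_slices
    else:
        lo, hi = roi.slices
        if not (0 <= lo < hi <= volume.n_slices):
            raise ValueError(f"slice range {roi.slices} outside volume")
    mask[:, :, lo:hi] = m2[:, :, None]
    return mask


@dataclass(frozen=True)
class OpeningResult:
    threshold: float
    per_slice_volume: tuple[float, ...]
    opening_volume: float
    n_voxels_max_slice: int
    total_volume: float
    n_sigma: float = 3.0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "per_slice_volume_mm3": list(self.per_slice_volume),
            "opening_volume_mm3": self.opening_volume,
            "n_voxels_max_slice": self.n_voxels_max_slice,
            "total_volume_mm3": self.total_volume,
            "n_sigma": self.n_sigma,
        }


def opening_volume(volume: ImageVolume, treated: ROISpec, control: ROISpec,
                   n_sigma: float = 3.0, ddof: int = 1) -> OpeningResult:
    """Quantify the opening volume from a post-contrast volume.

    Threshold = control-ROI mean + ``n_sigma`` * control-ROI std (sample
    std by default, ``ddof=0`` for population).  A treated-ROI voxel counts
    iff its intensity is strictly greater than the threshold.  The per-slice
    supra-threshold count times the voxel volume gives the slice volume;
    the maximum over slices is the reported opening volume.
    """
    t_mask = roi_mask(volume, treated)
    c_mask = roi_mask(volume, control)
    if np.any(t_mask & c_mask):
        raise ValueError("treated and control ROIs overlap")
    ctrl = volume.intensities[c_mask]
    if ctrl.size == 0:
        raise ValueError("control ROI selects no voxels")
    threshold = float(ctrl.mean() + n_sigma * ctrl.std(ddof=ddof))
    supra = (volume.intensities > threshold) & t_mask
    counts = supra.sum(axis=(0, 1))
    per_slice = tuple(float(c) * volume.voxel_volume for c in counts)
    k = int(np.argmax(counts))
    return OpeningResult(
        threshold=threshold,
        per_slice_volume=per_slice,
        opening_volume=max(per_slice) if per_slice else 0.0,
        n_voxels_max_slice=int(counts[k]),
        total_volume=float(sum(per_slice)),
        n_sigma=n_sigma)


def _ellipsoid_mask(shape, spacing, center_mm, axes_mm) -> np.ndarray:
    coords = [(np.arange(n) * d - c) / (ax / 2.0)
              for n, d, c, ax in zip(shape, spacing, center_mm, axes_mm)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return x * x + y * y + z * z <= 1.0


def synth_mri(shape: tuple[int, int, int] = (96, 96, 20),
              spacing: tuple[float, float, float] = DEFAULT_SPACING,
              bg_mean: float = 100.0, bg_std: float = 5.0,
              lesion_center: tuple[float, float, float] = (30.0, 30.0, 10.0),
              lesion_axes: tuple[float, float, float] = (8.0, 6.0, 6.0),
              contrast: float = 50.0,
              ventricle_center: tuple[float, float, float] | None = None,
              ventricle_axes: tuple[float, float, float] = (6.0, 6.0, 8.0),
              ventricle_intensity: float = 500.0,
              noise_clip: float | None = 2.5,
              seed: int = 0):
    """Seeded synthetic post-contrast volume with a planted enhancement.

    Gaussian background (mean ``bg_mean``, std ``bg_std``) plus an
    ellipsoidal lesion of the given additive ``contrast``; optionally a
    hyperintense "ventricle" blob to exercise ROI-avoidance.  Background
    noise is clipped at ``noise_clip`` standard deviations (default 2.5) so
    that, for well-separated contrasts, the set of supra-threshold voxels is
    exactly the planted lesion; pass ``noise_clip=None`` for an unclipped
    Gaussian.  Returns ``(ImageVolume, truth_mask, ventricle_mask)`` where
    ``truth_mask`` marks the planted supra-threshold voxels.
    """
    if contrast < 0:
        raise ValueError("lesion contrast must be non-negative")
    lesion = _ellipsoid_mask(shape, spacing, lesion_center, lesion_axes)
    if contrast > 0 and not lesion.any():
        raise ValueError("lesion lies outside the grid")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    if noise_clip is not None:
        noise = np.clip(noise, -noise_clip, noise_clip)
    data = bg_mean + bg_std * noise
    data[lesion] += contrast
    vent = np.zeros(shape, dtype=bool)
    if ventricle_center is not None:
        vent = _ellipsoid_mask(shape, spacing, ventricle_center,
                               ventricle_axes)
        data[vent] = ventricle_intensity
    truth = lesion if contrast > 3.0 * bg_std else np.zeros(shape, dtype=bool)
    truth = truth & ~vent
    return ImageVolume(data, spacing), truth, vent


RED_HUE_WINDOWS = ((0.0, 20.0), (340.0, 360.0))


def red_pixel_area(rgb: np.ndarray, pixel_size: float,
                   roi_mask: np.ndarray | None = None,
                   hue_windows=RED_HUE_WINDOWS,
                   s_min: float = 0.3, v_min: float = 0.2) -> float:
    """Area (mm^2) of red-hued pixels inside an ROI.

    ``rgb`` is an (H, W, 3) array, uint8 or float in [0, 1].  A pixel is red
    iff its HSV hue (degrees, [0, 360)) falls in one of ``hue_windows`` and
    saturation/value are at or above the floors.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an RGB image with three channels")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rgbf = rgb[..., :3].astype(np.float64)
    if rgbf.max() > 1.0:
        rgbf = rgbf / 255.0
    import matplotlib.colors as mcolors
    hsv = mcolors.rgb_to_hsv(rgbf)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    red = np.zeros(hue.shape, dtype=bool)
    for lo, hi in hue_windows:
        red |= (hue >= lo) & (hue < hi)
    red &= (sat >= s_min) & (val >= v_min)
    if roi_mask is not None:
        red &= np.asarray(roi_mask, dtype=bool)
    return float(red.sum()) * pixel_size ** 2


def lesion_axes_from_pressure(mean_pressure: float, dummy_pressure: float,
                              gain_mm_per_mpa: float = 600.0,
                              aspect: tuple[float, float, float] = (1.0, 0.4, 0.5),
                              ) -> tuple[float, float, float]:
    """Surrogate mapping from steady maintain pressure to lesion axes (mm).

    The planted lesion's axes grow linearly with the pressure excess above
    the dummy (baseline) pressure — a stand-in for the observed growth of
    opening volume with target level; gain and aspect are arbitrary.
    """
    excess = max(mean_pressure - dummy_pressure, 0.0)
    d = gain_mm_per_mpa * excess
    return tuple(d * a for a in aspect)
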