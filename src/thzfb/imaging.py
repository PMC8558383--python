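"""Time-of-flight reflection-image analysis.

A raster-scanned reflection measurement yields a cube of waveforms,
one per (x, y) pixel.  Insect inclusions under the leaf bed attenuate
the reflected pulse and lengthen its flight time, so two per-pixel
scalars carry the contrast: a grayscale statistic of the waveform
(peak amplitude by default) and the arrival-time (delay) map.
Windowing the grayscale map to a narrow value interval — the digital
analogue of adjusting display levels — saturates the bright tea
background and leaves contrast only in the attenuated range, after
which thresholding, morphological cleaning and shape gates isolate
worm-like connected components.

Pixel coordinates are (row, col), origin top-left, 0-based; physical
coordinates are index times the raster step in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _label_components, regionprops
from skimage.morphology import opening as _morphological_opening

from .errors import InvalidArgumentError
from .spectra import TimeTrace
from .synthetic import THzImageCube


@dataclass
class GrayscaleMap:
    """A per-pixel scalar map plus its observed value range."""

    values: np.ndarray
    value_range: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("map values must be 2-D")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GrayscaleMap":
        values = np.asarray(values, dtype=float)
        return cls(values=values, value_range=(float(values.min()), float(values.max())))


@dataclass
class Component:
    """Shape summary of one connected component."""

    label: int
    centroid: tuple
    area_px: int
    eccentricity: float
    solidity: float


@dataclass
class DetectionResult:
    """Binary detection mask with per-component shape features.

    ``components`` lists every connected component of ``mask``;
    ``accepted`` is the subset passing the shape gates and flagged as
    foreign bodies.  ``label_image`` maps pixels to component labels.
    """

    mask: np.ndarray
    components: list
    accepted: list
    label_image: np.ndarray
    threshold: float
    metadata: dict = _field(default_factory=dict)


def roi_mean_waveform(
    cube: THzImageCube, center: tuple, radius_px: float
) -> TimeTrace:
    """Mean waveform over a circular region of interest.

    Pixel membership is decided by pixel-centre distance; the pixel
    count is recorded in the trace metadata.
    """
    nx, ny, _ = cube.shape
    rows, cols = np.mgrid[0:nx, 0:ny]
    cx, cy = center
    inside = (rows - cx) ** 2 + (cols - cy) ** 2 <= float(radius_px) ** 2
    n_pixels = int(inside.sum())
    if n_pixels == 0:
        raise InvalidArgumentError(
            f"ROI at {center} with radius {radius_px} contains no pixel centres"
        )
    waveform = cube.cube[inside].mean(axis=0)
    return TimeTrace(
        time=cube.time.copy(),
        field=waveform,
        metadata={"roi_center": tuple(center), "roi_radius_px": float(radius_px), "n_pixels": n_pixels},
    )


_STATISTICS = ("peak", "peak_to_peak", "energy")


def grayscale_map(cube: THzImageCube, statistic: str = "peak") -> GrayscaleMap:
    """Per-pixel scalar map of the reflected waveform.

    ``peak`` is max |E(t)| (the default grayscale; insect pixels are
    darker because the inclusion absorbs THz radiation),
    ``peak_to_peak`` is max - min and ``energy`` is sum E(t)^2.
    """
    if statistic == "peak":
        values = np.max(np.abs(cube.cube), axis=2)
    elif statistic == "peak_to_peak":
        values = np.ptp(cube.cube, axis=2)
    elif statistic == "energy":
        values = np.sum(cube.cube**2, axis=2)
    else:
        raise InvalidArgumentError(
            f"unknown statistic {statistic!r}; expected one of {_STATISTICS}"
        )
    return GrayscaleMap.from_values(values)


def delay_map(cube: THzImageCube) -> GrayscaleMap:
    """Per-pixel arrival time (ps) of the main positive field excursion.

    The THz pulse is antisymmetric (a derivative-of-Gaussian), so the
    magnitude |E| peaks equally on both lobes and an |E|-based argmax
    is ill-posed — grid alignment or noise then picks either lobe.
    The signed maximum is unique and marks the arrival of the leading
    positive lobe, which is what the flight time through a denser
    inclusion delays.  The discrete argmax is refined by a three-point
    parabolic fit, clamped to half a sample.  An all-zero pixel has
    argmax 0 and thus reports the first sample time — the documented
    degenerate-pixel convention.
    """
    if cube.shape[2] < 2:
        raise InvalidArgumentError("delay map needs at least two time samples")
    signal = cube.cube
    k = np.argmax(signal, axis=2)
    nx, ny, nt = cube.shape
    rows, cols = np.mgrid[0:nx, 0:ny]
    dt = float(cube.time[1] - cube.time[0])
    times = cube.time[k].astype(float)
    interior = (k > 0) & (k < nt - 1)
    km, k0, kp = k[interior] - 1, k[interior], k[interior] + 1
    r, c = rows[interior], cols[interior]
    ym, y0, yp = signal[r, c, km], signal[r, c, k0], signal[r, c, kp]
    denom = ym - 2.0 * y0 + yp
    safe = np.where(denom == 0.0, 1.0, denom)
    shift = np.where(denom != 0.0, 0.5 * (ym - yp) / safe, 0.0)
    times[interior] += np.clip(shift, -0.5, 0.5) * dt
    return GrayscaleMap.from_values(times)


def window_grayscale(gray: GrayscaleMap, lo: float, hi: float) -> GrayscaleMap:
    """Clamp values to [lo, hi] and rescale linearly onto [0, 1].

    Out-of-window pixels saturate at 0 or 1; a window around the
    attenuated value range reveals low-contrast inclusions the full
    dynamic range hides.
    """
    if not lo < hi:
        raise InvalidArgumentError("window requires lo < hi")
    values = np.clip((gray.values - lo) / (hi - lo), 0.0, 1.0)
    return GrayscaleMap.from_values(values)


def detect_foreign_bodies(
    gray: GrayscaleMap,
    threshold: float | str = "auto",
    min_area_px: int = 20,
    max_eccentricity: float = 0.97,
    min_solidity: float = 0.5,
) -> DetectionResult:
    """Shape-gated detection of attenuating inclusions.

    Pixels strictly below the threshold (Otsu on the map when
    ``threshold='auto'``) are candidates — inclusions absorb, so they
    are dark.  A 3x3 morphological opening removes speckle, connected
    components are taken with 8-connectivity, and components failing
    the area / eccentricity / solidity gates are kept in
    ``components`` but not in ``accepted``.
    """
    values = gray.values
    if min_area_px < 0:
        raise InvalidArgumentError("min_area_px must be >= 0")
    if threshold == "auto":
        thr = float(threshold_otsu(values))
    else:
        thr = float(threshold)
    candidates = values < thr
    opened = _morphological_opening(candidates, footprint=np.ones((3, 3), dtype=bool))
    labels = _label_components(opened, connectivity=2)
    components = []
    accepted = []
    for region in regionprops(labels):
        comp = Component(
            label=int(region.label),
            centroid=tuple(float(c) for c in region.centroid),
            area_px=int(region.area),
            eccentricity=float(region.eccentricity),
            solidity=float(region.solidity),
        )
        components.append(comp)
        if (
            comp.area_px >= min_area_px
            and comp.eccentricity <= max_eccentricity
            and comp.solidity >= min_solidity
        ):
            accepted.append(comp)
    return DetectionResult(
        mask=opened,
        components=components,
        accepted=accepted,
        label_image=labels,
        threshold=thr,
        metadata={
            "min_area_px": int(min_area_px),
            "max_eccentricity": float(max_eccentricity),
            "min_solidity": float(min_solidity),
        },
    )


def component_iou(result: DetectionResult, true_mask: np.ndarray) -> list[float]:
    """Best IoU of each accepted component against the true-mask regions.

    The ground-truth mask is split into its own connected components;
    each accepted detection reports its intersection-over-union with
    the best-matching truth region.
    """
    true_mask = np.asarray(true_mask, dtype=bool)
    true_labels = _label_components(true_mask, connectivity=2)
    n_true = int(true_labels.max())
    ious = []
    for comp in result.accepted:
        comp_mask = result.label_image == comp.label
        best = 0.0
        for t in range(1, n_true + 1):
            tmask = true_labels == t
            union = np.logical_or(comp_mask, tmask).sum()
            if union:
                best = max(best, float(np.logical_and(comp_mask, tmask).sum() / union))
        ious.append(best)
    return ious
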