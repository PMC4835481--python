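"""Automatic detection of tracer labeling in section images.

Pipeline (one section): grayscale extraction (raw channel or colour
deconvolution) -> automatic thresholding on a 256-bin histogram -> binary
median filtering (majority vote in a disc) -> connected-component labeling ->
size-range selection -> per-cluster area/centroid measurement.  Tracer
labeling is dark on a light background, so raw channels are inverted
(255 - I) to make "high value = more labeling" uniform across modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DegenerateHistogramError, DomainError
from .stain_separation import StainProfile, deconvolve

__all__ = [
    "DetectionParams",
    "LabelingMap",
    "ClusterRecord",
    "to_gray",
    "histogram_256",
    "auto_threshold",
    "median_filter_binary",
    "label_clusters",
    "filter_by_size",
    "measure_clusters",
    "process_section",
    "process_series",
    "injection_site_volume",
    "records_to_frame",
    "THRESHOLD_METHODS",
]

GRAY_MODES = ("red", "green", "blue", "deconv")
THRESHOLD_METHODS = ("otsu", "isodata", "mean", "triangle", "yen", "fixed")


@dataclass(frozen=True)
class DetectionParams:
    """Per-batch configuration of the detection pipeline.

    pixel_size is in micrometres per pixel; min_area/max_area in pixels;
    median_radius in pixels (0 disables the noise filter).
    """

    gray_mode: str = "deconv"
    profile: Optional[StainProfile] = None
    threshold_method: str = "otsu"
    fixed_threshold: Optional[float] = None
    median_radius: int = 2
    min_area: int = 1
    max_area: Optional[int] = None
    pixel_size: float = 1.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.gray_mode not in GRAY_MODES:
            raise ConfigurationError(f"gray_mode must be one of {GRAY_MODES}, got {self.gray_mode!r}")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ConfigurationError(
                f"threshold_method must be one of {THRESHOLD_METHODS}, got {self.threshold_method!r}"
            )
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigurationError("threshold_method 'fixed' requires fixed_threshold")
        if self.gray_mode == "deconv" and self.profile is None:
            raise ConfigurationError("gray_mode 'deconv' requires a stain profile")
        if int(self.median_radius) != self.median_radius or self.median_radius < 0:
            raise ConfigurationError(f"median_radius must be an integer >= 0, got {self.median_radius}")
        if self.max_area is not None and self.min_area > self.max_area:
            raise ConfigurationError(f"min_area ({self.min_area}) > max_area ({self.max_area})")
        if self.pixel_size <= 0:
            raise ConfigurationError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass(frozen=True)
class ClusterRecord:
    """One detected labeled cluster on one section."""

    section_id: str
    cluster_id: int
    area_px: int
    area_mm2: float
    centroid_x_px: float
    centroid_y_px: float


@dataclass
class LabelingMap:
    """Binary labeling map of one section, with detection provenance."""

    section_id: str
    mask: np.ndarray
    params: DetectionParams
    threshold: float


def to_gray(rgb: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Extract the grayscale plane used for thresholding.

    Raw channels are inverted (255 - I); in deconv mode the primary
    deconvolved density plane is returned unchanged (already labeling-high).
    """
    rgb = np.asarray(rgb)
    if params.gray_mode == "deconv":
        assert params.profile is not None
        return deconvolve(rgb, params.profile)[..., params.profile.primary_index]
    chan = {"red": 0, "green": 1, "blue": 2}[params.gray_mode]
    return 255.0 - rgb[..., chan].astype(float)


def histogram_256(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram over the image's value range: (counts, bin centers)."""
    gray = np.asarray(gray, dtype=float)
    lo, hi = float(gray.min()), float(gray.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image: histogram has a single bin")
    counts, edges = np.histogram(gray.ravel(), bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def _otsu(counts: np.ndarray, centers: np.ndarray) -> float:
    p = counts / counts.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    valid = (w0 > 0) & (w0 < 1)
    sigma_b = np.full(256, -np.inf)
    sigma_b[valid] = (mu_t * w0[valid] - mu[valid]) ** 2 / (w0[valid] * (1 - w0[valid]))
    k = int(np.argmax(sigma_b))
    return float(centers[k])


def _isodata(counts: np.ndarray, centers: np.ndarray) -> float:
    w = counts
    t = float(np.average(centers, weights=w))
    for _ in range(512):
        low = centers <= t
        if w[low].sum() == 0 or w[~low].sum() == 0:
            break
        mu0 = np.average(centers[low], weights=w[low])
        mu1 = np.average(centers[~low], weights=w[~low])
        t_new = 0.5 * (mu0 + mu1)
        if abs(t_new - t) < 1e-9:
            t = t_new
            break
        t = t_new
    return float(t)


def _mean(counts: np.ndarray, centers: np.ndarray) -> float:
    return float(np.average(centers, weights=counts))


def _triangle(counts: np.ndarray, centers: np.ndarray) -> float:
    h = counts / counts.max()
    nz = np.nonzero(counts)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    p = int(np.argmax(counts))
    # work on the longer tail; flip so it lies to the right of the peak
    if (p - lo) > (hi - p):
        h = h[::-1]
        p, hi = 255 - p, 255 - lo
        flipped = True
    else:
        flipped = False
    if hi == p:
        raise DegenerateHistogramError("triangle: no tail on either side of the peak")
    # perpendicular distance from (x, h_x) to chord (p, h_p) -> (hi, h_hi),
    # x normalized so height and tail length are on comparable scales
    x = (np.arange(p, hi + 1) - p) / (hi - p)
    y = h[p : hi + 1]
    dx, dy = 1.0, h[hi] - h[p]
    dist = np.abs(dx * (h[p] - y) + dy * (x - 0.0)) / np.hypot(dx, dy)
    k = p + int(np.argmax(dist))
    if flipped:
        k = 255 - k
    return float(centers[k])


def _yen(counts: np.ndarray, centers: np.ndarray) -> float:
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    p1sq = np.cumsum(p * p)
    p2sq = np.cumsum((p * p)[::-1])[::-1]  # p2sq[k] = sum of p_i^2 for i >= k
    # split after bin k: low class = bins 0..k, high class = bins k+1..255
    w, lowsq, highsq = p1[:-1], p1sq[:-1], p2sq[1:]
    crit = np.full(255, -np.inf)
    valid = (w > 0) & (w < 1) & (lowsq > 0) & (highsq > 0)
    crit[valid] = -np.log(lowsq[valid] * highsq[valid]) + 2.0 * np.log(w[valid] * (1.0 - w[valid]))
    k = int(np.argmax(crit))
    return float(centers[k])


_METHODS = {"otsu": _otsu, "isodata": _isodata, "mean": _mean, "triangle": _triangle, "yen": _yen}


def auto_threshold(gray: np.ndarray, method: str) -> float:
    """Compute an automatic threshold on a 256-bin histogram.

    Pixels strictly greater than the returned value are classified as
    labeled.  Methods: otsu (maximal between-class variance), isodata
    (mean-of-means fixed point), mean (histogram mean), triangle (maximal
    distance to the peak-tail chord), yen (maximal Yen criterion).
    """
    if method not in _METHODS:
        raise ConfigurationError(f"unknown thresholding method {method!r}")
    try:
        counts, centers = histogram_256(gray)
    except DegenerateHistogramError as exc:
        raise DegenerateHistogramError(f"{method}: {exc}") from None
    return _METHODS[method](counts, centers)


def disc_footprint(radius: int) -> np.ndarray:
    """Boolean disc: offset (i, j) included iff i^2 + j^2 <= r^2."""
    r = int(radius)
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    return ii * ii + jj * jj <= r * r


def median_filter_binary(mask: np.ndarray, radius: int) -> np.ndarray:
    """Majority vote of each pixel's disc neighborhood (binary median filter).

    Border pixels are handled by edge replication; radius 0 is the identity.
    """
    if radius < 0:
        raise DomainError(f"median filter radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    out = ndimage.median_filter(mask.astype(np.uint8), footprint=disc_footprint(radius), mode="nearest")
    return out.astype(bool)


def label_clusters(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary mask.

    Returns (label image with labels 1..K, background 0; array of component
    sizes indexed 1..K with a leading 0 entry for background).
    """
    if connectivity not in (4, 8):
        raise ConfigurationError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    sizes[0] = 0
    return labels, sizes


def filter_by_size(
    labels: np.ndarray, min_area: int, max_area: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Keep components whose pixel area is within [min_area, max_area].

    Returns (filtered boolean mask, filtered label image with the original
    label ids of the survivors).
    """
    if max_area is not None and min_area > max_area:
        raise ConfigurationError(f"min_area ({min_area}) > max_area ({max_area})")
    labels = np.asarray(labels)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes >= min_area
    if max_area is not None:
        keep &= sizes <= max_area
    keep[0] = False
    survivor = keep[labels]
    out_labels = np.where(survivor, labels, 0)
    return survivor, out_labels


def measure_clusters(
    labels: np.ndarray, pixel_size: float, section_id: str = ""
) -> list[ClusterRecord]:
    """Measure area and centroid of every labeled component.

    Centroid is the arithmetic mean of member pixel coordinates, x right
    (column), y down (row), 0-based, pixel centers at integers.  Cluster ids
    are renumbered 1..K in ascending original label order.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    mm_per_px = pixel_size / 1000.0
    records = []
    for k, (lab, area, (cy, cx)) in enumerate(zip(ids, areas, centroids), start=1):
        records.append(
            ClusterRecord(
                section_id=section_id,
                cluster_id=k,
                area_px=int(round(area)),
                area_mm2=float(area) * mm_per_px**2,
                centroid_x_px=float(cx),
                centroid_y_px=float(cy),
            )
        )
    return records


def process_section(
    rgb: np.ndarray, params: DetectionParams, section_id: str = ""
) -> tuple[LabelingMap, list[ClusterRecord]]:
    """Run the full detection pipeline on one section image."""
    gray = to_gray(rgb, params)
    if params.threshold_method == "fixed":
        threshold = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        threshold = auto_threshold(gray, params.threshold_method)
    mask = gray > threshold
    mask = median_filter_binary(mask, params.median_radius)
    labels, _ = label_clusters(mask, params.connectivity)
    mask, labels = filter_by_size(labels, params.min_area, params.max_area)
    records = measure_clusters(labels, params.pixel_size, section_id)
    return LabelingMap(section_id=section_id, mask=mask, params=params, threshold=threshold), records


def records_to_frame(records: Iterable[ClusterRecord]) -> pd.DataFrame:
    """Collect ClusterRecords into the comprehensive results table."""
    cols = ["section_id", "cluster_id", "area_px", "area_mm2", "centroid_x_px", "centroid_y_px"]
    rows = [[getattr(r, c) for c in cols] for r in records]
    return pd.DataFrame(rows, columns=cols)


def process_series(
    sections: Sequence[tuple[str, np.ndarray]],
    params_by_batch: Mapping[str, DetectionParams],
    batch_of_section: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, dict[str, LabelingMap]]:
    """Process a whole image series, one parameter set per staining batch.

    ``batch_of_section`` maps section id -> batch id; it may be omitted when
    there is exactly one batch.  Sections lacking batch parameters raise a
    ConfigurationError that lists them.
    """
    if batch_of_section is None:
        if len(params_by_batch) != 1:
            raise ConfigurationError(
                "batch_of_section is required when more than one batch is configured"
            )
        only = next(iter(params_by_batch))
        batch_of_section = {sid: only for sid, _ in sections}
    missing = [
        sid
        for sid, _ in sections
        if sid not in batch_of_section or batch_of_section[sid] not in params_by_batch
    ]
    if missing:
        raise ConfigurationError(f"sections without batch parameters: {missing}")
    all_records: list[ClusterRecord] = []
    maps: dict[str, LabelingMap] = {}
    for sid, rgb in sections:
        lmap, recs = process_section(rgb, params_by_batch[batch_of_section[sid]], section_id=sid)
        maps[sid] = lmap
        all_records.extend(recs)
    return records_to_frame(all_records), maps


def injection_site_volume(areas_mm2: Sequence[float], section_spacing_mm: float) -> float:
    """Cavalieri volume estimate: sum of per-section areas times spacing (mm^3)."""
    if section_spacing_mm <= 0:
        raise DomainError(f"section spacing must be positive, got {section_spacing_mm}")
    return float(np.sum(np.asarray(areas_mm2, dtype=float))) * float(section_spacing_mm)
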