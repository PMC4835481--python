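"""Synthetic test material: rendered tracer sections and phantom atlas volumes.

Histology stand-ins are built by the same physics the pipeline inverts: per
-stain density fields (dense tracer clusters, thin "weak" fibers, a smooth
counterstain field, exponential-tailed background noise) are combined into
optical densities through a stain profile and forward-rendered to 8-bit RGB
via Beer-Lambert.  Phantom NIfTI volumes carry known affines, analytically
defined template fields (linear fields make trilinear interpolation exactly
checkable) and labeled box/ellipsoid regions.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .atlas_volume import AtlasVolume, Anchoring, extract_slice
from .errors import ConfigurationError, DomainError
from .labeling_detection import measure_clusters
from .series_anchoring import apply_affine_registration
from .stain_separation import StainProfile, complete_stain_matrix, od_to_rgb

__all__ = [
    "PlantedCluster",
    "FiberScene",
    "Region",
    "PhantomVolumeSpec",
    "CALIBRATION_PROFILE",
    "default_scene",
    "make_fiber_image",
    "make_phantom_volume",
    "make_section_series",
    "blob_pixels",
    "fiber_pixels",
]

#: Default synthetic calibration profile: two well-separated stain vectors
#: (tracer mostly red-absorbing, counterstain mostly blue-absorbing) whose
#: matrix is well conditioned, keeping deconvolution quantization-limited.
CALIBRATION_PROFILE = StainProfile(
    name="synthetic-calibration",
    vectors=complete_stain_matrix((0.9806, 0.1961, 0.0), (0.0, 0.1961, 0.9806)),
    primary_index=0,
)


@dataclass(frozen=True)
class PlantedCluster:
    """Ground-truth cluster: member pixels, density amplitude, stain index."""

    pixels: tuple[tuple[int, int], ...]  # (row, col) pairs
    amplitude: float
    stain_index: int = 0

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    @property
    def centroid_px(self) -> tuple[float, float]:
        """(x, y) mean of member pixel coordinates."""
        rc = np.asarray(self.pixels, dtype=float)
        return float(rc[:, 1].mean()), float(rc[:, 0].mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rc = np.asarray(self.pixels, dtype=int)
        m[rc[:, 0], rc[:, 1]] = True
        return m


@dataclass
class FiberScene:
    """Specification of one synthetic section image."""

    shape: tuple[int, int]  # (H, W)
    clusters: list[PlantedCluster] = field(default_factory=list)
    noise_amplitude: float = 0.0
    counterstain_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for c in self.clusters:
            if c.amplitude < 0:
                raise DomainError("cluster amplitudes must be non-negative")
            px = set(c.pixels)
            if px & seen:
                raise ConfigurationError("planted cluster pixel sets must be disjoint")
            seen |= px
        if self.noise_amplitude < 0 or self.counterstain_amplitude < 0:
            raise DomainError("noise and counterstain amplitudes must be non-negative")


def blob_pixels(center: tuple[int, int], radius: int, shape: tuple[int, int]) -> tuple:
    """Disc-shaped cluster clipped to the image: (row, col) pixel tuple."""
    r0, c0 = center
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius * radius
    return tuple(zip(*np.nonzero(m)))


def fiber_pixels(
    rng: np.random.Generator,
    start: tuple[int, int],
    n_steps: int,
    shape: tuple[int, int],
    width: int = 1,
) -> tuple:
    """Dilated random-walk polyline emulating a thin labeled fiber."""
    pos = np.asarray(start, dtype=float)
    direction = rng.uniform(0, 2 * np.pi)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_steps):
        direction += rng.normal(0.0, 0.35)
        pos = pos + np.array([np.sin(direction), np.cos(direction)])
        r, c = int(round(pos[0])), int(round(pos[1]))
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            mask[r, c] = True
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width - 1)
    return tuple(zip(*np.nonzero(mask)))


def default_scene(
    shape: tuple[int, int] = (256, 256),
    n_strong: int = 4,
    n_weak: int = 3,
    strong_amplitude: float = 0.9,
    weak_amplitude: float = 0.15,
    noise_amplitude: float = 0.05,
    counterstain_amplitude: float = 0.3,
    seed: int = 0,
) -> FiberScene:
    """A scene with dense tracer clusters and near-noise "weak" fibers.

    Strong blob clusters model terminal fields (density well above the
    background noise); weak dilated-random-walk fibers sit near the noise
    floor and are expected to fragment or vanish after thresholding, like
    weakly labeled solitary axons do.
    """
    rng = np.random.default_rng(seed)
    clusters: list[PlantedCluster] = []
    occupied = np.zeros(shape, dtype=bool)
    margin = 6  # keep planted objects separated so they stay distinct clusters

    def _claim(pixels) -> Optional[tuple]:
        if not pixels:
            return None
        cand = np.zeros(shape, dtype=bool)
        rc = np.asarray(pixels, dtype=int)
        cand[rc[:, 0], rc[:, 1]] = True
        halo = ndimage.binary_dilation(cand, iterations=margin)
        if (halo & occupied).any():
            return None
        occupied[halo] = True
        return pixels

    attempts = 0
    while sum(1 for c in clusters if c.amplitude >= strong_amplitude) < n_strong and attempts < 200:
        attempts += 1
        center = (int(rng.integers(20, shape[0] - 20)), int(rng.integers(20, shape[1] - 20)))
        radius = int(rng.integers(5, 10))
        px = _claim(blob_pixels(center, radius, shape))
        if px is not None:
            clusters.append(PlantedCluster(pixels=px, amplitude=strong_amplitude))
    attempts = 0
    n_placed_weak = 0
    while n_placed_weak < n_weak and attempts < 200:
        attempts += 1
        start = (int(rng.integers(10, shape[0] - 10)), int(rng.integers(10, shape[1] - 10)))
        px = _claim(fiber_pixels(rng, start, n_steps=40, shape=shape, width=2))
        if px is not None:
            clusters.append(PlantedCluster(pixels=px, amplitude=weak_amplitude))
            n_placed_weak += 1
    return FiberScene(
        shape=shape,
        clusters=clusters,
        noise_amplitude=noise_amplitude,
        counterstain_amplitude=counterstain_amplitude,
        seed=seed,
    )


def make_fiber_image(
    scene: FiberScene, profile: StainProfile = CALIBRATION_PROFILE, i0: float = 255.0
) -> tuple[np.ndarray, dict]:
    """Forward-render a scene to RGB; return (image, ground truth).

    Ground truth holds per-cluster masks and records (areas/centroids
    measured on the noiseless pixel sets), plus the full per-stain density
    fields used for rendering.
    """
    h, w = scene.shape
    rng = np.random.default_rng(scene.seed)
    densities = np.zeros((h, w, 3))
    for cluster in scene.clusters:
        rc = np.asarray(cluster.pixels, dtype=int)
        densities[rc[:, 0], rc[:, 1], cluster.stain_index] += cluster.amplitude
    if scene.counterstain_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        smooth = 0.5 * (1 + np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / h))
        densities[..., 1] += scene.counterstain_amplitude * smooth
    if scene.noise_amplitude > 0:
        densities[..., profile.primary_index] += rng.exponential(
            scale=scene.noise_amplitude, size=(h, w)
        )
    od = densities @ profile.matrix
    if np.any(od < 0):
        raise DomainError("scene produced negative optical densities")
    rgb = od_to_rgb(od, i0)
    truth = {
        "clusters": list(scene.clusters),
        "masks": [c.mask(scene.shape) for c in scene.clusters],
        "records": [
            measure_clusters(c.mask(scene.shape).astype(int), pixel_size=1.0, section_id="truth")[0]
            for c in scene.clusters
        ],
        "densities": densities,
    }
    return rgb, truth


@dataclass(frozen=True)
class Region:
    """A labeled phantom region: axis-aligned box or ellipsoid in voxel coords."""

    label: int
    name: str
    shape: str  # "box" | "ellipsoid"
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def rasterize(self, dims: tuple[int, int, int]) -> np.ndarray:
        xx, yy, zz = np.mgrid[0 : dims[0], 0 : dims[1], 0 : dims[2]].astype(float)
        dx = xx - self.center[0]
        dy = yy - self.center[1]
        dz = zz - self.center[2]
        rx, ry, rz = self.radii
        if self.shape == "box":
            return (np.abs(dx) <= rx) & (np.abs(dy) <= ry) & (np.abs(dz) <= rz)
        if self.shape == "ellipsoid":
            return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
        raise ConfigurationError(f"unknown region shape {self.shape!r}")


@dataclass
class PhantomVolumeSpec:
    """Phantom atlas: dims, affine, labeled regions and a template field.

    template_field is either ("linear", (a, b, c, d)) giving
    f(x, y, z) = a*x + b*y + c*z + d, or ("blobs", seed) for a smooth random
    mixture.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    regions: list[Region] = field(default_factory=list)
    template_field: tuple = ("linear", (1.0, 2.0, 3.0, 0.0))


def make_phantom_volume(
    spec: PhantomVolumeSpec, path: Optional[str | Path] = None
) -> AtlasVolume:
    """Build (and optionally write to NIfTI) a phantom template + label volume."""
    dims = tuple(int(d) for d in spec.dims)
    kind, params = spec.template_field
    if kind == "linear":
        a, b, c, d = params
        xx, yy, zz = np.mgrid[0 : dims[0], 0 : dims[1], 0 : dims[2]].astype(float)
        template = a * xx + b * yy + c * zz + d
    elif kind == "blobs":
        rng = np.random.default_rng(int(params))
        template = ndimage.gaussian_filter(rng.normal(size=dims), sigma=3.0)
        template = (template - template.min()) * 100.0
    else:
        raise ConfigurationError(f"unknown template field kind {kind!r}")
    labels = np.zeros(dims, dtype=np.int16)
    ids = [r.label for r in spec.regions]
    if len(ids) != len(set(ids)):
        raise ConfigurationError("region labels must be unique")
    for region in spec.regions:
        m = region.rasterize(dims)
        if not m.any():
            raise ConfigurationError(f"region {region.label} is empty within the volume")
        if (labels[m] != 0).any():
            raise ConfigurationError(f"region {region.label} overlaps another region")
        labels[m] = region.label
    names = {r.label: r.name for r in spec.regions}
    volume = AtlasVolume(
        template=template, affine=np.asarray(spec.affine, dtype=float),
        labels=labels, label_names=names,
    )
    if path is not None:
        path = Path(path)
        nib.save(nib.Nifti1Image(template.astype(np.float32), volume.affine), str(path))
        label_path = path.with_name(path.name.replace(".nii", "_labels.nii"))
        nib.save(nib.Nifti1Image(labels, volume.affine), str(label_path))
    return volume


def make_section_series(
    volume: AtlasVolume,
    true_anchorings: Sequence[Anchoring],
    perturbations: Optional[Sequence[tuple[np.ndarray, tuple[float, float]]]] = None,
    noise: float = 0.0,
    out_w: int = 64,
    out_h: int = 64,
    seed: int = 0,
) -> tuple[list[np.ndarray], dict]:
    """Simulate a cut section series from a phantom volume.

    Each section is the template slice at the true anchoring composed with a
    known in-plane affine perturbation (A, t), plus seeded Gaussian noise.
    The truth dict records anchorings and perturbations for registration
    round-trip tests.
    """
    if perturbations is None:
        perturbations = [(np.eye(2), (0.0, 0.0))] * len(true_anchorings)
    if len(perturbations) != len(true_anchorings):
        raise ConfigurationError("one perturbation per anchoring required")
    rng = np.random.default_rng(seed)
    images = []
    for anchor, (A, t) in zip(true_anchorings, perturbations):
        perturbed = apply_affine_registration(anchor, np.asarray(A, dtype=float), t)
        img = extract_slice(volume, perturbed, out_w, out_h, channel="template")
        if noise > 0:
            img = img + rng.normal(0.0, noise, img.shape)
        images.append(img)
    truth = {
        "anchorings": [a.to_dict() for a in true_anchorings],
        "perturbations": [
            {"A": np.asarray(A).tolist(), "t": list(t)} for A, t in perturbations
        ],
    }
    return images, truth
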