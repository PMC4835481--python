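"""Colour deconvolution of brightfield histology into per-stain density images.

Brightfield stains mix linearly in optical-density (OD) space (Beer-Lambert):
for incident intensity ``i0`` and transmitted intensity ``I`` in channel *c*,

    OD_c = -log10(I_c / i0)

and a pixel holding densities ``d_s`` of stains with unit OD direction
vectors ``v_s`` has ``OD = sum_s d_s * v_s``.  Inverting the 3x3 stain matrix
recovers the per-stain densities; the tracer stain (BDA or Pha-L, dark
reaction product) is the *primary* channel used downstream for labeling
detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DimensionalityError, DomainError, SingularMatrixError

__all__ = [
    "StainProfile",
    "BUILTIN_PROFILES",
    "rgb_to_od",
    "od_to_rgb",
    "complete_stain_matrix",
    "acquire_stain_vectors",
    "deconvolve",
]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class StainProfile:
    """A named set of unit OD direction vectors for a stain combination.

    Parameters
    ----------
    name:
        Label of the tracer/counterstain combination (e.g. ``"BDA+NeutralRed"``).
    vectors:
        3x3 array; each row is one stain's OD direction (R, G, B), unit
        Euclidean norm, all components non-negative.
    primary_index:
        Row index of the tracer stain — the "primary output channel".
    """

    name: str
    vectors: np.ndarray
    primary_index: int = 0

    def __post_init__(self) -> None:
        vecs = np.asarray(self.vectors, dtype=float)
        if vecs.shape != (3, 3):
            raise DimensionalityError(
                f"stain profile needs a 3x3 vector matrix, got shape {vecs.shape}"
            )
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise DomainError(f"stain vectors must be unit length, norms={norms}")
        if np.any(vecs < 0):
            raise DomainError("stain vector components must be non-negative")
        if self.primary_index not in (0, 1, 2):
            raise DomainError(f"primary_index must be 0, 1 or 2, got {self.primary_index}")
        object.__setattr__(self, "vectors", vecs)
        self.vectors.setflags(write=False)

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 stain matrix (rows = stain vectors)."""
        return self.vectors

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "vectors": self.vectors.tolist(),
                "primary_index": self.primary_index,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StainProfile":
        d = json.loads(text)
        return cls(
            name=d["name"],
            vectors=np.asarray(d["vectors"], dtype=float),
            primary_index=int(d["primary_index"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "StainProfile":
        return cls.from_json(Path(path).read_text())


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DomainError("cannot normalize a (near-)zero stain vector")
    return v / n


def rgb_to_od(rgb: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB image to optical densities per channel.

    Zero intensities are clamped to 1 before the logarithm so the OD stays
    finite; resulting densities are clipped at 0 (an intensity above ``i0``
    carries no stain).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise DimensionalityError(f"expected an HxWx3 RGB image, got shape {rgb.shape}")
    if i0 <= 0:
        raise DomainError(f"background intensity i0 must be positive, got {i0}")
    intens = np.maximum(rgb.astype(float), 1.0)
    od = -np.log10(intens / float(i0))
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Forward Beer-Lambert render: OD image -> 8-bit RGB.

    Rounds half away from zero and clips to [0, 255]; inverse of
    :func:`rgb_to_od` up to quantization for intensities >= 1.
    """
    od = np.asarray(od, dtype=float)
    if np.any(od < 0) or not np.all(np.isfinite(od)):
        raise DomainError("optical densities must be finite and non-negative")
    intens = float(i0) * np.power(10.0, -od)
    # round half away from zero (values are non-negative here)
    return np.clip(np.floor(intens + 0.5), 0, 255).astype(np.uint8)


def complete_stain_matrix(v1: Sequence[float], v2: Sequence[float]) -> np.ndarray:
    """Build an invertible 3x3 stain matrix from two stain vectors.

    Rows are the unit-normalized inputs plus a third vector orthogonal to
    both: the normalized cross product with components made non-negative by
    taking absolute values (the convention of ImageJ-style colour
    deconvolution for two-stain images).
    """
    u1 = _normalize(v1)
    u2 = _normalize(v2)
    cross = np.cross(u1, u2)
    if np.linalg.norm(cross) < 1e-9:
        raise SingularMatrixError("stain vectors are parallel; matrix would be singular")
    u3 = _normalize(np.abs(cross))
    m = np.vstack([u1, u2, u3])
    if abs(np.linalg.det(m)) <= 1e-6:
        raise SingularMatrixError("completed stain matrix is numerically singular")
    return m


def acquire_stain_vectors(
    rgb: np.ndarray,
    rois: Sequence[np.ndarray],
    i0: float = 255.0,
    name: str = "acquired",
    primary_index: int = 0,
) -> StainProfile:
    """Estimate stain vectors from user-marked single-stain regions.

    Each ROI is a boolean mask over the image marking pixels dominated by one
    stain; its vector is the unit-normalized mean OD over the ROI.  With two
    ROIs the third vector is completed via :func:`complete_stain_matrix`.
    """
    if len(rois) not in (2, 3):
        raise DomainError(f"need 2 or 3 ROIs, got {len(rois)}")
    od = rgb_to_od(rgb, i0)
    vectors = []
    for k, roi in enumerate(rois):
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != rgb.shape[:2]:
            raise DimensionalityError(f"ROI {k} shape {roi.shape} != image {rgb.shape[:2]}")
        if not roi.any():
            raise DomainError(f"ROI {k} is empty")
        mean_od = od[roi].mean(axis=0)
        if np.linalg.norm(mean_od) < 1e-9:
            raise DomainError(f"ROI {k} has zero mean OD (pure white carries no stain)")
        vectors.append(_normalize(mean_od))
    if len(vectors) == 2:
        matrix = complete_stain_matrix(vectors[0], vectors[1])
    else:
        matrix = np.vstack(vectors)
        if abs(np.linalg.det(matrix)) <= 1e-6:
            raise SingularMatrixError("acquired stain vectors are linearly dependent")
    return StainProfile(name=name, vectors=matrix, primary_index=primary_index)


def deconvolve(rgb: np.ndarray, profile: StainProfile, i0: float = 255.0) -> np.ndarray:
    """Recover per-stain density images from an RGB image.

    Solves ``OD = d @ M`` per pixel (``M`` rows = stain vectors) and clamps
    negative solutions to 0.  Returns an HxWx3 array of density planes; the
    tracer plane is ``result[..., profile.primary_index]``.
    """
    m = profile.matrix
    det = np.linalg.det(m)
    if abs(det) <= 1e-6:
        raise SingularMatrixError(f"stain matrix is singular (det={det:.2e})")
    od = rgb_to_od(rgb, i0)
    dens = od.reshape(-1, 3) @ np.linalg.inv(m)
    return np.maximum(dens, 0.0).reshape(od.shape)


def _profile(name: str, v1, v2, primary_index: int = 0) -> StainProfile:
    return StainProfile(name=name, vectors=complete_stain_matrix(v1, v2), primary_index=primary_index)


#: Built-in profiles for the supported tracer/counterstain combinations.
#: The vectors are plausible placeholders (DAB-like tracer reaction product,
#: Neutral Red / thionine counterstains), NOT calibrated against real
#: material — acquire series-specific vectors with acquire_stain_vectors or
#: override via a JSON profile file for quantitative work.
BUILTIN_PROFILES: dict[str, StainProfile] = {
    "BDA": _profile("BDA", (0.27, 0.57, 0.78), (0.58, 0.58, 0.58)),
    "BDA+NeutralRed": _profile("BDA+NeutralRed", (0.27, 0.57, 0.78), (0.21, 0.85, 0.48)),
    "PhaL": _profile("PhaL", (0.30, 0.60, 0.74), (0.58, 0.58, 0.58)),
    "PhaL+thionine": _profile("PhaL+thionine", (0.30, 0.60, 0.74), (0.60, 0.72, 0.35)),
    "BDA+CO": _profile("BDA+CO", (0.27, 0.57, 0.78), (0.52, 0.62, 0.59)),
}
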