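"""Coordinate transforms (voxel / WHS mm / stereotaxic mm) and region lookup.

Waxholm Space (WHS) millimetre coordinates come from the NIfTI affine.
Stereotaxic coordinates are bregma-referenced: (ML, AP, DV) with ML positive
to the right, AP anterior-positive from bregma, and DV negative ventral to
bregma.  The WHS -> stereotaxic mapping composes a translation to bregma, an
axis permutation, a pitch rotation about the ML axis (default -4.085 deg, the
flat-skull vs. template pitch difference) and a uniform scale (default 1.057,
from the bregma-lambda anteroposterior distance ratio of the two atlases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas_volume import AtlasVolume, Anchoring, nearest_sample
from .errors import ConfigurationError, DomainError, SingularMatrixError
from .labeling_detection import ClusterRecord
from .series_anchoring import section_point_to_voxel

__all__ = [
    "StereotaxicTransform",
    "DEFAULT_BREGMA_WHS",
    "voxel_to_whs",
    "whs_to_voxel",
    "whs_to_stereotaxic",
    "stereotaxic_to_whs",
    "assign_region",
    "build_report",
]

#: Approximate WHS (mm) position of bregma for the SD rat template.  The
#: skull landmark is not part of the MRI volume, so this default is an
#: estimate for convenience only — override it with a measured value for any
#: quantitative use.
DEFAULT_BREGMA_WHS = np.array([0.0, 1.18, 7.10])


@dataclass(frozen=True)
class StereotaxicTransform:
    """Bregma-referenced rotation + uniform scale from WHS mm to stereotaxic mm.

    axis_map is a signed permutation taking WHS (x, y, z) to stereotaxic
    (ML, AP, DV); the default assumes RAS-like WHS orientation (x right,
    y anterior, z superior), i.e. the identity.
    """

    bregma_whs: np.ndarray = field(default_factory=lambda: DEFAULT_BREGMA_WHS.copy())
    rotation_deg: float = -4.085
    scale: float = 1.057
    axis_map: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "bregma_whs", np.asarray(self.bregma_whs, dtype=float))
        object.__setattr__(self, "axis_map", np.asarray(self.axis_map, dtype=float))
        if self.bregma_whs.shape != (3,):
            raise DomainError("bregma_whs must be a 3-vector")
        if self.scale <= 0:
            raise DomainError(f"scale must be positive, got {self.scale}")
        m = self.axis_map
        if m.shape != (3, 3) or not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise DomainError("axis_map must be an orthogonal 3x3 matrix")
        if abs(abs(np.linalg.det(m)) - 1.0) > 1e-9:
            raise DomainError("axis_map determinant must be +-1")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Pitch rotation about the ML (first stereotaxic) axis."""
        c = np.cos(np.deg2rad(self.rotation_deg))
        s = np.sin(np.deg2rad(self.rotation_deg))
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

    @classmethod
    def from_config(cls, path) -> "StereotaxicTransform":
        """Load from a YAML/JSON mapping {bregma_whs, rotation_deg, scale, axis_map}."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        kwargs = {}
        if "bregma_whs" in cfg:
            kwargs["bregma_whs"] = np.asarray(cfg["bregma_whs"], dtype=float)
        if "rotation_deg" in cfg:
            kwargs["rotation_deg"] = float(cfg["rotation_deg"])
        if "scale" in cfg:
            kwargs["scale"] = float(cfg["scale"])
        if "axis_map" in cfg:
            kwargs["axis_map"] = np.asarray(cfg["axis_map"], dtype=float)
        return cls(**kwargs)


def voxel_to_whs(affine: np.ndarray, p_voxel: np.ndarray) -> np.ndarray:
    """Homogeneous voxel -> mm transform (supports single points and arrays)."""
    affine = np.asarray(affine, dtype=float)
    p = np.asarray(p_voxel, dtype=float)
    return p @ affine[:3, :3].T + affine[:3, 3]


def whs_to_voxel(affine: np.ndarray, p_mm: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_whs`."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise SingularMatrixError("affine is not invertible")
    p = np.asarray(p_mm, dtype=float)
    return (p - affine[:3, 3]) @ np.linalg.inv(affine[:3, :3]).T


def whs_to_stereotaxic(T: StereotaxicTransform, p_mm: np.ndarray) -> np.ndarray:
    """WHS mm -> stereotaxic (ML, AP, DV) mm relative to bregma."""
    p = np.asarray(p_mm, dtype=float)
    m = T.scale * (T.rotation_matrix @ T.axis_map)
    return (p - T.bregma_whs) @ m.T


def stereotaxic_to_whs(T: StereotaxicTransform, q: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`whs_to_stereotaxic`."""
    q = np.asarray(q, dtype=float)
    m = T.scale * (T.rotation_matrix @ T.axis_map)
    return q @ np.linalg.inv(m).T + T.bregma_whs


def assign_region(volume: AtlasVolume, p_voxel: np.ndarray) -> tuple[int, str]:
    """Region identity at a voxel point: nearest label; 0 -> "unassigned"."""
    if volume.labels is None:
        raise ConfigurationError("volume has no label array; cannot assign regions")
    label = int(nearest_sample(volume.labels, np.asarray(p_voxel, dtype=float)))
    if label == 0:
        return 0, "unassigned"
    return label, volume.label_names.get(label, "unassigned")


REPORT_COLUMNS = [
    "section_id",
    "cluster_id",
    "area_mm2",
    "voxel_x",
    "voxel_y",
    "voxel_z",
    "whs_x_mm",
    "whs_y_mm",
    "whs_z_mm",
    "ml_mm",
    "ap_mm",
    "dv_mm",
    "region_id",
    "region_name",
]


def build_report(
    records: Sequence[ClusterRecord],
    anchorings: Mapping[int, Anchoring],
    image_dims: Mapping[int, tuple[int, int]] | tuple[int, int],
    volume: AtlasVolume,
    T: Optional[StereotaxicTransform] = None,
) -> pd.DataFrame:
    """Final coordinate/region report for detected clusters.

    Each cluster centroid is mapped pixel -> voxel -> WHS mm -> stereotaxic
    mm, and assigned the atlas region of its nearest voxel.  ``image_dims``
    is (W, H), either shared or per section id.  Rows are sorted by
    (section_id, cluster_id).
    """
    if T is None:
        T = StereotaxicTransform()
    missing = sorted({int(r.section_id) for r in records} - set(anchorings))
    if missing:
        raise ConfigurationError(f"sections without anchoring: {missing}")
    rows = []
    for r in records:
        sid = int(r.section_id)
        dims = image_dims[sid] if isinstance(image_dims, Mapping) else image_dims
        p_vox = section_point_to_voxel(
            anchorings[sid], (r.centroid_x_px, r.centroid_y_px), dims
        )
        p_whs = voxel_to_whs(volume.affine, p_vox)
        q = whs_to_stereotaxic(T, p_whs)
        region_id, region_name = assign_region(volume, p_vox)
        rows.append(
            [sid, r.cluster_id, r.area_mm2, *p_vox, *p_whs, *q, region_id, region_name]
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values(["section_id", "cluster_id"], kind="stable").reset_index(drop=True)
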