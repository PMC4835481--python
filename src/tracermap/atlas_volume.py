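"""NIfTI atlas volumes and custom-angle rectangular slice extraction.

A 2D section's place inside a 3D volume is parameterized by three
voxel-space vectors: ``o`` (top-left corner sample), ``u`` (spanning the full
image width, left to right) and ``v`` (spanning the full image height, top to
bottom).  An output pixel (i, j) of a W x H slice is sampled at

    o + (i / (W - 1)) * u + (j / (H - 1)) * v

so corner pixels land exactly on o, o+u, o+v, o+u+v.  The template is
sampled trilinearly, integer label volumes by nearest neighbor; sample
points outside the volume return 0.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, SingularMatrixError

__all__ = [
    "AtlasVolume",
    "Anchoring",
    "Refinement",
    "load_volume",
    "read_label_names",
    "trilinear_sample",
    "nearest_sample",
    "extract_slice",
    "orthogonal_anchoring",
]


@dataclass
class AtlasVolume:
    """A 3D template (and optional integer label volume) with voxel->mm affine.

    Voxel coordinates are 0-based and continuous, with voxel centers at
    integers; the affine maps them homogeneously to atlas millimetres.
    """

    template: np.ndarray
    affine: np.ndarray
    labels: Optional[np.ndarray] = None
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.ndim != 3:
            raise DomainError(f"template must be 3D, got shape {self.template.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise DomainError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise SingularMatrixError("volume affine is not invertible")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.template.shape:
                raise DomainError(
                    f"label volume shape {self.labels.shape} != template shape {self.template.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.template.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Refinement:
    """Local in-plane alignment: a translation applied inside one pixel ROI.

    roi = (x0, y0, x1, y1) in pixels (half-open); dxy in normalized image
    units (fractions of u and v).
    """

    roi: tuple[float, float, float, float]
    dxy: tuple[float, float]

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.roi
        return max(x1 - x0, 0.0) * max(y1 - y0, 0.0)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.roi
        return x0 <= x < x1 and y0 <= y < y1


@dataclass
class Anchoring:
    """Placement of one section's image plane inside an atlas volume (o/u/v)."""

    section_id: int
    o: np.ndarray
    u: np.ndarray
    v: np.ndarray
    refinements: list[Refinement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, vec in (("o", self.o), ("u", self.u), ("v", self.v)):
            if vec.shape != (3,):
                raise DomainError(f"anchoring vector {name} must have 3 components")
        if self.is_degenerate():
            raise DomainError("degenerate anchoring: u and v must span a plane")

    def is_degenerate(self) -> bool:
        return (
            np.linalg.norm(self.u) < 1e-12
            or np.linalg.norm(self.v) < 1e-12
            or np.linalg.norm(np.cross(self.u, self.v)) < 1e-12
        )

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the section plane (u x v direction)."""
        n = np.cross(self.u, self.v)
        return n / np.linalg.norm(n)

    def to_dict(self) -> dict:
        d = {
            "section_id": int(self.section_id),
            "o": self.o.tolist(),
            "u": self.u.tolist(),
            "v": self.v.tolist(),
        }
        if self.refinements:
            d["refinements"] = [
                {"roi": list(r.roi), "dxy": list(r.dxy)} for r in self.refinements
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Anchoring":
        refs = [
            Refinement(roi=tuple(r["roi"]), dxy=tuple(r["dxy"]))
            for r in d.get("refinements", [])
        ]
        return cls(
            section_id=int(d["section_id"]),
            o=np.asarray(d["o"], dtype=float),
            u=np.asarray(d["u"], dtype=float),
            v=np.asarray(d["v"], dtype=float),
            refinements=refs,
        )


def read_label_names(path: str | Path) -> dict[int, str]:
    """Parse a label-name table: 2-column id<TAB|,>name, or ITK-SNAP format.

    ITK-SNAP label description lines look like
    ``7  255 0 0  1 1 1  "Thalamus"``; comment lines start with '#'.
    """
    names: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = re.match(r'^(\d+)\s+.*"(.*)"\s*$', line)
        if m:  # ITK-SNAP style
            names[int(m.group(1))] = m.group(2)
            continue
        parts = re.split(r"[\t,]", line, maxsplit=1)
        if len(parts) == 2:
            names[int(parts[0].strip())] = parts[1].strip()
        else:
            raise ConfigurationError(f"unparseable label-name line: {line!r}")
    return names


def load_volume(
    path: str | Path,
    label_path: Optional[str | Path] = None,
    names_path: Optional[str | Path] = None,
) -> AtlasVolume:
    """Load a NIfTI-1 template (and optional label volume + name table).

    The affine follows NIfTI rules: sform when valid, else qform, else the
    header fallback (nibabel's standard resolution order).  Arrays are
    presented in the file's native voxel order, untransposed.
    """
    img = nib.load(str(path))
    template = np.asarray(img.dataobj, dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    labels = None
    if label_path is not None:
        limg = nib.load(str(label_path))
        labels = np.asarray(limg.dataobj)
        if not np.issubdtype(labels.dtype, np.integer):
            labels = np.round(labels).astype(np.int32)
    names = read_label_names(names_path) if names_path is not None else {}
    return AtlasVolume(template=template, affine=affine, labels=labels, label_names=names)


def _prepare_points(p: np.ndarray) -> tuple[np.ndarray, bool]:
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    return np.atleast_2d(p), single


def trilinear_sample(volume_array: np.ndarray, p: np.ndarray) -> np.ndarray | float:
    """Trilinear interpolation at continuous voxel point(s) p.

    Accepts a single 3-vector or an (..., 3) array.  Points outside
    [0, dim-1] on any axis return the fill value 0.
    """
    vol = np.asarray(volume_array, dtype=float)
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    flat = np.atleast_2d(pts.reshape(-1, 3))
    inside = np.all((flat >= 0) & (flat <= np.asarray(vol.shape) - 1), axis=1)
    out = np.zeros(flat.shape[0])
    if inside.any():
        out[inside] = ndimage.map_coordinates(
            vol, flat[inside].T, order=1, mode="nearest"
        )
    if single:
        return float(out[0])
    return out.reshape(pts.shape[:-1])


def nearest_sample(label_array: np.ndarray, p: np.ndarray) -> np.ndarray | int:
    """Nearest-voxel lookup with round-half-away-from-zero; outside -> 0."""
    arr = np.asarray(label_array)
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    flat = np.atleast_2d(pts.reshape(-1, 3))
    idx = np.sign(flat) * np.floor(np.abs(flat) + 0.5)
    inside = np.all((idx >= 0) & (idx <= np.asarray(arr.shape) - 1), axis=1)
    out = np.zeros(flat.shape[0], dtype=arr.dtype)
    if inside.any():
        ii = idx[inside].astype(int)
        out[inside] = arr[ii[:, 0], ii[:, 1], ii[:, 2]]
    if single:
        return out[0].item()
    return out.reshape(pts.shape[:-1])


def slice_sample_points(a: Anchoring, out_w: int, out_h: int) -> np.ndarray:
    """Voxel-space sample point of every output pixel: array (out_h, out_w, 3).

    Computed as o + (i * u) / (W - 1) + (j * v) / (H - 1) so that integer
    lattice anchorings reproduce stored planes bit-exactly.
    """
    if out_w < 2 or out_h < 2:
        raise DomainError(f"output size must be >= 2 in both axes, got {out_w}x{out_h}")
    i = np.arange(out_w, dtype=float)
    j = np.arange(out_h, dtype=float)
    pts = (
        a.o[None, None, :]
        + (i[None, :, None] * a.u[None, None, :]) / (out_w - 1)
        + (j[:, None, None] * a.v[None, None, :]) / (out_h - 1)
    )
    return pts


def extract_slice(
    volume: AtlasVolume, a: Anchoring, out_w: int, out_h: int, channel: str = "template"
) -> np.ndarray:
    """Extract an arbitrarily oriented rectangular slice as an (out_h, out_w) image."""
    if a.is_degenerate():
        raise DomainError("degenerate anchoring")
    if channel not in ("template", "labels"):
        raise ConfigurationError(f"channel must be 'template' or 'labels', got {channel!r}")
    pts = slice_sample_points(a, out_w, out_h)
    if channel == "template":
        return np.asarray(trilinear_sample(volume.template, pts))
    if volume.labels is None:
        raise ConfigurationError("volume has no label array")
    return np.asarray(nearest_sample(volume.labels, pts))


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def orthogonal_anchoring(
    ap_position_voxel: float,
    pitch_deg: float,
    yaw_deg: float,
    width_voxels: int,
    height_voxels: int,
    volume_dims: Sequence[int],
    section_id: int = 0,
) -> Anchoring:
    """Near-coronal anchoring replicating a section series' slicing angle.

    Assumes an RAS-like voxel order (x mediolateral, y anteroposterior,
    z dorsoventral).  The plane is centered mediolaterally and
    dorsoventrally at the volume center and anteroposteriorly at
    ``ap_position_voxel``; pitch tilts it about the ML axis, yaw about the
    DV axis.  Image rows run superior -> inferior (v along -z before
    rotation).
    """
    if not (-90.0 < pitch_deg < 90.0) or not (-90.0 < yaw_deg < 90.0):
        raise DomainError("pitch and yaw must lie strictly inside (-90, 90) degrees")
    dims = np.asarray(volume_dims, dtype=float)
    if dims.shape != (3,):
        raise DomainError("volume_dims must have 3 components")
    rot = _rot_z(yaw_deg) @ _rot_x(pitch_deg)
    u_dir = rot @ np.array([1.0, 0.0, 0.0])
    v_dir = rot @ np.array([0.0, 0.0, -1.0])
    u = (width_voxels - 1) * u_dir
    v = (height_voxels - 1) * v_dir
    center = np.array([(dims[0] - 1) / 2.0, float(ap_position_voxel), (dims[2] - 1) / 2.0])
    o = center - u / 2.0 - v / 2.0
    return Anchoring(section_id=section_id, o=o, u=u, v=v)


def save_anchoring(a: Anchoring, path: str | Path) -> None:
    Path(path).write_text(json.dumps(a.to_dict(), indent=2))


def load_anchoring(path: str | Path) -> Anchoring:
    return Anchoring.from_dict(json.loads(Path(path).read_text()))
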