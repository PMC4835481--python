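"""Propagation of anchorings across a section series and pixel->voxel mapping.

A few key sections (typically 5-10 spread through the series) are anchored
manually; the anchorings of intermediate sections are interpolated linearly
in section index, component-wise in o, u and v.  Individual anchorings can
then be refined by composable in-plane affine adjustments and local ROI
translations, and finally map any section pixel to a continuous atlas voxel
position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas_volume import Anchoring, Refinement
from .errors import ConfigurationError, DomainError, SingularMatrixError

__all__ = [
    "AnchoredSeries",
    "interpolate_anchorings",
    "section_point_to_voxel",
    "apply_affine_registration",
    "load_series",
    "save_series",
]


@dataclass
class AnchoredSeries:
    """Manually anchored key sections within an ordered section series."""

    keys: list[Anchoring]
    section_ids: list[int]

    def __post_init__(self) -> None:
        if not self.keys:
            raise ConfigurationError("an anchored series needs at least one key anchoring")
        key_ids = [a.section_id for a in self.keys]
        if any(b <= a for a, b in zip(key_ids, key_ids[1:])):
            raise ConfigurationError(f"key section ids must be strictly increasing: {key_ids}")
        missing = set(key_ids) - set(self.section_ids)
        if missing:
            raise ConfigurationError(f"key sections not in the series: {sorted(missing)}")


def _lerp(a: Anchoring, b: Anchoring, s: int) -> Anchoring:
    w = (s - a.section_id) / (b.section_id - a.section_id)
    return Anchoring(
        section_id=s,
        o=(1.0 - w) * a.o + w * b.o,
        u=(1.0 - w) * a.u + w * b.u,
        v=(1.0 - w) * a.v + w * b.v,
    )


def interpolate_anchorings(
    series: AnchoredSeries, nominal_spacing: float = 1.0
) -> dict[int, Anchoring]:
    """Anchor every section of the series by interpolating between keys.

    Between two keys, o, u and v are interpolated linearly in section index;
    at a key index the key anchoring is returned exactly.  Beyond the first/
    last key, o is extrapolated linearly from the two nearest keys while u
    and v stay fixed at the nearest key's values (avoids runaway plane
    rotation).  With a single key, o is offset along the plane normal by
    (section index difference) x nominal_spacing (voxel units).
    """
    keys = series.keys
    key_ids = [a.section_id for a in keys]
    out: dict[int, Anchoring] = {}
    for s in series.section_ids:
        if s in key_ids:
            k = keys[key_ids.index(s)]
            out[s] = Anchoring(s, k.o.copy(), k.u.copy(), k.v.copy(), list(k.refinements))
        elif len(keys) == 1:
            k = keys[0]
            offset = (s - k.section_id) * nominal_spacing * k.normal
            out[s] = Anchoring(s, k.o + offset, k.u.copy(), k.v.copy())
        elif s < key_ids[0]:
            a, b = keys[0], keys[1]
            w = (s - a.section_id) / (b.section_id - a.section_id)
            out[s] = Anchoring(s, (1.0 - w) * a.o + w * b.o, a.u.copy(), a.v.copy())
        elif s > key_ids[-1]:
            a, b = keys[-2], keys[-1]
            w = (s - a.section_id) / (b.section_id - a.section_id)
            out[s] = Anchoring(s, (1.0 - w) * a.o + w * b.o, b.u.copy(), b.v.copy())
        else:
            hi = next(i for i, kid in enumerate(key_ids) if kid > s)
            out[s] = _lerp(keys[hi - 1], keys[hi], s)
    return out


def section_point_to_voxel(
    a: Anchoring, p_px: Sequence[float], image_dims: Sequence[int]
) -> np.ndarray:
    """Map a section pixel (x, y) to its continuous atlas voxel position.

    Normalized coordinates are (x/(W-1), y/(H-1)); if the pixel lies inside
    a refinement ROI, the innermost (smallest-area) matching ROI's dxy
    translation is added before evaluating o + s*u + t*v.
    """
    w, h = int(image_dims[0]), int(image_dims[1])
    if w < 2 or h < 2:
        raise DomainError(f"image dimensions must be >= 2, got {image_dims}")
    x, y = float(p_px[0]), float(p_px[1])
    # same association as the slice sampling lattice, so the round trip with
    # extract_slice is bit-identical
    p = a.o + (x * a.u) / (w - 1) + (y * a.v) / (h - 1)
    matching = [r for r in a.refinements if r.contains(x, y)]
    if matching:
        innermost = min(matching, key=lambda r: r.area)
        p = p + innermost.dxy[0] * a.u + innermost.dxy[1] * a.v
    return p


def apply_affine_registration(a: Anchoring, A: np.ndarray, t: Sequence[float]) -> Anchoring:
    """Absorb an in-plane affine (normalized image coordinates) into the anchoring.

    Returns a' such that section_point_to_voxel(a', p) equals
    section_point_to_voxel(a, A @ p_norm + t): the four alignment steps
    (position, width/height, rotation, translation) compose as such affines.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (2, 2):
        raise DomainError(f"A must be 2x2, got {A.shape}")
    if abs(np.linalg.det(A)) < 1e-12:
        raise SingularMatrixError("in-plane affine is singular")
    tx, ty = float(t[0]), float(t[1])
    return Anchoring(
        section_id=a.section_id,
        o=a.o + tx * a.u + ty * a.v,
        u=A[0, 0] * a.u + A[1, 0] * a.v,
        v=A[0, 1] * a.u + A[1, 1] * a.v,
        refinements=list(a.refinements),
    )


def save_series(series: AnchoredSeries, path: str | Path) -> None:
    """Serialize a series as a JSON list of anchorings with "key": true flags."""
    key_ids = {a.section_id for a in series.keys}
    entries = []
    for s in series.section_ids:
        if s in key_ids:
            a = next(k for k in series.keys if k.section_id == s)
            d = a.to_dict()
            d["key"] = True
            entries.append(d)
        else:
            entries.append({"section_id": s})
    Path(path).write_text(json.dumps(entries, indent=2))


def load_series(path: str | Path) -> AnchoredSeries:
    entries = json.loads(Path(path).read_text())
    section_ids = [int(e["section_id"]) for e in entries]
    keys = [Anchoring.from_dict(e) for e in entries if e.get("key") or "o" in e]
    return AnchoredSeries(keys=keys, section_ids=section_ids)


def save_anchorings(anchorings: Mapping[int, Anchoring], path: str | Path) -> None:
    """Write a full per-section anchoring list (output of interpolation)."""
    Path(path).write_text(
        json.dumps([anchorings[s].to_dict() for s in sorted(anchorings)], indent=2)
    )


def load_anchorings(path: str | Path) -> dict[int, Anchoring]:
    entries = json.loads(Path(path).read_text())
    out = {}
    for e in entries:
        a = Anchoring.from_dict(e)
        out[a.section_id] = a
    return out
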