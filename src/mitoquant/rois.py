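"""Per-slice polygonal regions of interest (cell contours).

An ROISet holds, for a contiguous range of z slices, one or more simple
closed polygons per slice in 0-based (row, col) pixel coordinates — the
programmatic stand-in for cell contours drawn along the plasma membrane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from skimage.draw import polygon2mask

__all__ = ["ROISet"]


def _polygon_is_simple(poly: np.ndarray) -> bool:
    """Reject self-intersecting polygons (O(n^2) segment test)."""
    n = len(poly)
    if n < 3:
        return False
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def _ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) > (b[1] - a[1]) * (c[0] - a[0])

    def _intersect(s, t):
        a, b = s
        c, d = t
        return _ccw(a, c, d) != _ccw(b, c, d) and _ccw(a, b, c) != _ccw(a, b, d)

    for i in range(n):
        for j in range(i + 1, n):
            if j in (i, (i + 1) % n, (i - 1) % n):
                continue
            if i == 0 and j == n - 1:
                continue
            if _intersect(segs[i], segs[j]):
                return False
    return True


@dataclass
class ROISet:
    """polygons[z] is a list of (n, 2) float arrays in (row, col) pixels."""

    polygons: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, list[np.ndarray]] = {}
        for z, polys in self.polygons.items():
            checked = []
            for p in polys:
                p = np.asarray(p, dtype=float)
                if p.ndim != 2 or p.shape[1] != 2:
                    raise ValueError("polygons must be (n, 2) arrays")
                if not _polygon_is_simple(p):
                    raise ValueError(f"self-intersecting polygon on slice {z}")
                checked.append(p)
            clean[int(z)] = checked
        self.polygons = clean

    @property
    def slice_range(self) -> tuple[int, int]:
        """(first, last) slice index covered, inclusive."""
        keys = sorted(self.polygons)
        if not keys:
            raise ValueError("empty ROISet")
        return keys[0], keys[-1]

    def slice_mask(self, z: int, shape: tuple[int, int]) -> np.ndarray:
        """Boolean union of this slice's polygons on a (rows, cols) grid."""
        mask = np.zeros(shape, dtype=bool)
        for poly in self.polygons.get(z, []):
            mask |= polygon2mask(shape, poly)
        return mask

    def volume_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean (z, y, x) mask; slices without polygons stay empty."""
        out = np.zeros(shape, dtype=bool)
        for z in self.polygons:
            if 0 <= z < shape[0]:
                out[z] = self.slice_mask(z, shape[1:])
        return out

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        payload = {
            str(z): [p.tolist() for p in polys] for z, polys in self.polygons.items()
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ROISet":
        raw = json.loads(Path(path).read_text())
        return cls(
            polygons={int(z): [np.asarray(p) for p in polys] for z, polys in raw.items()}
        )
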