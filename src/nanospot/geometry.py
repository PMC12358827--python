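"""Well-lattice geometry and the chip-to-membrane similarity transform.

Coordinates are ``(x, y)`` pixel positions (x along columns, y along rows);
array indexing order ``img[y, x]`` is converted at the boundaries.  Well ids
run row-major from 1, matching the numbering printed next to the imprint in
the membrane viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["WellLayout", "GridTransform", "assign_points_to_wells"]


@dataclass(frozen=True)
class WellLayout:
    """Regular square lattice of nanowells in the chip-scan pixel frame.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions (80 x 80 = 6,400 wells for the standard chip).
    pitch_px : float
        Center-to-center well spacing in pixels.
    origin_px : tuple of float
        ``(x, y)`` of the center of well 1 (row 0, col 0).
    well_radius_px : float
        Radius of the per-well measurement aperture.
    """

    n_rows: int
    n_cols: int
    pitch_px: float
    origin_px: tuple[float, float]
    well_radius_px: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if self.pitch_px <= 0:
            raise ValueError("pitch_px must be positive")
        if not 0 < self.well_radius_px < self.pitch_px / 2:
            raise ValueError("well_radius_px must be in (0, pitch/2)")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_id(self, row: int, col: int) -> int:
        """Row-major well id, starting at 1."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row={row}, col={col}) outside lattice")
        return row * self.n_cols + col + 1

    def rowcol(self, well_id):
        """Inverse of :meth:`well_id`; accepts scalars or arrays."""
        wid = np.asarray(well_id)
        if np.any((wid < 1) | (wid > self.n_wells)):
            raise ValueError("well_id outside [1, n_wells]")
        row, col = np.divmod(wid - 1, self.n_cols)
        return row, col

    def center(self, well_id):
        """``(x, y)`` center(s) of the given well id(s)."""
        row, col = self.rowcol(well_id)
        ox, oy = self.origin_px
        return np.stack(
            [ox + col * self.pitch_px, oy + row * self.pitch_px], axis=-1
        )

    def well_centers(self) -> np.ndarray:
        """All well centers, ``(n_wells, 2)``, ordered by well id."""
        return self.center(np.arange(1, self.n_wells + 1))


def assign_points_to_wells(
    layout: WellLayout, points: np.ndarray, max_dist_px: float
) -> np.ndarray:
    """Nearest-well assignment of ``(N, 2)`` chip-frame points.

    Returns an int array of well ids with 0 meaning "no well within
    ``max_dist_px``".  Exact distance ties go to the lowest well id; with
    continuous coordinates they are practically unreachable but the rule is
    fixed so results are reproducible.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ox, oy = layout.origin_px
    fx = (pts[:, 0] - ox) / layout.pitch_px
    fy = (pts[:, 1] - oy) / layout.pitch_px

    best_id = np.zeros(len(pts), dtype=np.int64)
    best_d2 = np.full(len(pts), np.inf)
    # candidate lattice nodes: floor/ceil in each axis
    for cy in (np.floor(fy), np.ceil(fy)):
        row = np.clip(cy, 0, layout.n_rows - 1).astype(np.int64)
        for cx in (np.floor(fx), np.ceil(fx)):
            col = np.clip(cx, 0, layout.n_cols - 1).astype(np.int64)
            wid = row * layout.n_cols + col + 1
            cxp = ox + col * layout.pitch_px
            cyp = oy + row * layout.pitch_px
            d2 = (pts[:, 0] - cxp) ** 2 + (pts[:, 1] - cyp) ** 2
            closer = d2 < best_d2 - 1e-9
            tie = (np.abs(d2 - best_d2) <= 1e-9) & (wid < best_id)
            take = closer | tie
            best_d2[take] = d2[take]
            best_id[take] = wid[take]
    best_id[np.sqrt(best_d2) > max_dist_px] = 0
    return best_id


@dataclass(frozen=True)
class GridTransform:
    """Similarity transform mapping chip pixel coordinates to the membrane.

    ``p_membrane = scale * R(rotation_deg) @ p_chip + translation``, with the
    rotation measured in the image plane from +x toward +y.  ``rms_residual``
    and ``n_support`` describe the lattice fit that produced the transform
    (0 and the full lattice for a ground-truth transform).
    """

    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    rms_residual: float = 0.0
    n_support: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    @property
    def _rot(self) -> np.ndarray:
        t = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self._rot.T + np.asarray(self.translation)
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - np.asarray(self.translation)) @ self._rot / self.scale
        return out if np.asarray(points).ndim == 2 else out[0]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["translation"] = [float(v) for v in d["translation"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GridTransform":
        d = yaml.safe_load(Path(path).read_text())
        d["translation"] = tuple(d["translation"])
        return cls(**d)
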