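"""Imprint-lattice detection and chip-to-membrane registration.

The anti-IgG imprint printed through the well pores reproduces the well
lattice on the membrane.  Detecting those spots and fitting a similarity
transform (scale, rotation, translation — contact printing preserves
angles) against the known layout lets any membrane coordinate be traced
back to a well number.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import SimilarityTransform, AffineTransform

from .geometry import GridTransform, WellLayout, assign_points_to_wells

__all__ = ["detect_imprint_spots", "fit_grid_transform", "map_point_to_well",
           "map_points_to_wells"]


def detect_imprint_spots(
    image: np.ndarray,
    threshold: float | None = None,
    min_area_px: int = 5,
    max_area_px: int | None = None,
) -> np.ndarray:
    """Centroids ``(x, y)`` of imprint spots above an automatic threshold.

    Connected components above the threshold (Otsu when not given) are kept
    if their pixel area lies in ``[min_area_px, max_area_px]``; raises if no
    spot survives.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    thr = threshold_otsu(img) if threshold is None else threshold
    lab = label(img > thr)
    cents = [
        p.centroid
        for p in regionprops(lab)
        if p.area >= min_area_px and (max_area_px is None or p.area <= max_area_px)
    ]
    if not cents:
        raise ValueError("no imprint found")
    yx = np.asarray(cents, dtype=float)
    return yx[:, ::-1].copy()  # (row, col) -> (x, y)


def _initial_guess(
    pts: np.ndarray, centers: np.ndarray, pitch: float, tree: cKDTree
) -> SimilarityTransform:
    """Closed-form seed for the lattice fit (no correspondences needed)."""
    if len(pts) < 5:
        return SimilarityTransform(
            translation=pts.mean(axis=0) - centers.mean(axis=0)
        )
    d, j = tree.query(pts, k=2)
    vec = pts[j[:, 1]] - pts
    # lattice-axis angles fold onto one class modulo 90 deg; re-center so
    # small rotations cluster around 0
    ang = np.arctan2(vec[:, 1], vec[:, 0]) % (np.pi / 2)
    theta = float(np.median((ang + np.pi / 4) % (np.pi / 2) - np.pi / 4))
    scale = float(np.median(d[:, 1])) / pitch
    guess = SimilarityTransform(scale=scale, rotation=theta)
    t = pts.mean(axis=0) - guess(centers).mean(axis=0)
    return SimilarityTransform(scale=scale, rotation=theta, translation=t)


def fit_grid_transform(
    centroids: np.ndarray,
    layout: WellLayout,
    n_iter: int = 20,
    reject_factor: float = 0.4,
    max_rms_factor: float = 0.25,
    min_support_frac: float = 0.5,
    affine: bool = False,
) -> GridTransform:
    """Fit the similarity transform taking well centers onto imprint spots.

    The initial guess exploits the lattice structure of the spots
    themselves: nearest-neighbor vectors within the centroid cloud cluster
    along the rotated lattice axes, giving rotation (folded to the +-45 deg
    ambiguity class, well inside the printing tolerance) and scale (median
    spacing over pitch), while the difference of point-cloud means gives
    the translation without needing correspondences.  The guess is then
    refined by iterated nearest-neighbor matching with outlier rejection at
    ``reject_factor * pitch`` and a least-squares similarity refit,
    stopping once the inlier set stabilizes (at most ``n_iter`` rounds).  Fails if fewer
    than 3 inliers support the fit, if fewer than ``min_support_frac`` of
    the wells find a matching spot (the imprint prints through every pore,
    so a genuine registration is supported by nearly the whole lattice), or
    if the final RMS residual exceeds ``max_rms_factor * pitch``.  ``affine=True`` fits a full affine instead
    and reports its average scale and rotation.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(pts) < 3:
        raise ValueError("at least 3 imprint centroids are required")
    centers = layout.well_centers()
    reject = reject_factor * layout.pitch_px
    tree = cKDTree(pts)

    tform = _initial_guess(pts, centers, layout.pitch_px, tree)
    matched_src = matched_dst = None
    prev_key = None
    for _ in range(n_iter):
        moved = tform(centers)
        dist, idx = tree.query(moved)
        inlier = dist < reject
        if inlier.sum() < 3:
            raise ValueError("fewer than 3 inlier lattice points")
        key = (int(inlier.sum()), idx[inlier].tobytes())
        if key == prev_key:
            break
        prev_key = key
        matched_src = centers[inlier]
        matched_dst = pts[idx[inlier]]
        cls = AffineTransform if affine else SimilarityTransform
        if hasattr(cls, "from_estimate"):
            fit = cls.from_estimate(matched_src, matched_dst)
            if not fit:
                raise ValueError("transform estimation failed")
        else:  # scikit-image < 0.26
            fit = cls()
            if not fit.estimate(matched_src, matched_dst):
                raise ValueError("transform estimation failed")
        tform = fit

    if len(matched_src) < min_support_frac * min(len(pts), layout.n_wells):
        raise ValueError(
            f"registration failed: only {len(matched_src)} of "
            f"{layout.n_wells} lattice points supported the fit"
        )
    resid = np.linalg.norm(tform(matched_src) - matched_dst, axis=1)
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > max_rms_factor * layout.pitch_px:
        raise ValueError(
            f"registration failed: rms residual {rms:.2f} px exceeds "
            f"{max_rms_factor:.2f} x pitch"
        )
    scale = float(np.mean(tform.scale)) if affine else float(tform.scale)
    return GridTransform(
        scale=scale,
        rotation_deg=float(np.rad2deg(tform.rotation)),
        translation=(float(tform.translation[0]), float(tform.translation[1])),
        rms_residual=rms,
        n_support=int(len(matched_src)),
    )


def map_points_to_wells(
    transform: GridTransform,
    layout: WellLayout,
    points: np.ndarray,
    assign_factor: float = 0.5,
) -> np.ndarray:
    """Well ids for membrane-frame points; 0 where no well is close enough.

    Points are pulled back to the chip frame through the inverse transform
    and assigned to the nearest well center within
    ``assign_factor * pitch`` (ties break to the lowest well id).
    """
    chip_pts = transform.inverse(np.atleast_2d(points))
    return assign_points_to_wells(
        layout, chip_pts, max_dist_px=assign_factor * layout.pitch_px
    )


def map_point_to_well(
    transform: GridTransform,
    layout: WellLayout,
    point,
    assign_factor: float = 0.5,
) -> int | None:
    """Single-point version of :func:`map_points_to_wells`; None if off-grid."""
    wid = int(map_points_to_wells(transform, layout, point, assign_factor)[0])
    return wid if wid > 0 else None
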