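"""PSA spot segmentation, normalization, calibration and pg/cell conversion.

The captured-PSA membrane (FITC) is segmented into candidate spots the way
an ImageJ particle analysis would be: threshold, connected components, then
an area window and a roundness window (``4 * area / (pi * major_axis^2)``,
between 0.64 and 1.0) to reject scratches and debris.  Spot intensities are
expressed as fold over the membrane background measured at leukocyte and
no-cell well positions, converted to PSA surface density (pg/um^2) through
a linear standard curve built from spotted dilutions, and multiplied by the
spot area to give pg per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from skimage.draw import disk
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import GridTransform, WellLayout
from .registration import map_points_to_wells

__all__ = [
    "SpotParams",
    "CalibrationModel",
    "segment_psa_spots",
    "match_spots_to_wells",
    "measure_background_wells",
    "normalize_intensities",
    "fit_calibration",
    "quantify_spot",
    "quantify_spots",
]


@dataclass(frozen=True)
class SpotParams:
    """Segmentation settings for the captured-PSA membrane.

    ``threshold`` is either a number (absolute), ``"otsu"``, or ``"sigma"``
    (median + ``sigma_k`` robust standard deviations of the background,
    estimated from the median absolute deviation — the better default when
    spots of very different brightness share one membrane).
    """

    threshold: float | str = "otsu"
    sigma_k: float = 5.0
    min_area_px: int = 50
    max_area_px: int = 5000
    roundness_min: float = 0.64
    roundness_max: float = 1.0


@dataclass(frozen=True)
class CalibrationModel:
    """Linear standard curve: normalized intensity vs density (pg/um^2)."""

    slope: float
    intercept: float
    r_squared: float
    density_range: tuple[float, float]
    slope_se: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def _resolve_threshold(img: np.ndarray, params: SpotParams) -> float:
    if isinstance(params.threshold, (int, float)):
        return float(params.threshold)
    if params.threshold == "otsu":
        return float(threshold_otsu(img))
    if params.threshold == "sigma":
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        return med + params.sigma_k * 1.4826 * mad
    raise ValueError(f"unknown threshold mode {params.threshold!r}")


def segment_psa_spots(
    image: np.ndarray,
    um_per_px: float,
    params: SpotParams = SpotParams(),
) -> pd.DataFrame:
    """Segment and filter PSA spots; one row per retained particle.

    Columns: ``x, y`` (centroid, px), ``pixel_area``, ``area_um2``
    (``pixel_area * um_per_px^2``), ``mean_intensity`` (raw counts over the
    component pixels) and ``roundness``.  An empty frame (no spots) is a
    valid result.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    thr = _resolve_threshold(img, params)
    lab = label(img > thr)
    rows = []
    for p in regionprops(lab, intensity_image=img):
        if not params.min_area_px <= p.area <= params.max_area_px:
            continue
        major = p.axis_major_length
        roundness = 1.0 if major == 0 else 4.0 * p.area / (np.pi * major**2)
        roundness = min(roundness, 1.0)  # discretization can push a hair past 1
        if not params.roundness_min <= roundness <= params.roundness_max:
            continue
        cy, cx = p.centroid
        rows.append(
            {
                "x": cx,
                "y": cy,
                "pixel_area": int(p.area),
                "area_um2": p.area * um_per_px**2,
                "mean_intensity": float(p.intensity_mean),
                "roundness": float(roundness),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["x", "y", "pixel_area", "area_um2", "mean_intensity", "roundness"],
    )


def match_spots_to_wells(
    spots: pd.DataFrame,
    transform: GridTransform,
    layout: WellLayout,
    assign_factor: float = 0.5,
) -> pd.DataFrame:
    """Assign each spot to a well via the fitted transform; merge fragments.

    Spots whose centroid maps to the same well are merged into one record
    (areas summed, mean intensity and centroid area-weighted); spots with no
    well within ``assign_factor * pitch`` keep ``matched_well`` = NA — they
    are retained for inspection but excluded from secretion records.
    """
    out = spots.copy()
    if len(out) == 0:
        out["matched_well"] = pd.array([], dtype="Int64")
        return out
    wid = map_points_to_wells(
        transform, layout, out[["x", "y"]].to_numpy(), assign_factor
    )
    out["matched_well"] = pd.array(
        np.where(wid > 0, wid, -1), dtype="Int64"
    )
    out.loc[out["matched_well"] == -1, "matched_well"] = pd.NA

    matched = out[out["matched_well"].notna()]
    unmatched = out[out["matched_well"].isna()]
    if matched["matched_well"].duplicated().any():
        w = matched["pixel_area"].astype(float)
        g = matched.assign(
            _w=w,
            _wx=matched["x"] * w,
            _wy=matched["y"] * w,
            _wi=matched["mean_intensity"] * w,
            _wr=matched["roundness"] * w,
        ).groupby("matched_well")
        wsum = g["_w"].sum()
        merged = pd.DataFrame(
            {
                "x": g["_wx"].sum() / wsum,
                "y": g["_wy"].sum() / wsum,
                "pixel_area": g["pixel_area"].sum(),
                "area_um2": g["area_um2"].sum(),
                "mean_intensity": g["_wi"].sum() / wsum,
                "roundness": g["_wr"].sum() / wsum,
            }
        ).reset_index()
        merged["matched_well"] = merged["matched_well"].astype("Int64")
        matched = merged[out.columns.tolist()]
    return pd.concat([matched, unmatched], ignore_index=True)


def measure_background_wells(
    image: np.ndarray,
    transform: GridTransform,
    layout: WellLayout,
    well_ids: np.ndarray,
    n: int = 50,
    radius_px: float | None = None,
) -> np.ndarray:
    """Membrane intensities at the transformed positions of background wells.

    Samples up to ``n`` of the given wells (lowest ids first, so the choice
    is reproducible) and returns the mean image intensity over a disc at
    each transformed well center.  The assay uses leukocyte and no-cell
    wells (n = 50) so nonspecific membrane staining is averaged out.
    """
    ids = np.sort(np.asarray(well_ids, dtype=int))
    if len(ids) == 0:
        raise ValueError("at least one background well is required")
    if len(ids) < n:
        warnings.warn(
            f"only {len(ids)} background wells available ({n} requested); "
            "using all of them",
            stacklevel=2,
        )
    ids = ids[:n]
    r = layout.well_radius_px if radius_px is None else radius_px
    centers = transform.forward(layout.center(ids))
    vals = np.empty(len(ids))
    for i, (x, y) in enumerate(centers):
        rr, cc = disk((y, x), r, shape=image.shape)
        vals[i] = image[rr, cc].mean()
    return vals


def normalize_intensities(
    spots: pd.DataFrame, background_intensities: np.ndarray
) -> pd.DataFrame:
    """Express spot means as fold over the membrane background.

    Adds ``normalized_intensity = mean_intensity / mean(background)``.
    Division (rather than subtraction) makes the quantity unit-free, so a
    global illumination or exposure change cancels out of the calibration.
    """
    bg = np.asarray(background_intensities, dtype=float)
    if bg.size == 0:
        raise ValueError("at least one background intensity is required")
    bg_mean = float(bg.mean())
    if bg_mean <= 0:
        raise ValueError(f"background mean must be positive, got {bg_mean}")
    out = spots.copy()
    out["normalized_intensity"] = out["mean_intensity"] / bg_mean
    return out


REQUIRED_STANDARD_COLUMNS = ("concentration_ug_per_ml", "volume_ul", "area_um2")


def fit_calibration(standards: pd.DataFrame) -> CalibrationModel:
    """Least-squares standard curve from a spotted dilution series.

    Each standard's surface density is
    ``concentration (ug/mL) * volume (uL) * 1000 / area (um^2)`` in pg/um^2
    (a 2 uL drop of 500 ug/mL over 10^6 um^2 is exactly 1 pg/um^2), and the
    normalized spot intensity is regressed on density.  Requires >= 3
    standards with non-degenerate densities.
    """
    for colname in REQUIRED_STANDARD_COLUMNS:
        if colname not in standards.columns:
            raise KeyError(f"missing standards column '{colname}'")
    if "normalized_intensity" not in standards.columns:
        raise KeyError("missing standards column 'normalized_intensity'")
    if len(standards) < 3:
        raise ValueError("at least 3 calibration standards are required")
    density = (
        standards["concentration_ug_per_ml"].to_numpy(dtype=float)
        * standards["volume_ul"].to_numpy(dtype=float)
        * 1000.0
        / standards["area_um2"].to_numpy(dtype=float)
    )
    if np.ptp(density) == 0:
        raise ValueError("calibration standards have zero density variance")
    ni = standards["normalized_intensity"].to_numpy(dtype=float)
    fit = linregress(density, ni)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(float(fit.rvalue**2), 1.0),
        density_range=(float(density.min()), float(density.max())),
        slope_se=float(fit.stderr),
    )


def quantify_spot(
    normalized_intensity: float,
    area_um2: float,
    model: CalibrationModel,
) -> tuple[float, float, bool]:
    """Convert one spot to ``(density pg/um^2, pg_per_cell, clamped)``.

    ``density = (NI - intercept) / slope`` clamped at zero (secretion cannot
    be negative; the flag records when clamping fired), and
    ``pg_per_cell = density * area_um2``.
    """
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive to invert")
    density = (normalized_intensity - model.intercept) / model.slope
    clamped = density < 0
    density = max(density, 0.0)
    return density, density * area_um2, bool(clamped)


def quantify_spots(
    spots: pd.DataFrame, model: CalibrationModel
) -> pd.DataFrame:
    """Per-well secretion records for all matched, normalized spots.

    Requires ``matched_well`` and ``normalized_intensity`` columns (i.e.
    :func:`match_spots_to_wells` then :func:`normalize_intensities` have
    run); unmatched spots are excluded.  Returns one row per well with
    ``well_id, normalized_intensity, area_um2, density_pg_per_um2,
    pg_per_cell, clamped``.
    """
    for colname in ("matched_well", "normalized_intensity"):
        if colname not in spots.columns:
            raise ValueError(
                f"spots must be matched and normalized first (missing '{colname}')"
            )
    matched = spots[spots["matched_well"].notna()]
    records = []
    for _, s in matched.iterrows():
        density, pg, clamped = quantify_spot(
            s["normalized_intensity"], s["area_um2"], model
        )
        records.append(
            {
                "well_id": int(s["matched_well"]),
                "normalized_intensity": s["normalized_intensity"],
                "area_um2": s["area_um2"],
                "density_pg_per_um2": density,
                "pg_per_cell": pg,
                "clamped": clamped,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "well_id", "normalized_intensity", "area_um2",
            "density_pg_per_um2", "pg_per_cell", "clamped",
        ],
    )
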