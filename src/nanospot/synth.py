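"""Synthetic nanowell-assay generator with ground-truth annotations.

Emulates the data a single-cell PSA secretion experiment produces: a
multi-channel chip scan of a nanowell array seeded with sorted cells, the
matched pair of membrane images (anti-IgG imprint lattice in PE, captured
PSA spots in FITC), a calibration-standard table of spotted PSA dilutions,
and instrument-style event tables for CTC enumeration.  Every output is a
pure function of the configuration, so downstream accuracy can be scored
against exact ground truth.

The geometry follows the standard chip: 6,400 wells on an 80 x 80 lattice
covering an 8 x 8 mm field (100 um pitch).  Secretion spots are rendered as
discs whose brightness encodes surface density through a linear calibration
in fold-over-background units: ``NI = intercept + slope * (pg / area_um2)``,
rendered on the membrane as ``pixel = membrane_background * NI``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from skimage.draw import disk

from .geometry import GridTransform, WellLayout

__all__ = [
    "PHENOTYPES",
    "SECRETOR_PHENOTYPES",
    "TransformParams",
    "AssayConfig",
    "make_layout",
    "make_ground_truth",
    "render_chip_images",
    "render_membrane_images",
    "make_calibration_standards",
    "PopulationSpec",
    "make_event_table",
    "sample_correlated_uniforms",
]

PHENOTYPES = (
    "psma_pos_secretor",
    "psma_neg_secretor",
    "psma_pos_nonsecretor",
    "psma_neg_nonsecretor",
    "leukocyte",
)
SECRETOR_PHENOTYPES = ("psma_pos_secretor", "psma_neg_secretor")
_PSMA_POS = ("psma_pos_secretor", "psma_pos_nonsecretor")


@dataclass(frozen=True)
class TransformParams:
    """Chip-to-membrane contact-print misalignment.

    Rotation and scale act about the lattice center (the chip pivots about
    its own middle when clamped, not about an image corner); translation is
    in membrane pixels.
    """

    rotation_deg: float = 1.0
    translation_px: tuple[float, float] = (8.0, -5.0)
    scale: float = 1.0


@dataclass(frozen=True)
class AssayConfig:
    """Study conditions for one synthetic chip + membrane experiment.

    Defaults mirror the physical assay: an 80 x 80 lattice at 100 um pitch
    (8 mm field edge), rendered at 2 um/px.  The phenotype mix reflects the
    reported cohort averages — roughly 23% PSMA+ and 8% PSMA- secretors
    among CTCs with ~69% of CTCs non-secreting — plus a 10% leukocyte
    carryover.  Per-cell secretion spans 2–15 pg over the 24 h capture.
    """

    n_rows: int = 80
    n_cols: int = 80
    pitch_um: float = 100.0
    um_per_px: float = 2.0
    well_radius_um: float = 16.0

    n_cells: int = 200
    phenotype_mix: dict = field(
        default_factory=lambda: {
            "psma_pos_secretor": 0.21,
            "psma_neg_secretor": 0.07,
            "psma_pos_nonsecretor": 0.31,
            "psma_neg_nonsecretor": 0.31,
            "leukocyte": 0.10,
        }
    )
    secretion_pg_range: tuple[float, float] = (2.0, 15.0)
    spot_radius_um_range: tuple[float, float] = (12.0, 16.0)

    # chip-scan rendering (16-bit counts)
    calcein_mean: float = 2000.0
    psma_pos_mean: float = 1500.0
    psma_neg_mean: float = 30.0
    cd45_leukocyte_mean: float = 1800.0
    cd45_other_mean: float = 10.0
    intensity_cv: float = 0.10
    chip_background: float = 100.0
    noise_sd: float = 5.0

    # membrane rendering
    membrane_background: float = 500.0
    membrane_noise_sd: float = 20.0
    imprint_background: float = 100.0
    imprint_intensity: float = 3000.0
    imprint_spot_radius_um: float = 10.0

    # linear calibration: NI = intercept + slope * density(pg/um^2)
    calib_slope: float = 200.0
    calib_intercept: float = 1.0

    transform_params: TransformParams = field(default_factory=TransformParams)
    seed: int = 0

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.um_per_px

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_cells > self.n_rows * self.n_cols:
            raise ValueError(
                f"n_cells={self.n_cells} exceeds well count "
                f"{self.n_rows * self.n_cols}"
            )
        mix = self.phenotype_mix
        if set(mix) - set(PHENOTYPES):
            raise ValueError(f"unknown phenotypes: {set(mix) - set(PHENOTYPES)}")
        if any(p < 0 for p in mix.values()):
            raise ValueError("phenotype proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-8:
            raise ValueError("phenotype proportions must sum to 1")
        tp = self.transform_params
        if tp.scale <= 0:
            raise ValueError("transform scale must be positive")
        if abs(tp.rotation_deg) > 10:
            raise ValueError("|rotation| must be <= 10 degrees")
        if max(abs(tp.translation_px[0]), abs(tp.translation_px[1])) > self.pitch_px:
            raise ValueError("|translation| must be <= one pitch")

    def with_(self, **kwargs) -> "AssayConfig":
        return replace(self, **kwargs)


_MARGIN_PITCHES = 3  # field margin around the lattice, in pitches


def make_layout(config: AssayConfig) -> WellLayout:
    """Pixel-frame lattice for the configured chip, centered in the field."""
    pitch = config.pitch_px
    m = _MARGIN_PITCHES * pitch
    return WellLayout(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        pitch_px=pitch,
        origin_px=(m, m),
        well_radius_px=config.well_radius_um / config.um_per_px,
    )


def image_shape(config: AssayConfig) -> tuple[int, int]:
    """(height, width) of rendered rasters: lattice extent + margins."""
    pitch = config.pitch_px
    h = int(math.ceil((config.n_rows - 1) * pitch + 2 * _MARGIN_PITCHES * pitch)) + 1
    w = int(math.ceil((config.n_cols - 1) * pitch + 2 * _MARGIN_PITCHES * pitch)) + 1
    return h, w


def _allocate_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment: exact, deterministic class counts."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def make_ground_truth(config: AssayConfig) -> tuple[pd.DataFrame, WellLayout]:
    """Sample occupied wells, phenotypes, marker intensities and secretion.

    Wells are drawn without replacement; phenotype counts follow the mix by
    largest-remainder apportionment (exact class sizes); secretion is uniform
    over ``secretion_pg_range`` for secretors and 0 otherwise.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    layout = make_layout(config)
    rng = np.random.default_rng(config.seed)

    columns = [
        "well_id", "row", "col", "phenotype",
        "calcein", "psma", "cd45",
        "secretion_pg", "spot_radius_um",
    ]
    if config.n_cells == 0:
        return pd.DataFrame(columns=columns), layout

    wells = np.sort(
        rng.choice(layout.n_wells, size=config.n_cells, replace=False) + 1
    )
    props = np.array([config.phenotype_mix.get(p, 0.0) for p in PHENOTYPES])
    counts = _allocate_counts(props, config.n_cells)
    labels = np.repeat(np.array(PHENOTYPES, dtype=object), counts)
    rng.shuffle(labels)

    def jitter(mean: float, size: int) -> np.ndarray:
        return np.clip(
            mean * (1.0 + config.intensity_cv * rng.standard_normal(size)), 0, None
        )

    n = config.n_cells
    is_leuk = labels == "leukocyte"
    is_psma_pos = np.isin(labels, _PSMA_POS)
    is_secretor = np.isin(labels, SECRETOR_PHENOTYPES)

    calcein = jitter(config.calcein_mean, n)
    psma = np.where(
        is_psma_pos, jitter(config.psma_pos_mean, n), jitter(config.psma_neg_mean, n)
    )
    cd45 = np.where(
        is_leuk, jitter(config.cd45_leukocyte_mean, n), jitter(config.cd45_other_mean, n)
    )

    lo, hi = config.secretion_pg_range
    secretion = np.where(is_secretor, rng.uniform(lo, hi, n), 0.0)
    rlo, rhi = config.spot_radius_um_range
    radius = np.where(is_secretor, rng.uniform(rlo, rhi, n), 0.0)

    row, col = layout.rowcol(wells)
    truth = pd.DataFrame(
        {
            "well_id": wells,
            "row": row,
            "col": col,
            "phenotype": labels,
            "calcein": calcein,
            "psma": psma,
            "cd45": cd45,
            "secretion_pg": secretion,
            "spot_radius_um": radius,
        }
    )
    return truth, layout


def _paint_discs(img, centers_xy, radii_px, values) -> None:
    for (x, y), r, v in zip(centers_xy, radii_px, values):
        rr, cc = disk((y, x), r, shape=img.shape)
        img[rr, cc] = v


def render_chip_images(
    truth: pd.DataFrame, layout: WellLayout, config: AssayConfig
) -> dict[str, np.ndarray]:
    """Render the three fluorescence channels of the chip scan.

    Each occupied well gets a disc of that cell's true channel intensity at
    the well center; background is a constant plus Gaussian noise of
    ``noise_sd`` (noise-free when ``noise_sd == 0``).  Returned as float64;
    write with :func:`nanospot.io.write_tiff` for the 16-bit on-disk form.
    """
    shape = image_shape(config)
    rng = np.random.default_rng(config.seed + 1)
    centers = (
        layout.center(truth["well_id"].to_numpy())
        if len(truth)
        else np.empty((0, 2))
    )
    radius = config.well_radius_um / config.um_per_px
    out: dict[str, np.ndarray] = {}
    for channel in ("calcein", "psma", "cd45"):
        img = np.full(shape, config.chip_background, dtype=float)
        _paint_discs(img, centers, np.full(len(centers), radius),
                     truth[channel].to_numpy() if len(truth) else [])
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, shape)
        out[channel] = img
    return out


def render_membrane_images(
    truth: pd.DataFrame, layout: WellLayout, config: AssayConfig
) -> tuple[np.ndarray, np.ndarray, GridTransform]:
    """Render the membrane pair and return the true chip->membrane transform.

    The imprint (PE) image has one small bright spot per well pore at the
    transformed lattice position.  The PSA (FITC) image has a disc per
    secreting cell at its transformed well position, with pixel value
    ``membrane_background * NI`` where
    ``NI = calib_intercept + calib_slope * pg / (pi * spot_radius_um^2)``;
    non-secretors contribute nothing.
    """
    config.validate()
    tp = config.transform_params
    # rotation/scale about the lattice center: fold the pivot into the
    # translation of the origin-anchored similarity transform
    pivot = layout.well_centers().mean(axis=0)
    anchored = GridTransform(scale=tp.scale, rotation_deg=tp.rotation_deg,
                             translation=(0.0, 0.0))
    t_eff = np.asarray(tp.translation_px) + pivot - anchored.forward(pivot)
    transform = GridTransform(
        scale=tp.scale,
        rotation_deg=tp.rotation_deg,
        translation=(float(t_eff[0]), float(t_eff[1])),
        rms_residual=0.0,
        n_support=layout.n_wells,
    )
    shape = image_shape(config)
    rng = np.random.default_rng(config.seed + 2)

    all_centers = transform.forward(layout.well_centers())
    pad = max(
        config.imprint_spot_radius_um, config.spot_radius_um_range[1]
    ) / config.um_per_px + 1
    if (
        all_centers.min() < pad
        or all_centers[:, 0].max() > shape[1] - 1 - pad
        or all_centers[:, 1].max() > shape[0] - 1 - pad
    ):
        raise ValueError(
            "transform pushes the lattice outside the rendered field; "
            "reduce rotation/translation or the lattice size"
        )
    imprint = np.full(shape, config.imprint_background, dtype=float)
    r_imp = config.imprint_spot_radius_um / config.um_per_px
    _paint_discs(
        imprint, all_centers, np.full(len(all_centers), r_imp),
        np.full(len(all_centers), config.imprint_intensity),
    )

    psa = np.full(shape, config.membrane_background, dtype=float)
    secretors = truth[truth["secretion_pg"] > 0]
    if len(secretors):
        centers = transform.forward(layout.center(secretors["well_id"].to_numpy()))
        radii_px = secretors["spot_radius_um"].to_numpy() / config.um_per_px
        area_um2 = np.pi * secretors["spot_radius_um"].to_numpy() ** 2
        ni = (
            config.calib_intercept
            + config.calib_slope * secretors["secretion_pg"].to_numpy() / area_um2
        )
        _paint_discs(psa, centers, radii_px, config.membrane_background * ni)

    if config.membrane_noise_sd > 0:
        imprint += rng.normal(0.0, config.membrane_noise_sd, shape)
        psa += rng.normal(0.0, config.membrane_noise_sd, shape)
    return imprint, psa, transform


DEFAULT_STANDARD_CONCENTRATIONS = (31.5, 62.5, 125.0, 250.0, 500.0)


def make_calibration_standards(
    config: AssayConfig,
    concentrations_ug_per_ml=DEFAULT_STANDARD_CONCENTRATIONS,
    volume_ul: float = 2.0,
    mean_area_um2: float = 2.0e6,
    area_cv: float = 0.05,
    intensity_noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spotted PSA dilution series with intensities on the true calibration.

    Each standard is a 2 uL drop of known concentration spread over a
    measured area; surface density is ``conc * volume / area`` in pg/um^2
    and the normalized intensity follows the configured line plus optional
    Gaussian noise.  ``raw_mean_intensity`` is the same quantity in membrane
    counts (``NI * membrane_background``) for pipelines that normalize
    standards and spots against the same background.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    conc = np.repeat(np.asarray(concentrations_ug_per_ml, dtype=float), n_replicates)
    area = mean_area_um2 * (1.0 + area_cv * rng.standard_normal(len(conc)))
    density = conc * volume_ul * 1000.0 / area  # ug/mL * uL -> ng -> pg
    ni = config.calib_intercept + config.calib_slope * density
    if intensity_noise_sd > 0:
        ni = ni + rng.normal(0.0, intensity_noise_sd, len(conc))
    return pd.DataFrame(
        {
            "concentration_ug_per_ml": conc,
            "volume_ul": volume_ul,
            "area_um2": area,
            "normalized_intensity": ni,
            "raw_mean_intensity": ni * config.membrane_background,
            "true_density_pg_per_um2": density,
        }
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Lognormal marker-intensity population for enumeration event tables.

    ``*_median`` are the medians of the lognormal intensity distributions
    (``exp(mu)``); ``*_sigma`` the log-scale spreads.  ``dapi_pos_rate`` and
    ``cd45_pos_rate`` set the fraction of events passing/failing the nuclear
    and leukocyte gates.
    """

    name: str
    weight: float
    ck_median: float
    psma_median: float
    ck_sigma: float = 0.5
    psma_sigma: float = 0.5
    cd45_median: float = 5.0
    cd45_sigma: float = 0.5
    dapi_pos_rate: float = 1.0
    cd45_pos_rate: float = 0.0


def make_event_table(
    n: int, populations: list[PopulationSpec], seed: int
) -> pd.DataFrame:
    """Draw an instrument-style event table from a population mixture.

    Events carry CK/PSMA/CD45 intensities (lognormal per population), a
    DAPI-positivity flag, a CD45-positivity flag, and the hidden population
    label.  Deterministic given ``seed``.
    """
    if not populations:
        raise ValueError("at least one population is required")
    weights = np.array([p.weight for p in populations], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("population weights must be non-negative and sum to 1")

    columns = [
        "ck_intensity", "psma_intensity", "cd45_intensity",
        "dapi_positive", "cd45_positive", "population",
    ]
    if n == 0:
        return pd.DataFrame(columns=columns)

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(populations), size=n, p=weights)

    def draw(med, sig):
        return np.exp(np.log(med) + sig * rng.standard_normal(n))

    med = lambda attr: np.array([getattr(p, attr) for p in populations])[idx]
    ck = draw(med("ck_median"), med("ck_sigma"))
    psma = draw(med("psma_median"), med("psma_sigma"))
    cd45 = draw(med("cd45_median"), med("cd45_sigma"))
    dapi = rng.random(n) < med("dapi_pos_rate")
    cd45_pos = rng.random(n) < med("cd45_pos_rate")
    return pd.DataFrame(
        {
            "ck_intensity": ck,
            "psma_intensity": psma,
            "cd45_intensity": cd45,
            "dapi_positive": dapi,
            "cd45_positive": cd45_pos,
            "population": np.array([p.name for p in populations], dtype=object)[idx],
        }
    )


def sample_correlated_uniforms(
    n: int, spearman_rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-copula pairs of uniforms with a target Spearman correlation.

    The latent Pearson correlation is ``2 sin(pi * rho_s / 6)``, the exact
    inversion of the bivariate-normal rank correlation, so the population
    Spearman of the returned pair equals ``spearman_rho``.
    """
    if not -1.0 < spearman_rho < 1.0:
        raise ValueError("spearman_rho must be in (-1, 1)")
    r = 2.0 * np.sin(np.pi * spearman_rho / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return norm.cdf(z1), norm.cdf(z2)
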