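"""CTC enumeration: marker-intensity gating and CK-vs-PSMA concordance.

Instrument event tables (one row per detected object, with CK, PSMA and
CD45 mean intensities plus a DAPI flag) are gated into the three CTC groups
CK+PSMA+, CK+PSMA- and CK-PSMA+ after excluding DAPI-negative and
CD45-positive events.  Per-sample CK+ and PSMA+ totals are then compared
across a cohort by ordinary least squares on log10 counts and by Spearman
rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, spearmanr

__all__ = ["GateThresholds", "GroupCounts", "RegressionFit",
           "classify_events", "fit_loglog_regression"]

GROUP_LABELS = ("ck_pos_psma_pos", "ck_pos_psma_neg", "ck_neg_psma_pos")


@dataclass(frozen=True)
class GateThresholds:
    """Inclusive positivity cutoffs for event gating.

    CK >= 50 and PSMA >= 200 are the cutoffs set on prostate cell lines;
    the boundaries are inclusive, matching the ">=" phrasing of the assay
    definition.  DAPI and CD45 gate as booleans when the event table carries
    flag columns; ``cd45_max`` is the numeric fallback for tables that carry
    a CD45 intensity instead.
    """

    ck_min: float = 50.0
    psma_min: float = 200.0
    cd45_max: float = 100.0
    require_dapi: bool = True

    def __post_init__(self) -> None:
        if min(self.ck_min, self.psma_min, self.cd45_max) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class GroupCounts:
    """Per-sample event partition after gating."""

    n_ck_pos_psma_pos: int
    n_ck_pos_psma_neg: int
    n_ck_neg_psma_pos: int
    n_unclassified: int
    n_excluded: int

    @property
    def total(self) -> int:
        return (
            self.n_ck_pos_psma_pos + self.n_ck_pos_psma_neg
            + self.n_ck_neg_psma_pos + self.n_unclassified + self.n_excluded
        )

    @property
    def n_ck_pos(self) -> int:
        return self.n_ck_pos_psma_pos + self.n_ck_pos_psma_neg

    @property
    def n_psma_pos(self) -> int:
        return self.n_ck_pos_psma_pos + self.n_ck_neg_psma_pos


@dataclass(frozen=True)
class RegressionFit:
    """Log-log OLS fit plus rank correlation of per-sample CTC counts."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    spearman_rho: float
    n_used: int

    def __post_init__(self) -> None:
        if np.isfinite(self.spearman_rho) and abs(self.spearman_rho) > 1 + 1e-12:
            raise ValueError("|spearman_rho| must be <= 1")


def classify_events(
    events: pd.DataFrame, thresholds: GateThresholds = GateThresholds()
) -> tuple[pd.DataFrame, GroupCounts]:
    """Label every event and count the CTC groups.

    Events failing the DAPI+ or CD45- gate are labeled ``excluded``;
    the rest split by the inclusive CK/PSMA cutoffs into the three CTC
    groups, with CK-PSMA- events labeled ``unclassified``.  The five labels
    partition the table exactly.
    """
    for colname in ("ck_intensity", "psma_intensity"):
        if colname not in events.columns:
            raise KeyError(f"missing column '{colname}'")

    n = len(events)
    if "cd45_positive" in events.columns:
        cd45_ok = ~events["cd45_positive"].to_numpy(dtype=bool)
    elif "cd45_intensity" in events.columns:
        cd45_ok = events["cd45_intensity"].to_numpy(dtype=float) <= thresholds.cd45_max
    else:
        raise KeyError("missing column 'cd45_positive' (or 'cd45_intensity')")
    if thresholds.require_dapi:
        if "dapi_positive" not in events.columns:
            raise KeyError("missing column 'dapi_positive'")
        dapi_ok = events["dapi_positive"].to_numpy(dtype=bool)
    else:
        dapi_ok = np.ones(n, dtype=bool)

    ck = events["ck_intensity"].to_numpy(dtype=float) >= thresholds.ck_min
    psma = events["psma_intensity"].to_numpy(dtype=float) >= thresholds.psma_min
    kept = cd45_ok & dapi_ok
    group = np.where(
        ~kept, "excluded",
        np.where(ck & psma, "ck_pos_psma_pos",
                 np.where(ck, "ck_pos_psma_neg",
                          np.where(psma, "ck_neg_psma_pos", "unclassified"))),
    )
    labeled = events.copy()
    labeled["ctc_group"] = group
    counts = GroupCounts(
        n_ck_pos_psma_pos=int(np.sum(group == "ck_pos_psma_pos")),
        n_ck_pos_psma_neg=int(np.sum(group == "ck_pos_psma_neg")),
        n_ck_neg_psma_pos=int(np.sum(group == "ck_neg_psma_pos")),
        n_unclassified=int(np.sum(group == "unclassified")),
        n_excluded=int(np.sum(group == "excluded")),
    )
    return labeled, counts


def fit_loglog_regression(
    ck_counts: np.ndarray, psma_counts: np.ndarray
) -> RegressionFit:
    """OLS of log10(PSMA+ count) on log10(CK+ count) across samples.

    Samples with a zero count on either axis are dropped with a warning
    (their logarithm is undefined; no pseudocount is applied).  The Spearman
    coefficient is computed on the retained raw counts with midrank ties.
    Requires >= 3 usable samples with CK-count variance.
    """
    x = np.asarray(ck_counts, dtype=float)
    y = np.asarray(psma_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    usable = (x > 0) & (y > 0)
    if np.any(~usable):
        warnings.warn(
            f"dropping {int(np.sum(~usable))} sample(s) with zero counts "
            "from the log-log fit",
            stacklevel=2,
        )
    x, y = x[usable], y[usable]
    if len(x) < 3:
        raise ValueError("at least 3 samples with positive counts are required")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined: CK counts have zero variance")
    fit = linregress(np.log10(x), np.log10(y))
    rho = spearmanr(x, y).statistic
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        spearman_rho=float(rho),
        n_used=int(len(x)),
    )
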