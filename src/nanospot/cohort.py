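"""Joining chip phenotypes with secretion records; patient-level summaries.

A CTC candidate well (calcein+ CD45-) becomes one of four groups once the
membrane is quantified: PSMA+PSA+, PSMA-PSA+, PSMA+PSA-, PSMA-PSA-.  The
per-patient summary reports the group counts, the secreting fraction, and
the mean/median pg/cell over secretors, next to the clinical serum PSA and
screening CTC count; across patients the serum-vs-CTC secretion association
is a Spearman rank correlation over patients with at least one secretor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["FOUR_GROUPS", "PatientSummary", "assemble_cells",
           "summarize_patient", "summaries_frame", "correlate_serum",
           "cohort_mean_secretion"]

FOUR_GROUPS = ("PSMA+PSA+", "PSMA-PSA+", "PSMA+PSA-", "PSMA-PSA-")
_PHENO_TO_PSMA = {"psma_pos_ctc": "PSMA+", "psma_neg_ctc": "PSMA-"}


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    n_psma_pos_psa_pos: int
    n_psma_neg_psa_pos: int
    n_psma_pos_psa_neg: int
    n_psma_neg_psa_neg: int
    n_leukocyte: int
    n_empty: int
    n_anomaly: int
    pct_secreting: float  # NaN when no CTC candidates
    mean_pg: float        # NaN when no secretors
    median_pg: float
    serum_psa_ng_per_ml: float = float("nan")
    screening_ctc: float = float("nan")

    @property
    def n_ctc(self) -> int:
        return (
            self.n_psma_pos_psa_pos + self.n_psma_neg_psa_pos
            + self.n_psma_pos_psa_neg + self.n_psma_neg_psa_neg
        )


def assemble_cells(
    observations: pd.DataFrame,
    secretion: pd.DataFrame,
    patient_id: str,
    min_pg: float = 0.0,
) -> pd.DataFrame:
    """Left-join secretion records onto well phenotypes and assign groups.

    A CTC-candidate well is PSA+ when a matched spot yields
    ``pg_per_cell > min_pg`` (default: any positive amount after clamping),
    PSA- otherwise.  A secretion record at a leukocyte or empty well is
    physically inconsistent (no viable tumor cell to secrete), so it is
    flagged as an anomaly and carries no pg value and no group.
    """
    if observations["well_id"].duplicated().any():
        raise ValueError("duplicate well_id in observations")
    if len(secretion) and secretion["well_id"].duplicated().any():
        raise ValueError("duplicate well_id in secretion records")

    cells = observations[["well_id", "phenotype"]].merge(
        secretion[["well_id", "pg_per_cell"]] if len(secretion)
        else pd.DataFrame({"well_id": [], "pg_per_cell": []}),
        on="well_id", how="left",
    )
    cells.insert(0, "patient_id", patient_id)

    is_ctc = cells["phenotype"].isin(_PHENO_TO_PSMA)
    has_record = cells["pg_per_cell"].notna()
    psa_pos = has_record & (cells["pg_per_cell"] > min_pg)

    cells["anomaly"] = has_record & ~is_ctc
    cells.loc[cells["anomaly"], "pg_per_cell"] = np.nan

    psma = cells["phenotype"].map(_PHENO_TO_PSMA)
    group = np.where(
        is_ctc,
        psma.astype(str) + np.where(psa_pos, "PSA+", "PSA-"),
        cells["phenotype"],
    )
    cells["group"] = group
    # non-secreting candidates carry an explicit 0 rather than a missing value
    cells.loc[is_ctc & ~psa_pos, "pg_per_cell"] = (
        cells.loc[is_ctc & ~psa_pos, "pg_per_cell"].fillna(0.0)
    )
    return cells


def summarize_patient(
    cells: pd.DataFrame,
    serum_psa: float = float("nan"),
    screening_ctc: float = float("nan"),
) -> PatientSummary:
    """Four-group counts and secretion statistics for one patient's chip."""
    pids = cells["patient_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"cells span multiple patients: {pids}")
    patient_id = str(pids[0]) if len(pids) else ""

    n = {g: int((cells["group"] == g).sum()) for g in FOUR_GROUPS}
    n_ctc = sum(n.values())
    n_secreting = n["PSMA+PSA+"] + n["PSMA-PSA+"]
    pg = cells.loc[
        cells["group"].isin(("PSMA+PSA+", "PSMA-PSA+")), "pg_per_cell"
    ].to_numpy(dtype=float)
    return PatientSummary(
        patient_id=patient_id,
        n_psma_pos_psa_pos=n["PSMA+PSA+"],
        n_psma_neg_psa_pos=n["PSMA-PSA+"],
        n_psma_pos_psa_neg=n["PSMA+PSA-"],
        n_psma_neg_psa_neg=n["PSMA-PSA-"],
        n_leukocyte=int((cells["group"] == "leukocyte").sum()),
        n_empty=int((cells["group"] == "empty").sum()),
        n_anomaly=int(cells["anomaly"].sum()),
        pct_secreting=100.0 * n_secreting / n_ctc if n_ctc else float("nan"),
        mean_pg=float(pg.mean()) if len(pg) else float("nan"),
        median_pg=float(np.median(pg)) if len(pg) else float("nan"),
        serum_psa_ng_per_ml=float(serum_psa),
        screening_ctc=float(screening_ctc),
    )


def summaries_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    """One row per patient, ready for CSV export or correlation."""
    return pd.DataFrame([asdict(s) for s in summaries])


def correlate_serum(summaries: pd.DataFrame) -> tuple[float, int]:
    """Spearman rho between serum PSA and mean per-cell CTC secretion.

    Patients without any secreting CTC have no mean secretion and are
    excluded.  Returns ``(rho, n_patients_used)``; requires >= 3 usable
    patients and non-constant values on both axes.
    """
    usable = summaries[
        summaries["mean_pg"].notna() & summaries["serum_psa_ng_per_ml"].notna()
    ]
    if len(usable) < 3:
        raise ValueError("at least 3 patients with secreting CTCs are required")
    x = usable["serum_psa_ng_per_ml"].to_numpy(dtype=float)
    y = usable["mean_pg"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: constant values on one axis")
    rho = spearmanr(x, y).statistic
    return float(rho), int(len(usable))


def cohort_mean_secretion(
    cells: pd.DataFrame, mode: str = "pooled"
) -> tuple[float, float]:
    """Cohort ``(mean, median)`` pg/cell over secreting CTCs.

    ``mode="pooled"`` pools every secreting cell across patients (default);
    ``mode="per_patient"`` averages within patients first and then across
    patients, which weights patients equally regardless of CTC yield.
    """
    sec = cells[cells["group"].isin(("PSMA+PSA+", "PSMA-PSA+"))]
    if len(sec) == 0:
        return float("nan"), float("nan")
    if mode == "pooled":
        vals = sec["pg_per_cell"].to_numpy(dtype=float)
    elif mode == "per_patient":
        vals = sec.groupby("patient_id")["pg_per_cell"].mean().to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(vals)), float(np.median(vals))
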