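"""Nodule-level data model shared by the simulator, IO layer and metrics.

A cohort is carried as a :class:`pandas.DataFrame` with one row per nodule
(the canonical in-memory container for tabular biostatistics work); the
:class:`NoduleRecord` dataclass is the typed row view.  Histology subtypes
collapse into three outcome classes — benign, borderline (NIFTP / WT-UMP,
pre-malignant entities managed surgically) and malignant — and the
*borderline policy* decides on which side of the 2×2 truth the borderline
class falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alterations import Alteration, format_alteration_list, parse_alteration_list
from .errors import ContractError

__all__ = [
    "BENIGN_HISTOLOGIES",
    "BORDERLINE_HISTOLOGIES",
    "MALIGNANT_HISTOLOGIES",
    "HISTOLOGY_CLASS",
    "UNRESECTED",
    "NODULE_COLUMNS",
    "NoduleRecord",
    "histology_class",
    "truth_labels",
    "records_to_frame",
    "frame_to_records",
]

BENIGN_HISTOLOGIES = ("hyperplasia", "thyroiditis", "adenoma")
BORDERLINE_HISTOLOGIES = ("NIFTP", "WT_UMP")
MALIGNANT_HISTOLOGIES = (
    "PTC_classic",
    "PTC_classic_follicular",
    "PTC_follicular",
    "PTC_solid",
    "PTC_oncocytic",
    "follicular_carcinoma",
    "hurthle_carcinoma",
    "anaplastic_carcinoma",
)
UNRESECTED = "unresected"

HISTOLOGY_CLASS: dict[str, str] = {
    **{h: "benign" for h in BENIGN_HISTOLOGIES},
    **{h: "borderline" for h in BORDERLINE_HISTOLOGIES},
    **{h: "malignant" for h in MALIGNANT_HISTOLOGIES},
}

NODULE_COLUMNS = [
    "nodule_id",
    "patient_id",
    "bethesda",
    "size_cm",
    "histology",
    "resected",
    "alterations",
    "rna_score",
    "gc_score",
    "rna_call",
    "gc_call",
]


@dataclass
class NoduleRecord:
    """One fine-needle-aspirated nodule of indeterminate cytology."""

    nodule_id: str
    patient_id: str
    bethesda: str  # "III" (AUS/FLUS) or "IV" (FN/SFN)
    size_cm: float
    histology: str
    resected: bool
    alterations: list[Alteration] = field(default_factory=list)
    rna_score: float | None = None
    gc_score: float | None = None
    rna_call: str | None = None
    gc_call: str | None = None

    def __post_init__(self):
        if self.bethesda not in ("III", "IV"):
            raise ContractError(f"bethesda must be III or IV, got {self.bethesda!r}")
        if self.size_cm <= 0:
            raise ContractError(f"size_cm must be positive, got {self.size_cm}")
        if self.histology != UNRESECTED and not self.resected:
            raise ContractError(
                f"nodule {self.nodule_id}: histology {self.histology!r} without resection"
            )
        if self.histology != UNRESECTED and self.histology not in HISTOLOGY_CLASS:
            raise ContractError(f"unknown histology {self.histology!r}")


def histology_class(histology: str) -> str:
    """benign / borderline / malignant / unresected for one subtype label."""
    if histology == UNRESECTED:
        return UNRESECTED
    try:
        return HISTOLOGY_CLASS[histology]
    except KeyError:
        raise ContractError(f"unknown histology {histology!r}") from None


def truth_labels(histologies: pd.Series, borderline_policy: str = "as_malignant") -> pd.Series:
    """Boolean disease-truth labels for resected histologies under a policy.

    ``as_malignant`` counts borderline lesions (NIFTP, WT-UMP) as disease —
    the primary analysis, since they are pre-malignant entities managed
    surgically; ``as_benign`` counts only carcinomas.
    """
    if borderline_policy not in ("as_malignant", "as_benign"):
        raise ContractError(f"unknown borderline policy {borderline_policy!r}")
    classes = histologies.map(histology_class)
    if (classes == UNRESECTED).any():
        raise ContractError("truth labels require resected nodules with known histology")
    positive = {"malignant", "borderline"} if borderline_policy == "as_malignant" else {"malignant"}
    return classes.isin(positive)


def records_to_frame(records: list[NoduleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "nodule_id": r.nodule_id,
                "patient_id": r.patient_id,
                "bethesda": r.bethesda,
                "size_cm": r.size_cm,
                "histology": r.histology,
                "resected": r.resected,
                "alterations": format_alteration_list(r.alterations),
                "rna_score": r.rna_score,
                "gc_score": r.gc_score,
                "rna_call": r.rna_call,
                "gc_call": r.gc_call,
            }
        )
    return pd.DataFrame(rows, columns=NODULE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[NoduleRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            NoduleRecord(
                nodule_id=str(row["nodule_id"]),
                patient_id=str(row["patient_id"]),
                bethesda=str(row["bethesda"]),
                size_cm=float(row["size_cm"]),
                histology=str(row["histology"]),
                resected=bool(row["resected"]),
                alterations=parse_alteration_list(row.get("alterations", "") or ""),
                rna_score=None if pd.isna(row.get("rna_score")) else float(row["rna_score"]),
                gc_score=None if pd.isna(row.get("gc_score")) else float(row["gc_score"]),
                rna_call=None if pd.isna(row.get("rna_call")) else str(row["rna_call"]),
                gc_call=None if pd.isna(row.get("gc_call")) else str(row["gc_call"]),
            )
        )
    return records
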