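"""Tabular IO and run configuration.

Nodule tables travel as TSV (UTF-8, tab-separated, ``.`` decimal, mandatory
header); the ``alterations`` cell is a semicolon-joined list in the
``GENE[:DETAIL][:KIND]`` grammar.  Reading validates every row and reports
the 1-based data row number on failure; writing is canonical so that
write∘read is byte-identical on canonical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alterations import parse_alteration_list
from .errors import AlterationParseError, ConfigError, LoadError
from .nodules import HISTOLOGY_CLASS, NODULE_COLUMNS, UNRESECTED

__all__ = ["read_nodule_table", "write_nodule_table", "RunConfig"]

_REQUIRED = ["nodule_id", "patient_id", "bethesda", "size_cm", "histology", "resected", "alterations"]
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_nodule_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a nodule TSV (or CSV, by extension) into a frame."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path} is empty (no header)") from None
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise LoadError(f"missing required column(s) {missing}", column=missing[0])
    for col in NODULE_COLUMNS:
        if col not in frame.columns:
            frame[col] = ""
    out = frame[NODULE_COLUMNS].copy()

    for i, raw in enumerate(out.itertuples(index=False), start=1):
        row = raw._asdict()
        if row["bethesda"] not in ("III", "IV"):
            raise LoadError(f"bethesda must be III or IV, got {row['bethesda']!r}",
                            row=i, column="bethesda")
        try:
            size = float(row["size_cm"])
        except ValueError:
            raise LoadError(f"non-numeric size {row['size_cm']!r}", row=i, column="size_cm") from None
        if size <= 0:
            raise LoadError(f"size_cm must be positive, got {size}", row=i, column="size_cm")
        if row["resected"].strip().lower() not in _BOOL_MAP:
            raise LoadError(f"resected must be boolean-like, got {row['resected']!r}",
                            row=i, column="resected")
        hist = row["histology"]
        if hist != UNRESECTED and hist not in HISTOLOGY_CLASS:
            raise LoadError(f"unknown histology {hist!r}", row=i, column="histology")
        try:
            parse_alteration_list(row["alterations"])
        except AlterationParseError as exc:
            raise LoadError(str(exc), row=i, column="alterations") from exc
        for col in ("rna_score", "gc_score"):
            cell = row[col].strip()
            if cell:
                try:
                    v = float(cell)
                except ValueError:
                    raise LoadError(f"non-numeric score {cell!r}", row=i, column=col) from None
                if not (0.0 <= v <= 100.0):
                    raise LoadError(f"score {v} outside [0, 100]", row=i, column=col)
        for col in ("rna_call", "gc_call"):
            cell = row[col].strip()
            if cell and cell not in ("positive", "negative"):
                raise LoadError(f"call must be positive/negative, got {cell!r}",
                                row=i, column=col)

    out["size_cm"] = out["size_cm"].astype(float)
    out["resected"] = out["resected"].str.strip().str.lower().map(_BOOL_MAP)
    for col in ("rna_score", "gc_score"):
        out[col] = pd.to_numeric(out[col].mask(out[col].str.strip() == "", np.nan))
    for col in ("rna_call", "gc_call"):
        out[col] = out[col].mask(out[col].str.strip() == "", np.nan)
    return out


def _fmt_float(v) -> str:
    if pd.isna(v):
        return ""
    return f"{float(v):g}"


def write_nodule_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a nodule frame as canonical TSV (stable formatting, LF endings)."""
    out = frame.copy()
    for col in NODULE_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[NODULE_COLUMNS]
    out["size_cm"] = out["size_cm"].map(_fmt_float)
    out["resected"] = out["resected"].map(lambda b: "true" if bool(b) else "false")
    for col in ("rna_score", "gc_score"):
        out[col] = out[col].map(_fmt_float)
    for col in ("rna_call", "gc_call", "alterations"):
        out[col] = out[col].fillna("") if out[col].dtype == object else out[col]
    text = "\t".join(NODULE_COLUMNS) + "\n"
    for row in out.itertuples(index=False):
        text += "\t".join("" if pd.isna(v) else str(v) for v in row) + "\n"
    Path(path).write_text(text, encoding="utf-8")


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run.

    Either ``nodule_table`` points at an existing TSV/CSV, or ``simulate``
    holds a cohort-simulation config dict; exactly one input mode is active.
    Round-trips losslessly through YAML/JSON.
    """

    out_dir: str = "thyrisk_out"
    nodule_table: str | None = None
    weight_table: str | None = None
    vcf: str | None = None
    simulate: dict | None = None
    rna_threshold: float = 10.0
    gc_threshold: float = 70.0
    rule: str = "saturating_sum"
    ci_method: str = "wilson"
    borderline_policy: str = "as_malignant"
    correction: str = "none"
    npv_target: float = 0.90
    ppv_target: float = 0.75
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.nodule_table is None and self.simulate is None:
            raise ConfigError("config needs either nodule_table or simulate")
        if self.nodule_table is not None and self.simulate is not None:
            raise ConfigError("nodule_table and simulate are mutually exclusive")
        if self.ci_method not in ("wilson", "wald_cc", "none"):
            raise ConfigError(f"unknown ci_method {self.ci_method!r}")
        if self.borderline_policy not in ("as_malignant", "as_benign"):
            raise ConfigError(f"unknown borderline_policy {self.borderline_policy!r}")
        for p in (self.nodule_table, self.weight_table, self.vcf):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
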