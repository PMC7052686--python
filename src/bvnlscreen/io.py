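"""Readers and writers for cohort tables, model documents and manifests.

Cohorts are delimited text (comma by default, tab auto-detected) with header
``sample_id,idua,hs[,status]``; analytes are raw assay units. A fitted model
is serialized to a flat key-value document; manifests are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CohortValidationError
from .model import NormativeModel

__all__ = ["read_cohort", "write_cohort", "read_model", "write_model",
           "read_manifest", "write_manifest"]

_REQUIRED = ("sample_id", "idua", "hs")
_STATUS_VALUES = {"normal", "pseudo_deficient", "affected", "unknown"}
_MODEL_KEYS = ("mu_log_idua", "sd_log_idua", "mu_log_hs", "sd_log_hs",
               "rho", "n", "detection_limit_idua", "detection_limit_hs")


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Auto-detects comma vs tab. Requires sample_id/idua/hs columns; a
    header-only file yields an empty table. Unknown columns are preserved.
    Errors name the offending column and, for bad cells, the row number
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    if not path.exists():
        raise CohortValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path), dtype={"sample_id": str})
    for col in _REQUIRED:
        if col not in df.columns:
            raise CohortValidationError(
                f"cohort {path} is missing required column {col!r}"
            )
    for col in ("idua", "hs"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
            raise CohortValidationError(
                f"nonnumeric {col!r} value {df[col].iloc[row - 2]!r} "
                f"at {path} row {row}"
            )
        if values.isna().any():
            row = int(np.flatnonzero(values.isna())[0]) + 2
            raise CohortValidationError(f"missing {col!r} value at {path} row {row}")
        df[col] = values.astype(float)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise CohortValidationError(f"duplicate sample_id {dup!r} in {path}")
    if "status" in df.columns and len(df):
        bad = ~df["status"].isin(_STATUS_VALUES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise CohortValidationError(
                f"invalid status {df['status'].iloc[row - 2]!r} at {path} "
                f"row {row}; expected one of {sorted(_STATUS_VALUES)}"
            )
    return df


def write_cohort(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort table; full float precision (repr round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=False)


def write_model(model: NormativeModel, path) -> None:
    """Serialize a fitted model to a flat key-value text document."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key in _MODEL_KEYS:
            fh.write(f"{key}: {getattr(model, key)!r}\n")


def read_model(path) -> NormativeModel:
    """Read a model document written by :func:`write_model`."""
    doc = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            doc[key.strip()] = value.strip()
    missing = [k for k in _MODEL_KEYS if k not in doc]
    if missing:
        raise CohortValidationError(f"model document {path} missing keys {missing}")
    kwargs = {k: float(doc[k]) for k in _MODEL_KEYS}
    kwargs["n"] = int(float(doc["n"]))
    return NormativeModel(**kwargs)


def write_manifest(doc: dict, path) -> None:
    """Write a run manifest (all effective parameters and seeds) as YAML."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
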