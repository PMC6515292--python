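"""Readers and writers for the delimited formats the pipeline touches.

All files are UTF-8, tab-delimited by default. The screen-table reader
accepts a configurable column mapping because PubChem export dialects vary;
the defaults match PubChem bioassay exports
(``SID, AID, PUBCHEM_ACTIVITY_OUTCOME, PUBCHEM_ACTIVITY_SCORE, AC50``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ACTIVITY_COLUMNS,
    ANNOTATION_COLUMNS,
    META_COLUMNS,
    RECORD_COLUMNS,
    SignatureMatrix,
    ValidationError,
    validate_annotations,
    validate_meta,
    validate_records,
)

log = logging.getLogger(__name__)

#: default source-column names for :func:`read_screen_table`
DEFAULT_SCREEN_COLUMNS = {
    "sid": "SID",
    "assay_id": "AID",
    "outcome": "PUBCHEM_ACTIVITY_OUTCOME",
    "score": "PUBCHEM_ACTIVITY_SCORE",
    "ac50": "AC50",
}


def read_screen_table(
    path: str | Path,
    sep: str = "\t",
    column_map: dict[str, str] | None = None,
    ac50_scale: float = 1.0,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a long-format screen table into a validated record table.

    Parameters
    ----------
    column_map
        maps canonical names (``sid, assay_id, outcome, score, ac50``) to
        the file's header names; defaults to the PubChem export dialect.
    ac50_scale
        factor applied to the AC50 column to convert it to molar units
        (use ``1e-6`` for micromolar sources). pAC50 is derived as
        ``-log10(AC50 in molar)``.
    strict
        raise on outcome/score violations (True) or drop offending rows
        with a logged count (False).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_SCREEN_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map is None and all(c in raw.columns for c in RECORD_COLUMNS[:4]):
        # file already uses the canonical schema (e.g. a pipeline export)
        cmap = {k: k for k in cmap}
    missing = [v for k, v in cmap.items() if k != "ac50" and v not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    df = pd.DataFrame({
        "sid": raw[cmap["sid"]].astype(str),
        "assay_id": raw[cmap["assay_id"]].astype(str),
        "outcome": raw[cmap["outcome"]].str.strip().str.lower(),
    })
    score = pd.to_numeric(raw[cmap["score"]], errors="coerce")
    if score.isna().any():
        lines = (np.flatnonzero(score.isna()) + 2).tolist()  # header is line 1
        msg = f"{path}: malformed score values at lines {lines[:20]}"
        if strict:
            raise ValidationError(msg)
        log.warning(msg)
    df["score"] = score
    if cmap["ac50"] in raw.columns:
        ac50 = pd.to_numeric(raw[cmap["ac50"]], errors="coerce")  # "" -> NaN
        df["ac50"] = ac50 * ac50_scale
    else:
        df["ac50"] = np.nan
    df["pac50"] = np.where(df["ac50"] > 0, -np.log10(df["ac50"]), np.nan)
    if not strict:
        df = df[df["score"].notna()]
    return validate_records(df, strict=strict)


def write_screen_table(records: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    records[RECORD_COLUMNS].to_csv(path, sep=sep, index=False)


def read_records(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a record table previously written by :func:`write_screen_table`."""
    df = pd.read_csv(path, sep=sep, dtype={"sid": str, "assay_id": str})
    return validate_records(df)


def read_substance_meta(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read substance metadata (SID -> CID map, SMILES, purity grades).

    Unknown purity-grade strings map to ``other``; a missing CID cell is
    preserved as absent (the record can later be dropped by the unmapped
    filter). Duplicate SIDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df = df.copy()
    df["cid"] = df["cid"].replace("", pd.NA)
    df["smiles"] = df["smiles"].replace("", pd.NA)
    return validate_meta(df)


def write_substance_meta(meta: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    meta[META_COLUMNS].to_csv(path, sep=sep, index=False)


def read_assay_annotations(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    return validate_annotations(df)


def write_assay_annotations(annotations: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep=sep, index=False)


def write_activities(activities: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    activities[ACTIVITY_COLUMNS].to_csv(path, sep=sep, index=False)


def read_activities(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"cid": str, "assay_id": str})
    return df[ACTIVITY_COLUMNS]


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a dense binary signature matrix as TSV (CID rows, assay columns).

    The category and set label travel in the filename chosen by the caller;
    the file itself is a plain labelled 0/1 matrix that round-trips through
    :func:`read_signature_matrix`.
    """
    matrix.values.to_csv(path, sep=sep, index=True, index_label="cid")


def read_signature_matrix(
    path: str | Path, category: str, set_label: str = "", sep: str = "\t"
) -> SignatureMatrix:
    values = pd.read_csv(path, sep=sep, index_col="cid")
    values.index = values.index.astype(str)
    return SignatureMatrix(category=category, set_label=set_label, values=values)
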