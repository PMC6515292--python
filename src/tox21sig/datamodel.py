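"""Schemas and validation for screening-data tables.

Tables are carried as :class:`pandas.DataFrame` with fixed column contracts:

``records``
    one row per substance-batch x assay measurement:
    ``sid, assay_id, outcome, score, ac50, pac50``
``meta``
    one row per substance batch:
    ``sid, cid, smiles, purity_t0, purity_t4``
``annotations``
    one row per assay (controlled-vocabulary description):
    ``assay_id, tox21_id, title, stage, reporter_type, cell_line_id,
    organism_taxon, target_gene_id, target_relationship, pathway_go_id,
    pair_id``
``activities``
    one row per unique compound x assay after aggregation:
    ``cid, assay_id, outcome, mean_pac50, n_sids, concentration_class``

The activity outcome vocabulary and its score ranges follow the PubChem
Activity Score convention: inactive compounds score exactly 0, inconclusive
1-39, active 40-100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

OUTCOMES = ("active", "inactive", "inconclusive")

#: inclusive PubChem Activity Score range legal for each outcome
SCORE_RANGES = {
    "inactive": (0, 0),
    "inconclusive": (1, 39),
    "active": (40, 100),
}

PURITY_T0 = ("A", "B", "C", "other")
PURITY_T4 = ("A", "B", "C", "untested", "other")

#: T0 grades that pass the purity filter / T4 grades that pass it
PURITY_T0_PASS = frozenset({"A", "B", "C"})
PURITY_T4_PASS = frozenset({"A", "B", "C", "untested"})

STAGES = ("confirmatory", "counter")
REPORTER_TYPES = ("luciferase", "beta_lactamase", "fluorescent_protein", "other")
CATEGORIES = ("reporter_active", "toxicity_active", "reporter_selective")
CONCENTRATION_CLASSES = ("low_conc_active", "high_conc_active", "not_applicable")

RECORD_COLUMNS = ["sid", "assay_id", "outcome", "score", "ac50", "pac50"]
META_COLUMNS = ["sid", "cid", "smiles", "purity_t0", "purity_t4"]
ANNOTATION_COLUMNS = [
    "assay_id", "tox21_id", "title", "stage", "reporter_type",
    "cell_line_id", "organism_taxon", "target_gene_id",
    "target_relationship", "pathway_go_id", "pair_id",
]
ACTIVITY_COLUMNS = [
    "cid", "assay_id", "outcome", "mean_pac50", "n_sids", "concentration_class",
]


class ValidationError(ValueError):
    """Raised when a table violates its schema or the score/outcome contract."""


class ConfigError(ValueError):
    """Raised for inconsistent configuration (e.g. unpaired assays)."""


def score_outcome_consistent(outcome: str, score: int) -> bool:
    """True iff ``score`` lies in the legal range for ``outcome``."""
    rng = SCORE_RANGES.get(outcome)
    if rng is None:
        return False
    return rng[0] <= score <= rng[1]


def validate_records(records: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a substance-record table against the score/outcome contract.

    Violations are collected in bulk. With ``strict=True`` a single
    :class:`ValidationError` listing the offending SIDs is raised; with
    ``strict=False`` offending rows are dropped and their count logged.
    Also enforces that ``pac50`` is present iff ``ac50`` is present and
    positive.
    """
    missing = [c for c in ("sid", "assay_id", "outcome", "score") if c not in records.columns]
    if missing:
        raise ValidationError(f"record table missing columns: {missing}")
    df = records.copy()
    if "ac50" not in df.columns:
        df["ac50"] = np.nan
    if "pac50" not in df.columns:
        df["pac50"] = np.where(df["ac50"] > 0, -np.log10(df["ac50"]), np.nan)

    bad_outcome = ~df["outcome"].isin(OUTCOMES)
    score = pd.to_numeric(df["score"], errors="coerce")
    lo = df["outcome"].map({k: v[0] for k, v in SCORE_RANGES.items()})
    hi = df["outcome"].map({k: v[1] for k, v in SCORE_RANGES.items()})
    bad_score = score.isna() | (score < lo) | (score > hi)
    bad_pac50 = (df["ac50"] > 0) != df["pac50"].notna()
    bad = bad_outcome | bad_score | bad_pac50
    if bad.any():
        offenders = sorted(df.loc[bad, "sid"].astype(str).unique())
        if strict:
            raise ValidationError(
                f"{int(bad.sum())} records violate the outcome/score contract; "
                f"offending SIDs: {offenders[:50]}"
            )
        log.warning("dropping %d invalid records (%d SIDs)", int(bad.sum()), len(offenders))
        df = df.loc[~bad]
    df = df.copy()
    df["score"] = pd.to_numeric(df["score"]).astype(int)
    return df[RECORD_COLUMNS]


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a substance-metadata table: one row per SID, known grades."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata table missing columns: {missing}")
    dup = meta["sid"][meta["sid"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate SIDs in metadata: {sorted(dup.astype(str).unique())[:20]}")
    df = meta.copy()
    df["purity_t0"] = df["purity_t0"].where(df["purity_t0"].isin(PURITY_T0), "other")
    df["purity_t4"] = df["purity_t4"].where(df["purity_t4"].isin(PURITY_T4), "other")
    return df[META_COLUMNS]


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate an assay-annotation table and its reporter/counter pairing.

    Every ``pair_id`` must link exactly one confirmatory (reporter) assay to
    exactly one counter (viability) assay.
    """
    missing = [c for c in ("assay_id", "stage", "pair_id") if c not in annotations.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    if annotations["assay_id"].duplicated().any():
        raise ValidationError("assay_id not unique within annotation table")
    if not annotations["stage"].isin(STAGES).all():
        bad = annotations.loc[~annotations["stage"].isin(STAGES), "stage"].unique()
        raise ValidationError(f"unknown assay stages: {list(bad)}")
    counts = annotations.groupby("pair_id")["stage"].value_counts().unstack(fill_value=0)
    ok = (counts.get("confirmatory", 0) == 1) & (counts.get("counter", 0) == 1)
    if not np.asarray(ok).all():
        bad_pairs = list(counts.index[~np.asarray(ok)])
        raise ConfigError(f"pairs without exactly one reporter + one counter assay: {bad_pairs}")
    df = annotations.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[ANNOTATION_COLUMNS]


def pair_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """One row per reporter/counter pair: ``pair_id, reporter_aid, counter_aid``."""
    ann = annotations
    rep = ann[ann["stage"] == "confirmatory"].set_index("pair_id")["assay_id"]
    ctr = ann[ann["stage"] == "counter"].set_index("pair_id")["assay_id"]
    out = pd.DataFrame({"reporter_aid": rep, "counter_aid": ctr}).reset_index()
    return out.sort_values("pair_id", ignore_index=True)


@dataclass
class SignatureMatrix:
    """Dense binary compounds x assays matrix for one activity category.

    ``values`` is indexed by CID with assay IDs (or pair IDs for the
    reporter-selective category) as columns; cells are 0/1 with no missing
    entries.
    """

    category: str
    set_label: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown signature category: {self.category}")
        v = self.values
        if v.isna().any().any():
            raise ValidationError("signature matrix contains missing cells")
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("signature matrix cells must be 0 or 1")
        self.values = v.astype(np.int8)
        self.values.index.name = "cid"

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)
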