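"""Cleaning filters, compound-level aggregation, and dense-set partitioning.

The cleaning sequence mirrors the curation this pipeline reconstructs:

1. purity filter — keep a batch (SID) iff its T0 grade is A/B/C *and* its
   T4 grade is A/B/C/untested;
2. drop records whose SID has no standardized compound (CID) assignment;
3. aggregate the surviving substance records per unique compound and
   assay by majority outcome (strictly more than half of the SIDs, else
   inconclusive) with replicate pAC50 values averaged within SID first;
4. derive the low/high-concentration cutoff as mean + 1 SD of the pAC50
   values of active data points;
5. partition compounds into dense matrix sets by the exact set of assays
   each was tested in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    PURITY_T0_PASS,
    PURITY_T4_PASS,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Attrition accounting: every input SID lands in exactly one bucket.

    Purity is applied first, so an impure SID that is also unmapped counts
    toward the purity removals.
    """

    n_input_sids: int = 0
    n_removed_purity: int = 0
    n_removed_unmapped: int = 0
    n_kept: int = 0
    #: per-assay record counts before/after cleaning
    per_assay: pd.DataFrame | None = field(default=None, repr=False)

    def check(self) -> None:
        total = self.n_removed_purity + self.n_removed_unmapped + self.n_kept
        if total != self.n_input_sids:
            raise ValidationError(
                f"filter report does not reconcile: {self.n_input_sids} != "
                f"{self.n_removed_purity} + {self.n_removed_unmapped} + {self.n_kept}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("per_assay")
        return d


@dataclass
class Pac50Cutoff:
    """Low-concentration activity cutoff: mean + 1 sample SD of active pAC50s."""

    mean: float
    sd: float
    cutoff: float
    n_actives_used: int

    def __post_init__(self) -> None:
        if not np.isclose(self.cutoff, self.mean + self.sd):
            raise ValidationError("cutoff must equal mean + sd")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_purity(meta: pd.DataFrame) -> tuple[pd.Index, FilterReport]:
    """Keep SIDs with T0 in {A,B,C} and T4 in {A,B,C,untested}.

    Returns the kept SID index and a partially-filled :class:`FilterReport`
    (unmapped/kept buckets are completed by :func:`drop_unmapped`).
    """
    ok = meta["purity_t0"].isin(PURITY_T0_PASS) & meta["purity_t4"].isin(PURITY_T4_PASS)
    kept = pd.Index(meta.loc[ok, "sid"])
    report = FilterReport(
        n_input_sids=len(meta),
        n_removed_purity=int((~ok).sum()),
    )
    log.info("purity filter: %d of %d SIDs removed", report.n_removed_purity, len(meta))
    return kept, report


def drop_unmapped(
    records: pd.DataFrame, meta: pd.DataFrame, report: FilterReport | None = None
) -> pd.DataFrame:
    """Restrict records to SIDs with an assigned CID.

    A record whose SID is absent from the metadata altogether is an error
    (it cannot be attributed to a removal reason). When a
    :class:`FilterReport` is passed, its unmapped/kept buckets are filled
    in over the SIDs present in ``records``.
    """
    meta_idx = meta.set_index("sid")
    unknown = pd.Index(records["sid"].unique()).difference(meta_idx.index)
    if len(unknown):
        raise ValidationError(f"records reference SIDs absent from metadata: {sorted(unknown)[:20]}")
    has_cid = records["sid"].map(meta_idx["cid"].notna())
    out = records.loc[has_cid].copy()
    n_dropped_sids = records.loc[~has_cid, "sid"].nunique()
    log.info("CID mapping: dropped %d records over %d SIDs", int((~has_cid).sum()), n_dropped_sids)
    if report is not None:
        report.n_removed_unmapped = n_dropped_sids
        report.n_kept = out["sid"].nunique()
        # SIDs filtered out earlier and absent here were already counted
        report.check()
    return out


def clean_records(
    records: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the full cleaning sequence (purity, then CID mapping)."""
    kept_sids, report = filter_purity(meta)
    pure = records[records["sid"].isin(kept_sids)]
    # SIDs in the library but never screened still count toward the report
    out = drop_unmapped(pure, meta, report=None)
    report.n_removed_unmapped = int(
        meta.loc[meta["sid"].isin(kept_sids), "cid"].isna().sum()
    )
    report.n_kept = report.n_input_sids - report.n_removed_purity - report.n_removed_unmapped
    report.check()
    before = records.groupby("assay_id").size().rename("n_before")
    after = out.groupby("assay_id").size().rename("n_after")
    report.per_assay = pd.concat([before, after], axis=1).fillna(0).astype(int).reset_index()
    return out, report


def aggregate_by_cid(records: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Aggregate substance records to one activity per (CID, assay).

    The aggregate outcome is the one held by strictly more than 50% of the
    compound's SIDs in that assay; with no such majority the outcome is
    inconclusive. ``mean_pac50`` is the mean over SIDs of each SID's own
    replicate-averaged pAC50 (absent when no SID reports one); ``n_sids``
    counts distinct SIDs aggregated.
    """
    cid_of = meta.set_index("sid")["cid"]
    df = records.copy()
    df["cid"] = df["sid"].map(cid_of)
    if df["cid"].isna().any():
        raise ValidationError("records contain SIDs without a CID; run drop_unmapped first")

    # one outcome per SID x assay may repeat across replicates: majority is
    # over SIDs, so collapse replicates to each SID's modal outcome first
    # (replicated rows in the generated data are unique per SID x assay)
    per_sid = (
        df.groupby(["cid", "assay_id", "sid"], sort=True)
        .agg(outcome=("outcome", _sid_outcome), pac50=("pac50", "mean"))
        .reset_index()
    )
    grouped = per_sid.groupby(["cid", "assay_id"], sort=True)
    agg = grouped.agg(
        n_sids=("sid", "nunique"),
        mean_pac50=("pac50", "mean"),
    )
    counts = (
        per_sid.groupby(["cid", "assay_id"])["outcome"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["active", "inactive", "inconclusive"], fill_value=0)
    )
    top = counts.max(axis=1)
    winner = counts.idxmax(axis=1)
    majority = top * 2 > counts.sum(axis=1)
    agg["outcome"] = np.where(majority, winner, "inconclusive")
    agg = agg.reset_index()
    agg["concentration_class"] = "not_applicable"
    return agg[["cid", "assay_id", "outcome", "mean_pac50", "n_sids", "concentration_class"]]


def _sid_outcome(outcomes: pd.Series) -> str:
    """Collapse replicate outcomes of one SID: strict majority, else inconclusive."""
    counts = outcomes.value_counts()
    if counts.iloc[0] * 2 > counts.sum():
        return counts.index[0]
    return "inconclusive"


def compute_pac50_cutoff(
    data: pd.DataFrame | pd.Series | np.ndarray,
    outcome_col: str = "outcome",
    value_col: str | None = None,
) -> Pac50Cutoff:
    """Derive the low-concentration cutoff from active pAC50 values.

    Accepts either a plain vector of pAC50 values of active data points, or
    a table with an outcome column (only ``active`` rows contribute) and a
    pAC50 column (``pac50`` or ``mean_pac50``, autodetected). The cutoff is
    the sample mean plus one sample (n-1) standard deviation. Fewer than
    two usable values leave the cutoff undefined and raise.
    """
    if isinstance(data, pd.DataFrame):
        if value_col is None:
            value_col = "pac50" if "pac50" in data.columns else "mean_pac50"
        values = data.loc[data[outcome_col] == "active", value_col]
    else:
        values = pd.Series(np.asarray(data, dtype=float))
    values = values.dropna().astype(float)
    if len(values) < 2:
        raise ValidationError(
            f"pAC50 cutoff undefined: need >= 2 active values, got {len(values)}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return Pac50Cutoff(mean=mean, sd=sd, cutoff=mean + sd, n_actives_used=len(values))


def annotate_concentration(activities: pd.DataFrame, cutoff: Pac50Cutoff) -> pd.DataFrame:
    """Label actives as low- or high-concentration actives.

    An active with mean pAC50 at or above the cutoff acts at low
    concentration; below it, at high concentration. Non-actives and
    actives without a pAC50 stay ``not_applicable``.
    """
    out = activities.copy()
    active = out["outcome"] == "active"
    has_val = out["mean_pac50"].notna()
    out["concentration_class"] = "not_applicable"
    out.loc[active & has_val & (out["mean_pac50"] >= cutoff.cutoff), "concentration_class"] = "low_conc_active"
    out.loc[active & has_val & (out["mean_pac50"] < cutoff.cutoff), "concentration_class"] = "high_conc_active"
    return out


@dataclass
class DenseSet:
    """One dense block of the activity matrix: every listed compound has an
    outcome in every listed assay."""

    set_label: str
    cids: list[str]
    assays: list[str]

    @property
    def n_compounds(self) -> int:
        return len(self.cids)

    @property
    def n_assays(self) -> int:
        return len(self.assays)

    @property
    def data_points(self) -> int:
        return len(self.cids) * len(self.assays)


def partition_dense_sets(activities: pd.DataFrame) -> list[DenseSet]:
    """Group compounds by the exact set of assays they were tested in.

    Each group is a dense matrix by construction. Groups are ordered by
    descending compound count (ties broken by assay list) and labelled
    ``set1, set2, ...``; compound sets are disjoint and exhaustive.
    """
    assay_sets = activities.groupby("cid")["assay_id"].agg(lambda s: tuple(sorted(set(s))))
    groups: dict[tuple, list[str]] = {}
    for cid, aset in assay_sets.items():
        groups.setdefault(aset, []).append(cid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out = []
    for i, (aset, cids) in enumerate(ordered, start=1):
        out.append(DenseSet(set_label=f"set{i}", cids=sorted(cids), assays=list(aset)))
    return out


def dense_set_table(sets: list[DenseSet]) -> pd.DataFrame:
    """Data-matrix statistics per dense set, with a totals row.

    ``data_points`` is compounds x assays; the grand total also reports the
    pair-level count (data points aggregated to reporter/toxicity pairs,
    i.e. half the assay-level total).
    """
    rows = [
        {
            "set": s.set_label,
            "compounds": s.n_compounds,
            "assays": s.n_assays,
            "data_points": s.data_points,
        }
        for s in sets
    ]
    total = sum(r["data_points"] for r in rows)
    assay_union: set[str] = set()
    for s in sets:
        assay_union.update(s.assays)
    rows.append({
        "set": "total",
        "compounds": sum(r["compounds"] for r in rows),
        "assays": len(assay_union),
        "data_points": total,
    })
    rows.append({"set": "total_pairs", "compounds": "", "assays": "", "data_points": total // 2})
    return pd.DataFrame(rows)
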