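"""Promiscuity indices, z-score classification, and quadrant analysis.

A promiscuity index (PI) is the fraction of tested assays (within a
category) in which an entity is active; inconclusive results count as
tested but not active. PIs are standardized to z-scores across entities,
and z >= +1 flags an entity as promiscuous in that category. Four labels
are assigned independently and reported in a fixed sequence:

1. ``generally_promiscuous``  — total activity across all assays;
2. ``potentially_cytotoxic``  — activity across viability counter assays;
3. ``reporter_promiscuous``   — activity across reporter assays;
4. ``privileged_selective``   — reporter-selective activity (active in
   reporters but not their counters), suggesting action on a shared
   regulator or reporter pathway rather than general toxicity.

Compounds are additionally placed into quadrants by their reporter-active
and toxicity-active PIs (thresholds 0.45 / 0.30, closed on the
promiscuous/cytotoxic side): promiscuous/selective x inert/cytotoxic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import pair_table

log = logging.getLogger(__name__)

PI_CATEGORIES = ("total", "reporter_active", "toxicity_active", "reporter_selective")

#: classification labels in reporting order, keyed by their PI category
CLASS_LABELS = (
    ("generally_promiscuous", "total"),
    ("potentially_cytotoxic", "toxicity_active"),
    ("reporter_promiscuous", "reporter_active"),
    ("privileged_selective", "reporter_selective"),
)

QUADRANT_THRESHOLDS = (0.45, 0.30)
SELECTIVE_RATIO_THRESHOLD = 5.0


def promiscuity_index(n_active: int, n_tested: int) -> float:
    """Active fraction of tested assays; NaN when nothing was tested."""
    if n_tested == 0:
        return float("nan")
    return n_active / n_tested


def pi_zscores(pis: pd.Series) -> pd.Series:
    """Standardize PIs across entities (sample mean/SD over defined values).

    A zero SD yields all-zero z-scores with a warning; undefined PIs stay
    undefined.
    """
    vals = pis.dropna()
    if len(vals) < 2:
        log.warning("z-scores need >= 2 defined PIs; returning zeros")
        return pis * 0.0
    sd = vals.std(ddof=1)
    if np.isclose(sd, 0.0):
        log.warning("PI standard deviation is zero; all z-scores set to 0")
        return pis * 0.0
    return (pis - vals.mean()) / sd


def compound_profiles(activities: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-compound tested/active counts and PIs for all four categories.

    ``total`` counts active outcomes over all tested assays;
    ``reporter_active`` / ``toxicity_active`` restrict to confirmatory /
    counter assays; ``reporter_selective`` counts pairs where the reporter
    is active and its counter inactive, over pairs with both assays tested.
    """
    stage_of = annotations.set_index("assay_id")["stage"]
    df = activities.copy()
    df["stage"] = df["assay_id"].map(stage_of)
    df["active"] = (df["outcome"] == "active").astype(int)

    def counts(sub: pd.DataFrame, label: str) -> pd.DataFrame:
        g = sub.groupby("cid")["active"].agg(["size", "sum"])
        g.columns = [f"n_tested_{label}", f"n_active_{label}"]
        return g

    total = counts(df, "total")
    rep = counts(df[df["stage"] == "confirmatory"], "reporter_active")
    tox = counts(df[df["stage"] == "counter"], "toxicity_active")

    pairs = pair_table(annotations)
    pair_of = {}
    for _, row in pairs.iterrows():
        pair_of[row["reporter_aid"]] = (row["pair_id"], "reporter")
        pair_of[row["counter_aid"]] = (row["pair_id"], "counter")
    dfp = df[df["assay_id"].isin(pair_of)].copy()
    dfp["pair_id"] = dfp["assay_id"].map(lambda a: pair_of[a][0])
    dfp["role"] = dfp["assay_id"].map(lambda a: pair_of[a][1])
    wide = dfp.pivot_table(
        index=["cid", "pair_id"], columns="role", values="outcome", aggfunc="first"
    )
    both = wide.dropna(subset=["reporter", "counter"])
    sel_hit = ((both["reporter"] == "active") & (both["counter"] == "inactive")).astype(int)
    sel = sel_hit.groupby(level="cid").agg(["size", "sum"])
    sel.columns = ["n_tested_reporter_selective", "n_active_reporter_selective"]

    out = pd.concat([total, rep, tox, sel], axis=1).fillna(0).astype(int)
    for cat in PI_CATEGORIES:
        tested = out[f"n_tested_{cat}"]
        out[f"pi_{cat}"] = np.where(tested > 0, out[f"n_active_{cat}"] / tested, np.nan)
    out.index.name = "entity_id"
    return out


def add_zscores(profiles: pd.DataFrame) -> pd.DataFrame:
    """Attach a z column per category, standardized across the table's rows."""
    out = profiles.copy()
    for cat in PI_CATEGORIES:
        out[f"z_{cat}"] = pi_zscores(out[f"pi_{cat}"])
    return out


def classify(profile: pd.Series, z_threshold: float = 1.0) -> tuple[str, ...]:
    """Ordered promiscuity class labels for one profile row.

    Each label is assigned independently by its ``z >= +1`` test; the
    result preserves the canonical (1)-(4) sequence.
    """
    labels = []
    for label, cat in CLASS_LABELS:
        z = profile.get(f"z_{cat}")
        if z is not None and not pd.isna(z) and z >= z_threshold:
            labels.append(label)
    return tuple(labels)


def quadrant(
    reporter_pi: float,
    toxicity_pi: float,
    thresholds: tuple[float, float] = QUADRANT_THRESHOLDS,
) -> str:
    """Quadrant label from reporter-active and toxicity-active PIs.

    Reporter PI >= 0.45 reads promiscuous (else selective); toxicity PI
    >= 0.30 reads cytotoxic (else inert). Missing PIs are unclassified.
    """
    if pd.isna(reporter_pi) or pd.isna(toxicity_pi):
        return "unclassified"
    rep = "promiscuous" if reporter_pi >= thresholds[0] else "selective"
    tox = "cytotoxic" if toxicity_pi >= thresholds[1] else "inert"
    return f"{rep}_{tox}"


def selective_ratio_flag(
    selective_pi: float,
    toxicity_pi: float,
    threshold: float = SELECTIVE_RATIO_THRESHOLD,
) -> bool:
    """Flag a high selective-PI / toxicity-PI ratio (>= 5).

    With zero toxicity PI, any positive selective PI qualifies (the ratio
    is unbounded); an undefined selective PI never does.
    """
    if pd.isna(selective_pi):
        return False
    if pd.isna(toxicity_pi) or toxicity_pi == 0:
        return selective_pi > 0
    return selective_pi / toxicity_pi >= threshold


def profile_table(activities: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Full per-compound promiscuity table: counts, PIs, z, labels, quadrant."""
    prof = add_zscores(compound_profiles(activities, annotations))
    prof["labels"] = [";".join(classify(row)) for _, row in prof.iterrows()]
    prof["quadrant"] = [
        quadrant(row["pi_reporter_active"], row["pi_toxicity_active"])
        for _, row in prof.iterrows()
    ]
    prof["selective_flag"] = [
        selective_ratio_flag(row["pi_reporter_selective"], row["pi_toxicity_active"])
        for _, row in prof.iterrows()
    ]
    return prof


def cluster_promiscuity(
    assignment: pd.Series, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Chemotype-level promiscuity: mean member PI per cluster, re-standardized.

    ``assignment`` maps CID -> cluster id. A cluster's PI in a category is
    the arithmetic mean over members with a defined PI (absent when no
    member has one); z-scores are computed across clusters.
    """
    prof = profiles.copy()
    prof["cluster"] = prof.index.map(assignment)
    prof = prof[prof["cluster"].notna()]
    agg = prof.groupby("cluster")[[f"pi_{c}" for c in PI_CATEGORIES]].mean()
    agg["n_members"] = prof.groupby("cluster").size()
    for cat in PI_CATEGORIES:
        agg[f"z_{cat}"] = pi_zscores(agg[f"pi_{cat}"])
    agg["labels"] = [";".join(classify(row)) for _, row in agg.iterrows()]
    agg["quadrant"] = [
        quadrant(row["pi_reporter_active"], row["pi_toxicity_active"])
        for _, row in agg.iterrows()
    ]
    agg.index.name = "entity_id"
    return agg
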