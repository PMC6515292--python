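"""Binary signature construction from aggregated activities.

Three categories are built per dense set:

- ``reporter_active``   — 1 iff the aggregate outcome in a reporter
  (confirmatory) assay is active; one column per reporter assay.
- ``toxicity_active``   — 1 iff active in a viability counter assay; one
  column per counter assay.
- ``reporter_selective`` — 1 iff active in the reporter assay *and*
  strictly inactive in its paired counter assay (an inconclusive counter
  result does not qualify); one column per reporter/counter pair.
"""

from __future__ import annotations

import pandas as pd

from .cleaning import DenseSet
from .datamodel import ConfigError, SignatureMatrix, pair_table


def build_signatures(
    activities: pd.DataFrame,
    annotations: pd.DataFrame,
    dense_sets: list[DenseSet],
    counter_inactive_strict: bool = True,
) -> dict[str, dict[str, SignatureMatrix]]:
    """Build the three signature matrices for every dense set.

    Returns ``{set_label: {category: SignatureMatrix}}``. Every reporter
    assay appearing in a set must bring its paired counter assay (the
    panel design guarantees this for generated data); an unpaired assay is
    a configuration error.

    ``counter_inactive_strict=True`` (the default) requires the counter
    outcome to be literally inactive for selectivity; with ``False`` an
    inconclusive counter result also passes, for sensitivity analysis.
    """
    pairs = pair_table(annotations)
    stage_of = annotations.set_index("assay_id")["stage"]
    out: dict[str, dict[str, SignatureMatrix]] = {}
    for ds in dense_sets:
        unknown = [a for a in ds.assays if a not in stage_of.index]
        if unknown:
            raise ConfigError(f"{ds.set_label}: assays without annotation: {unknown}")
        sub = activities[
            activities["cid"].isin(ds.cids) & activities["assay_id"].isin(ds.assays)
        ]
        outcome = sub.pivot(index="cid", columns="assay_id", values="outcome")
        outcome = outcome.reindex(index=sorted(ds.cids), columns=ds.assays)
        if outcome.isna().any().any():
            raise ConfigError(f"{ds.set_label}: activity block is not dense")

        rep_cols = [a for a in ds.assays if stage_of[a] == "confirmatory"]
        ctr_cols = [a for a in ds.assays if stage_of[a] == "counter"]
        set_pairs = pairs[
            pairs["reporter_aid"].isin(ds.assays) | pairs["counter_aid"].isin(ds.assays)
        ]
        incomplete = set_pairs[
            ~(set_pairs["reporter_aid"].isin(ds.assays) & set_pairs["counter_aid"].isin(ds.assays))
        ]
        if len(incomplete):
            raise ConfigError(
                f"{ds.set_label}: unpaired assays in set: "
                f"{incomplete[['reporter_aid', 'counter_aid']].to_dict('records')}"
            )

        reporter_active = (outcome[rep_cols] == "active").astype(int)
        toxicity_active = (outcome[ctr_cols] == "active").astype(int)
        selective = {}
        for _, prow in set_pairs.iterrows():
            rep_ok = outcome[prow["reporter_aid"]] == "active"
            if counter_inactive_strict:
                ctr_ok = outcome[prow["counter_aid"]] == "inactive"
            else:
                ctr_ok = outcome[prow["counter_aid"]] != "active"
            selective[prow["pair_id"]] = (rep_ok & ctr_ok).astype(int)
        selective_df = pd.DataFrame(selective, index=outcome.index)

        out[ds.set_label] = {
            "reporter_active": SignatureMatrix("reporter_active", ds.set_label, reporter_active),
            "toxicity_active": SignatureMatrix("toxicity_active", ds.set_label, toxicity_active),
            "reporter_selective": SignatureMatrix("reporter_selective", ds.set_label, selective_df),
        }
    return out


def summarize_categories(
    matrices: dict[str, dict[str, SignatureMatrix]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column and global positive counts across signature matrices.

    Returns ``(per_column, global_counts)``. The global table counts, per
    category, the compounds positive in one or more columns (set
    semantics: a compound active in several columns counts once).
    """
    col_rows = []
    global_rows = []
    per_category_positive: dict[str, set[str]] = {}
    per_category_total: dict[str, set[str]] = {}
    for set_label, cats in matrices.items():
        for category, mat in cats.items():
            v = mat.values
            for col in v.columns:
                col_rows.append({
                    "set": set_label,
                    "category": category,
                    "column": col,
                    "n_compounds": len(v),
                    "n_positive": int(v[col].sum()),
                    "positive_fraction": float(v[col].mean()) if len(v) else 0.0,
                })
            hits = set(v.index[v.any(axis=1)]) if len(v.columns) else set()
            per_category_positive.setdefault(category, set()).update(hits)
            per_category_total.setdefault(category, set()).update(v.index)
    for category, hits in per_category_positive.items():
        global_rows.append({
            "category": category,
            "n_compounds": len(per_category_total[category]),
            "n_active_in_ge1": len(hits),
        })
    return pd.DataFrame(col_rows), pd.DataFrame(global_rows)
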