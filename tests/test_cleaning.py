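"""Cleaning filters, majority aggregation, cutoff, and dense partitioning."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from tox21sig.cleaning import (
    aggregate_by_cid,
    annotate_concentration,
    clean_records,
    compute_pac50_cutoff,
    dense_set_table,
    drop_unmapped,
    filter_purity,
    partition_dense_sets,
)
from tox21sig.datamodel import OUTCOMES, PURITY_T0, PURITY_T4, ValidationError


def _meta(rows):
    df = pd.DataFrame(rows, columns=["sid", "cid", "purity_t0", "purity_t4"])
    df["smiles"] = "C"
    return df[["sid", "cid", "smiles", "purity_t0", "purity_t4"]]


def _records(rows):
    df = pd.DataFrame(rows, columns=["sid", "assay_id", "outcome"])
    df["score"] = df["outcome"].map({"active": 80, "inactive": 0, "inconclusive": 20})
    df["ac50"] = np.nan
    df["pac50"] = np.nan
    return df


def test_purity_filter_exhaustive_over_grades():
    """SID kept iff T0 in {A,B,C} and T4 in {A,B,C,untested}."""
    rows = [
        (f"S-{t0}-{t4}", "C1", t0, t4) for t0 in PURITY_T0 for t4 in PURITY_T4
    ]
    kept, report = filter_purity(_meta(rows))
    expected = {
        f"S-{t0}-{t4}"
        for t0 in ("A", "B", "C")
        for t4 in ("A", "B", "C", "untested")
    }
    assert set(kept) == expected
    assert report.n_removed_purity == len(rows) - len(expected)


def test_drop_unmapped():
    meta = _meta([("S1", "C1", "A", "A"), ("S2", None, "A", "A"), ("S3", "C2", "A", "A")])
    records = _records([("S1", "A1", "active"), ("S2", "A1", "active"), ("S3", "A1", "inactive")])
    out = drop_unmapped(records, meta)
    assert set(out["sid"]) == {"S1", "S3"}
    all_mapped = drop_unmapped(records[records["sid"] != "S2"], meta)
    assert len(all_mapped) == 2
    with pytest.raises(ValidationError, match="S9"):
        drop_unmapped(_records([("S9", "A1", "active")]), meta)


@pytest.mark.parametrize("size", [1, 2, 3, 4, 5])
def test_majority_rule_matches_brute_force(size):
    """Aggregate outcome equals a direct count over the compound's SIDs for
    every outcome multiset up to size 5: strict majority or inconclusive."""
    for combo in itertools.product(OUTCOMES, repeat=size):
        meta = _meta([(f"S{i}", "C1", "A", "A") for i in range(size)])
        records = _records([(f"S{i}", "A1", o) for i, o in enumerate(combo)])
        agg = aggregate_by_cid(records, meta)
        assert len(agg) == 1
        counts = Counter(combo)
        top_outcome, top_n = counts.most_common(1)[0]
        expected = top_outcome if top_n * 2 > size else "inconclusive"
        assert agg["outcome"].iloc[0] == expected, combo
        assert agg["n_sids"].iloc[0] == size


def test_aggregation_is_permutation_invariant(small_cleaned):
    records = small_cleaned["clean"]
    meta = small_cleaned["data"]["meta"]
    shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = aggregate_by_cid(records, meta).sort_values(["cid", "assay_id"], ignore_index=True)
    b = aggregate_by_cid(shuffled, meta).sort_values(["cid", "assay_id"], ignore_index=True)
    pd.testing.assert_frame_equal(a, b)


def test_pac50_replicates_average_within_sid_first():
    meta = _meta([("S1", "C1", "A", "A"), ("S2", "C1", "A", "A")])
    records = _records([
        ("S1", "A1", "active"), ("S1", "A1", "active"), ("S2", "A1", "active"),
    ])
    records["pac50"] = [5.0, 7.0, 4.0]
    records["ac50"] = 10.0 ** -records["pac50"]
    agg = aggregate_by_cid(records, meta)
    # S1 replicates average to 6.0 first, then the SID means average: (6+4)/2
    assert agg["mean_pac50"].iloc[0] == pytest.approx(5.0)
    assert agg["n_sids"].iloc[0] == 2


def test_cutoff_mean_plus_sample_sd():
    df = pd.DataFrame({"outcome": ["active"] * 3, "pac50": [4.0, 5.0, 6.0]})
    cut = compute_pac50_cutoff(df)
    assert cut.mean == pytest.approx(5.0)
    assert cut.sd == pytest.approx(1.0)
    assert cut.cutoff == pytest.approx(6.0)
    with pytest.raises(ValidationError):
        compute_pac50_cutoff(pd.DataFrame({"outcome": ["active"], "pac50": [5.0]}))


def test_concentration_annotation():
    from tox21sig.cleaning import Pac50Cutoff

    cut = Pac50Cutoff(mean=4.60, sd=0.55, cutoff=5.15, n_actives_used=2)
    activities = pd.DataFrame({
        "cid": ["C1", "C2", "C3", "C4", "C5"],
        "assay_id": "A1",
        "outcome": ["active", "active", "active", "inactive", "active"],
        "mean_pac50": [6.0, 4.0, 5.15, 6.0, np.nan],
        "n_sids": 1,
        "concentration_class": "not_applicable",
    })
    out = annotate_concentration(activities, cut)
    assert list(out["concentration_class"]) == [
        "low_conc_active", "high_conc_active", "low_conc_active",
        "not_applicable", "not_applicable",
    ]


def test_filter_report_reconciles(small_cleaned):
    report = small_cleaned["report"]
    report.check()  # n_input = purity + unmapped + kept
    assert report.n_input_sids == len(small_cleaned["data"]["meta"])


def test_partition_dense_sets_properties(small_cleaned):
    activities = small_cleaned["activities"]
    sets = partition_dense_sets(activities)
    seen = set()
    tested = activities.set_index(["cid", "assay_id"]).index
    for ds in sets:
        assert not seen & set(ds.cids)  # disjoint
        seen.update(ds.cids)
        for cid in ds.cids:  # dense: every cell present
            for assay in ds.assays:
                assert (cid, assay) in tested
    assert seen == set(activities["cid"])  # exhaustive
    sizes = [ds.n_compounds for ds in sets]
    assert sizes == sorted(sizes, reverse=True)


def test_partition_two_compounds_different_assay_sets():
    activities = pd.DataFrame({
        "cid": ["C1", "C1", "C2"],
        "assay_id": ["A1", "A2", "A1"],
        "outcome": "inactive",
        "mean_pac50": np.nan,
        "n_sids": 1,
        "concentration_class": "not_applicable",
    })
    sets = partition_dense_sets(activities)
    assert len(sets) == 2
    single = partition_dense_sets(activities[activities["cid"] == "C1"])
    assert len(single) == 1


def test_clean_records_conservation(small_campaign):
    _, data = small_campaign
    out, report = clean_records(data["records"], data["meta"])
    report.check()
    kept_sids = set(out["sid"])
    meta = data["meta"].set_index("sid")
    for sid in kept_sids:
        assert meta.loc[sid, "purity_t0"] in ("A", "B", "C")
        assert pd.notna(meta.loc[sid, "cid"])
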