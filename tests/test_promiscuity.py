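"""Promiscuity indices, z-scores, class labels, quadrants, and clusters."""

import numpy as np
import pandas as pd
import pytest

from tox21sig.promiscuity import (
    PI_CATEGORIES,
    classify,
    cluster_promiscuity,
    compound_profiles,
    pi_zscores,
    profile_table,
    promiscuity_index,
    quadrant,
    selective_ratio_flag,
)

ANNOTATIONS = pd.DataFrame({
    "assay_id": ["R1", "T1", "R2", "T2"],
    "stage": ["confirmatory", "counter", "confirmatory", "counter"],
    "pair_id": ["P1", "P1", "P2", "P2"],
})


def test_promiscuity_index_examples():
    assert promiscuity_index(3, 10) == pytest.approx(0.3)
    assert promiscuity_index(10, 10) == 1.0
    assert np.isnan(promiscuity_index(0, 0))


def test_zscore_example_and_degenerate():
    z = pi_zscores(pd.Series([0.0, 0.0, 0.0, 1.0]))
    assert z.iloc[3] == pytest.approx(1.5)  # mean .25, sample sd .5
    assert pi_zscores(pd.Series([0.4, 0.4, 0.4])).tolist() == [0.0, 0.0, 0.0]


def test_zscores_match_direct_recomputation():
    rng = np.random.default_rng(0)
    for _ in range(100):
        pis = pd.Series(rng.random(rng.integers(3, 30)))
        z = pi_zscores(pis)
        expected = (pis - pis.mean()) / pis.std(ddof=1)
        assert np.allclose(z, expected)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0)


def test_undefined_pis_stay_undefined():
    z = pi_zscores(pd.Series([0.1, np.nan, 0.9]))
    assert np.isnan(z.iloc[1]) and np.isfinite(z.iloc[0])


def test_classification_labels_ordered():
    row = pd.Series({"z_total": 2.0, "z_toxicity_active": 0.0,
                     "z_reporter_active": 1.5, "z_reporter_selective": 0.0})
    assert classify(row) == ("generally_promiscuous", "reporter_promiscuous")
    none = pd.Series({f"z_{c}": 0.5 for c in PI_CATEGORIES})
    assert classify(none) == ()
    sel_only = pd.Series({"z_total": 0.0, "z_toxicity_active": 0.0,
                          "z_reporter_active": 0.0, "z_reporter_selective": 2.0})
    assert classify(sel_only) == ("privileged_selective",)


def test_quadrants():
    assert quadrant(0.50, 0.10) == "promiscuous_inert"
    assert quadrant(0.50, 0.50) == "promiscuous_cytotoxic"
    assert quadrant(0.10, 0.10) == "selective_inert"
    assert quadrant(0.10, 0.50) == "selective_cytotoxic"
    assert quadrant(0.45, 0.30) == "promiscuous_cytotoxic"  # closed thresholds
    assert quadrant(np.nan, 0.2) == "unclassified"


def test_selective_ratio_flag():
    assert selective_ratio_flag(0.5, 0.05) is True  # ratio 10
    assert selective_ratio_flag(0.5, 0.2) is False  # ratio 2.5
    assert selective_ratio_flag(0.3, 0.0) is True  # unbounded ratio
    assert selective_ratio_flag(0.0, 0.0) is False
    assert selective_ratio_flag(np.nan, 0.1) is False


def test_compound_profiles_counts():
    """Inconclusive counts as tested but not active; selective counts pairs
    with reporter active + counter inactive."""
    activities = pd.DataFrame({
        "cid": ["C1"] * 4,
        "assay_id": ["R1", "T1", "R2", "T2"],
        "outcome": ["active", "inactive", "inconclusive", "active"],
    })
    prof = compound_profiles(activities, ANNOTATIONS)
    row = prof.loc["C1"]
    assert row["n_tested_total"] == 4 and row["n_active_total"] == 2
    assert row["pi_total"] == pytest.approx(0.5)
    assert row["pi_reporter_active"] == pytest.approx(0.5)  # active in R1 of R1,R2
    assert row["pi_toxicity_active"] == pytest.approx(0.5)  # active in T2
    # P1: reporter active + counter inactive -> selective; P2: not
    assert row["n_tested_reporter_selective"] == 2
    assert row["pi_reporter_selective"] == pytest.approx(0.5)


def test_pi_monotonicity():
    """Adding an active column never decreases PI; adding an inactive
    tested column never increases it."""
    base = promiscuity_index(3, 10)
    assert promiscuity_index(4, 11) >= base
    assert promiscuity_index(3, 11) <= base


def test_profile_table_on_synthetic_run(small_cleaned):
    prof = profile_table(small_cleaned["activities"], small_cleaned["data"]["annotations"])
    for cat in PI_CATEGORIES:
        pis = prof[f"pi_{cat}"].dropna()
        assert ((pis >= 0) & (pis <= 1)).all()
        z = prof[f"z_{cat}"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert set(prof["quadrant"]).issubset({
        "promiscuous_inert", "promiscuous_cytotoxic",
        "selective_inert", "selective_cytotoxic", "unclassified",
    })


def test_cluster_promiscuity_mean_and_zscores():
    rng = np.random.default_rng(1)
    n = 120
    profiles = pd.DataFrame(
        {f"pi_{c}": rng.random(n) for c in PI_CATEGORIES},
        index=pd.Index([f"C{i}" for i in range(n)], name="entity_id"),
    )
    assignment = pd.Series(rng.integers(0, 30, size=n), index=profiles.index)
    agg = cluster_promiscuity(assignment, profiles)
    # direct recomputation oracle
    for cluster_id in agg.index:
        members = assignment.index[assignment == cluster_id]
        expected = profiles.loc[members, "pi_total"].mean()
        assert agg.loc[cluster_id, "pi_total"] == pytest.approx(expected)
    z = agg["z_total"]
    expected_z = (agg["pi_total"] - agg["pi_total"].mean()) / agg["pi_total"].std(ddof=1)
    assert np.allclose(z, expected_z)


def test_cluster_promiscuity_singleton_and_mean_pair():
    profiles = pd.DataFrame(
        {f"pi_{c}": [0.2, 0.4, 0.8] for c in PI_CATEGORIES},
        index=pd.Index(["C1", "C2", "C3"], name="entity_id"),
    )
    assignment = pd.Series([0, 0, 1], index=profiles.index)
    agg = cluster_promiscuity(assignment, profiles)
    assert agg.loc[0, "pi_total"] == pytest.approx(0.3)
    assert agg.loc[1, "pi_total"] == pytest.approx(0.8)  # singleton keeps its PI
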