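"""Shared fixtures: small synthetic campaigns reused across test modules."""

import pytest

from tox21sig.cleaning import (
    aggregate_by_cid,
    clean_records,
    partition_dense_sets,
)
from tox21sig.signatures import build_signatures
from tox21sig.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_campaign():
    """A 6-pair, 400-batch campaign: fast, with all structural features."""
    config = SyntheticConfig(n_pairs=6, n_sids=400, seed=5)
    return config, generate_dataset(config)


@pytest.fixture(scope="session")
def small_cleaned(small_campaign):
    """Cleaned + aggregated view of the small campaign."""
    _, data = small_campaign
    clean, report = clean_records(data["records"], data["meta"])
    activities = aggregate_by_cid(clean, data["meta"])
    dense_sets = partition_dense_sets(activities)
    matrices = build_signatures(activities, data["annotations"], dense_sets)
    return {
        "data": data,
        "clean": clean,
        "report": report,
        "activities": activities,
        "dense_sets": dense_sets,
        "matrices": matrices,
    }


@pytest.fixture(scope="session")
def planted_assay():
    """One reporter assay over a 2000-compound library with the default
    planted pharmacophore signal: (features, labels) for NB benchmarking."""
    from tox21sig.features import modeling_features

    config = SyntheticConfig(
        n_pairs=1,
        n_sids=2000,
        sid_per_cid_mean=1.0,
        purity_fail_rate=0.0,
        unmapped_rate=0.0,
        panel_fractions=(1.0, 0.0, 0.0),
        seed=7,
    )
    data = generate_dataset(config)
    clean, _ = clean_records(data["records"], data["meta"])
    activities = aggregate_by_cid(clean, data["meta"])
    dense_sets = partition_dense_sets(activities)
    matrices = build_signatures(activities, data["annotations"], dense_sets)
    reporter = matrices["set1"]["reporter_active"].values
    cids = list(reporter.index)
    feats_by_cid = modeling_features(
        data["compounds"][data["compounds"]["cid"].isin(cids)][["cid", "smiles"]]
    )
    features = [feats_by_cid[c] for c in cids]
    labels = reporter[reporter.columns[0]].to_numpy()
    return features, labels
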