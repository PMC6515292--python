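"""Fingerprints, descriptors, binning, and the Tanimoto metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from tox21sig.datamodel import ValidationError
from tox21sig.features import (
    BinningScheme,
    FeaturizationError,
    apply_bins,
    descriptors,
    featurize,
    featurize_table,
    learn_bins,
    modeling_features,
    tanimoto,
)


def test_fingerprint_deterministic_and_kind_sensitive():
    assert featurize("CC") == featurize("CC")
    assert featurize("CCO", kind="ECFP6") != featurize("CCO", kind="FCFP6")
    with pytest.raises(ValidationError):
        featurize("CC", kind="MACCS")


def test_aromatic_vs_aliphatic_rings_disjoint():
    """Benzene and cyclohexane share no environment under ECFP typing."""
    assert featurize("c1ccccc1") & featurize("C1CCCCC1") == frozenset()


def test_fingerprint_invariant_to_atom_order():
    for kind in ("ECFP6", "FCFP6"):
        assert featurize("Oc1ccccc1", kind=kind) == featurize("c1ccc(O)cc1", kind=kind)
        assert featurize("CC(N)C", kind=kind) == featurize("CC(C)N", kind=kind)


def test_unparseable_smiles_carries_cid():
    with pytest.raises(FeaturizationError) as err:
        featurize("not-a-smiles", cid="C42")
    assert err.value.cid == "C42"


def test_descriptors_alkane_has_zero_polar_surface():
    d = descriptors("CCCCCC")
    assert d["fpsa"] == pytest.approx(0.0)
    assert d["hbd"] == 0 and d["hba"] == 0
    assert d["mol_weight"] == pytest.approx(86.18, abs=0.1)


def test_salt_stripping_keeps_largest_organic_fragment():
    assert featurize("CCCCCCCCCC[N+](C)(C)C.[Cl-]") == featurize("CCCCCCCCCC[N+](C)(C)C")


def test_featurize_table_drop_mode():
    import pandas as pd

    df = pd.DataFrame({"cid": ["C1", "C2"], "smiles": ["CCO", "xyz("]})
    with pytest.raises(FeaturizationError):
        featurize_table(df)
    fps, desc = featurize_table(df, on_error="drop")
    assert set(fps) == {"C1"} and list(desc.index) == ["C1"]


class TestBinning:
    def test_median_split(self):
        cuts = learn_bins(np.arange(1, 11), n_bins=2)
        assert cuts == pytest.approx([5.5])
        assert apply_bins(cuts, [3, 8]).tolist() == [0, 1]

    def test_constant_descriptor_single_bin(self):
        cuts = learn_bins(np.full(20, 7.0), n_bins=10)
        assert len(cuts) == 0
        assert apply_bins(cuts, [7.0, 100.0]).tolist() == [0, 0]

    def test_out_of_range_clamps_to_edge_bins(self):
        cuts = learn_bins(np.arange(100.0), n_bins=4)
        assert apply_bins(cuts, [-50.0]).tolist() == [0]
        assert apply_bins(cuts, [1e6]).tolist() == [len(cuts)]

    def test_every_value_maps_to_exactly_one_bin(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=500)
        cuts = learn_bins(vals, n_bins=10)
        bins = apply_bins(cuts, vals)
        assert bins.min() == 0 and bins.max() == len(cuts)

    def test_scheme_does_not_peek_at_test_values(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        train = pd.DataFrame({"x": rng.normal(size=100)})
        test = pd.DataFrame({"x": rng.normal(10.0, 1.0, size=50)}, index=[f"T{i}" for i in range(50)])
        scheme = BinningScheme.learn(train, n_bins=5)
        before = {k: v.copy() for k, v in scheme.cuts.items()}
        scheme.features(test)
        assert all(np.array_equal(before[k], scheme.cuts[k]) for k in before)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            learn_bins(np.array([]), n_bins=5)


def test_modeling_features_single_space():
    import pandas as pd

    df = pd.DataFrame({"cid": ["C1", "C2"], "smiles": ["CCO", "c1ccccc1CCCC"]})
    feats = modeling_features(df, n_bins=2)
    f1 = feats["C1"]
    assert any(str(f).startswith("fp:") for f in f1)
    assert any(str(f).startswith("logp:bin") for f in f1)
    # exactly one bin feature per descriptor
    assert sum(1 for f in f1 if str(f).startswith("mol_weight:")) == 1


def test_sdf_reader_round_trips_structures(tmp_path):
    from rdkit.Chem import SDWriter
    from tox21sig.features import read_sdf_structures

    p = tmp_path / "mols.sdf"
    writer = SDWriter(str(p))
    for cid, smi in (("C1", "CCO"), ("C2", "c1ccccc1")):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("cid", cid)
        writer.write(mol)
    writer.close()
    df = read_sdf_structures(p)
    assert list(df["cid"]) == ["C1", "C2"]
    assert featurize(df["smiles"][0]) == featurize("CCO")


class TestTanimoto:
    def test_examples(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0
        assert tanimoto({1, 2}, {3, 4}) == 0.0
        assert tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5
        assert tanimoto(set(), set()) == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.frozensets(st.integers(0, 30), max_size=15),
        b=st.frozensets(st.integers(0, 30), max_size=15),
        c=st.frozensets(st.integers(0, 30), max_size=15),
    )
    def test_metric_properties(self, a, b, c):
        """Symmetry, [0,1] range, and triangle inequality of 1 - T."""
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        d = lambda x, y: 1.0 - tanimoto(x, y)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12
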