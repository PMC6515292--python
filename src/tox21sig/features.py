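"""Chemical descriptors and circular fingerprints.

Fingerprints are unordered sets of hashed substructure identifiers from
circular environments of radius 3 (diameter 6): ECFP-style atom typing
uses element/connectivity invariants, FCFP-style typing uses
pharmacophoric feature classes. Six interpretable descriptors accompany
them: a Crippen-type atomic-contribution logP (standing in for platform
ALogP), molecular weight, H-bond donor and acceptor counts, rotatable
bonds, and fractional polar surface area (TPSA over Labute approximate
surface area).

Continuous descriptors feed the frequency-based Bayesian learner through
equal-frequency binning: bins are learned on training data only and each
value activates exactly one bin feature, with out-of-range values clamped
to the edge bins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .datamodel import ValidationError

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

DESCRIPTOR_NAMES = ("logp", "mol_weight", "hbd", "hba", "rotatable_bonds", "fpsa")

_ECFP6 = rdFingerprintGenerator.GetMorganGenerator(radius=3)
_FCFP6 = rdFingerprintGenerator.GetMorganGenerator(
    radius=3, atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
)


class FeaturizationError(ValueError):
    """Raised for an unparseable structure; carries the compound ID if known."""

    def __init__(self, message: str, cid: str | None = None):
        super().__init__(message)
        self.cid = cid


def _mol_from_smiles(smiles: str, cid: str | None = None, strip_salts: bool = True) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}", cid=cid)
    if strip_salts and "." in smiles:
        frags = Chem.GetMolFrags(mol, asMols=True)
        # keep the largest organic (carbon-containing if any) fragment
        organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
        pool = organic or list(frags)
        mol = max(pool, key=lambda f: f.GetNumHeavyAtoms())
    return mol


def featurize(smiles: str, kind: str = "ECFP6", cid: str | None = None) -> frozenset[int]:
    """Circular fingerprint of a molecule as a set of hashed feature IDs.

    ``kind`` selects ECFP6 (element/connectivity atom typing) or FCFP6
    (pharmacophoric function-class typing). Feature IDs are the raw
    (unfolded) hashes, stable across runs.
    """
    gen = {"ECFP6": _ECFP6, "FCFP6": _FCFP6}.get(kind)
    if gen is None:
        raise ValidationError(f"unknown fingerprint kind: {kind}")
    mol = _mol_from_smiles(smiles, cid=cid)
    fp = gen.GetSparseCountFingerprint(mol)
    return frozenset(fp.GetNonzeroElements())


def descriptors(smiles: str, cid: str | None = None) -> dict[str, float]:
    """The six modeling descriptors for one molecule."""
    mol = _mol_from_smiles(smiles, cid=cid)
    asa = rdMolDescriptors.CalcLabuteASA(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    return {
        "logp": Crippen.MolLogP(mol),
        "mol_weight": Descriptors.MolWt(mol),
        "hbd": float(rdMolDescriptors.CalcNumHBD(mol)),
        "hba": float(rdMolDescriptors.CalcNumHBA(mol)),
        "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "fpsa": tpsa / asa if asa > 0 else 0.0,
    }


def featurize_table(
    structures: pd.DataFrame, kind: str = "ECFP6", on_error: str = "raise"
) -> tuple[dict[str, frozenset[int]], pd.DataFrame]:
    """Fingerprints and descriptors for a ``cid, smiles`` table.

    ``on_error='drop'`` skips unparseable structures with a logged count;
    ``'raise'`` propagates the first failure.
    """
    fps: dict[str, frozenset[int]] = {}
    desc_rows = []
    dropped = 0
    for cid, smiles in zip(structures["cid"], structures["smiles"]):
        try:
            fps[cid] = featurize(smiles, kind=kind, cid=cid)
            row = descriptors(smiles, cid=cid)
        except FeaturizationError:
            if on_error == "raise":
                raise
            dropped += 1
            continue
        row["cid"] = cid
        desc_rows.append(row)
    if dropped:
        log.warning("featurization dropped %d structures", dropped)
    desc = pd.DataFrame(desc_rows, columns=["cid", *DESCRIPTOR_NAMES])
    return fps, desc.set_index("cid")


# -- descriptor binning ------------------------------------------------------


def learn_bins(values: np.ndarray | pd.Series, n_bins: int = 10) -> np.ndarray:
    """Learn equal-frequency cut points from training values.

    Returns the strictly increasing interior cut points (at most
    ``n_bins - 1``; fewer when the data has few distinct values, down to
    zero cut points for a constant descriptor).
    """
    vals = pd.Series(values).dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot learn bins from an empty training set")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    cuts = np.unique(np.quantile(vals, qs))
    # drop cuts outside the observed range (can happen with heavy ties)
    return cuts[(cuts > vals.min()) & (cuts < vals.max())]


def apply_bins(cuts: np.ndarray, values: np.ndarray | pd.Series) -> np.ndarray:
    """Map each value to its bin index; out-of-range values clamp to edges."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(values, dtype=float), side="right")


class BinningScheme:
    """Per-descriptor equal-frequency cut points learned from a training set."""

    def __init__(self, cuts: dict[str, np.ndarray]):
        self.cuts = cuts

    @classmethod
    def learn(cls, desc: pd.DataFrame, n_bins: int = 10) -> "BinningScheme":
        return cls({name: learn_bins(desc[name], n_bins) for name in desc.columns})

    def features(self, desc: pd.DataFrame) -> dict[str, frozenset[str]]:
        """One binary bin feature per descriptor per compound."""
        per_desc = {
            name: apply_bins(cuts, desc[name]) for name, cuts in self.cuts.items()
        }
        out = {}
        for i, cid in enumerate(desc.index):
            out[cid] = frozenset(f"{name}:bin{per_desc[name][i]}" for name in self.cuts)
        return out


def modeling_features(
    structures: pd.DataFrame,
    kind: str = "ECFP6",
    n_bins: int = 10,
    on_error: str = "raise",
) -> dict[str, frozenset]:
    """Combined NB feature sets: fingerprint hashes plus binned descriptors.

    Fingerprint features are tagged ``fp:<hash>`` and descriptor bins
    ``<name>:bin<k>`` so both live in a single feature space.
    """
    fps, desc = featurize_table(structures, kind=kind, on_error=on_error)
    scheme = BinningScheme.learn(desc, n_bins=n_bins)
    bin_feats = scheme.features(desc)
    return {
        cid: frozenset(f"fp:{f}" for f in fps[cid]) | bin_feats[cid]
        for cid in fps
    }


def read_sdf_structures(path, id_prop: str = "cid") -> pd.DataFrame:
    """Optional SDF input: one ``cid, smiles`` row per molecule.

    The compound ID comes from the ``id_prop`` property when present,
    else the molecule title, else a running index. Unreadable entries are
    skipped with a logged count.
    """
    rows = []
    skipped = 0
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            skipped += 1
            continue
        if mol.HasProp(id_prop):
            cid = mol.GetProp(id_prop)
        else:
            cid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"MOL{i}"
        rows.append({"cid": cid, "smiles": Chem.MolToSmiles(mol)})
    if skipped:
        log.warning("SDF reader skipped %d unreadable entries", skipped)
    return pd.DataFrame(rows, columns=["cid", "smiles"])


def tanimoto(a: frozenset | set, b: frozenset | set) -> float:
    """Tanimoto similarity |a n b| / |a u b|; 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)
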