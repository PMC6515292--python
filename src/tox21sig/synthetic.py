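"""Synthetic library, assay panel, and screening-result generator.

Emulates the statistical structure of an aggregated reporter-gene /
cytotoxicity-counter screening campaign: a batch library mapping
many-to-one onto unique compounds, purity grades with a majority of
failing batches, 34 reporter/counter assay pairs, three test panels
producing an incomplete overall matrix, inconclusive outcomes, sparse
AC50 reporting, and a planted structure-activity signal that circular
fingerprints can learn.

Chemistry comes from combinatorial SMILES templates (aromatic scaffolds x
alkyl chains x functional-group heads), never from random molecular
graphs, so every structure is valid and the planted signal is a concrete
substructure. Cross-panel cytotoxicity is driven by surfactant-like
features: a long aliphatic chain plus a cationic head.

Randomness is split into one stream per logical stage (library, panel,
screen), each seeded from ``(seed, stage name)``, so e.g. enlarging the
library does not reshuffle the panel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import ValidationError

# -- chemistry templates -----------------------------------------------------

#: scaffold name -> (unsubstituted SMILES, template with one branch site)
SCAFFOLDS: list[tuple[str, str, str]] = [
    ("benzene", "c1ccccc1", "c1ccc({r})cc1"),
    ("pyridine", "c1ccccn1", "c1ccc({r})cn1"),
    ("thiophene", "c1cccs1", "c1ccc({r})s1"),
    ("furan", "c1ccco1", "c1ccc({r})o1"),
    ("naphthalene", "c1ccc2ccccc2c1", "c1ccc2ccc({r})cc2c1"),
    ("cyclohexane", "C1CCCCC1", "C1CCC({r})CC1"),
]

#: head-group name -> branch-form SMILES fragment appended to the chain
HEADS: list[tuple[str, str]] = [
    ("none", ""),
    ("carboxylic_acid", "C(=O)O"),
    ("quaternary_ammonium", "[N+](C)(C)C"),
    ("primary_amine", "N"),
    ("hydroxyl", "O"),
    ("sulfonic_acid", "S(=O)(=O)O"),
    ("nitro", "[N+](=O)[O-]"),
    ("methoxy", "OC"),
]

#: heads that carry a (protonatable or fixed) cationic charge
CATIONIC_HEADS = frozenset({"quaternary_ammonium", "primary_amine"})

#: head groups that can serve as an assay's planted pharmacophore
PHARMACOPHORE_HEADS = [name for name, frag in HEADS if frag]

MAX_CHAIN = 12


def assemble_smiles(scaffold_idx: int, chain_len: int, head_idx: int) -> str:
    """Build a SMILES string from template indices.

    The substituent is an aliphatic chain of ``chain_len`` carbons
    terminated by the head group, attached at the scaffold's single
    substitution site. Zero-length chain with no head yields the bare
    scaffold.
    """
    _, bare, template = SCAFFOLDS[scaffold_idx]
    frag = "C" * chain_len + HEADS[head_idx][1]
    if not frag:
        return bare
    return template.format(r=frag)


def toxicity_latent(chain_len: int, head_name: str) -> float:
    """Surfactant-likeness in [0, 1]: long chain plus cationic head."""
    chain_part = min(chain_len, 10) / 10.0
    return 0.7 * chain_part + 0.3 * (head_name in CATIONIC_HEADS)


# -- configuration -----------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic screening campaign.

    Defaults emulate the aggregated Tox21-style campaign this pipeline is
    built for: 34 reporter/counter pairs, ~55% of batches failing purity,
    three test panels of 11/21/2 pairs covering fractions of the compound
    set, ~10% inconclusive calls, AC50 reported for about a third of
    records, and active pAC50 ~ Normal(4.60, 0.55) so that mean + 1 SD of
    the actives sits near 5.15.
    """

    n_pairs: int = 34
    n_sids: int = 2000
    sid_per_cid_mean: float = 1.5
    purity_fail_rate: float = 0.55
    #: fraction of CIDs assigned to the full / partial / tiny test panels;
    #: the leftover fraction joins the full panel
    panel_fractions: tuple[float, float, float] = (0.36, 0.23, 0.004)
    #: number of assay pairs each panel tests (scaled to n_pairs if smaller)
    panel_pair_counts: tuple[int, int, int] = (11, 21, 2)
    inconclusive_rate: float = 0.1
    ac50_report_rate: float = 0.33
    pac50_mean: float = 4.60
    pac50_sd: float = 0.55
    pac50_bounds: tuple[float, float] = (3.0, 8.0)
    base_active_rate: float = 0.03
    #: log-odds added to a reporter assay's activity when the compound
    #: carries that assay's pharmacophore head group
    planted_effect: float = 5.0
    #: log-odds scale of the surfactant-driven signal in counter assays;
    #: multiplied by the compound's toxicity latent in [0, 1]
    toxicity_gain: float = 6.0
    unmapped_rate: float = 0.01
    luciferase_fraction: float = 12 / 34
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "purity_fail_rate": self.purity_fail_rate,
            "inconclusive_rate": self.inconclusive_rate,
            "ac50_report_rate": self.ac50_report_rate,
            "base_active_rate": self.base_active_rate,
            "unmapped_rate": self.unmapped_rate,
            "luciferase_fraction": self.luciferase_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {p}")
        for p in self.panel_fractions:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"panel fractions must be probabilities, got {p}")
        if sum(self.panel_fractions) > 1.0 + 1e-12:
            raise ValidationError("panel_fractions must sum to at most 1")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.sid_per_cid_mean < 1.0:
            raise ValidationError("sid_per_cid_mean must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth behind a simulated screen, for recovery tests.

    ``assay_tokens``: per assay, the pharmacophore head group (reporter
    assays) or the surfactant latent coefficient (counter assays).
    ``compound_latents``: per CID, structural indices and toxicity latent.
    ``record_truth``: per generated record, the generating activity
    probability and the pre-noise label.
    """

    assay_tokens: pd.DataFrame = field(repr=False)
    compound_latents: pd.DataFrame = field(repr=False)
    record_truth: pd.DataFrame = field(repr=False)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One deterministic stream per logical stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


# -- generators --------------------------------------------------------------


def generate_library(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a substance library and its unique-compound structures.

    Returns ``(meta, compounds)``: ``meta`` is a substance-metadata table
    (sid, cid, smiles, purity grades); ``compounds`` has one row per CID
    with its SMILES, template indices, and toxicity latent. A small
    fraction of SIDs (``unmapped_rate``) carries no CID; purity grades are
    drawn so that the expected batch-level fail fraction equals
    ``purity_fail_rate``.
    """
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, "library")

    n_cids = max(1, int(round(config.n_sids / config.sid_per_cid_mean)))

    scaffold = rng.integers(0, len(SCAFFOLDS), size=n_cids)
    head = rng.integers(0, len(HEADS), size=n_cids)
    # chain length: mostly short (truncated geometric), with a surfactant-like
    # long-chain subpopulation so cross-panel toxicity has carriers
    short = np.minimum(rng.geometric(0.35, size=n_cids) - 1, 7)
    long_tail = rng.integers(8, MAX_CHAIN + 1, size=n_cids)
    chain = np.where(rng.random(n_cids) < 0.15, long_tail, short)

    cids = np.array([f"CID{i:06d}" for i in range(n_cids)])
    smiles = [assemble_smiles(s, c, h) for s, c, h in zip(scaffold, chain, head)]
    head_names = [HEADS[h][0] for h in head]
    tox = [toxicity_latent(c, hn) for c, hn in zip(chain, head_names)]
    compounds = pd.DataFrame({
        "cid": cids,
        "smiles": smiles,
        "scaffold": [SCAFFOLDS[s][0] for s in scaffold],
        "chain_len": chain,
        "head": head_names,
        "tox_latent": tox,
    })

    # SID -> CID assignment: every CID gets one SID, the surplus is spread
    # uniformly, so the mean multiplicity equals sid_per_cid_mean
    n_extra = config.n_sids - n_cids
    owner = np.concatenate([np.arange(n_cids), rng.integers(0, n_cids, size=n_extra)])
    owner = owner[: config.n_sids]
    sids = np.array([f"SID{i:06d}" for i in range(config.n_sids)])
    sid_cid = cids[owner]
    sid_smiles = compounds["smiles"].to_numpy()[owner]

    unmapped = rng.random(config.n_sids) < config.unmapped_rate
    meta = pd.DataFrame({
        "sid": sids,
        "cid": pd.array(np.where(unmapped, None, sid_cid), dtype="string"),
        "smiles": pd.array(np.where(unmapped, None, sid_smiles), dtype="string"),
    })

    fail = rng.random(config.n_sids) < config.purity_fail_rate
    t0 = rng.choice(["A", "B", "C"], size=config.n_sids, p=[0.6, 0.25, 0.15])
    t4 = rng.choice(["A", "B", "C", "untested"], size=config.n_sids, p=[0.5, 0.2, 0.1, 0.2])
    # failing batches break the filter at T0 (70%) or at T4 (30%)
    fail_at_t0 = fail & (rng.random(config.n_sids) < 0.7)
    t0 = np.where(fail_at_t0, "other", t0)
    t4 = np.where(fail & ~fail_at_t0, "other", t4)
    meta["purity_t0"] = t0
    meta["purity_t4"] = t4
    return meta, compounds


def generate_assay_panel(
    config: SyntheticConfig, compounds: pd.DataFrame, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired assay annotations and a per-CID test-panel assignment.

    Each of the ``n_pairs`` pairs has one confirmatory (reporter) and one
    counter (viability) assay; roughly 12/34 of pairs use a luciferase
    reporter and the remainder beta-lactamase. Each CID joins exactly one
    panel group (full / partial / tiny) that determines which pairs test
    it; leftover probability mass joins the full group.
    """
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, "panel")

    n = config.n_pairs
    n_luc = int(round(config.luciferase_fraction * n))
    rows = []
    for i in range(n):
        pair = f"P{i:03d}"
        reporter_type = "luciferase" if i < n_luc else "beta_lactamase"
        token = PHARMACOPHORE_HEADS[i % len(PHARMACOPHORE_HEADS)]
        for stage, suffix in (("confirmatory", "R"), ("counter", "T")):
            rows.append({
                "assay_id": f"AID{i:03d}{suffix}",
                "tox21_id": f"tox21-synth-{i:03d}",
                "title": f"synthetic {reporter_type} {'reporter' if stage == 'confirmatory' else 'viability counter'} assay {i}",
                "stage": stage,
                "reporter_type": reporter_type,
                "cell_line_id": f"CLO:{9000000 + i}",
                "organism_taxon": "9606",
                "target_gene_id": f"GENE{i:03d}",
                "target_relationship": "agonist" if i % 2 == 0 else "antagonist",
                "pathway_go_id": f"GO:{7000000 + i}",
                "pair_id": pair,
            })
    annotations = pd.DataFrame(rows)

    # contiguous pair blocks per panel group, scaled down if n_pairs < 34
    counts = list(config.panel_pair_counts)
    total = sum(counts)
    if total > n:
        scaled = [max(0, int(round(c * n / total))) for c in counts]
        scaled[0] = max(1, scaled[0])
        counts = scaled
    bounds = np.cumsum([0] + counts)
    group_pairs = []
    for g in range(3):
        lo, hi = int(bounds[g]), int(min(bounds[g + 1], n))
        pairs = [f"P{i:03d}" for i in range(lo, hi)]
        group_pairs.append(pairs if pairs else [f"P{i:03d}" for i in range(min(counts[0], n))])

    f_full, f_partial, f_tiny = config.panel_fractions
    u = rng.random(len(compounds))
    group = np.full(len(compounds), 0)
    group[u < f_tiny] = 2
    group[(u >= f_tiny) & (u < f_tiny + f_partial)] = 1
    # everything else (including the leftover 1 - sum fraction) -> full panel
    panel = pd.DataFrame({
        "cid": compounds["cid"].to_numpy(),
        "panel_group": group,
        "panel_label": np.array(["full", "partial", "tiny"])[group],
    })
    panel.attrs["group_pairs"] = {g: group_pairs[g] for g in range(3)}
    return annotations, panel


def simulate_screen(
    meta: pd.DataFrame,
    compounds: pd.DataFrame,
    annotations: pd.DataFrame,
    panel: pd.DataFrame,
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate outcomes for every tested SID x assay.

    Activity probability is ``logistic(base + planted_effect * [pharmacophore
    match])`` in reporter assays and ``logistic(base + toxicity_gain *
    toxicity_latent)`` in counter assays. A fraction of outcomes is
    overridden to inconclusive; scores are drawn uniformly inside each
    outcome's legal range; AC50 values are attached with probability
    ``ac50_report_rate`` with pAC50 drawn from a truncated normal
    independent of the outcome (the campaign this emulates showed no
    outcome/pAC50 correlation).
    """
    config.validate()
    rng = _stage_rng(config.seed if seed is None else seed, "screen")
    group_pairs: dict[int, list[str]] = panel.attrs["group_pairs"]

    base_logit = _logit(config.base_active_rate)
    ann = annotations.set_index("assay_id")
    pair_token = {
        f"P{i:03d}": PHARMACOPHORE_HEADS[i % len(PHARMACOPHORE_HEADS)]
        for i in range(config.n_pairs)
    }
    assay_rows = []
    for aid, arow in ann.iterrows():
        assay_rows.append({
            "assay_id": aid,
            "pair_id": arow["pair_id"],
            "stage": arow["stage"],
            "pharmacophore": pair_token[arow["pair_id"]] if arow["stage"] == "confirmatory" else "",
            "toxicity_gain": config.toxicity_gain if arow["stage"] == "counter" else 0.0,
        })
    assay_tokens = pd.DataFrame(assay_rows)

    comp = compounds.set_index("cid")
    # substance table: mapped SIDs inherit their compound's structure;
    # unmapped SIDs are screened too (dropped later by the CID filter)
    sid_df = meta[["sid", "cid"]].copy()
    sid_df["head"] = sid_df["cid"].map(comp["head"]).fillna("none")
    sid_df["tox_latent"] = sid_df["cid"].map(comp["tox_latent"]).fillna(0.0)
    cid_group = panel.set_index("cid")["panel_group"]
    sid_group = sid_df["cid"].map(cid_group)
    # unmapped SIDs get a panel group from the same distribution
    unmapped_mask = sid_group.isna()
    if unmapped_mask.any():
        sid_group = sid_group.copy()
        sid_group[unmapped_mask] = rng.choice(
            panel["panel_group"].to_numpy(), size=int(unmapped_mask.sum())
        )
    sid_df["panel_group"] = sid_group.astype(int)

    blocks = []
    for g, pairs in group_pairs.items():
        sub = sid_df[sid_df["panel_group"] == g]
        if not len(sub) or not pairs:
            continue
        aids = assay_tokens[assay_tokens["pair_id"].isin(pairs)]
        block = sub.merge(aids, how="cross")
        blocks.append(block)
    records = pd.concat(blocks, ignore_index=True)

    match = (records["pharmacophore"] == records["head"]) & (records["stage"] == "confirmatory")
    logit = base_logit + config.planted_effect * match.to_numpy(dtype=float)
    logit = logit + records["toxicity_gain"].to_numpy() * records["tox_latent"].to_numpy()
    p_active = 1.0 / (1.0 + np.exp(-logit))

    n = len(records)
    true_active = rng.random(n) < p_active
    inconclusive = rng.random(n) < config.inconclusive_rate
    outcome = np.where(inconclusive, "inconclusive", np.where(true_active, "active", "inactive"))
    score = np.zeros(n, dtype=int)
    score[outcome == "inconclusive"] = rng.integers(1, 40, size=int((outcome == "inconclusive").sum()))
    score[outcome == "active"] = rng.integers(40, 101, size=int((outcome == "active").sum()))

    has_ac50 = rng.random(n) < config.ac50_report_rate
    pac50 = np.full(n, np.nan)
    pac50[has_ac50] = _truncated_normal(
        rng, config.pac50_mean, config.pac50_sd, config.pac50_bounds, int(has_ac50.sum())
    )
    ac50 = np.where(np.isnan(pac50), np.nan, np.power(10.0, -pac50))

    out = pd.DataFrame({
        "sid": records["sid"],
        "assay_id": records["assay_id"],
        "outcome": outcome,
        "score": score,
        "ac50": ac50,
        "pac50": pac50,
    })
    truth = PlantedTruth(
        assay_tokens=assay_tokens,
        compound_latents=compounds.copy(),
        record_truth=pd.DataFrame({
            "sid": records["sid"],
            "assay_id": records["assay_id"],
            "p_active": p_active,
            "true_active": true_active,
        }),
    )
    return out, truth


def generate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> dict[str, pd.DataFrame | PlantedTruth]:
    """Run all three generator stages; convenience wrapper for the pipeline."""
    seed = config.seed if seed is None else seed
    meta, compounds = generate_library(config, seed)
    annotations, panel = generate_assay_panel(config, compounds, seed)
    records, truth = simulate_screen(meta, compounds, annotations, panel, config, seed)
    return {
        "meta": meta,
        "compounds": compounds,
        "annotations": annotations,
        "panel": panel,
        "records": records,
        "truth": truth,
    }


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValidationError(f"rate must be strictly inside (0, 1), got {p}")
    return float(np.log(p / (1.0 - p)))


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    """Rejection-sampled normal restricted to ``bounds``."""
    lo, hi = bounds
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw > lo) & (draw < hi)]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out
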