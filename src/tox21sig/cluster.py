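"""Chemotype clustering by Tanimoto distance on circular fingerprints.

Cluster count follows the average-size rule k = max(1, round(N / 20)).
Centers are seeded by maximal dissimilarity (the compound with the
largest mean distance to all others), grown by MaxMin (each new center
maximizes its minimum distance to the existing centers), and refined by
medoid relocation: each cluster's representative becomes the member with
the highest mean within-cluster similarity, compounds reassign to the
nearest medoid, and the two steps alternate until assignments are stable.
All ties resolve by sorted-CID order so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ValidationError

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Cluster labels (CID -> cluster id), medoid CIDs, and bookkeeping."""

    labels: pd.Series = field(repr=False)
    medoids: list[str]
    n_clusters: int
    target_avg_size: int
    n_iterations: int
    #: value of sum(1 - similarity to own medoid) after each relocation pass
    objective_trace: list[float] = field(default_factory=list, repr=False)


def pairwise_tanimoto(fingerprints: list[frozenset]) -> np.ndarray:
    """Dense pairwise Tanimoto similarity matrix over fingerprint sets.

    Two empty sets are identical (similarity 1); an empty set shares
    nothing with a non-empty one (similarity 0).
    """
    n = len(fingerprints)
    index: dict = {}
    rows, cols = [], []
    for i, fp in enumerate(fingerprints):
        for f in fp:
            rows.append(i)
            cols.append(index.setdefault(f, len(index)))
    from scipy import sparse

    x = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, max(len(index), 1))
    )
    inter = np.asarray((x @ x.T).todense(), dtype=float)
    sizes = np.array([len(fp) for fp in fingerprints], dtype=float)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def n_clusters_for(n_compounds: int, target_avg_size: int) -> int:
    """Average-size rule with round-half-up, at least one cluster."""
    return max(1, int(np.floor(n_compounds / target_avg_size + 0.5)))


def maxmin_centers(dist: np.ndarray, k: int) -> list[int]:
    """Maximal-dissimilarity seeding: first center has the largest mean
    distance to all others; each next center maximizes its minimum
    distance to the chosen set. Ties take the lowest index."""
    n = dist.shape[0]
    if n == 0:
        raise ValidationError("no compounds to cluster")
    mean_d = dist.sum(axis=1) / max(n - 1, 1)
    centers = [int(np.argmax(mean_d))]
    min_d = dist[centers[0]].copy()
    while len(centers) < min(k, n):
        min_d[centers] = -np.inf
        nxt = int(np.argmax(min_d))
        centers.append(nxt)
        min_d = np.minimum(min_d, dist[nxt])
    return centers


def cluster_compounds(
    fingerprints: dict[str, frozenset],
    target_avg_size: int = 20,
    max_relocation_iters: int = 10,
) -> ClusterAssignment:
    """Cluster compounds into chemotypes of ~``target_avg_size`` members.

    ``fingerprints`` maps CID to a fingerprint feature set (FCFP6-style
    pharmacophoric fingerprints are the conventional choice). Raises if
    every fingerprint is empty.
    """
    cids = sorted(fingerprints)
    if not cids:
        raise ValidationError("no compounds to cluster")
    fps = [fingerprints[c] for c in cids]
    if all(len(fp) == 0 for fp in fps):
        raise ValidationError("all fingerprints are empty")
    n = len(cids)
    sim = pairwise_tanimoto(fps)
    dist = 1.0 - sim
    k = n_clusters_for(n, target_avg_size)

    centers = maxmin_centers(dist, k)
    assign = np.argmax(sim[:, centers], axis=1)  # ties -> lowest center index

    trace: list[float] = []
    iters = 0
    for iters in range(1, max_relocation_iters + 1):
        new_centers = []
        for c in range(len(centers)):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue  # degenerate (duplicate medoids); drop the cluster
            within = sim[np.ix_(members, members)].mean(axis=1)
            new_centers.append(int(members[np.argmax(within)]))
        centers = new_centers
        new_assign = np.argmax(sim[:, centers], axis=1)
        trace.append(float((1.0 - sim[np.arange(n), np.asarray(centers)[new_assign]]).sum()))
        if np.array_equal(new_assign, assign) and len(centers) == len(set(centers)):
            assign = new_assign
            break
        assign = new_assign

    labels = pd.Series(assign, index=pd.Index(cids, name="cid"), name="cluster")
    return ClusterAssignment(
        labels=labels,
        medoids=[cids[c] for c in centers],
        n_clusters=len(centers),
        target_avg_size=target_avg_size,
        n_iterations=iters,
        objective_trace=trace,
    )


def cluster_report(
    assignment: ClusterAssignment, fingerprints: dict[str, frozenset],
    smiles: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-cluster summary: size, medoid, mean intra-cluster similarity.

    A singleton cluster reports intra-similarity 1.0 by convention.
    """
    rows = []
    for cluster_id, medoid in enumerate(assignment.medoids):
        members = assignment.labels.index[assignment.labels == cluster_id]
        if len(members) <= 1:
            intra = 1.0
        else:
            fps = [fingerprints[c] for c in members]
            s = pairwise_tanimoto(fps)
            iu = np.triu_indices(len(members), k=1)
            intra = float(s[iu].mean())
        rows.append({
            "cluster": cluster_id,
            "size": int(len(members)),
            "medoid_cid": medoid,
            "medoid_smiles": (smiles.get(medoid) if smiles is not None else ""),
            "mean_intra_similarity": intra,
        })
    return pd.DataFrame(rows)
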