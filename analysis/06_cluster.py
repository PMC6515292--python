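"""Cluster compounds into chemotypes and profile cluster promiscuity.

Clusters the filtered compound set on FCFP6 Tanimoto similarity with
maximal-dissimilarity seeding and medoid relocation, targeting an
average cluster size of 20, then aggregates member promiscuity indices
into per-chemotype profiles. Prints cluster statistics and the most
cytotoxic chemotypes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

import pandas as pd

from tox21sig.cluster import cluster_compounds, cluster_report
from tox21sig.features import featurize_table
from tox21sig.io import read_activities
from tox21sig.promiscuity import cluster_promiscuity


def main() -> None:
    activities = read_activities(RESULTS / "clean" / "activities.tsv")
    compounds = pd.read_csv(RESULTS / "raw" / "compounds.tsv", sep="\t", dtype={"cid": str})
    kept = compounds[compounds["cid"].isin(set(activities["cid"]))]

    fps, _ = featurize_table(kept[["cid", "smiles"]], kind="FCFP6")
    assignment = cluster_compounds(fps, target_avg_size=20)
    report = cluster_report(assignment, fps, kept.set_index("cid")["smiles"])

    profiles = pd.read_csv(RESULTS / "promiscuity.tsv", sep="\t", index_col="entity_id")
    profiles.index = profiles.index.astype(str)
    cprom = cluster_promiscuity(assignment.labels, profiles)

    out = RESULTS / "clusters"
    out.mkdir(parents=True, exist_ok=True)
    members = assignment.labels.reset_index()
    members["is_medoid"] = members["cid"].isin(assignment.medoids)
    members.to_csv(out / "assignment.tsv", sep="\t", index=False)
    report.to_csv(out / "summary.tsv", sep="\t", index=False)
    cprom.to_csv(out / "promiscuity.tsv", sep="\t")

    print(f"{assignment.n_clusters} clusters over {len(assignment.labels)} compounds "
          f"(average size {len(assignment.labels) / assignment.n_clusters:.1f}, "
          f"{assignment.n_iterations} relocation passes)")
    print(f"mean intra-cluster Tanimoto similarity: {report['mean_intra_similarity'].mean():.3f}")
    top = cprom.sort_values("pi_toxicity_active", ascending=False).head(3)
    print("most cytotoxic chemotypes (by toxicity-active PI):")
    print(top[["n_members", "pi_toxicity_active", "z_toxicity_active", "quadrant"]]
          .round(3).to_string())


if __name__ == "__main__":
    main()
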