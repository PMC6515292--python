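"""Benchmark the signatures against chemical structure.

Trains a Laplacian-corrected Naive Bayes classifier per signature column
on ECFP6 fingerprints plus six binned physicochemical descriptors, scores
every compound by leave-one-out cross validation, and reports ROC,
enrichment at 1/5/10%, and the 10-repetition randomized-label control.
A high ROC says the signature is predictable from structure — evidence
the underlying curation preserved real structure-activity signal; the
randomized control should sit at 0.5.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

import pandas as pd

from tox21sig.bayes import benchmark_all
from tox21sig.cleaning import DenseSet
from tox21sig.features import modeling_features
from tox21sig.io import read_activities, read_assay_annotations
from tox21sig.signatures import build_signatures


def main() -> None:
    activities = read_activities(RESULTS / "clean" / "activities.tsv")
    annotations = read_assay_annotations(RESULTS / "raw" / "assays.tsv")
    members = json.loads((RESULTS / "clean" / "dense_set_members.json").read_text())
    sets = [DenseSet(label, v["cids"], v["assays"]) for label, v in members.items()]
    compounds = pd.read_csv(RESULTS / "raw" / "compounds.tsv", sep="\t", dtype={"cid": str})

    matrices = build_signatures(activities, annotations, sets)
    feats = modeling_features(compounds[["cid", "smiles"]], kind="ECFP6")
    bench = benchmark_all(matrices, feats, randomized_reps=10, seed=SEED)
    bench.to_csv(RESULTS / "benchmark.tsv", sep="\t", index=False)

    scored = bench[bench["roc"].notna()]
    print(f"benchmarked {len(scored)} columns ({len(bench) - len(scored)} skipped, "
          f"too few actives)")
    print(scored.groupby("category")[["roc", "ef1", "ef5", "ef10", "roc_randomized"]]
          .mean().round(3).to_string())
    print(f"{(scored['roc'] > 0.8).sum()} columns with ROC > 0.8, "
          f"{((scored['roc'] > 0.75) & (scored['roc'] <= 0.8)).sum()} more with ROC > 0.75")


if __name__ == "__main__":
    main()
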