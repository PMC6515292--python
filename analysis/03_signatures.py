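"""Build the three binary signature categories per dense set.

For every dense set, writes one 0/1 matrix per category — reporter
active, toxicity active, reporter selective — and prints per-category
counts of compounds positive in one or more columns.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from tox21sig.cleaning import DenseSet
from tox21sig.io import (
    read_activities,
    read_assay_annotations,
    write_signature_matrix,
)
from tox21sig.signatures import build_signatures, summarize_categories


def main() -> None:
    activities = read_activities(RESULTS / "clean" / "activities.tsv")
    annotations = read_assay_annotations(RESULTS / "raw" / "assays.tsv")
    members = json.loads((RESULTS / "clean" / "dense_set_members.json").read_text())
    sets = [DenseSet(label, v["cids"], v["assays"]) for label, v in members.items()]

    matrices = build_signatures(activities, annotations, sets)
    out = RESULTS / "signatures"
    out.mkdir(parents=True, exist_ok=True)
    for set_label, cats in matrices.items():
        for category, mat in cats.items():
            write_signature_matrix(mat, out / f"{set_label}_{category}.tsv")
    per_col, global_counts = summarize_categories(matrices)
    per_col.to_csv(out / "summary_columns.tsv", sep="\t", index=False)
    global_counts.to_csv(out / "summary_global.tsv", sep="\t", index=False)

    print(f"wrote {sum(len(c) for c in matrices.values())} signature matrices to {out}")
    print("compounds active in >= 1 column, per category:")
    print(global_counts.to_string(index=False))


if __name__ == "__main__":
    main()
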