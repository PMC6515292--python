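"""Profile compound promiscuity across the signature categories.

Computes promiscuity indices (active fraction of tested assays) for the
total, reporter-active, toxicity-active, and reporter-selective
categories, standardizes them to z-scores, assigns the four promiscuity
class labels (z >= +1), and places every compound into a
promiscuous/selective x cytotoxic/inert quadrant (PI thresholds
0.45 / 0.30). Prints the class and quadrant census.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from tox21sig.io import read_activities, read_assay_annotations
from tox21sig.promiscuity import profile_table


def main() -> None:
    activities = read_activities(RESULTS / "clean" / "activities.tsv")
    annotations = read_assay_annotations(RESULTS / "raw" / "assays.tsv")
    profiles = profile_table(activities, annotations)
    profiles.to_csv(RESULTS / "promiscuity.tsv", sep="\t")

    print(f"profiled {len(profiles)} compounds")
    for label in ("generally_promiscuous", "potentially_cytotoxic",
                  "reporter_promiscuous", "privileged_selective"):
        n = profiles["labels"].str.contains(label).sum()
        print(f"- {label}: {n}")
    print("quadrants:")
    print(profiles["quadrant"].value_counts().to_string())
    print(f"high selective/toxicity PI ratio (>=5): {profiles['selective_flag'].sum()}")


if __name__ == "__main__":
    main()
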