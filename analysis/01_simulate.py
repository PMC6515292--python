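"""Generate the synthetic screening campaign and write its raw tables.

Produces the three input tables the curation pipeline expects — substance
records, substance metadata with purity grades, and paired assay
annotations — plus the planted ground truth kept aside for recovery
checks. Prints the library and panel composition.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CAMPAIGN, RESULTS, SEED

from tox21sig.io import (
    write_assay_annotations,
    write_screen_table,
    write_substance_meta,
)
from tox21sig.synthetic import generate_dataset


def main() -> None:
    data = generate_dataset(CAMPAIGN, seed=SEED)
    out = RESULTS / "raw"
    out.mkdir(parents=True, exist_ok=True)
    write_screen_table(data["records"], out / "records.tsv")
    write_substance_meta(data["meta"], out / "substances.tsv")
    write_assay_annotations(data["annotations"], out / "assays.tsv")
    data["compounds"].to_csv(out / "compounds.tsv", sep="\t", index=False)
    data["truth"].assay_tokens.to_csv(out / "truth_assays.tsv", sep="\t", index=False)

    meta, records = data["meta"], data["records"]
    print(f"library: {len(meta)} SIDs over {meta['cid'].nunique()} unique CIDs "
          f"({meta['cid'].isna().sum()} SIDs without a CID)")
    print(f"panel: {data['annotations']['pair_id'].nunique()} reporter/counter pairs, "
          f"{len(data['annotations'])} assays")
    print(f"screen: {len(records)} records; "
          f"{(records['outcome'] == 'active').mean():.3f} active fraction; "
          f"{records['pac50'].notna().mean():.3f} of records carry an AC50")
    print(f"wrote raw tables to {out}")


if __name__ == "__main__":
    main()
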