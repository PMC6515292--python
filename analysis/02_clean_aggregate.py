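"""Clean the raw screen, aggregate by compound, and partition dense sets.

Applies the purity filter (T0 in A/B/C and T4 in A/B/C/untested), drops
records without a CID, aggregates substance records to unique compounds
by majority outcome, derives the low-concentration pAC50 cutoff
(mean + 1 SD of active data points), and partitions compounds into dense
matrix sets. Prints the attrition accounting and the data-matrix
statistics table.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from tox21sig.cleaning import (
    aggregate_by_cid,
    annotate_concentration,
    clean_records,
    compute_pac50_cutoff,
    dense_set_table,
    partition_dense_sets,
)
from tox21sig.io import read_records, read_substance_meta, write_activities


def main() -> None:
    raw = RESULTS / "raw"
    records = read_records(raw / "records.tsv")
    meta = read_substance_meta(raw / "substances.tsv")

    clean, report = clean_records(records, meta)
    cutoff = compute_pac50_cutoff(clean)
    activities = annotate_concentration(aggregate_by_cid(clean, meta), cutoff)
    sets = partition_dense_sets(activities)

    out = RESULTS / "clean"
    out.mkdir(parents=True, exist_ok=True)
    write_activities(activities, out / "activities.tsv")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    (out / "cutoff.json").write_text(json.dumps(cutoff.to_dict(), indent=2) + "\n")
    (out / "dense_set_members.json").write_text(json.dumps(
        {s.set_label: {"cids": s.cids, "assays": s.assays} for s in sets}) + "\n")
    table = dense_set_table(sets)
    table.to_csv(out / "dense_sets.tsv", sep="\t", index=False)

    r = report.to_dict()
    print(f"purity filter removed {r['n_removed_purity']} of {r['n_input_sids']} batches "
          f"({r['n_removed_purity'] / r['n_input_sids']:.1%}); "
          f"{r['n_removed_unmapped']} more lacked a CID; {r['n_kept']} kept")
    print(f"pAC50 cutoff = {cutoff.cutoff:.3f} "
          f"(mean {cutoff.mean:.3f} + SD {cutoff.sd:.3f}, {cutoff.n_actives_used} actives)")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
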