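"""Shared settings for the numbered analysis scripts.

The synthetic campaign defined here is the study condition every script
consumes: 34 reporter/counter pairs, 2,000 substance batches over ~1,333
unique compounds, ~55% purity failures, three test panels producing an
incomplete overall matrix, 10% inconclusive calls, AC50 reported on about
a third of records, active pAC50 placed so mean + 1 SD sits near 5.15,
and a planted pharmacophore signal with surfactant-driven cytotoxicity.
"""

from pathlib import Path

from tox21sig.synthetic import SyntheticConfig

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"

SEED = 1604

CAMPAIGN = SyntheticConfig(seed=SEED)
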