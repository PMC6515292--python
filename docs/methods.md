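# Methods

## Scope and data model

The package reconstructs a curation-and-benchmarking workflow for paired
reporter-gene / cytotoxicity-counter qHTS campaigns. Its inputs are three
delimited tables: substance records (one row per batch x assay with a
categorical PubChem-style activity outcome, a 0–100 activity score, and
an optional AC50 in molar units), substance metadata (SID → CID map,
SMILES, purity grades at timepoints T0 and T4), and assay annotations
(controlled-vocabulary fields; each reporter assay linked to its
viability counter assay by a pair ID). Outcome/score consistency is
enforced exactly: inactive ⇔ score 0, inconclusive ⇔ 1–39, active ⇔
40–100. Validation failures are collected in bulk and either raised
(strict) or dropped with a logged count (lenient), since real exports
contain stragglers. CURIEs and ontology identifiers are carried as
opaque strings; no ontology files are parsed.

## Cleaning and aggregation

Filters apply in a fixed order so each batch is attributed to exactly
one removal reason: purity first (keep iff T0 ∈ {A,B,C} and T4 ∈
{A,B,C,untested}; a hypothetical T0 "untested" fails, since only T4
admits it), then CID mapping (batches without a standardized structure
are dropped). The attrition report reconciles by construction and is
checked at run time.

Aggregation to unique compounds uses a strict majority: the aggregate
outcome per (CID, assay) is the outcome held by strictly more than 50%
of that compound's SIDs, else inconclusive; inconclusive records count
toward the denominator. pAC50 = −log10(AC50 in molar); replicate values
are averaged within SID first, then across SIDs, so a heavily
replicated batch cannot dominate the compound mean.

The low/high-concentration cutoff is the sample mean plus one sample
(n−1) standard deviation of the pAC50 values of *active data points*,
computed at record level before CID aggregation (aggregating first would
shrink the spread of compound means and bias the cutoff low). Actives at
or above the cutoff are labelled low-concentration actives (ties
classify as low-concentration); actives without any reported pAC50 keep
`not_applicable` rather than an imputed class.

Dense sets partition compounds by the exact set of assays in which they
have any record; each resulting block is a complete compounds x assays
matrix, blocks are disjoint and exhaustive, and the pair-level data
count is half the assay-level count (every assay belongs to exactly one
reporter/counter pair).

## Signature categories

Per dense set: reporter-active and toxicity-active matrices are indexed
by assay (1 iff the aggregate outcome is active); the reporter-selective
matrix is indexed by pair ID, 1 iff the reporter outcome is active and
the counter outcome is *literally* inactive. An inconclusive counter
result does not qualify — the strictest reading of "inactive in the
counter assay" — but `counter_inactive_strict=False` relaxes this for
sensitivity analysis. Two invariants hold elementwise and are tested:
selective ≤ reporter-active of the pair, and selective = 1 ⇒
toxicity-active of the pair = 0.

## Chemical features

ECFP6/FCFP6-style fingerprints are Morgan fingerprints of radius 3
(diameter 6) with connectivity or pharmacophoric-feature atom
invariants, kept as unordered sets of raw hashed identifiers (no
folding), via RDKit. Descriptors are Crippen logP (an atomic-contribution
logP standing in for platform ALogP — a documented substitution, exact
parity with proprietary implementations is not claimed), molecular
weight, H-bond donors/acceptors, rotatable bonds, and fractional polar
surface area computed as TPSA / Labute ASA. Multi-fragment inputs keep
the largest carbon-containing fragment (configurable).

Continuous descriptors enter the Bayesian feature space through
equal-frequency binning: B = 10 bins by default, cut points learned from
the modeling set only, out-of-range values clamped to edge bins, ties
collapsing to fewer bins down to a single bin for a constant descriptor.
Fingerprint and descriptor-bin features share a single feature space
(tags `fp:` and `<descriptor>:bin<k>`), one learner over both.

## Laplacian-corrected Naive Bayes and validation

Feature weights use the relative-estimator form w_i = ln[(A_i+1) /
(T_i·p+1)] with p the prior active fraction; a feature unseen in
training has weight exactly 0, the weight of a feature with fixed
enrichment ratio r = P(active|i)/p tends to ln r as counts grow, and
natural log is immaterial to the ranking metrics. Training requires both
classes and fails loudly naming the category otherwise.

Leave-one-out scores are computed in closed form: removing compound c
changes only the prior (A−y_c)/(T−1) and the counts of c's own
features, so all held-out actives share one adjusted weight vector and
all held-out inactives another; two sparse matrix-vector products give
scores bit-identical to naive retraining (oracle-tested at n = 60). If
holding out a compound empties a class, the prior is clamped to
[1/(2(n−1)), 1 − 1/(2(n−1))] and the event logged. Descriptor bins are
learned once on the modeling set, not per LOO fold: equal-frequency cut
points are insensitive to any single compound and re-learning them n
times would dominate the runtime without changing ranks.

ROC AUC is the Mann–Whitney pair statistic with 0.5 credit for ties
(equal to trapezoidal integration of the empirical curve, cross-checked
against scikit-learn in tests). Enrichment at fraction f takes the top
ceil(f·n) by score with stable-sort tie-breaking. The randomized-label
control permutes labels uniformly with the active count preserved and
averages full LOO ROC over 10 repetitions; its expectation is 0.5, with
a small negative bias (≲ 0.02) from the usual LOO pessimism.

## Promiscuity

PI = n_active / n_tested within a category; inconclusive counts as
tested but not active. The selective category's denominator is the
number of pairs with both assays tested. z-scores standardize PIs with
the sample mean/SD over entities with a defined PI; zero SD yields zero
z-scores with a warning. The four class labels are independent z ≥ +1
tests reported in a fixed order; quadrant thresholds (reporter 0.45,
toxicity 0.30) and the selective/toxicity ratio threshold (5) compare
with ≥, closed on the promiscuous side, with the convention that a
positive selective PI over zero toxicity PI passes the ratio flag.
z-scores are reported globally across all compounds by default; note
that PIs of compounds tested in 4 vs 64 assays have different sampling
variance, so per-dense-set standardization is also possible through the
same functions grouped by set. No capping is applied to computed
z-scores.

Cluster promiscuity is the arithmetic mean of member PIs (members with
defined PI only), re-standardized across clusters.

## Chemotype clustering

k = max(1, round(N / 20)) clusters (round half up), from FCFP6 Tanimoto
similarity; Tanimoto of two empty sets is defined as 1. Seeding is
maximal-dissimilarity: the first center maximizes mean distance to all
others, each subsequent center maximizes its minimum distance to the
chosen set (MaxMin). Compounds join the most similar center, then medoid
relocation alternates medoid update (member with highest mean
within-cluster similarity) and reassignment until stable or 10 passes;
the objective Σ(1 − similarity to own medoid) is non-increasing and
recorded. All ties resolve by sorted-CID order so runs are reproducible.
A cluster can only empty in the degenerate case of duplicate medoids,
in which case it is dropped. The exact relocation variant of the
original screening platform is proprietary; this reconstruction is
validated by family recovery on synthetic two-template libraries, not
by parity with any particular historical clustering. Pairwise distances
are materialized densely (fine to ~20k compounds).

## Synthetic campaign: what it emulates, and what it does not

The generator produces the statistical structure the curation pipeline
assumes, with chemistry from combinatorial SMILES templates (six
scaffolds x aliphatic chains of 0–12 carbons x eight head groups), never
random graphs, so every structure parses and the planted signal is a
concrete substructure. Defaults (the study conditions):

| parameter | default | why |
|---|---|---|
| n_pairs | 34 | campaign-scale panel of reporter/counter pairs |
| n_sids / sid_per_cid_mean | 2000 / 1.5 | desk-scale library with realistic batch multiplicity |
| purity_fail_rate | 0.55 | a majority of batches fails QC, as in the emulated campaign |
| panel_fractions / pair counts | 0.36/0.23/0.004 over 11/21/2 pairs | three test panels yielding an incomplete overall matrix (leftover mass joins the full panel so every compound is tested somewhere) |
| inconclusive_rate | 0.10 | ambiguous curve fits |
| ac50_report_rate | 0.33 | AC50 reported for a minority of records; pAC50 drawn independently of outcome (the emulated data showed no outcome/pAC50 correlation) |
| pac50_mean / sd | 4.60 / 0.55 | places mean + 1 SD of actives at ≈ 5.15, truncated to (3, 8) |
| base_active_rate | 0.03 | typical confirmed qHTS hit rate |
| planted_effect | 5.0 log-odds | strong, near-deterministic structure–activity signal — the regime in which curated signatures are highly predictable from structure |
| toxicity_gain | 6.0 | cytotoxicity scales with a surfactant latent = 0.7·min(chain,10)/10 + 0.3·[cationic head] |

Each reporter pair is assigned one head-group pharmacophore; counter
assays respond to the surfactant latent only. Randomness is split into
per-stage streams seeded from (seed, stage name), so enlarging the
library does not reshuffle the panel, and identical (config, seed) is
byte-identical.

What passing tests on this generator demonstrate: the filters,
aggregation, cutoff derivation, signature logic, benchmark statistics,
and clustering recover planted structure exactly or within stated
stochastic tolerances. What they do not demonstrate: real assay biology.
In particular, the synthetic reporter-selective category inherits two
strongly structure-driven parent labels and therefore benchmarks
*better* than toxicity-active here, whereas in real campaigns the
selective category compounds two independent error sources and tends to
benchmark worst while cytotoxicity benchmarks best. Real chemistry,
3D structure, tautomers, and assay-technology artifacts (e.g. direct
luciferase inhibition) are all out of scope.

## Problem sizes

The default analysis (2,000 batches, 34 pairs, ~50k records) runs in
about a minute end to end; the test suite uses smaller campaigns
(150–2,000 batches) chosen so each statistical check retains its power —
e.g. cutoff recovery uses ≥ 5,000 active pAC50 values, and the planted-
signal benchmark uses ≥ 200 compounds per class on a 2,000-compound
single-pair screen.
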