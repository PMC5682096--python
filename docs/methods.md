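# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind `herbnet`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Screening model

A compound is *active* when it passes every evaluated criterion of the
ADME screen. All comparisons are inclusive: OB ≥ 15 %, DL ≥ 0.08,
Caco-2 ≥ −0.4 (log-scale), MW ≤ 500 Da, H-bond donors ≤ 5, acceptors
≤ 10, AlogP ≤ 5. Inclusive boundaries were chosen because the operative
criteria listing in the source literature of this workflow states them
with ≥/≤; threshold comparison is exact (no epsilon), which is stable
because curated ADME tables carry at most two decimals. Lipinski fields
missing from a record are marked *not evaluated* and pass vacuously, so
inventories that only annotate OB/Caco-2/DL screen exactly on those
three axes.

The assembly order is fixed: (1) threshold evaluation, (2) whitelist
union — compounds named on the whitelist are retained even when they
fail the numeric screen, and tagged `whitelist_rescued`; (3) cross-herb
duplicate merge keyed on the *normalized name* (case-folded, whitespace
and punctuation stripped), because shared phytochemicals appear once
per herb inventory under near-identical spellings while identifiers are
inventory-local; the surviving record is the first in input order and
carries the union of herb memberships; (4) compounds absent from the
compound→target index are dropped with reason `no_target`. Every input
record ends up in exactly one of: the active set or the exclusion log
(threshold_fail / duplicate_merged_into:<id> / no_target).

Drug-likeness itself is the continuous Tanimoto similarity
F(A,B) = A·B / (|A|² + |B|² − A·B) between a compound's descriptor
vector and a reference "average drug" vector. Curated DL values in
compound tables are consumed as given and never recomputed; the
function exists to score synthetic or unannotated compounds, for which
the descriptor space is any user-supplied numeric vector (the synthetic
generator's convention is a 5-vector of MW, AlogP, H-bond donors,
acceptors and rotatable bonds). The similarity is undefined for two
zero vectors (vanishing denominator) and raises accordingly.

### The bundled inventory and whitelist

The packaged example is the published ADME inventory of the CG–DG herb
pair: 65 compounds, 8 present in both herbs. Auditing the printed
OB/Caco-2/DL values against the default thresholds shows exactly 19 of
the 65 fail the numeric screen; the shipped whitelist lists those 19
names, so screening the per-herb expansion of the table (73 rows)
reproduces the published final set: 46 threshold passes + 19 rescues,
with the 8 cross-herb duplicates merged. The original study's wider
bookkeeping (it started from a 314-compound inventory whose full
property table was never published) cannot be audited from released
data; the packaged table is the released subset and is treated as
authoritative input.

## Target fishing

Interaction records carry two scores from upstream chemogenomic
predictors (an SVM and a random forest); a pair is retained iff
svm ≥ 0.8 **and** rf ≥ 0.7, both inclusive. Score ranges are not
assumed — the thresholds are the only semantics used. Duplicate
(compound, target) pairs are collapsed at load (first occurrence wins,
with a warning), so all edge counts are over unique pairs. Accessions
missing from the target mapping are diverted to an unmapped log rather
than dropped, keeping the stage total: mapped + unmapped = retained.
One-to-many accession→symbol mappings are rejected at load.

## Enrichment

Over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n), computed through scipy's log-space survival
function (stable to universes of at least 10⁵ genes). Terms with zero
overlap are not tested; the Benjamini–Hochberg family is the set of
tested terms of one annotation kind, and BH is applied separately for
GO-BP and pathway collections, mirroring how the two annotation
services are queried separately in practice. An optional EASE mode
(tail at k − 1, the conservative variant popularised by annotation
servers) is available behind a flag and off by default, because plain
p-values plus BH are the documented procedure.

The significance cut (default adjusted p < 0.01 for GO-BP, < 0.05 for
pathways) applies to adjusted p-values by default with a switch to raw,
since the literature of this workflow is ambiguous on which it
thresholds. The universe defaults to all genes in the loaded
collection; query genes outside it are logged and clipped. Top-N
extraction (default 30 GO terms, 40 pathways) ranks by gene count
descending, then adjusted p ascending, then term id, so ties never
depend on input order.

## Networks

Graphs are undirected and simple, with typed layers (herb, compound,
target, pathway); edges may only join adjacent layers (herb–compound,
compound–target, target–pathway), and self-loops, intra-layer and
skip-layer edges are rejected at insertion. Degree counts all incident
edges (herb edges included) for display, but the summary statistics use
compound–target edges only, matching how the workflow's headline counts
are computed: the edge count; the conventional *unique-target ratio*
(unique targets / unique compounds, 2 decimals) — note this is not the
mean compound degree (edges / compounds), which is reported alongside,
and the two differ by the factor of target sharing; and the percentage
of targets with degree ≥ 2 (1 decimal). Top-k nodes per layer use
degree descending then node id, deterministically. SIF exports orient
each edge upper-layer-first and sort lines; GraphML carries layer and
degree attributes. SIF cannot represent isolated nodes, so round trips
are exact on the connected subgraph.

## Organ mapping

The four-step procedure: fetch each query gene's expression profile;
compute its mean over all tissues; flag tissues strictly above that
mean; aggregate flags into named organ groups (membership = flagged in
≥ 1 group tissue). "Above average" is per-gene across tissues — not
per-tissue across genes — which makes the flags invariant to rescaling
a gene's row, so cross-gene normalization differences cannot change the
result. The strict inequality means a constant gene maps nowhere.

The default scheme has six groups over a 176-tissue atlas layout:
uterus (uterus, uterus corpus), placenta/fetus, hypothalamus/pituitary,
smooth muscle, pituitary, whole blood — pituitary deliberately appears
both alone and in the combined group, following the group listing this
workflow conventionally reports; the scheme is fully overridable via a
JSON file. Tissue-to-group assignment is by exact label match, not
substring, to avoid accidental captures ("smooth muscle" vs "uterus
smooth muscle"). Query genes absent from the matrix are listed as
excluded, never silently dropped.

## Synthetic data

Every pipeline input has a seeded generator returning planted ground
truth computed by direct comparison, independent of the code path under
test. All generators are pure functions of (parameters, seed); each
draws from an RNG stream derived from the master seed plus a fixed
per-generator tag, so adding a generator never perturbs existing
outputs.

Defaults emulate the study conditions of the bundled example where
stated, and otherwise a realistic mid-scale dataset, chosen once:

- **Compounds** — 2 herbs × 50 compounds, 10 % cross-herb duplicates;
  OB lognormal (log-mean 3.4, log-sd 0.9) clipped to the observed
  0.31–149.03 % range of the bundled inventory; DL ~ Beta(1.2, 6)
  (most herbal compounds are weakly drug-like); Caco-2 ~ Normal(1.0,
  0.9), allowing the negative tail of polar compounds.
- **Interactions** — 65 compounds × 100 targets at density 0.15, SVM
  and RF scores independent uniform on [0, 1], so the analytic retained
  fraction under the default thresholds is 0.2 × 0.3 = 0.06.
- **Annotations** — universe of 1,000 genes, 100 terms of size 10–80,
  a 50-gene query, and one planted term of size 50 whose genes are
  drawn with query members weighted by the odds parameter (odds 1 ⇒
  null; default odds 8 gives expected overlap ≈ 15 vs ≈ 2.5 under the
  null).
- **Expression** — 200 genes × 176 tissues, lognormal baseline
  (log-mean 4.6, log-sd 0.3); the first 20 genes are signal genes whose
  planted-group tissues are multiplied by the boost factor (default 5).

What the generators do *not* emulate: real chemistry (descriptor
correlations, the OB/DL dependence on structure), annotation-term
overlap structure (decoy terms are independent uniform draws), probe-set
collapsing or normalization artifacts of real atlases, and the degree
distribution of real compound–target networks. Passing the planted
tests therefore demonstrates that the arithmetic of each stage is
correct and recovers known signal under the stated noise model — not
that any biological conclusion transfers to real data.

The bundled 739-edge interaction stand-in (65 compounds × 185 targets)
is likewise synthetic: only its counts mirror the published network;
edge identities, node degrees and degree-dependent statistics computed
from it are placeholders.

## Pipeline and determinism

Stages run screen → fish → enrich → network → organ map; each stage's
input and output counts reconcile, and a failure halts the run with a
stage-labeled error and a FAILED marker, retaining partial outputs.
Writers use stable ordering and fixed float formats (ratios 2 dp,
percentages 1 dp, p-values 3 significant digits, scientific); the run
summary records counts, parameters and SHA-256 input checksums but no
timestamps, so identical config + inputs reproduce every output file
byte for byte. The provenance capture exists because the workflow this
package implements is notoriously snapshot-dependent (compound
databases, annotation services and expression atlases all drift), and a
run should be auditable against exactly the inputs it consumed.

## Problem sizes in the test suite

The property suites run at sizes chosen to make the checks exhaustive
or statistically decisive while keeping the default suite fast:
hypergeometric-tail equivalence against full subset enumeration for all
universes N ≤ 12; BH against a hand-written step-up on 100 random
vectors; screening monotonicity over a 5 × 5 × 5 threshold grid on a
1,000-compound synthetic database; degree identities and SIF/GraphML
round trips on 200 random bipartite graphs; planted-enrichment recovery
over 100 seeds and null calibration over 200; planted organ-group
recovery over 50 seeds; and byte-identical pipeline reruns.

## Known limitations

- OB, Caco-2 and DL are consumed, never predicted from structure; there
  is no SMILES/SDF handling.
- The interaction predictor is upstream: scores are inputs, and no
  SVM/RF model is trained here.
- Annotation terms are flat gene sets — no GO graph traversal or
  ancestor propagation.
- Statistics beyond degree (betweenness, closeness, layouts) are out of
  scope; exports target Cytoscape for visualization.
- Expression matrices are assumed post-normalization; no probe-level
  processing.
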