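# Methods

## The screening model

The pipeline formalizes a standard network-pharmacology quality-marker
screen as four composable stages.

**Ligand-based target transfer.** Compounds are represented by fixed-length
binary fingerprints. A query compound inherits the union of the annotated
target sets of every reference ligand whose Tanimoto similarity exceeds a
threshold *t*. Two conventions matter and are fixed here: the comparison is
*strict* (`similarity > t`, so a ligand exactly at the threshold contributes
nothing), and predictions from multiple passing ligands are merged by
*union*. The default `t = 0.80` is the conventional cutoff for "same
scaffold, transferable pharmacology". When target sets are supplied directly
(e.g. transcribed from a published interaction table), the prediction stage
is bypassed and the supplied sets are taken as already screened: published
target lists come from external prediction platforms whose ligand libraries
are version-dependent and not reproducible, while their output is printed in
full.

**Disease intersection.** Per-compound predicted targets are intersected
with a disease gene list. Components with a non-empty intersection are
"active"; the rest are excluded before network assembly. All gene symbols
pass through one normalization (trim, uppercase, split on ASCII and
fullwidth commas) so set operations compare like with like; symbols as
printed are treated as canonical — no alias resolution is attempted, since
the upstream databases' alias tables are themselves version-dependent.

**Heterogeneous network and degree screen.** The graph has five node types
and four edge rules: prescription–compound (every active component),
compound–gene (every common pair), disease–gene (every common gene),
pathway–gene (membership of the top-N pathway sets, restricted to common
genes). Self-edges and duplicate edges are structurally impossible. The
marker-screening degree of a component counts its compound–gene edges only,
i.e. equals the size of its common target set; the single prescription edge
is excluded. This is the only convention under which degrees recomputed
from published gene lists equal the published degree columns, and it makes
the screen independent of how many decorative nodes surround the compounds.
The threshold is either the full network's mean degree 2E/N
(`computed_mean`) or a fixed value; selection is strict `>`. Ordering
everywhere is primary key descending, ties alphabetical, for cross-platform
determinism.

**Over-representation.** One-sided hypergeometric upper tail
P(X ≥ k | N, K, n) — equivalently one-sided Fisher's exact — per gene set,
BH step-up FDR across all tested sets (those with overlap ≥ 1), raw p
reported alongside. The default universe is the union of all annotated
genes; an explicit universe can be supplied. Query genes outside the
universe are dropped from the test, as they carry no information under the
sampling model. Rows are ordered by overlap count descending, then p
ascending, then set id.

## Bundled reference tables

The package embeds three tables transcribed from the originating HXJTY/T2DM
study: the 22-component monitoring-ion table, the 21 active components with
their common target-gene sets and published degrees, and the top-20 pathway
table (ids, names, published p-values, per-pathway common-gene counts).

*Curation.* As printed, three gene lists (calycosin, astragaloside IV,
astragaloside I) carry more tokens than their published degree, and the
gene union is 128 against a published summary count of 125. The degree
column, the prose degree listing and the union count all agree with each
other, so the lists were reconciled to them: four tokens were removed
(KDM1A and ALOX5 from calycosin, SELL from astragaloside IV, CTSD from
astragaloside I), the unique removal pattern — three union-singletons plus
one duplicate — that satisfies the per-row degrees and the 125-gene union
simultaneously. Which singletons to remove is underdetermined; the choice
does not affect marker selection (all affected degrees remain well above
the threshold) or any reported count. The original mixed comma dialects are
preserved verbatim to keep the parser honest.

*Reference profile.* The disease list and pathway memberships behind the
reproduction run are synthetic stand-ins built to the published shape: the
disease list contains the 125 common genes padded with synthetic tokens to
the published size of 969; each of the 20 pathway sets samples its
published gene count from the 125 common genes (seeded, deterministic);
acteoside — the one component with no disease-common target — carries
synthetic off-disease predicted targets so the intersection stage excludes
it, as in the original screen. Consequently the reproduction asserts the
published *counts* (22 components, 21 active, 125 genes, 168 nodes, the 12
named markers), not the published edge total or p-values, which depend on
database versions and undocumented conventions. The published edge total
(1362) is additionally irreconcilable with the published mean degree of 12
(2 × 1362 / 168 ≈ 16.2), so the mean is reproduced via the fixed-threshold
mode, which is the default for the reference profile. Whether the original
network linked the disease node to genes, compounds or both is unstated;
the disease–gene rule used here is an explicit assumption. PPI
confidence filtering (the "highest confidence > 0.9" STRING setting) is
recorded as provenance metadata only — bundled and synthetic edge lists
carry no scores to filter on.

## Adduct arithmetic

Monitoring-ion m/z values are audited as `neutral monoisotopic mass +
delta`, with deltas +1.007276 ([M+H]+), −1.007276 ([M−H]−) and +44.998204
([M+HCOO]−) Da; deltas include the electron and are applied at machine
precision (rounding is display-only). The default tolerance is 0.2 Da:
SIM monitoring ions are typically configured as low-resolution nominal
targets (the bundled table's saponin formate adducts sit ~0.11 Da from
their exact masses), so exact-mass matching would misclassify correct
entries. Neutral masses are supplied externally; nothing is hardcoded.
Only ±1 charge states and these three adducts are modelled — no isotope
patterns, no calibration.

## Synthetic data generator

The generator emulates the *shape* of a quality-marker study, not its
chemistry. Defaults: 22 compounds of which 12 are planted markers
(mirroring the reference study's proportions), a 2000-gene universe with a
900-gene disease set, markers carrying 30 disease-overlapping targets
against 3 for non-markers (plus 5 off-disease decoy targets each, so the
intersection stage has work to do), 20 pathway sets of 20–60 genes with 2
planted enriched sets oversampling the common genes at 3× the baseline
expectation, and 1024-bit fingerprints at density 0.3. Reference ligands
are constructed so that screening at the default threshold reconstructs
each compound's intended target set exactly: each compound gets two
above-threshold ligands splitting its target set (exercising the union
rule) and bit-flip-noise decoys at or below the threshold (exercising the
strict comparison); cross-compound similarities are verified below
threshold at generation time. One integer seed drives the whole study
through fixed-offset substreams; identical seeds yield byte-identical
files. Gene identifiers are synthetic tokens (G000001…), so no real gene
identities are implied.

What passing on synthetic data shows: the pipeline's set arithmetic,
graph rules, threshold logic and test calibration are correct under the
generative model. What it does not show: robustness to alias ambiguity,
annotation incompleteness, correlated pathway membership, or fingerprint
similarity distributions of real chemotypes — none of which the generator
attempts to simulate.

## Numerical and testing choices

- Hypergeometric tails use survival-function evaluation (no explicit
  factorials), stable to universe sizes of at least 1e5; the k = 0 tail is
  returned as exactly 1. Correctness is checked against exhaustive draw
  enumeration for every parameter combination with N ≤ 12.
- BH adjustment is checked against hand-computed step-up examples and an
  order-invariance property.
- The null calibration test (fraction of p < 0.05 within 3 standard errors
  of 0.05 over 1000 uniform null queries) runs at a configuration with
  dense discrete support (universe 2000, set size 140, query 125). Exact
  tests are conservative wherever the discrete tail has no achievable value
  near the nominal level, so sparse configurations would measure the
  discreteness of the support, not the correctness of the test.
- Multi-seed sweeps (100 seeds for the planted-enrichment ranking property)
  run with 128-bit fingerprints and one decoy ligand per compound; the
  property under test is fingerprint-independent and the reduction keeps
  the sweep inside a few seconds.
- Degenerate inputs are defined, not accidental: empty disease set → all
  compounds excluded (with a warning); empty gene-list row → empty set
  (warning); pathway set emptied by restriction → dropped before network
  assembly; two all-zero fingerprints → error (similarity undefined);
  published degree column disagreeing with its gene list → warning, never
  an error, and the recomputed value wins.

## Known limitations

- No alias/ortholog resolution for gene symbols; inputs are trusted as
  canonical after normalization.
- The prediction stage models target transfer as a threshold rule on one
  similarity; real platforms blend multiple fingerprints and machine-learned
  scores.
- ORA treats gene sets as independent; no topology-aware enrichment, no GO
  term-ancestry handling (GO analysis is treated as plain gene-set ORA).
- PPI handling is summary-only (dedup, counts, top-frequency genes); no
  confidence-score filtering of score-free edge lists, no graph layout.
- Quantification (batch content heatmaps) is out of scope; the compound
  table is metadata, not raw spectra.
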