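# qmnet

Network-pharmacology quality-marker discovery for multi-herb formulations.

Traditional Chinese medicine decoctions contain dozens of quantifiable
constituents, but only some of them carry the therapeutic activity. A
*quality marker* (Q-marker) is a constituent worth monitoring in quality
control because it is both measurable (it appears in the HPLC-MS
monitoring-ion table of the final preparation) and mechanistically linked to
the treated disease. `qmnet` implements the network-pharmacology screen that
makes that link, end to end and fully offline:

1. **Target screening.** Each quantified compound inherits the annotated
   targets of reference ligands whose binary-fingerprint Tanimoto similarity
   `T(a, b) = |a ∧ b| / |a ∨ b|` strictly exceeds a threshold (default
   0.80). Predicted targets are intersected per compound with a disease gene
   list; compounds with at least one *common target gene* are the active
   components.
2. **Heterogeneous network.** A typed graph over prescription, active
   components, disease, common target genes and top-N enriched pathways,
   with prescription–compound, compound–gene, disease–gene and pathway–gene
   edges.
3. **Degree screen.** Each component's degree is recomputed from its common
   gene set (compound–gene edges only); components whose degree strictly
   exceeds a threshold — the network mean degree 2E/N, or a fixed value —
   are the quality markers.
4. **Over-representation analysis.** Hypergeometric upper tail
   `P(X ≥ k)` for overlap *k* between the *n* common genes and a *K*-gene
   set in an *N*-gene universe, with Benjamini–Hochberg FDR adjustment.

The package bundles the published tables of the HXJTY (Huo-Xue-Jiang-Tang
Yin) study of type 2 diabetes mellitus — the 22-component monitoring-ion
table, the 21 active components with their common target sets, and the
top-20 pathway table — so the whole reference analysis reproduces offline.
A synthetic-data generator with planted ground truth (marker compounds,
enriched pathways, exact Venn counts) makes every stage testable without
any download. An ESI adduct calculator ([M+H]+, [M−H]−, [M+HCOO]−) audits
monitoring-ion tables against neutral monoisotopic masses.

## Worked example

```python
from qmnet import run_reference_analysis

analysis = run_reference_analysis(seed=0)
s = analysis.summary()
print(f"{s['prescription']} vs {s['disease']}: "
      f"{s['n_active_compounds']}/{s['n_compounds']} active components, "
      f"{s['n_common_genes']} common target genes")
print(f"network: {s['n_network_nodes']} nodes / {s['n_network_edges']} edges; "
      f"threshold {s['degree_threshold']:g} ({s['threshold_mode']})")
for m in s["markers"]:
    print(f"  {m['degree']:>3}  {m['name']}  ({', '.join(m['herbs'])})")
```

prints

```
HXJTY vs T2DM: 21/22 active components, 125 common target genes
network: 168 nodes / 731 edges; threshold 12 (fixed)
   32  Isoastragaloside II  (AR)
   31  Astragaloside II  (AR)
   31  Astragaloside IV  (AR)
   31  Calycosin-7-O-β-D-glucoside  (AR)
   28  Isoastragaloside I  (AR)
   28  Ophiopojaponin C  (OR)
   27  Astragaloside I  (AR)
   27  Calycosin  (AR)
   27  Gallic acid  (RR, RRER)
   26  Astragaloside III  (AR)
   24  Hydroxysafflor yellow A  (CF)
   17  Rhmannioside D  (RR)
```

Of the 22 quantified components, all but acteoside share at least one
target with the disease; the union of their common sets holds 125 genes.
The degree screen at the fixed threshold of 12 selects 12 quality markers —
astragalosides and flavonoids from Astragali Radix (AR), gallic acid and
rhmannioside D from Rehmanniae Radix (RR), hydroxysafflor yellow A from
Carthami Flos (CF), and ophiopojaponin C from Ophiopogonis Radix (OR).
Rhein, at degree 11, falls just below the cutoff.

## Command line

One subcommand per stage, files in between:

```sh
qmnet simulate --seed 1 --out-dir study/           # synthetic study + truth.json
qmnet screen --fingerprints study/fingerprints.tsv --library study/ligand_library.tsv \
             --disease study/disease_genes.txt --out-dir screened/
qmnet network --common-targets screened/common_targets.tsv \
              --pathways study/pathways.gmt --out-dir net/
qmnet enrich --query genes.txt --gmt study/pathways.gmt --out enrichment.tsv
qmnet ms-check --compounds study/compounds.tsv --masses study/masses.tsv --out ms.tsv
qmnet run-all --out-dir results/                   # bundled reference profile
```

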