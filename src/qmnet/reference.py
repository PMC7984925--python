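"""Bundled reference study tables for the HXJTY quality-marker analysis.

Huo-Xue-Jiang-Tang Yin (HXJTY) is an eight-herb Chinese decoction prescribed
for type 2 diabetes mellitus (T2DM). The originating study quantified 22
components by HPLC-MS in SIM mode, predicted their targets, intersected them
with a T2DM gene list, and screened quality markers by network degree. Three
of its printed tables are bundled here so the whole analysis is executable
offline:

* ``COMPOUND_TABLE_TSV`` — the 22-component monitoring-ion table (retention
  time, adduct, monitored m/z, source herb, compound class).
* ``TARGET_TABLE_TSV`` — the 21 active components with their common
  (disease-intersected) target-gene sets and the published degree column.
  The original gene-list delimiters (ASCII and fullwidth commas) are kept
  verbatim to exercise the parser on real typography.
* ``PATHWAY_TABLE_TSV`` — the top-20 enriched KEGG pathways with the
  published p-values and per-pathway common-gene counts.

Curation note: as printed, three gene lists (calycosin, astragaloside IV,
astragaloside I) carried more tokens than their degree column, and the gene
union was 128 rather than the summary count of 125. The degree column, the
prose degree listing and the union count agree with each other, so four
spurious list tokens (KDM1A and ALOX5 under calycosin, SELL under
astragaloside IV, CTSD under astragaloside I) were removed to make the
table self-consistent with every published summary statistic. ALOX5 remains
in the union through rhein and emodin; marker selection is unaffected.
"""

from __future__ import annotations

import csv
import io as _io

from .model import CompoundRecord, CompoundTargetMap

PRESCRIPTION_NAME = "HXJTY"
DISEASE_NAME = "T2DM"

#: The published network-average degree used as the fixed marker threshold.
PUBLISHED_MEAN_DEGREE = 12

#: The 12 published quality markers (compound_id).
PUBLISHED_MARKERS = (
    "gallic_acid",
    "rhmannioside_d",
    "hydroxysafflor_yellow_a",
    "calycosin_7_o_b_d_glucoside",
    "calycosin",
    "astragaloside_iv",
    "astragaloside_iii",
    "ophiopojaponin_c",
    "astragaloside_ii",
    "isoastragaloside_ii",
    "astragaloside_i",
    "isoastragaloside_i",
)

COMPOUND_TABLE_TSV = """\
compound_id\tname\trt_min\tion_mode\tmz\therbs\tcompound_class
catalpol\tCatalpol\t5.06\t[M + HCOO]−\t407.10\tRR\tGlycosides
aucubin\tAucubin\t8.40\t[M + HCOO]−\t391.10\tRR\tGlycosides
gallic_acid\tGallic acid\t8.58\t[M − H]−\t169.10\tRR, RRER\tOrganic acid
rhmannioside_d\tRhmannioside D\t9.67\t[M + HCOO]−\t731.10\tRR\tGlycosides
leonuride\tLeonuride\t14.18\t[M + HCOO]−\t393.10\tRR\tGlycosides
hydroxysafflor_yellow_a\tHydroxysafflor yellow A\t18.12\t[M − H]−\t611.10\tCF\tFlavonoids
amygdalin\tAmygdalin\t18.78\t[M + HCOO]−\t502.10\tPS\tGlycosides
echinacoside\tEchinacoside\t19.87\t[M − H]−\t785.15\tRR\tGlycosides
calycosin_7_o_b_d_glucoside\tCalycosin-7-O-β-D-glucoside\t22.24\t[M + H]+\t447.05\tAR\tFlavonoids
acteoside\tActeoside\t22.53\t[M − H]−\t623.15\tRR\tGlycosides
ononin\tOnonin\t26.59\t[M + HCOO]−\t475.05\tAR\tGlycosides
calycosin\tCalycosin\t29.34\t[M + H]+\t285.10\tAR\tFlavonoids
astragaloside_iv\tAstragaloside IV\t31.77\t[M + HCOO]−\t829.35\tAR\tSaponins
astragaloside_iii\tAstragaloside III\t32.35\t[M + HCOO]−\t829.35\tAR\tSaponins
ophiopojaponin_c\tOphiopojaponin C\t33.19\t[M + HCOO]−\t931.35\tOR\tSaponins
astragaloside_ii\tAstragaloside II\t33.93\t[M + HCOO]−\t871.40\tAR\tSaponins
formononetin\tFormononetin\t34.99\t[M + H]+\t269.10\tAR\tFlavonoids
isoastragaloside_ii\tIsoastragaloside II\t35.25\t[M + HCOO]−\t871.40\tAR\tSaponins
rhein\tRhein\t37.61\t[M − H]−\t283.05\tRRER\tAnthraquinones
astragaloside_i\tAstragaloside I\t38.12\t[M + HCOO]−\t913.35\tAR\tSaponins
isoastragaloside_i\tIsoastragaloside I\t39.33\t[M + HCOO]−\t913.35\tAR\tSaponins
emodin\tEmodin\t43.27\t[M − H]−\t269.05\tRRER\tAnthraquinones
"""

TARGET_TABLE_TSV = """\
compound_id\tdegree\ttargets
catalpol\t1\tLGALS3
aucubin\t1\tLGALS3
gallic_acid\t27\tCA1, TTR, IGF1R, SERPINE1, COMT, ALB, KDR, CNR2, ESR1, PARP1, FASN, ELANE, ADRA2A, ADRA2C, ADRA2B、ADRB2、DRD3、PTPN1、PTGS2, EGFR, DPP4, CNR1, FTO, OPRM1, PTGS1, RXRG, RXRA
rhmannioside_d\t17\tCA1, FGF2, HRAS, FN1, F2, F7, SIRT1, AKR1B1, PTPN1, SLC5A2, ACE, SELP, MMP2, MMP12, STAT3, PRKCD, RORC
leonuride\t1\tSLCO1B3
hydroxysafflor_yellow_a\t24\tCA1, PTPN1, SLC6A4, PTGS2, PRKCD, TERT, IKBKB, GSTM1, ACP1, PTPN2, GSK3B, AKR1B1, ABCB1, MMP2, MMP12, HSD11B1, APP, CNR1, MTOR, HMGCR, TLR9, F2, F10, IL1B
amygdalin\t1\tLGALS3
echinacoside\t2\tALDH2, LGALS3
calycosin_7_o_b_d_glucoside\t31\tTNF, ALDH2, AKR1B1, CA1, XDH, HRAS, MAPK14, F10, ADRA2C, PARP1, ABCB1, HCAR2, PTGS1, ADRA2A, EGFR, CD38, MIF, MMP9, MMP2, MMP8, ALB, MMP12, PTPN22, TLR9, PPARA, APP、LGALS3, IRAK4, SLC5A2, CASP1, INSR
ononin\t3\tALDH2, MTTP, SHBG
calycosin\t27\tABCB1, MIF, PPARA, ESR1, TLR9, EGFR, PTGS1, ALDH2, XDH, CA1, PTPN1, PON1, PLAT, F10, TNF, IGFBP3, AKR1B1, SNCA, GCGR, ADRB2, TNNC1, TNNT2, TNNI3, IGFBP5, IGFBP2, IGFBP1, PPARG
astragaloside_iv\t31\tVEGFA, FGF1, FGF2, HPSE, LGALS3, ADRA2A, ABCB1, ADRA2C, ADRA2B, STAT3, AKT2, AKT1, CNR1, CNR2, FAAH, ADRB2, MTOR, PIK3CG, RORC, F10, IGF2R, DRD3、F7, VDR, PIK3CA, PIK3R1, PTPN2, EGFR, MMP1, SLC6A4, SELP
astragaloside_iii\t26\tVEGFA, FGF1, FGF2, HPSE, LGALS3, RORC, ADRA2A, ADRA2C, ADRA2B, DRD3、STAT3、VDR, SLC5A1, CNR1, CNR2、HSD11B2、HSD11B1, ABCB1, ADRB2, MMP2, MMP12, IGF2R, GLB1, PPARG, ADRB3, IGF1R
ophiopojaponin_c\t28\tSTAT3, F2, HSD11B2, HSD11B1, PTPN1, ADRB2, MMP2, MMP8, SLC5A2, SLC5A1, AKR1B1, ADRA2A, ADRA2C, ADRA2B, OPRM1, IGF1R, CASP1, DGAT1, EPHX2, LIPC, KCNH2, PRKCD, NR3C1, MMP1, FAAH, ABCG2, DPP4, ADRB3
astragaloside_ii\t31\tVEGFA, FGF1, FGF2, HPSE, ABCB1, ADRA2A, ADRA2C, ADRA2B, STAT3, LGALS3, VDR, RORC, REN, IKBKB, ADRB2, SLC5A1, CNR1, CNR2, DRD3, EGFR, FAAH, IGF1R, IGF2R, AKT2, AKT1, INSR, FKBP5, LIPC, MMP1, TLR9, MTOR
formononetin\t4\tESR1, MTTP, AKT1, SHBG
isoastragaloside_ii\t32\tVEGFA, FGF1, FGF2, HPSE, ABCB1, ADRA2A, ADRA2C, ADRA2B, STAT3, LGALS3, VDR, RORC, REN, IKBKB, ADRB2, SLC5A1, CNR1, CNR2, DRD3, EGFR, FAAH, IGF1R, IGF2R, AKT2, AKT1, INSR, FKBP5, LIPC, MMP1, TLR9, MTOR, SLCO1B3
rhein\t11\tALOX5, MAPK8IP1, CYP1A2, CYP2C9, CYP3A4, CYP3A43, CYP3A5, GSTP1, NR1H2, PTGS1, PTGS2
astragaloside_i\t27\tVEGFA, FGF1, FGF2, RORC, ADRA2A, ADRA2C, ADRA2B, VDR, LGALS3, MTOR, HPSE, MAPK14, HLA-A, P2RY12, SLC5A1, REN, ABCB1, DRD3, LIPC, MMP9, MMP8, IKBKB, PPARG, F3, F7, MMP3, MMP1
isoastragaloside_i\t28\tVEGFA, FGF1, FGF2, HPSE, ADRA2C, ADRA2B, ABCB1, VDR, LGALS3, DRD3, RORC, ADRA2A, CNR1, CNR2, SLC5A1, HLA-A, LIPC, TERT, ALDH2, PRKCD, EDNRB, IGF1R, DPP4, REN, MTOR, MMP9, MMP8, AKT1
emodin\t8\tALOX5, CYP1A2, CYP2C9, CYP3A4, CYP3A43, CYP3A5, GSTP1, NR1H2
"""

PATHWAY_TABLE_TSV = """\
pathway_id\tname\tp_printed\tgene_count
hsa04151\tPI3K-Akt signaling pathway\t3.19e-6\t17
hsa04010\tMAPK signaling pathway\t1.12e-6\t16
hsa04933\tAGE-RAGE signaling pathway\t1.04e-11\t15
hsa04015\tRap1 signaling pathway\t1.06e-5\t13
hsa04915\tEstrogen signaling pathway\t6.86e-7\t12
hsa04014\tRas signaling pathway\t1.36e-4\t12
hsa04625\tC-type lectin receptor signaling pathway\t2.84e-7\t11
hsa04066\tHIF-1 signaling pathway\t4.59e-7\t10
hsa04926\tRelaxin signaling pathway\t2.49e-6\t11
hsa04068\tFoxO signaling pathway\t2.90e-6\t11
hsa04022\tcGMP-PKG signaling pathway\t2.97e-6\t10
hsa04668\tTNF signaling pathway\t4.83e-6\t10
hsa04152\tAMPK signaling pathway\t8.98e-6\t10
hsa04910\tInsulin signaling pathway\t2.88e-5\t10
hsa04072\tPhospholipase D signaling pathway\t5.60e-5\t10
hsa04150\tmTOR signaling pathway\t7.42e-5\t10
hsa04920\tAdipocytokine signaling pathway\t6.00e-7\t9
hsa04211\tLongevity regulating pathway\t5.27e-6\t9
hsa04657\tIL-17 signaling pathway\t8.30e-6\t9
hsa04620\tToll-like receptor signaling pathway\t1.90e-5\t9
"""


def compound_records() -> list[CompoundRecord]:
    """The 22 quantified components as parsed records."""
    import tempfile
    from pathlib import Path

    from .io import read_compound_table

    with tempfile.TemporaryDirectory() as tmp:
        p = Path(tmp) / "compounds.tsv"
        p.write_text(COMPOUND_TABLE_TSV)
        return read_compound_table(p)


def target_map() -> CompoundTargetMap:
    """The 21 active components' common target sets (curated transcription)."""
    import tempfile
    from pathlib import Path

    from .io import read_target_map

    with tempfile.TemporaryDirectory() as tmp:
        p = Path(tmp) / "targets.tsv"
        p.write_text(TARGET_TABLE_TSV)
        return read_target_map(p, provenance="fixture")


def pathway_table() -> list[tuple[str, str, float, int]]:
    """The top-20 pathway rows as (id, name, published p, gene count)."""
    reader = csv.DictReader(_io.StringIO(PATHWAY_TABLE_TSV), delimiter="\t")
    return [
        (r["pathway_id"], r["name"], float(r["p_printed"]), int(r["gene_count"]))
        for r in reader
    ]
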