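"""Printed cross-study comparison data for F508del-CFTR expression studies.

Six bulk-microarray comparisons of F508del-CFTR airway epithelium versus
control are compared in this package's motivating analysis: Zabner 2005
(Z), Wright 2006 (W), Virella-Lowell 2004 (V-L), Verhaeghe 2007 (V),
Ogilvie 2011 (O) and the current nasal-brushing study (C).  This module
holds the published summary data from that comparison: per-study list
sizes, the genes each study shares (same direction of regulation) with the
current study, the combined lists of genes regulated in the same direction
in two or more of the six studies, and the 30-gene airway epithelial
molecular signature (genes regulated concordantly in the current nasal
list and in both tissues of the reanalysed Ogilvie dataset).

These are data inputs, usable to rebuild the published overlap statistics
without access to the underlying expression matrices.
"""

from __future__ import annotations

STUDIES = ("Z", "W", "V-L", "V", "O", "C")

#: collapsed symbol-list sizes per study and direction
LIST_SIZES: dict[str, dict[str, int]] = {
    "Z": {"up": 300, "down": 300},
    "W": {"up": 300, "down": 300},
    "V-L": {"up": 300, "down": 300},
    "V": {"up": 300, "down": 300},
    "O": {"up": 115, "down": 110},
    "C": {"up": 117, "down": 220},
}

#: genes each study shares, same direction, with the current study (C)
SHARED_WITH_CURRENT: dict[str, dict[str, tuple[str, ...]]] = {
    "Z": {
        "up": ("ACAA2", "CDKN2B"),
        "down": ("IGFBP2",),
    },
    "W": {
        "up": ("C9ORF3", "KRT14"),
        "down": ("CYP24A1", "HLA-DQA1", "SAA4"),
    },
    "V-L": {
        "up": ("CAV1", "CCNE2"),
        "down": ("CLGN", "ENO2", "EPB41L3", "GPX3", "TIMP4"),
    },
    "V": {
        "up": ("BCL2A1", "G0S2", "IL1B", "MMP1", "RGS2"),
        "down": ("CKB", "CRIP1", "CYP24A1", "DNALI1", "FHL1", "GSTT1", "IGFBP2"),
    },
    "O": {
        "up": ("BCL2A1", "G0S2", "IL1B", "IL1R2", "LCP2", "NDRG1", "RGS2",
               "RNF149", "TCN1"),
        "down": ("PROS1", "SCGB1A1", "SPAG8"),
    },
}

#: genes regulated in the same direction in >=2 of the six studies
COMBINED_SHARED_UP: tuple[str, ...] = (
    "ACAA2", "AGL", "AKR1C1", "ANXA8L2", "BCHE", "BLOC1S1", "BTBD3",
    "C9ORF3", "CAPG", "CAV1", "CCL20", "CCNE2", "CD24", "CD83", "CDKN2B",
    "CLGN", "CSF3", "DDX3Y", "ELK3", "FOLR1", "FOLR3", "FOXG1", "GCA",
    "GFPT2", "HCLS1", "HIST1H1C", "HMOX1", "HPCAL1", "HSPB11", "IFIT1",
    "IFIT3", "IFITM1", "IL1R2", "IL7R", "ISG15", "KCTD12", "KRT14",
    "KRT81", "LCP2", "LITAF", "LYPD1", "MLF1", "MMP1", "MRPL28", "MX2",
    "NCF1", "NDRG1", "NET1", "PLAU", "PLAUR", "PLTP", "PRSS3", "PSG9",
    "PTPN13", "RAC2", "RAGE", "RNF149", "RPA3", "SEMA3B", "SERPINA3",
    "SERPINF1", "SLITRK5", "SOD2", "SULT1A3", "TCF15", "TCIRG1", "TCN1",
    "TXNIP", "BCL2A1", "G0S2", "IL1B", "NCF2", "PLAT", "PTGS2", "RGS2",
)

COMBINED_SHARED_DOWN: tuple[str, ...] = (
    "ACTA2", "ADAR", "ALDH1A1", "ANKRD1", "ASNS", "ASS1", "BEX4", "BST2",
    "BTG1", "C5ORF13", "CALD1", "CAP1", "CCL20", "CD164", "CFB", "CGREF1",
    "CKB", "CLGN", "COL8A1", "COL9A3", "CRIP1", "CSTA", "CXCR4",
    "CYP51A1", "DDB2", "DDIT4", "DNALI1", "DSP", "DSTN", "DYNLT1",
    "EDNRA", "EFEMP1", "EIF4A2", "ENO2", "EPB41L3", "EPS8", "F3", "FBLN5",
    "FCGBP", "FHL1", "GABRP", "GCH1", "GINS1", "GPNMB", "GPR1", "GPX3",
    "GSTT1", "GZMB", "HCP5", "HES1", "HLA-B", "HLA-DQA1", "HLA-DRA",
    "HLA-DRB1", "HLA-F", "HLA-G", "HMGCS1", "HSPB1", "HTRA1", "ID1",
    "IFI16", "IFITM1", "IFRD1", "IGFBP7", "IL32", "KCNN4", "KIT", "KLRK1",
    "KRT15", "LCN2", "LGALS3BP", "LOX", "MGAM", "MSC", "NID2", "NPR3",
    "NTS", "PGD", "PNMA2", "PPP1R3C", "PROS1", "RASGRP1", "RND3", "RUNX3",
    "SAA4", "SC5DL", "SCGB1A1", "SERPINB3", "SERPINB4", "SGK1",
    "SLC2A3P1", "SNAPC1", "SPAG8", "STAC", "STAT4", "TES", "TFPI", "THBD",
    "TIMP4", "TPBG", "TRIB2", "TWIST1", "VDAC1", "ZNF643", "CTSC",
    "CYP24A1", "IFI27", "IGFBP2", "IGFBP3", "NAMPT", "PRSS23", "SEL1L3",
    "TMSB4X", "TRIM22",
)

#: 30-gene molecular signature for native CF airway epithelium: regulated
#: concordantly in the current nasal study and in both the nasal and
#: bronchial lists of the reanalysed Ogilvie dataset.
SIGNATURE_UP: tuple[str, ...] = (
    "ALOX5AP", "BCL2A1", "CXCR4", "FCGR3A", "FOS", "G0S2", "GCNT3",
    "HIST1H1C", "HIST1H2BK", "IL1B", "IL1R2", "LITAF", "OSM", "PLEK",
    "PTGS2", "RGS2", "S100A8", "S100A9", "SERPINA3", "TCN1", "TPM4",
)

SIGNATURE_DOWN: tuple[str, ...] = (
    "CAPS", "CHST9", "DNALI1", "MAOB", "NELL2", "PPP1R16A", "PROS1",
    "PTGFR", "RAGE",
)

#: qPCR validation panel: per-gene fold changes measured by array and by
#: relative qPCR (negative values are the reciprocal display convention
#: for down-regulation), and primer amplification efficiencies (percent).
QPCR_PANEL: dict[str, dict[str, float]] = {
    "ADM": {"fc_array": 2.9, "fc_qpcr": 1.7, "efficiency_pct": 100.0},
    "AQP9": {"fc_array": 4.9, "fc_qpcr": 1.8, "efficiency_pct": 106.0},
    "AREG": {"fc_array": 3.6, "fc_qpcr": 1.3, "efficiency_pct": 97.0},
    "GJA1": {"fc_array": 3.4, "fc_qpcr": 2.7, "efficiency_pct": 98.0},
    "IGFBP3": {"fc_array": 2.2, "fc_qpcr": 1.2, "efficiency_pct": 100.0},
    "NDRG1": {"fc_array": 2.6, "fc_qpcr": 2.0, "efficiency_pct": 106.0},
    "TMEM45A": {"fc_array": 3.0, "fc_qpcr": 1.0, "efficiency_pct": 97.0},
    "SCGB1A1": {"fc_array": -3.3, "fc_qpcr": -2.3, "efficiency_pct": 100.0},
    "SPAG6": {"fc_array": -2.5, "fc_qpcr": -3.4, "efficiency_pct": 100.0},
    "TEKT1": {"fc_array": -3.3, "fc_qpcr": -3.0, "efficiency_pct": 103.0},
}

QPCR_REFERENCES: dict[str, float] = {"ACTB": 100.0, "GAPDH": 97.0}


# ---------------------------------------------------------------------------
# reconstruction of list sets from the printed summaries
# ---------------------------------------------------------------------------


def _placeholder_list(study, direction, known, size):
    """Collapsed GeneList of ``size`` symbols: the known genes plus unique
    per-study placeholder symbols (the unprinted remainder of the list)."""
    import pandas as pd

    from .listbuild import GeneList

    tag = study.replace("-", "")
    symbols = list(known) + [
        f"{tag}_{direction.upper()}_FILL{i:04d}" for i in range(size - len(known))
    ]
    fc = 2.0 if direction == "up" else 0.5
    entries = pd.DataFrame(
        {
            "rank": range(1, size + 1),
            "probe_id": symbols,
            "symbol": symbols,
            "FC": fc,
            "p": 0.0,
            "pfp": 0.0,
        }
    )
    return GeneList(
        study_name=study, direction=direction, entries=entries,
        collapsed=True, universe_size=size,
    )


def reconstruct_comparison_listset():
    """Rebuild the six-study list set from the printed shared-gene rows.

    Each study's directional list is its printed genes-shared-with-the-
    current-study padded with unique placeholders up to the printed list
    size; the current study's lists are the unions of the shared rows,
    likewise padded.  Every pairwise intersection involving the current
    study, and the current-study ALL summary cells, are therefore exactly
    the printed values, so the published overlap percentages can be
    recomputed from first principles.  Intersections *between* the five
    other studies are not printed and are empty here.
    """
    from .meta_compare import StudyListSet

    lists = {}
    for study, rows in SHARED_WITH_CURRENT.items():
        lists[study] = {
            d: _placeholder_list(study, d, rows[d], LIST_SIZES[study][d])
            for d in ("up", "down")
        }
    current = {}
    for d in ("up", "down"):
        union: list[str] = []
        for rows in SHARED_WITH_CURRENT.values():
            union.extend(s for s in rows[d] if s not in union)
        current[d] = _placeholder_list("C", d, union, LIST_SIZES["C"][d])
    lists["C"] = current
    return StudyListSet(lists=lists)


def signature_stand_in_listset(
    sizes: dict[str, dict[str, int]] | None = None,
):
    """Synthetic stand-in for the three collapsed reanalysis lists.

    The full current-study extended list and the reanalysed nasal and
    bronchial lists live in external supplementary files; only their
    three-way intersection (the 30-gene signature) is printed.  This
    builds three synthetic collapsed lists whose common core is exactly
    the printed signature, padded with list-specific placeholders to the
    reported reanalysis list-length scale, for exercising the k-way
    intersection machinery against the published signature counts.
    """
    from .meta_compare import StudyListSet

    sizes = sizes or {
        "C-N": {"up": 600, "down": 300},
        "O-N": {"up": 616, "down": 303},
        "O-B": {"up": 441, "down": 510},
    }
    core = {"up": SIGNATURE_UP, "down": SIGNATURE_DOWN}
    lists = {
        study: {
            d: _placeholder_list(study, d, core[d], sizes[study][d])
            for d in ("up", "down")
        }
        for study in sizes
    }
    return StudyListSet(lists=lists)
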