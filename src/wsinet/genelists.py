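"""Published immune-response gene panels for the treated APP/PS1
neurosphere contrasts.

Two curated panels of immune genes modulated by the kinin treatments:
genes underexpressed after B2-receptor blockade (HOE-140-treated vs
untreated APP/PS1 neurospheres) and genes overexpressed after bradykinin
treatment.  Symbols are kept exactly as printed.  The panels' set algebra
(sizes, union of treatment-modulated genes, and the intersection of genes
responding in opposite directions to the two treatments) is a fixed,
checkable property of the lists themselves.
"""

from __future__ import annotations

HOE_UNDEREXPRESSED: tuple[str, ...] = (
    "BST2", "C4B", "CCL5", "CX3CR1", "CXCL10", "DDX58", "GBP5", "GBP6",
    "GPR65", "IFIH1", "IFIT1", "IFIT3", "ISG15", "LY86", "PTPN6", "RSAD2",
    "TLR2", "ZC3HAV1",
)

BK_OVEREXPRESSED: tuple[str, ...] = (
    "BCL3", "BLNK", "C1QB", "CASP4", "CCL2", "CCL3", "CCL4", "CD14",
    "CX3CR1", "CXCL5", "EMR1", "FAS", "GBP5", "GCH1", "IFIT1", "IGSF6",
    "ISG15", "LILRB4", "TLR2", "TNF-alpha", "TREM2", "TYROBP", "VAV1",
    "VCAM1",
)


def panel_summary() -> dict:
    """Set algebra over the two panels.

    Returns sizes of each panel, of their union (all treatment-modulated
    genes) and of their intersection (genes overexpressed under bradykinin
    yet underexpressed under HOE-140, i.e. opposite responders), plus the
    intersection members themselves.
    """
    under = set(HOE_UNDEREXPRESSED)
    over = set(BK_OVEREXPRESSED)
    return {
        "n_underexpressed": len(under),
        "n_overexpressed": len(over),
        "n_modulated": len(under | over),
        "n_opposite": len(under & over),
        "opposite_genes": sorted(under & over),
    }
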