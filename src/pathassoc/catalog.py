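"""Packaged innate-immunity / inflammation pathway catalog.

46 candidate genes grouped into 6 biological sub-pathways, with the number
of tag SNPs retained per gene after QC (320 in total), plus 39
ancestry-informative markers (AIMs).  Gene symbols, sub-pathway membership,
chromosomes and per-gene SNP counts describe the real candidate panel; the
individual SNP identifiers are synthetic placeholders (``<gene>_tagNN``),
since no per-SNP manifest is distributed with the package.
"""

from __future__ import annotations

import pandas as pd

from .geno_io import SnpAnnotation, PathwayHierarchy

__all__ = ["GENE_CATALOG", "N_AIMS", "packaged_annotation", "packaged_hierarchy"]

# gene, sub-pathway, chromosome, SNPs retained after QC
GENE_CATALOG: list[tuple[str, str, int, int]] = [
    # cytokine signaling (26 genes, 179 SNPs)
    ("IL10",    "cytokine signaling", 1, 8),
    ("IL12RB2", "cytokine signaling", 1, 11),
    ("IL6R",    "cytokine signaling", 1, 1),
    ("IL18R1",  "cytokine signaling", 2, 16),
    ("IL1B",    "cytokine signaling", 2, 4),
    ("IL1RN",   "cytokine signaling", 2, 7),
    ("IL12A",   "cytokine signaling", 3, 4),
    ("TGFBR2",  "cytokine signaling", 3, 33),
    ("IL2",     "cytokine signaling", 4, 5),
    ("IL8",     "cytokine signaling", 4, 4),
    ("IL12B",   "cytokine signaling", 5, 6),
    ("IL13",    "cytokine signaling", 5, 4),
    ("IL4",     "cytokine signaling", 5, 4),
    ("IL5",     "cytokine signaling", 5, 1),
    ("IFNGR1",  "cytokine signaling", 6, 5),
    ("IL17",    "cytokine signaling", 6, 8),
    ("TNF/LTA", "cytokine signaling", 6, 11),
    ("TGFBR1",  "cytokine signaling", 9, 6),
    ("IL18",    "cytokine signaling", 11, 8),
    ("IFNG",    "cytokine signaling", 12, 6),
    ("IL23A",   "cytokine signaling", 12, 1),
    ("IL12RB1", "cytokine signaling", 19, 5),
    ("MIC1",    "cytokine signaling", 19, 6),
    ("TGFB1",   "cytokine signaling", 19, 4),
    ("IFNGR2",  "cytokine signaling", 21, 9),
    ("MIF",     "cytokine signaling", 22, 2),
    # eicosanoid signaling (1 gene, 9 SNPs)
    ("COX2",    "eicosanoid signaling", 1, 9),
    # extracellular pattern recognition (8 genes, 56 SNPs)
    ("TLR5",    "extracellular pattern recognition", 1, 7),
    ("TLR1",    "extracellular pattern recognition", 4, 7),
    ("TLR10",   "extracellular pattern recognition", 4, 7),
    ("TLR2",    "extracellular pattern recognition", 4, 8),
    ("TLR3",    "extracellular pattern recognition", 4, 1),
    ("TLR6",    "extracellular pattern recognition", 4, 5),
    ("MSR1",    "extracellular pattern recognition", 8, 16),
    ("TLR4",    "extracellular pattern recognition", 9, 5),
    # intracellular antiviral molecules (4 genes, 40 SNPs)
    ("RNASEL",  "intracellular antiviral molecules", 1, 7),
    ("EIF2AK2", "intracellular antiviral molecules", 2, 11),
    ("OAS1",    "intracellular antiviral molecules", 12, 5),
    ("OAS2",    "intracellular antiviral molecules", 12, 17),
    # NFKB signaling (5 genes, 27 SNPs)
    ("NFKB1",   "NFKB signaling", 4, 10),
    ("IKBKB",   "NFKB signaling", 8, 7),
    ("CHUK",    "NFKB signaling", 10, 6),
    ("RELA",    "NFKB signaling", 11, 2),
    ("NFKBIA",  "NFKB signaling", 14, 2),
    # selenoproteins (2 genes, 9 SNPs)
    ("SEP15",   "selenoproteins", 1, 5),
    ("SELS",    "selenoproteins", 15, 4),
]

N_AIMS = 39


def packaged_annotation(n_aims: int = N_AIMS) -> SnpAnnotation:
    """Annotation table for the packaged catalog (synthetic SNP ids)."""
    rows = []
    for gene, sub, chrom, n in GENE_CATALOG:
        stem = gene.replace("/", "_")
        for i in range(n):
            rows.append({
                "snp_id": f"{stem}_tag{i + 1:02d}",
                "chrom": chrom,
                "pos": (i + 1) * 1000,
                "gene": gene,
                "subpathway": sub,
                "is_aim": False,
            })
    for i in range(n_aims):
        rows.append({
            "snp_id": f"AIM{i + 1:02d}",
            "chrom": (i % 22) + 1,
            "pos": 10_000_000 + i * 1000,
            "gene": None,
            "subpathway": None,
            "is_aim": True,
        })
    return SnpAnnotation(pd.DataFrame(rows))


def packaged_hierarchy() -> PathwayHierarchy:
    return PathwayHierarchy.from_annotation(packaged_annotation())
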