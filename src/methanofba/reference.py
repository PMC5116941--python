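"""Published summary statistics of the full iMR539 reconstruction.

The complete 688-reaction genome-scale reconstruction is distributed
separately (BioModels MODEL1607200000); rebuilding it is out of scope
here. Its headline statistics are nevertheless useful as reference
inputs, and two derived percentages are recomputed from them so the
arithmetic is checkable.
"""

from __future__ import annotations

#: headline statistics of the deposited iMR539 reconstruction
IMR539_STATS = {
    "protein_encoding_genes": 539,
    "orf_coverage_percent": 31,
    "intracellular_metabolites": 657,
    "extracellular_metabolites": 53,
    "dead_end_metabolites": 260,
    "internal_reactions": 580,
    "transport_reactions": 49,
    "exchange_reactions": 59,
    "dead_end_reactions": 206,
    "gene_associated_reactions": 497,
}

#: trained maintenance values for iMR539 and the reported GAM of the
#: Methanosarcina barkeri reconstruction used for comparison
IMR539_GAM = 169.9   # mmol ATP / gDCW
IMR539_NGAM = 5.0    # mmol ATP / gDCW / h
M_BARKERI_GAM = 65.00


def gene_association_percentage(
    gene_associated: int = IMR539_STATS["gene_associated_reactions"],
    internal: int = IMR539_STATS["internal_reactions"],
) -> float:
    """Percentage of internal reactions assigned to at least one gene."""
    if internal <= 0:
        raise ValueError("internal reaction count must be positive")
    return 100.0 * gene_associated / internal


def gam_ratio_percent(
    other_gam: float = M_BARKERI_GAM,
    this_gam: float = IMR539_GAM,
) -> float:
    """Another organism's GAM as a percentage of the trained GAM."""
    if this_gam <= 0:
        raise ValueError("GAM must be positive")
    return 100.0 * other_gam / this_gam
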