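"""Published summary inputs for the lead epilepsy risk marker in Siberian
Huskies (CFA3, intron 2 of KCNIP4; marker BICF2P1282800, G>A, CanFam3.1
chr3:88,803,651).

These are printed genotype-count and allele-count tables usable as model
inputs when raw genotypes are unavailable; all per-dog analyses run on
cohort files or simulator output instead.
"""

from __future__ import annotations

import numpy as np

from .dosage import ContingencyTable

__all__ = [
    "lead_marker_dosage_table",
    "reference_panel_allele_counts",
    "LEAD_MARKER",
    "KCNIP4_INTERVAL",
    "GWAS_SNP_COUNT",
    "REPORTED_MEDIAN_IBD_CM",
]

#: Lead risk marker identity: (marker id, chromosome, bp, ref, risk allele).
LEAD_MARKER = ("BICF2P1282800", "3", 88_803_651, "G", "A")

#: Association interval used for IBD-overlap summaries (chr, start, end bp).
KCNIP4_INTERVAL = ("3", 87_771_875, 88_894_884)

#: Post-QC SNP count of the discovery array dataset (Bonferroni divisor).
GWAS_SNP_COUNT = 153_704

#: Reported median per-pair maximum IBD overlap among risk-risk haplotype
#: pairs across the association interval, in cM.
REPORTED_MEDIAN_IBD_CM = 4.46


def lead_marker_dosage_table() -> ContingencyTable:
    """Risk-allele dosage x status counts per cohort at the lead marker.

    Rows are dosage 0/1/2; columns are (cases, controls). The discovery
    cohort (113 dogs, CanineHD array) and the follow-up cohort (57 dogs,
    Sanger-genotyped at the lead marker) pool to 170 dogs.
    """
    return ContingencyTable({
        "GWAS": np.array([[11, 86], [9, 3], [4, 0]]),
        "Sanger": np.array([[13, 24], [10, 9], [1, 0]]),
    })


def reference_panel_allele_counts() -> dict:
    """Risk-allele counts / chromosomes per Siberian Husky subpopulation in
    the external unascertained Arctic-lineage reference panel.

    Returns ``{subpopulation: (risk_alleles, chromosomes)}``.
    """
    return {
        "Show/Sled-Show": (23, 246),
        "Pet": (6, 42),
        "Racing": (9, 222),
        "Seppala": (0, 48),
    }
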