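"""Census of the yeast ncRNA deletion strain collections.

Per-background strain counts for the barcoded ncRNA deletion collections
(original release plus the expansion), and the headline arithmetic derived
from them: total strain count, the fraction of ncRNA deletions essential
on rich media, and the number of independent barcode measurements each
strain contributes to a pooled competition.
"""

from __future__ import annotations

#: strains per background: (original release, expansion)
COLLECTION_COUNTS = {
    "heterozygous_diploid": (428, 81),
    "haploid_MATa": (373, 66),
    "haploid_MATalpha": (370, 67),
    "homozygous_diploid": (331, 63),
}

#: distinct ncRNAs deleted in at least one background
N_DISTINCT_NCRNAS = 532

#: ncRNA deletions essential on rich media (YPD)
N_ESSENTIAL = 17

#: distinct molecular barcodes integrated per strain (UPTAG + DOWNTAG)
N_TAGS_PER_STRAIN = 2


def total_strains(expanded: bool = True) -> int:
    """Total strains across all backgrounds (1502 original; 1779 expanded)."""
    return sum(orig + (add if expanded else 0)
               for orig, add in COLLECTION_COUNTS.values())


def essential_percent(n_essential: int = N_ESSENTIAL,
                      n_total: int = N_DISTINCT_NCRNAS) -> int:
    """Essential ncRNA deletions as a whole-number percentage."""
    return round(100.0 * n_essential / n_total)


def barcodes_per_strain(n_tags: int = N_TAGS_PER_STRAIN, n_bio_reps: int = 2) -> int:
    """Independent barcode measurements per strain in a pooled competition:
    two TAGs sequenced in each of the biological repeats."""
    return n_tags * n_bio_reps
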