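"""Built-in example inputs.

``published_screen_summaries`` reconstructs the per-variant summaries of
six recessive candidate variants from a published founder-population
screen of 153,054 genotyped individuals: five missense variants later
shown to cause severe childhood disease or embryonic lethality in the
homozygous state, plus the second miscarriage-associated variant from
the same screen. The minor allele frequencies, cohort size and the
complete absence of observed homozygotes are the published summary
values; genotype counts at individual level were not published, so these
records carry MAFs directly (the screen then uses them verbatim).
"""

from __future__ import annotations

from .screen import VariantSummary

#: size of the published genotyped population set
PUBLISHED_COHORT_N = 153_054


def published_screen_summaries() -> list[VariantSummary]:
    """Six deficit variants: (gene, protein change, MAF%, observed homozygotes)."""
    rows = [
        # variant_id, chrom, pos (GRCh38 where published), ref, alt, MAF
        ("SLC52A2_p.Leu339Pro", "chr8", 144360604, "T", "C", 0.0060),
        ("SLC13A5_p.Gly219Arg", "chr17", 6703031, "G", "A", 0.0049),
        ("GLB1_p.Glu186Ala", "chr3", 33058265, "A", "C", 0.0052),
        ("CPSF3_p.Gly468Glu", "chr2", 9452920, "G", "A", 0.0041),
        ("GNE_p.Asp378Tyr", "chr9", 36227397, "G", "T", 0.0060),
        ("GLE1_p.Arg569His", "chr9", 1, "G", "A", 0.0082),  # position not published
    ]
    return [
        VariantSummary(
            variant_id=vid,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            n_hom_alt=0,  # complete deficit: no homozygote observed
            maf=maf,
            imputation_info=0.99,
            consequence="missense",
        )
        for vid, chrom, pos, ref, alt, maf in rows
    ]
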