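"""Published reference inputs for the *Brassica rapa* 'Z1' vs 'Chiifu'
comparison, usable as worked-example data.

The region table lists the six large 'Z1'-specific regions (intervals are
stored 0-based half-open internally); the scalar constants are the printed
genome-size and repeat-content figures they accompany.
"""

from __future__ import annotations

from .structural import RegionSummary

#: the six 'Z1'-specific regions: seqid, start, end, length, N%, GC%,
#: gene count, cumulative gene bp, TE count, cumulative TE bp, rDNA count,
#: cumulative rDNA bp
Z1_SPECIFIC_REGIONS: list[tuple] = [
    ("A01", 16_062_101, 23_330_349, 7_268_248, 25.51, 30.39,
     230, 360_211, 3_207, 4_608_900, 47, 157_414),
    ("A05", 0, 6_383_565, 6_383_565, 24.99, 35.01,
     118, 709_602, 2_549, 4_337_199, 7, 22_711),
    ("A05", 19_127_968, 33_629_471, 14_501_503, 21.90, 36.61,
     153, 947_497, 6_431, 11_118_253, 18, 57_395),
    ("A06", 12_173_305, 42_412_226, 30_238_921, 29.87, 32.49,
     419, 2_408_139, 12_363, 19_669_728, 61, 193_702),
    ("A08", 6_540_348, 8_868_417, 2_328_069, 27.25, 29.90,
     8, 1_953, 580, 1_554_720, 0, 0),
    ("A09", 21_830_259, 34_184_774, 12_354_515, 54.00, 22.20,
     35, 268_743, 3_370, 5_288_282, 20, 64_209),
]


def z1_region_summaries() -> list[RegionSummary]:
    """The published region table as :class:`RegionSummary` rows."""
    return [
        RegionSummary(seqid=r[0], start=r[1], end=r[2], length_bp=r[3],
                      pct_n=r[4], pct_gc=r[5], n_genes=r[6],
                      cum_gene_len_bp=r[7], n_tes=r[8], cum_te_len_bp=r[9],
                      n_rdna=r[10], cum_rdna_len_bp=r[11])
        for r in Z1_SPECIFIC_REGIONS
    ]


#: k-mer-based genome-size estimate used as the original TE-fraction
#: denominator, and the flow-cytometry sizes measured for the two accessions
KMER_GENOME_SIZE_MB = 529.0
Z1_FLOW_SIZE_MB = 577.0
CHIIFU_FLOW_SIZE_MB = 545.0

#: TE genome fractions on the k-mer genome size
Z1_TE_FRACTION_PCT = 31.73
CHIIFU_TE_FRACTION_PCT = 22.16

#: measured 1C DNA contents (pg)
Z1_1C_PG = 0.590
CHIIFU_1C_PG = 0.557

#: the reciprocal inversion catalogue between the accessions: number of
#: inverted regions and the total genes / TEs found within them on 'Z1'
N_INVERSIONS = 81
GENES_IN_Z1_INVERSIONS = 22_274
TES_IN_Z1_INVERSIONS = 9_240
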