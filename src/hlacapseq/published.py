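"""Published PBMC cohort summary statistics used as worked-example inputs.

These are the printed per-locus five-number summaries of normalized RNA
levels (reads per million within the all-loci set) and the per-locus
lowest/highest expressed allele medians from a healthy PBMC reference
cohort, plus the normalized medians of two known HLA-A null alleles.  They
serve as inputs to the ratio-of-hinges, fold-change and null-allele
fraction operations; the package does not recompute them (the underlying
raw reads are not distributed).
"""

from __future__ import annotations

from .stats import FiveNumber

__all__ = [
    "PBMC_LOCUS_FIVE_NUMBER",
    "PBMC_ALLELE_EXTREMES",
    "PBMC_NULL_ALLELE_MEDIANS",
    "PBMC_AVERAGE_MEDIAN",
]

#: Per-locus five-number summaries of normalized reads (all-loci set, PBMC).
#: n is the number of phased alleles summarized per locus (not published
#: per locus; 0 marks "not recorded").
PBMC_LOCUS_FIVE_NUMBER: dict[str, FiveNumber] = {
    "A": FiveNumber(59_565, 75_996, 86_788, 100_109, 134_318, 0),
    "B": FiveNumber(121_917, 148_807, 165_092, 187_736, 242_948, 0),
    "C": FiveNumber(56_391, 84_675, 98_672, 120_247, 172_204, 0),
    "DPA1": FiveNumber(4_032, 8_058, 12_585, 15_217, 24_991, 0),
    "DPB1": FiveNumber(8_101, 15_232, 20_354, 25_442, 34_833, 0),
    "DQA1": FiveNumber(1_602, 4_623, 7_744, 12_744, 22_625, 0),
    "DQB1": FiveNumber(2_083, 5_201, 8_096, 18_605, 43_870, 0),
    "DRA": FiveNumber(12_069, 27_862, 36_511, 46_162, 69_618, 0),
    "DRB1": FiveNumber(9_046, 25_641, 35_606, 43_578, 64_661, 0),
    "DRB3": FiveNumber(1_535, 7_164, 9_972, 13_113, 20_243, 0),
    "DRB4": FiveNumber(6_819, 12_271, 15_445, 21_270, 31_237, 0),
    "DRB5": FiveNumber(2_101, 9_093, 13_634, 17_941, 29_122, 0),
}

#: Per-locus (average median over alleles, lowest allele + median,
#: highest allele + median) of normalized reads in PBMC.
PBMC_ALLELE_EXTREMES: dict[str, dict] = {
    "A": {
        "average_median": 120_366,
        "lowest": ("A*30:01:01", 99_814),
        "highest": ("A*24:20:01", 139_413),
    },
    "B": {
        "average_median": 231_598,
        "lowest": ("B*15:27:01", 196_005),
        "highest": ("B*35:01:01", 258_664),
    },
    "C": {
        "average_median": 142_987,
        "lowest": ("C*03:03:01", 119_834),
        "highest": ("C*04:01:01", 212_951),
    },
    "DPA1": {
        "average_median": 49_804,
        "lowest": ("DPA1*02:01:01", 48_111),
        "highest": ("DPA1*02:02:02", 51_134),
    },
    "DPB1": {
        "average_median": 73_344,
        "lowest": ("DPB1*04:01:01", 47_828),
        "highest": ("DPB1*05:01:01", 99_193),
    },
    "DQA1": {
        "average_median": 29_024,
        "lowest": ("DQA1*05:03:01", 14_991),
        "highest": ("DQA1*03:03:01", 57_501),
    },
    "DQB1": {
        "average_median": 50_644,
        "lowest": ("DQB1*04:02:01", 17_371),
        "highest": ("DQB1*05:02:01", 99_929),
    },
    "DRA": {
        "average_median": 151_031,
        "lowest": ("DRA*01:01:01", 148_601),
        "highest": ("DRA*01:02:02", 153_460),
    },
    "DRB1": {
        "average_median": 132_803,
        "lowest": ("DRB1*08:03:02", 99_464),
        "highest": ("DRB1*10:01:01", 182_883),
    },
    "DRB3": {
        "average_median": 33_383,
        "lowest": ("DRB3*02:02:01", 26_715),
        "highest": ("DRB3*01:01:02", 37_037),
    },
    "DRB4": {
        "average_median": 70_578,
        "lowest": ("DRB4*01:03:01", 58_794),
        "highest": ("DRB4*01:03:02", 82_362),
    },
    "DRB5": {
        "average_median": 50_935,
        "lowest": ("DRB5*02:02:01", 42_508),
        "highest": ("DRB5*01:02", 57_684),
    },
}

#: HLA-A average median across alleles (class-I set, PBMC).
PBMC_AVERAGE_MEDIAN: float = 120_366.0

#: Normalized median reads observed for two known HLA-A null alleles —
#: transcripts are still detectable despite the absent protein product.
PBMC_NULL_ALLELE_MEDIANS: dict[str, float] = {
    "A*02:15N": 41_242.0,
    "A*02:53N": 21_902.0,
}
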