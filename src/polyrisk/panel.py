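"""Published summary counts for the age-related cataract SNP panel.

A population-based Chinese case-control study (789 age-related cataract
cases, 531 controls) genotyped 18 tag SNPs in four DNA damage-repair
genes (BLM, WRN, ERCC6, OGG1). The published per-SNP allele and
genotype distributions are embedded here as summary-level inputs: they
determine every single-SNP statistic (allele/genotype tables, ORs,
dominant/recessive codings, HWE among controls) and, via
:func:`matched_cohort`, seed a synthetic individual-level cohort whose
marginals reproduce them exactly.

rs8027126 was out of Hardy-Weinberg equilibrium among controls and was
excluded from the published downstream analyses; no genotype
distribution was published for it, so only its allele counts appear
here and :data:`GENOTYPE_COUNTS` covers the 17 retained SNPs.
"""

from __future__ import annotations

import numpy as np

from .io import GenotypeCounts, GenotypeDataset, SnpDescriptor
from .simulate import marginal_matched_dataset

N_CASES = 789
N_CONTROLS = 531

#: case counts per cataract subtype: cortical, nuclear, posterior
#: subcapsular, mixed
SUBTYPE_COUNTS = {"C": 257, "N": 366, "PSC": 34, "M": 132}

#: the full genotyped panel (18 SNPs), Bonferroni denominator of the study
MANIFEST: list[SnpDescriptor] = [
    SnpDescriptor("rs1063147", "BLM", "C", "T"),
    SnpDescriptor("rs7183308", "BLM", "A", "G"),
    SnpDescriptor("rs17273206", "BLM", "G", "A"),
    SnpDescriptor("rs8027126", "BLM", "G", "T"),
    SnpDescriptor("rs7175811", "BLM", "G", "A"),
    SnpDescriptor("rs3815003", "BLM", "T", "C"),
    SnpDescriptor("rs6496724", "BLM", "A", "C"),
    SnpDescriptor("rs4733220", "WRN", "G", "A"),
    SnpDescriptor("rs2725361", "WRN", "G", "A"),
    SnpDescriptor("rs2725338", "WRN", "G", "A"),
    SnpDescriptor("rs1801195", "WRN", "T", "G"),
    SnpDescriptor("rs2725383", "WRN", "G", "C"),
    SnpDescriptor("rs1863280", "WRN", "T", "G"),
    SnpDescriptor("rs11574311", "WRN", "T", "C"),
    SnpDescriptor("rs4838519", "ERCC6", "A", "C"),
    SnpDescriptor("rs4253038", "ERCC6", "A", "G"),
    SnpDescriptor("rs2072668", "OGG1", "G", "C"),
    SnpDescriptor("rs2304277", "OGG1", "A", "G"),
]

#: published allele counts: snp_id -> (control major, control minor,
#: case major, case minor). For rs4838519 the published allele row
#: (801/777 case alleles) is inconsistent with the genotype row; the
#: genotype-derived values are used everywhere genotypes are available.
ALLELE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "rs1063147": (898, 164, 1312, 266),
    "rs7183308": (1010, 52, 1489, 89),
    "rs17273206": (829, 233, 1206, 372),
    "rs8027126": (978, 84, 1445, 133),
    "rs7175811": (766, 296, 1116, 462),
    "rs3815003": (762, 300, 1101, 477),
    "rs6496724": (738, 324, 1059, 519),
    "rs4733220": (620, 442, 955, 623),
    "rs2725361": (693, 369, 988, 590),
    "rs2725338": (779, 283, 1187, 391),
    "rs1801195": (686, 376, 985, 593),
    "rs2725383": (945, 117, 1363, 215),
    "rs1863280": (831, 231, 1229, 349),
    "rs11574311": (950, 112, 1342, 236),
    "rs4838519": (539, 523, 801, 777),
    "rs4253038": (730, 332, 1057, 521),
    "rs2072668": (636, 426, 978, 600),
    "rs2304277": (616, 446, 960, 618),
}

#: published genotype class counts (major-hom, het, minor-hom) for the
#: 17 HWE-surviving SNPs: snp_id -> (control, case). The rs2072668 case
#: row is reconstructed from its published percentages and allele
#: counts, whose printed class labels were garbled.
GENOTYPE_COUNTS: dict[str, tuple[GenotypeCounts, GenotypeCounts]] = {
    "rs1063147": (GenotypeCounts(379, 140, 12), GenotypeCounts(544, 224, 21)),
    "rs7183308": (GenotypeCounts(479, 52, 0), GenotypeCounts(702, 85, 2)),
    "rs17273206": (GenotypeCounts(323, 183, 25), GenotypeCounts(463, 280, 46)),
    "rs7175811": (GenotypeCounts(277, 212, 42), GenotypeCounts(401, 314, 74)),
    "rs3815003": (GenotypeCounts(274, 214, 43), GenotypeCounts(383, 335, 71)),
    "rs6496724": (GenotypeCounts(263, 212, 56), GenotypeCounts(361, 337, 91)),
    "rs4733220": (GenotypeCounts(190, 240, 101), GenotypeCounts(282, 391, 116)),
    "rs2725361": (GenotypeCounts(227, 239, 65), GenotypeCounts(312, 364, 113)),
    "rs2725338": (GenotypeCounts(290, 199, 42), GenotypeCounts(448, 291, 50)),
    "rs1801195": (GenotypeCounts(227, 232, 72), GenotypeCounts(311, 363, 115)),
    "rs2725383": (GenotypeCounts(422, 101, 8), GenotypeCounts(594, 175, 20)),
    "rs1863280": (GenotypeCounts(326, 179, 26), GenotypeCounts(474, 281, 34)),
    "rs11574311": (GenotypeCounts(428, 94, 9), GenotypeCounts(575, 192, 22)),
    "rs4838519": (GenotypeCounts(135, 269, 127), GenotypeCounts(208, 367, 214)),
    "rs4253038": (GenotypeCounts(247, 236, 48), GenotypeCounts(359, 339, 91)),
    "rs2072668": (GenotypeCounts(195, 246, 90), GenotypeCounts(308, 362, 119)),
    "rs2304277": (GenotypeCounts(184, 248, 99), GenotypeCounts(295, 370, 124)),
}

#: control minor-allele frequencies of the retained SNPs (simulation
#: presets at the study's allele-frequency spectrum)
CONTROL_MAFS: dict[str, float] = {
    s: ALLELE_COUNTS[s][1] / (ALLELE_COUNTS[s][0] + ALLELE_COUNTS[s][1])
    for s in GENOTYPE_COUNTS
}


def manifest(retained_only: bool = False) -> list[SnpDescriptor]:
    """The SNP manifest, optionally restricted to the 17 retained SNPs."""
    if retained_only:
        return [s for s in MANIFEST if s.snp_id in GENOTYPE_COUNTS]
    return list(MANIFEST)


def allele_counts(snp_id: str, from_genotypes: bool = True) -> tuple[int, int, int, int]:
    """(control major, control minor, case major, case minor) alleles."""
    if from_genotypes and snp_id in GENOTYPE_COUNTS:
        control, case = GENOTYPE_COUNTS[snp_id]
        return (
            control.n_major_alleles,
            control.n_minor_alleles,
            case.n_major_alleles,
            case.n_minor_alleles,
        )
    return ALLELE_COUNTS[snp_id]


def matched_cohort(seed: int = 0, with_subtypes: bool = True) -> GenotypeDataset:
    """Synthetic 1320-individual cohort with the published marginals.

    Every per-SNP genotype (hence allele, dominant and recessive) count
    equals the published value exactly; the joint genotype structure is
    random (SNPs filled independently within each group), so multi-locus
    results on this cohort do not reproduce the published interaction
    analyses, which require the individual-level data.
    """
    return marginal_matched_dataset(
        GENOTYPE_COUNTS,
        manifest(retained_only=True),
        seed=seed,
        subtype_counts=SUBTYPE_COUNTS if with_subtypes else None,
    )
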