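"""Core genotype data structures, file I/O, quality filtering and recoding.

Genotypes are stored as minor-allele counts: 0 = major homozygote,
1 = heterozygote, 2 = minor homozygote, ``MISSING`` (-1) = no call.
Allele orientation is fixed by the SNP manifest, never by observed
frequency, so a minor allele that is enriched in cases keeps its label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1

PHENOTYPE_LABELS = {"control": 0, "case": 1}
SUBTYPES = ("C", "N", "PSC", "M")


@dataclass(frozen=True)
class SnpDescriptor:
    """One biallelic SNP: identifier, gene, and allele orientation."""

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(
                f"{self.snp_id}: major and minor allele must differ "
                f"(both {self.major_allele!r})"
            )


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one SNP within one phenotype group."""

    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        if min(self.n_major_hom, self.n_het, self.n_minor_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def n_minor_alleles(self) -> int:
        return self.n_het + 2 * self.n_minor_hom

    @property
    def n_major_alleles(self) -> int:
        return 2 * self.n_major_hom + self.n_het

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_major_hom, self.n_het, self.n_minor_hom)


class GenotypeDataset:
    """Individuals x SNPs genotype matrix with case/control phenotype.

    Parameters
    ----------
    snps
        Ordered SNP manifest; column order of ``genotypes`` follows it.
    genotypes
        Integer matrix (n_individuals, n_snps) of codes in
        {0, 1, 2, MISSING}.
    phenotype
        Per-individual label, 0 = control, 1 = case.
    subtype
        Optional per-individual cataract subtype ("C", "N", "PSC", "M");
        empty string means unlabelled. Only cases may carry a subtype.
    """

    def __init__(
        self,
        snps: Sequence[SnpDescriptor],
        genotypes: np.ndarray,
        phenotype: np.ndarray,
        subtype: np.ndarray | None = None,
        ids: Sequence[str] | None = None,
    ) -> None:
        self.snps = list(snps)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.phenotype = np.asarray(phenotype, dtype=np.int8)
        n = self.phenotype.shape[0]
        if self.genotypes.shape != (n, len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} inconsistent "
                f"with {n} individuals x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.genotypes[~valid][0]
            raise ValueError(f"invalid genotype code {bad}")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype codes must be 0 (control) or 1 (case)")
        if subtype is None:
            subtype = np.full(n, "", dtype=object)
        self.subtype = np.asarray(subtype, dtype=object)
        if self.subtype.shape[0] != n:
            raise ValueError("subtype length inconsistent with phenotype")
        labelled = self.subtype != ""
        if np.any(labelled & (self.phenotype == 0)):
            raise ValueError("controls cannot carry a cataract subtype label")
        unknown = set(self.subtype[labelled]) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
        seen: set[str] = set()
        for s in self.snps:
            if s.snp_id in seen:
                raise ValueError(f"duplicate SNP id {s.snp_id}")
            seen.add(s.snp_id)
        if ids is None:
            ids = [f"I{i:05d}" for i in range(n)]
        self.ids = list(ids)
        self._index = {s.snp_id: j for j, s in enumerate(self.snps)}

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.phenotype.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Iterable[str]) -> "GenotypeDataset":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeDataset(
            [self.snps[j] for j in idx],
            self.genotypes[:, idx],
            self.phenotype,
            self.subtype,
            self.ids,
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.snps,
            self.genotypes[mask],
            self.phenotype[mask],
            self.subtype[mask],
            [i for i, keep in zip(self.ids, mask) if keep],
        )

    def subtype_view(self, subtype: str) -> "GenotypeDataset":
        """Cases of one subtype together with every control."""
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {subtype!r}")
        mask = (self.phenotype == 0) | (self.subtype == subtype)
        return self.subset_individuals(mask)

    def to_dataframe(self) -> pd.DataFrame:
        pheno = np.where(self.phenotype == 1, "case", "control")
        df = pd.DataFrame({"id": self.ids, "phenotype": pheno, "subtype": self.subtype})
        for j, s in enumerate(self.snps):
            df[s.snp_id] = self.genotypes[:, j]
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.subtype, other.subtype)
        )


# -- manifest and genotype table I/O ----------------------------------


def read_manifest(path: str | Path) -> list[SnpDescriptor]:
    """Read a SNP manifest TSV with columns snp_id, gene, major, minor."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "gene", "major", "minor"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return [
        SnpDescriptor(r.snp_id, r.gene, r.major, r.minor)
        for r in df.itertuples(index=False)
    ]


def write_manifest(snps: Sequence[SnpDescriptor], path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "gene": [s.gene for s in snps],
            "major": [s.major_allele for s in snps],
            "minor": [s.minor_allele for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


def _code_genotype(gt: str, snp: SnpDescriptor, individual: str) -> int:
    if gt == "" or gt.lower() in ("na", "nan", "--", "."):
        return MISSING
    if len(gt) != 2:
        raise ValueError(
            f"individual {individual}, SNP {snp.snp_id}: genotype {gt!r} "
            "is not a two-letter string"
        )
    code = 0
    for allele in gt:
        if allele == snp.minor_allele:
            code += 1
        elif allele != snp.major_allele:
            raise ValueError(
                f"individual {individual}, SNP {snp.snp_id}: allele "
                f"{allele!r} not in ({snp.major_allele}/{snp.minor_allele})"
            )
    return code


def read_genotype_table(path: str | Path, manifest: str | Path) -> GenotypeDataset:
    """Read a genotype TSV (one row per individual, two-letter genotypes).

    Header: ``id  phenotype  subtype  <snp_id ...>``; the manifest fixes
    allele orientation and the output SNP order.
    """
    snps = read_manifest(manifest)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"genotype table lacks required column {col!r}")
    missing_cols = [s.snp_id for s in snps if s.snp_id not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks manifest SNP columns {missing_cols}")
    bad_pheno = set(df["phenotype"]) - set(PHENOTYPE_LABELS)
    if bad_pheno:
        raise ValueError(
            f"phenotype values outside {{control, case}}: {sorted(bad_pheno)}"
        )
    phenotype = df["phenotype"].map(PHENOTYPE_LABELS).to_numpy(dtype=np.int8)
    subtype = (
        df["subtype"].to_numpy(dtype=object)
        if "subtype" in df.columns
        else np.full(len(df), "", dtype=object)
    )
    geno = np.empty((len(df), len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        col = df[snp.snp_id].to_numpy(dtype=object)
        ids = df["id"].to_numpy(dtype=object)
        geno[:, j] = [_code_genotype(g, snp, i) for g, i in zip(col, ids)]
    return GenotypeDataset(snps, geno, phenotype, subtype, list(df["id"]))


def write_genotype_table(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dataset as two-letter genotype strings (round-trippable)."""
    pheno = np.where(ds.phenotype == 1, "case", "control")
    out = pd.DataFrame({"id": ds.ids, "phenotype": pheno, "subtype": ds.subtype})
    for j, s in enumerate(ds.snps):
        strings = {
            0: s.major_allele * 2,
            1: s.major_allele + s.minor_allele,
            2: s.minor_allele * 2,
            MISSING: "",
        }
        out[s.snp_id] = [strings[int(c)] for c in ds.genotypes[:, j]]
    out.to_csv(path, sep="\t", index=False)


def read_vcf_minimal(
    path: str | Path,
    phenotype_table: str | Path,
    manifest: str | Path | None = None,
) -> GenotypeDataset:
    """Minimal VCF import: biallelic sites, GT field only.

    ``0/0`` -> 0, ``0/1``/``1/0`` -> 1, ``1/1`` -> 2, ``./.`` -> missing.
    REF is treated as the major allele unless a manifest overrides the
    orientation. Phenotype (and optional subtype) come from a side TSV
    with columns ``id  phenotype  [subtype]``.
    """
    samples: list[str] = []
    snps: list[SnpDescriptor] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"site {vid or chrom + ':' + pos} is multiallelic (ALT={alt})")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"site {vid}: no GT field")
            gt_at = fmt.index("GT")
            codes = []
            for sample_field in fields[9:]:
                gt = sample_field.split(":")[gt_at].replace("|", "/")
                if gt in ("./.", "."):
                    codes.append(MISSING)
                else:
                    alleles = gt.split("/")
                    if not set(alleles) <= {"0", "1"}:
                        raise ValueError(f"site {vid}: unsupported GT {gt!r}")
                    codes.append(sum(a == "1" for a in alleles))
            snps.append(SnpDescriptor(vid or f"{chrom}:{pos}", ".", ref, alt))
            rows.append(codes)
    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    if manifest is not None:
        by_id = {s.snp_id: s for s in read_manifest(manifest)}
        for j, s in enumerate(snps):
            m = by_id.get(s.snp_id)
            if m is None:
                continue
            if (m.major_allele, m.minor_allele) == (s.minor_allele, s.major_allele):
                col = geno[:, j]
                flip = col != MISSING
                geno[flip, j] = 2 - col[flip]
            snps[j] = m
    side = pd.read_csv(phenotype_table, sep="\t", dtype=str, keep_default_na=False)
    side = side.set_index("id").reindex(samples)
    if side["phenotype"].isna().any():
        absent = [s for s in samples if s not in side.index or pd.isna(side.loc[s, "phenotype"])]
        raise ValueError(f"phenotype table lacks samples {absent}")
    phenotype = side["phenotype"].map(PHENOTYPE_LABELS)
    if phenotype.isna().any():
        raise ValueError("phenotype values outside {control, case}")
    subtype = (
        side["subtype"].fillna("").to_numpy(dtype=object)
        if "subtype" in side.columns
        else None
    )
    return GenotypeDataset(snps, geno, phenotype.to_numpy(np.int8), subtype, samples)


# -- summary counts, HWE, recoding ------------------------------------


def genotype_counts(ds: GenotypeDataset, snp_id: str, group: str) -> GenotypeCounts:
    """Counts of genotype classes 0/1/2 for one SNP within one group."""
    if group not in PHENOTYPE_LABELS:
        raise ValueError(f"group must be 'control' or 'case', got {group!r}")
    col = ds.column(snp_id)[ds.phenotype == PHENOTYPE_LABELS[group]]
    return GenotypeCounts(
        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
    )


def hwe_test(gc: GenotypeCounts, method: str = "chisq") -> float:
    """Hardy-Weinberg goodness-of-fit p-value for one SNP in one group.

    ``chisq`` is the 1-df Pearson test against expected counts from the
    sample allele frequency; ``exact`` is the exact conditional test
    (sum over heterozygote counts no more probable than the observed).
    Monomorphic samples fit HWE perfectly and return 1.0.
    """
    n = gc.total
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = gc.n_minor_alleles
    n_major = gc.n_major_alleles
    if n_minor == 0 or n_major == 0:
        return 1.0
    if method == "chisq":
        p = n_minor / (2 * n)
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p]) * n
        observed = np.array(gc.as_tuple(), dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact(gc.n_het, min(n_minor, n_major), n)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_het: int, n_rare: int, n: int) -> float:
    """Exact HWE test: probability of heterozygote counts <= P(observed)."""
    parity = n_rare % 2
    hets = range(parity, n_rare + 1, 2)
    logp = {}
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[h] = (
            math.lgamma(n + 1)
            - math.lgamma(common_hom + 1)
            - math.lgamma(h + 1)
            - math.lgamma(rare_hom + 1)
            + h * math.log(2)
            - (math.lgamma(2 * n + 1) - math.lgamma(n_rare + 1) - math.lgamma(2 * n - n_rare + 1))
        )
    mx = max(logp.values())
    probs = {h: math.exp(lp - mx) for h, lp in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / total)


def filter_hwe(
    ds: GenotypeDataset, alpha: float = 0.05, method: str = "chisq"
) -> tuple[GenotypeDataset, list[str]]:
    """Drop SNPs out of HWE among controls at level ``alpha``.

    Returns the filtered dataset and the list of removed SNP ids.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    removed = [
        s.snp_id
        for s in ds.snps
        if hwe_test(genotype_counts(ds, s.snp_id, "control"), method) < alpha
    ]
    kept = [s for s in ds.snp_ids if s not in removed]
    return ds.subset_snps(kept), removed


RECODE_MODELS = ("dominant", "recessive", "allelic-count")


def recode(ds: GenotypeDataset, snp_id: str, model: str) -> np.ndarray:
    """Recode one SNP's genotypes; missing propagates as NaN.

    dominant: carrier of >=1 minor allele; recessive: minor homozygote;
    allelic-count: the 0/1/2 code itself.
    """
    col = ds.column(snp_id).astype(float)
    col[col == MISSING] = np.nan
    if model == "dominant":
        return np.where(np.isnan(col), np.nan, (col >= 1).astype(float))
    if model == "recessive":
        return np.where(np.isnan(col), np.nan, (col == 2).astype(float))
    if model == "allelic-count":
        return col
    raise ValueError(f"unknown recoding model {model!r}; choose from {RECODE_MODELS}")
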