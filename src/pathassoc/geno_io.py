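"""Genotype / phenotype / annotation input-output and quality control.

Genotypes are held as sample x SNP minor-allele counts (0/1/2, NaN for
missing).  The TSV genotype dialect is: tab-separated, header row of SNP
ids, first column ``sample_id``, cells in {0, 1, 2, NA}.  VCF input is
parsed GT-only (diploid, phased or unphased) via cyvcf2.

QC mirrors a candidate-gene study design with two ethnic groups: a SNP is
excluded when its call rate is below 0.90, or it departs from
Hardy-Weinberg proportions at P < 0.01 in *both* ethnic groups, or its MAF
is below 0.01 in *both* groups; samples with call rate below 0.90 are
excluded.  All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix", "SampleTable", "SnpAnnotation", "PathwayHierarchy",
    "read_genotypes", "write_genotypes", "read_samples", "read_annotation",
    "compute_maf", "hwe_chisq", "qc_snps", "qc_samples",
]

SUBPATHWAYS = (
    "cytokine signaling",
    "eicosanoid signaling",
    "extracellular pattern recognition",
    "intracellular antiviral molecules",
    "NFKB signaling",
    "selenoproteins",
)

SAMPLE_COLUMNS = ["sample_id", "status", "age", "institution", "ethnicity"]
ANNOTATION_COLUMNS = ["snp_id", "chrom", "pos", "gene", "subpathway", "is_aim"]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class GenotypeMatrix:
    """Sample x SNP matrix of minor-allele counts; NaN marks missing."""

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    allele_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.snp_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError("duplicate SNP ids")
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise FormatError(f"genotype call {bad!r} not in {{0,1,2,NA}}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"SNPs absent from genotype matrix: {missing}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_snps)
        sample_ids, snp_ids = self.sample_ids, self.snp_ids
        if samples is not None:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            rows = np.array([lookup[s] for s in samples], dtype=int)
            sample_ids = list(samples)
        if snps is not None:
            cols = self.snp_index(snps)
            snp_ids = list(snps)
        labels = {s: self.allele_labels[s] for s in snp_ids if s in self.allele_labels}
        return GenotypeMatrix(sample_ids, snp_ids, self.calls[np.ix_(rows, cols)], labels)

    def call_rate(self, axis: str) -> np.ndarray:
        """Fraction of non-missing calls per 'sample' (row) or 'snp' (column)."""
        ax = {"sample": 1, "snp": 0}[axis]
        return 1.0 - np.mean(np.isnan(self.calls), axis=ax)

    def mean_imputed(self, snps=None) -> np.ndarray:
        """Calls with missing entries replaced by the per-SNP mean count."""
        cols = self.snp_index(snps) if snps is not None else slice(None)
        g = self.calls[:, cols].copy()
        means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = np.take(means, idx[1])
        return g


@dataclass
class SampleTable:
    """Per-subject phenotype and adjustment covariates."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"sample table missing columns {missing}; expected {SAMPLE_COLUMNS}"
            )
        if len(df) == 0:
            raise FormatError("empty sample table")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample table")
        bad = set(df["status"].unique()) - {0, 1}
        if bad:
            raise FormatError(f"status values {sorted(bad)} not in {{0,1}}")
        if (df["age"] <= 0).any():
            raise FormatError("non-positive age")
        if df["ethnicity"].nunique() > 2:
            raise FormatError("more than two ethnicity groups")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def status(self) -> np.ndarray:
        return self.table["status"].to_numpy(dtype=float)

    def aligned_to(self, genotypes: GenotypeMatrix) -> "SampleTable":
        df = self.table.set_index("sample_id").loc[genotypes.sample_ids].reset_index()
        return SampleTable(df)

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def with_ancestry(self, scores: pd.Series) -> "SampleTable":
        df = self.table.copy()
        df["ancestry_pc1"] = scores.reindex(df["sample_id"]).to_numpy()
        return SampleTable(df)


@dataclass
class SnpAnnotation:
    """SNP -> gene -> sub-pathway map; AIMs carry no gene/sub-pathway."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(
                f"annotation missing columns {missing}; expected {ANNOTATION_COLUMNS}"
            )
        if len(df) == 0:
            raise FormatError("empty annotation")
        if df["snp_id"].duplicated().any():
            raise FormatError("duplicate SNP ids in annotation")
        df = df.copy()
        df["is_aim"] = df["is_aim"].astype(bool)
        cand = df[~df["is_aim"]]
        unknown = set(cand["subpathway"].unique()) - set(SUBPATHWAYS)
        if unknown:
            raise FormatError(
                f"unknown sub-pathway names {sorted(unknown)}; expected {SUBPATHWAYS}"
            )
        if cand["gene"].isna().any() or (cand["gene"] == "").any():
            raise FormatError("candidate SNP without gene")
        multi = cand.groupby("snp_id")["gene"].nunique()
        if (multi > 1).any():
            raise FormatError("SNP mapped to more than one gene")
        self.table = df.reset_index(drop=True)

    @property
    def candidate(self) -> pd.DataFrame:
        return self.table[~self.table["is_aim"]]

    @property
    def aim_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_aim"], "snp_id"])

    def gene_of(self) -> pd.Series:
        return self.candidate.set_index("snp_id")["gene"]


@dataclass
class PathwayHierarchy:
    """Pathway -> sub-pathway -> gene partition of the candidate SNP set."""

    pathway_name: str
    pathway: list[str]
    subpathways: dict[str, list[str]]
    genes: dict[str, list[str]]
    gene_subpathway: dict[str, str]

    @classmethod
    def from_annotation(cls, ann: SnpAnnotation,
                        pathway_name: str = "innate immunity and inflammation"):
        cand = ann.candidate
        genes = {g: list(t["snp_id"]) for g, t in cand.groupby("gene", sort=True)}
        subs = {s: list(t["snp_id"]) for s, t in cand.groupby("subpathway", sort=True)}
        gene_sub = cand.drop_duplicates("gene").set_index("gene")["subpathway"].to_dict()
        h = cls(pathway_name, list(cand["snp_id"]), subs, genes, gene_sub)
        h.validate()
        return h

    def validate(self):
        whole = sorted(self.pathway)
        from_subs = sorted(s for ids in self.subpathways.values() for s in ids)
        from_genes = sorted(s for ids in self.genes.values() for s in ids)
        if whole != from_subs or whole != from_genes:
            raise FormatError("gene/sub-pathway SNP sets do not partition the pathway")

    def level_sets(self, level: str) -> dict[str, list[str]]:
        if level == "pathway":
            return {self.pathway_name: self.pathway}
        if level == "subpathway":
            return dict(self.subpathways)
        if level == "gene":
            return dict(self.genes)
        raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# readers / writers

def _orient_to_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns whose coded allele has frequency > 0.5 (ties keep coding)."""
    calls = gm.calls.copy()
    labels = dict(gm.allele_labels)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    for j, f in enumerate(freq):
        snp = gm.snp_ids[j]
        a, b = labels.get(snp, ("A1", "A2"))
        if np.isnan(f):
            continue
        flip = f > 0.5 or (f == 0.5 and a > b)
        if flip:
            calls[:, j] = 2.0 - calls[:, j]
            labels[snp] = (b, a)
    return GenotypeMatrix(gm.sample_ids, gm.snp_ids, calls, labels)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dialect.

    Calls are re-oriented to minor-allele counts: the minor allele is the
    one with observed frequency <= 0.5, ties broken lexicographically by
    allele symbol.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "tsv":
        gm = _read_tsv_matrix(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return _orient_to_minor(gm)


def _read_tsv_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("genotype TSV needs a sample_id column and >=1 SNP column")
    sample_ids = list(df.iloc[:, 0])
    snp_ids = list(df.columns[1:])
    calls = np.full((len(sample_ids), len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        for i, raw in enumerate(df[snp]):
            v = raw.strip()
            if v in ("NA", "", "."):
                continue
            if v not in ("0", "1", "2"):
                raise FormatError(
                    f"genotype entry {raw!r} at sample {sample_ids[i]!r}, SNP {snp!r} "
                    "is not one of 0/1/2/NA"
                )
            calls[i, j] = float(v)
    return GenotypeMatrix(sample_ids, snp_ids, calls)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    snp_ids, columns, labels = [], [], {}
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise FormatError(f"multi-allelic variant {snp} not supported")
        # gts012: 0/1/2 = ALT count, 3 = missing
        col = np.asarray(var.gt_types, dtype=float)
        col[col == 3] = np.nan
        snp_ids.append(snp)
        columns.append(col)
        labels[snp] = (var.ALT[0], var.REF)  # ALT counted; orientation fixed later
    if not snp_ids:
        raise FormatError(f"no variants in {path}")
    calls = np.column_stack(columns)
    return GenotypeMatrix(sample_ids, snp_ids, calls, labels)


def write_genotypes(gm: GenotypeMatrix, path):
    df = pd.DataFrame(gm.calls, columns=gm.snp_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise FormatError(f"empty sample table {path}")
    return SampleTable(df)


def read_annotation(path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    if len(df) == 0:
        raise FormatError(f"empty annotation {path}")
    return SnpAnnotation(df)


# ---------------------------------------------------------------------------
# per-SNP statistics

def compute_maf(calls) -> float:
    """Minor-allele frequency min(f, 1-f) from 0/1/2 calls; NaN-aware."""
    calls = np.asarray(calls, dtype=float)
    ok = ~np.isnan(calls)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all calls missing")
    f = calls[ok].sum() / (2.0 * n)
    return float(min(f, 1.0 - f))


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    Genotype counts are (common hom, het, rare hom) — orientation does not
    matter.  Monomorphic input returns (0, 1).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotype counts")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return stat, float(chi2.sf(stat, df=1))


def _hwe_p_from_calls(calls) -> float:
    calls = calls[~np.isnan(calls)]
    if calls.size == 0:
        return 1.0
    n0 = int((calls == 0).sum()); n1 = int((calls == 1).sum()); n2 = int((calls == 2).sum())
    return hwe_chisq(n0, n1, n2)[1]


# ---------------------------------------------------------------------------
# QC filters

CALL_RATE_MIN = 0.90
HWE_P_MIN = 0.01
MAF_MIN = 0.01


def qc_samples(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples with genotype call rate < 0.90 (strict)."""
    rate = gm.call_rate("sample")
    keep = rate >= CALL_RATE_MIN
    if not keep.any():
        raise ValueError("sample QC removed every sample")
    log = pd.DataFrame({
        "id": [s for s, k in zip(gm.sample_ids, keep) if not k],
        "reason": [f"call_rate<{CALL_RATE_MIN}" for k in keep if not k],
    })
    kept = gm.subset(samples=[s for s, k in zip(gm.sample_ids, keep) if k])
    return kept, log


def qc_snps(gm: GenotypeMatrix, samples: SampleTable) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the SNP exclusion rules; returns kept matrix and reason log.

    A SNP is removed iff its call rate is < 0.90, or HWE P < 0.01 in both
    ethnicity groups, or MAF < 0.01 in both groups.  When only one group is
    present the group rules are evaluated on it alone (logged in reason).
    """
    samples = samples.aligned_to(gm)
    eth = samples.table["ethnicity"].to_numpy()
    groups = [eth == g for g in pd.unique(eth)]
    single_group = len(groups) == 1
    rate = gm.call_rate("snp")
    drop_reasons: list[tuple[str, str]] = []
    keep = []
    for j, snp in enumerate(gm.snp_ids):
        col = gm.calls[:, j]
        if rate[j] < CALL_RATE_MIN:
            drop_reasons.append((snp, f"call_rate<{CALL_RATE_MIN}"))
            keep.append(False)
            continue
        hwe_fail, maf_fail = [], []
        for mask in groups:
            sub = col[mask]
            hwe_fail.append(_hwe_p_from_calls(sub) < HWE_P_MIN)
            try:
                maf_fail.append(compute_maf(sub) < MAF_MIN)
            except ValueError:
                maf_fail.append(True)
        tag = "single_group:" if single_group else ""
        if all(hwe_fail):
            drop_reasons.append((snp, f"{tag}hwe_p<{HWE_P_MIN}_both_groups"))
            keep.append(False)
        elif all(maf_fail):
            drop_reasons.append((snp, f"{tag}maf<{MAF_MIN}_both_groups"))
            keep.append(False)
        else:
            keep.append(True)
    log = pd.DataFrame(drop_reasons, columns=["id", "reason"])
    kept = gm.subset(snps=[s for s, k in zip(gm.snp_ids, keep) if k])
    return kept, log
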