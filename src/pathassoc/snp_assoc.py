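"""Per-SNP logistic association: codominant and log-additive (trend) models.

Each SNP is tested by unconditional multivariate logistic regression
adjusted for the study covariates.  The codominant coding contrasts
heterozygotes and rare homozygotes against the common-homozygote
reference; the log-additive coding fits a single 0/1/2 allele-count trend
whose exponentiated coefficient is the per-allele odds ratio.  Wald 95%
confidence intervals and two-sided p-values are reported.  Contrasts with
an empty genotype-by-status cell are flagged undefined (rendered "-")
rather than reported as enormous unstable odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geno_io import GenotypeMatrix, SampleTable
from .kernel import build_design, DEFAULT_COVARIATES, SeparationError

__all__ = ["Contrast", "SnpAssocResult", "code_genotypes", "assoc_single_snp",
           "assoc_all_snps", "snp_results_frame"]

Z975 = 1.959963984540054


@dataclass
class Contrast:
    name: str                      # het | hom | trend
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    undefined: bool = False
    note: str = ""


@dataclass
class SnpAssocResult:
    snp_id: str
    coding: str                    # codominant | log-additive
    stratum: str
    n_used: int
    contrasts: list[Contrast]


def code_genotypes(calls, coding: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Predictor columns for one SNP; returns (X_snp, names, used_mask).

    Missing calls are dropped (per-SNP complete case).  Codominant coding
    yields heterozygote and rare-homozygote indicators against the
    common-homozygote (0 copies) reference.
    """
    calls = np.asarray(calls, dtype=float)
    used = ~np.isnan(calls)
    g = calls[used]
    if coding == "log-additive":
        return g[:, None], ["trend"], used
    if coding == "codominant":
        het = (g == 1).astype(float)
        hom = (g == 2).astype(float)
        return np.column_stack([het, hom]), ["het", "hom"], used
    raise ValueError(f"unknown coding {coding!r}")


def _zero_cell(y: np.ndarray, indicator: np.ndarray) -> bool:
    """True when any status x (carrier / non-carrier) margin cell is empty."""
    for val in (0.0, 1.0):
        sub = y[indicator == val]
        if sub.size == 0 or sub.min() == sub.max():
            return True
    return False


def _fit_logit(y, X):
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton", gtol=1e-10)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    if np.abs(res.params).max() > 30:
        raise SeparationError("diverging coefficients")
    return res


def assoc_single_snp(gm: GenotypeMatrix, samples: SampleTable, snp_id: str,
                     coding: str = "log-additive",
                     covariates=DEFAULT_COVARIATES,
                     stratum_label: str = "overall") -> SnpAssocResult:
    """Adjusted logistic association for one SNP under the given coding."""
    samples = samples.aligned_to(gm)
    j = gm.snp_index([snp_id])[0]
    snp_x, names, used = code_genotypes(gm.calls[:, j], coding)
    sub = samples.subset(used)
    y = sub.status
    X_cov, _ = build_design(sub, covariates)
    contrasts: list[Contrast] = []

    # genotype-margin screen: any empty status x genotype cell -> undefined
    defined = []
    g_used = gm.calls[used, j]
    for k, name in enumerate(names):
        if coding == "codominant":
            indicator = snp_x[:, k]
            ok = not _zero_cell(y, indicator) and np.ptp(indicator) > 0
        else:
            ok = np.ptp(snp_x[:, 0]) > 0 and not (
                _zero_cell(y, (g_used > 0).astype(float)))
        defined.append(ok)

    if not any(defined):
        for name in names:
            contrasts.append(Contrast(name, None, None, None, None, True,
                                      "no genotype variation"))
        return SnpAssocResult(snp_id, coding, stratum_label, int(used.sum()), contrasts)

    cols = [k for k, ok in enumerate(defined) if ok]
    X = np.column_stack([snp_x[:, cols], X_cov])
    try:
        res = _fit_logit(y, X)
        beta = np.asarray(res.params)[: len(cols)]
        se = np.asarray(res.bse)[: len(cols)]
        fitted = {cols[i]: (beta[i], se[i]) for i in range(len(cols))}
    except SeparationError as exc:
        fitted = {}
        note = f"separation: {exc}"
    for k, name in enumerate(names):
        if k in fitted:
            b, s = fitted[k]
            contrasts.append(Contrast(
                name, float(np.exp(b)), float(np.exp(b - Z975 * s)),
                float(np.exp(b + Z975 * s)),
                float(2.0 * norm.sf(abs(b / s))) if s > 0 else None))
        else:
            why = "empty genotype-by-status cell" if not defined[k] else note
            contrasts.append(Contrast(name, None, None, None, None, True, why))
    return SnpAssocResult(snp_id, coding, stratum_label, int(used.sum()), contrasts)


def assoc_all_snps(gm: GenotypeMatrix, samples: SampleTable,
                   covariates=DEFAULT_COVARIATES,
                   codings=("codominant", "log-additive"),
                   strata: str | None = None) -> list[SnpAssocResult]:
    """All SNPs x codings, overall or per stratum of a sample column."""
    samples = samples.aligned_to(gm)
    groups: list[tuple[str, GenotypeMatrix, SampleTable]] = []
    if strata is None:
        groups.append(("overall", gm, samples))
    else:
        for value in pd.unique(samples.table[strata]):
            mask = (samples.table[strata] == value).to_numpy()
            sub = samples.subset(mask)
            groups.append((str(value), gm.subset(samples=sub.sample_ids), sub))
    out = []
    for label, g_sub, s_sub in groups:
        for snp in g_sub.snp_ids:
            for coding in codings:
                out.append(assoc_single_snp(g_sub, s_sub, snp, coding,
                                            covariates, label))
    return out


def snp_results_frame(results: list[SnpAssocResult],
                      annotation=None) -> pd.DataFrame:
    """Long-format results table; one row per SNP x stratum x contrast."""
    gene_of = {}
    chrom_of = {}
    if annotation is not None:
        t = annotation.table.set_index("snp_id")
        gene_of = t["gene"].to_dict()
        chrom_of = t["chrom"].to_dict()
    rows = []
    for r in results:
        for c in r.contrasts:
            rows.append({
                "snp": r.snp_id,
                "gene": gene_of.get(r.snp_id),
                "chrom": chrom_of.get(r.snp_id),
                "stratum": r.stratum,
                "coding": r.coding,
                "contrast": c.name,
                "n": r.n_used,
                "OR": c.odds_ratio,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "undefined": c.undefined,
            })
    return pd.DataFrame(rows)
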