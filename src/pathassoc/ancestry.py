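"""Genetic-ancestry estimation from ancestry-informative markers (AIMs).

Genotypes are standardized per SNP in the EIGENSTRAT convention (mean
impute missing calls, center at twice the allele frequency, scale by the
binomial standard deviation sqrt(2p(1-p))) and decomposed by SVD.  The
first principal component separates the two ancestral populations and is
used downstream as the single genetic-ancestry adjustment covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix

__all__ = ["AncestryScores", "standardize_genotypes", "pca_ancestry"]


@dataclass
class AncestryScores:
    scores: pd.DataFrame          # index sample_id, columns PC1..PCk
    explained_variance: np.ndarray
    loadings: pd.DataFrame        # index snp_id, columns PC1..PCk

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def standardize_genotypes(gm: GenotypeMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    """EIGENSTRAT standardization; returns (Z, kept snp ids, dropped snp ids).

    Missing calls are replaced by the SNP mean (hence 0 after centering);
    monomorphic SNPs carry no ancestry information and are dropped.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples to standardize")
    g = gm.mean_imputed()
    p_hat = g.mean(axis=0) / 2.0
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    dropped = [s for s, k in zip(gm.snp_ids, poly) if not k]
    if not poly.any():
        raise ValueError("all SNPs monomorphic; standardization undefined")
    g = g[:, poly]
    p = p_hat[poly]
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    kept = [s for s, k in zip(gm.snp_ids, poly) if k]
    return z, kept, dropped


def pca_ancestry(gm: GenotypeMatrix, k: int = 2) -> AncestryScores:
    """PCA of the standardized AIM matrix.

    Scores are left singular vectors scaled by singular values.  The sign
    of each component is fixed so that its largest-magnitude SNP loading is
    positive, making runs reproducible across LAPACK backends.
    """
    z, kept, _ = standardize_genotypes(gm)
    if len(kept) < 2:
        raise ValueError("need at least two polymorphic AIMs for PCA")
    zc = z - z.mean(axis=0)
    if not np.any(np.abs(zc) > 1e-12):
        raise ValueError("degenerate input: all samples identical")
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    if k > rank:
        import warnings

        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=pd.Index(gm.sample_ids, name="sample_id"),
                          columns=cols)
    loadings = pd.DataFrame(vt.T, index=pd.Index(kept, name="snp_id"), columns=cols)
    explained = s ** 2 / (gm.n_samples - 1)
    return AncestryScores(scores, explained, loadings)
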