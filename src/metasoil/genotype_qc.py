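"""Genotype quality control, single-SNP association, LD pruning, ReliefF.

Mirrors a standard PLINK-style pre-processing chain for a case/control
panel: sample/SNP call-rate filters and a Hardy-Weinberg exact test, a
Cochran-Armitage trend scan for single-variant effects, sliding-window
r-squared pruning, and a ReliefF relevance filter that keeps the SNPs most
informative about the phenotype (including purely interacting ones, which a
marginal scan cannot see).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, ttest_ind

from .types import GenotypeStudy

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    snps_removed_callrate: int
    snps_removed_hwe: int
    samples_removed_callrate: int
    snp_callrate_min: float
    sample_callrate_min: float
    hwe_alpha: float


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided Hardy-Weinberg exact test (Levene-Haldane distribution).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one. Monomorphic SNPs return 1.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0
    rare = min(n_minor, 2 * n - n_minor)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het = h | allele counts) under HWE, Levene-Haldane
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def _genotype_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (hom_minor, het, hom_major) counts over non-missing calls."""
    return (g == 2).sum(axis=0), (g == 1).sum(axis=0), (g == 0).sum(axis=0)


def apply_qc(
    study: GenotypeStudy,
    snp_callrate_min: float = 0.90,
    sample_callrate_min: float = 0.90,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeStudy, QcReport]:
    """Call-rate and Hardy-Weinberg filtering.

    Samples below ``sample_callrate_min`` are removed first; then SNPs with
    call-rate below ``snp_callrate_min`` or HWE exact p below ``hwe_alpha``
    (computed on all surviving samples). MAF is recomputed on survivors.
    """
    g = study.genotypes
    sample_cr = (g >= 0).mean(axis=1)
    keep_samples = np.flatnonzero(sample_cr >= sample_callrate_min)
    n_samples_removed = study.n_samples - keep_samples.size
    study = study.subset_samples(keep_samples)

    g = study.genotypes
    snp_cr = (g >= 0).mean(axis=0)
    low_cr = snp_cr < snp_callrate_min

    hom2, het, hom0 = _genotype_counts(g)
    hwe_p = np.array(
        [hwe_exact_p(int(h), int(a), int(b)) for h, a, b in zip(het, hom2, hom0)]
    )
    fail_hwe = hwe_p < hwe_alpha

    keep = ~(low_cr | fail_hwe)
    if not keep.any():
        raise ValueError("quality control removed every SNP")
    out = study.subset_snps(np.flatnonzero(keep))
    out.recompute_maf()
    report = QcReport(
        snps_removed_callrate=int(low_cr.sum()),
        snps_removed_hwe=int((fail_hwe & ~low_cr).sum()),
        samples_removed_callrate=int(n_samples_removed),
        snp_callrate_min=snp_callrate_min,
        sample_callrate_min=sample_callrate_min,
        hwe_alpha=hwe_alpha,
    )
    return out, report


def single_snp_association(study: GenotypeStudy) -> pd.DataFrame:
    """Cochran-Armitage trend test per SNP with additive scores (0, 1, 2).

    Returns a table with ``snp, statistic, p, genome_wide_significant``
    (flagged at the conventional 5e-8 threshold). Constant SNPs get
    statistic 0 and p = 1.
    """
    y = study.phenotype
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes are required for association testing")
    stats = np.zeros(study.n_snps)
    for k in range(study.n_snps):
        g = study.genotypes[:, k]
        ok = g >= 0
        gk, yk = g[ok], y[ok]
        n = gk.size
        counts = np.array([[(gk[yk == 1] == v).sum() for v in (0, 1, 2)],
                           [(gk[yk == 0] == v).sum() for v in (0, 1, 2)]], dtype=float)
        r = counts[0].sum()
        ni = counts.sum(axis=0)
        w = np.array([0.0, 1.0, 2.0])
        t_num = n * (w * counts[0]).sum() - r * (w * ni).sum()
        var = r * (n - r) * (n * (w**2 * ni).sum() - ((w * ni).sum()) ** 2)
        stats[k] = 0.0 if var <= 0 else n * t_num**2 / var
    p = chi2.sf(stats, df=1)
    p[stats == 0] = 1.0
    return pd.DataFrame(
        {
            "snp": study.snp_ids,
            "statistic": stats,
            "p": p,
            "genome_wide_significant": p < 5e-8,
        }
    )


def _pairwise_r2(ga: np.ndarray, gb: np.ndarray) -> float:
    ok = (ga >= 0) & (gb >= 0)
    if ok.sum() < 3:
        return 0.0
    a = ga[ok].astype(float)
    b = gb[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(
    study: GenotypeStudy, window: int = 50, step: int = 5, r2_max: float = 0.5
) -> GenotypeStudy:
    """Greedy sliding-window LD pruning on squared genotype correlation.

    Within each window of ``window`` SNPs (advanced by ``step``) on a
    chromosome, whenever a retained pair exceeds ``r2_max`` the member with
    the lower MAF is dropped (tie: the later position). Missing calls are
    ignored pairwise.
    """
    tbl = study.snp_table
    removed = np.zeros(study.n_snps, dtype=bool)
    for chrom in tbl["chrom"].unique():
        idx = np.flatnonzero((tbl["chrom"] == chrom).to_numpy())
        idx = idx[np.argsort(tbl["pos"].iloc[idx].to_numpy(), kind="stable")]
        start = 0
        while start < idx.size:
            win = idx[start : start + window]
            for a_pos in range(win.size):
                i = win[a_pos]
                if removed[i]:
                    continue
                for b_pos in range(a_pos + 1, win.size):
                    j = win[b_pos]
                    if removed[j]:
                        continue
                    r2 = _pairwise_r2(study.genotypes[:, i], study.genotypes[:, j])
                    if r2 > r2_max:
                        maf_i = tbl["maf"].iat[i]
                        maf_j = tbl["maf"].iat[j]
                        if np.isclose(maf_i, maf_j):
                            victim = i if tbl["pos"].iat[i] > tbl["pos"].iat[j] else j
                        else:
                            victim = i if maf_i < maf_j else j
                        removed[victim] = True
                        if victim == i:
                            break
            if start + window >= idx.size:
                break
            start += step
    return study.subset_snps(np.flatnonzero(~removed))


def relief_scores(study: GenotypeStudy, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF relevance score per SNP.

    Per-SNP genotype difference is ``|g_a - g_b| / 2``; neighbours are the
    k nearest hits and k nearest misses under Manhattan distance over
    co-observed SNPs. A SNP constant across samples scores exactly 0.
    """
    y = study.phenotype
    for cls in (0, 1):
        if (y == cls).sum() <= k_neighbors:
            raise ValueError(
                f"k_neighbors={k_neighbors} must be below the size of both classes"
            )
    g = study.genotypes.astype(np.int16)
    missing = g < 0
    n, p = g.shape
    gz = np.where(missing, 0, g)

    # pairwise Manhattan distances, ignoring pairs where either call is missing
    dist = np.zeros((n, n))
    chunk = max(1, int(2e7) // max(n * p, 1))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        diff = np.abs(gz[s:e, None, :] - gz[None, :, :]).astype(np.float32)
        pair_missing = missing[s:e, None, :] | missing[None, :, :]
        diff[pair_missing] = 0.0
        dist[s:e] = diff.sum(axis=2) / 2.0
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(p)
    denom = n * k_neighbors
    for s in range(n):
        same = np.flatnonzero(y == y[s])
        other = np.flatnonzero(y != y[s])
        hits = same[np.argsort(dist[s, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(dist[s, other], kind="stable")[:k_neighbors]]
        for group, sign in ((hits, -1.0), (misses, 1.0)):
            diff = np.abs(gz[group] - gz[s]) / 2.0
            diff[missing[group] | missing[s]] = 0.0
            w += sign * diff.sum(axis=0) / denom
    return w


def relief_filter(
    study: GenotypeStudy, keep: int, k_neighbors: int = 10
) -> GenotypeStudy:
    """Retain the ``keep`` most ReliefF-relevant SNPs (ties by SNP id)."""
    if keep > study.n_snps:
        raise ValueError(f"keep={keep} exceeds the {study.n_snps} available SNPs")
    scores = relief_scores(study, k_neighbors=k_neighbors)
    order = sorted(range(study.n_snps), key=lambda i: (-scores[i], study.snp_ids[i]))
    chosen = sorted(order[:keep])
    return study.subset_snps(chosen)


def load_top_snp_table() -> pd.DataFrame:
    """The published table of top-ranked metastasis-susceptibility SNPs.

    Columns: SNP id, nearest gene, chromosome, SNP-rank score, location
    class and population minor-allele frequency (one entry missing). Used
    as the reference input for :func:`maf_summary` reporting.
    """
    import importlib.resources

    with importlib.resources.files("metasoil").joinpath("data/top_snps.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def maf_summary(
    mafs: pd.Series | np.ndarray | list,
    comparison: pd.Series | np.ndarray | list | None = None,
) -> dict:
    """Median and quartiles of a MAF list (missing dropped, 2-dp rounding).

    Quartiles use the linear-interpolation convention. When a comparison
    MAF list is given, a Welch two-sample t statistic and p-value against
    it are included.
    """
    x = pd.Series(mafs, dtype=float).dropna().to_numpy()
    if x.size == 0:
        raise ValueError("no non-missing MAF values to summarise")
    out = {
        "n": int(x.size),
        "median": round(float(np.quantile(x, 0.5)), 2),
        "q1": round(float(np.quantile(x, 0.25)), 2),
        "q3": round(float(np.quantile(x, 0.75)), 2),
    }
    if comparison is not None:
        y = pd.Series(comparison, dtype=float).dropna().to_numpy()
        t, p = ttest_ind(x, y, equal_var=False)
        out["welch_t"] = float(t)
        out["welch_p"] = float(p)
    return out
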