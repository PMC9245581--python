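"""Regression-based genetic association interaction network and SNP ranking.

:func:`regain` fits, for every SNP pair, the logistic model
``phenotype ~ g_i + g_j + g_i*g_j`` and records the absolute Wald z of the
product term as the pair's epistatic interaction strength; the matrix
diagonal holds each SNP's univariate main-effect |z|. :func:`snprank` then
ranks SNPs by a damped eigenvector iteration on that matrix, with
teleportation weighted by main effects, so a variant is important when it
interacts strongly with other important variants.

Because additive genotypes are discrete, each pairwise fit depends on the
data only through its 2 x 3 x 3 case/control genotype-cell table; all pair
tables are produced with a handful of one-hot matrix products and the
logistic fits run as batched Newton iterations on those sufficient
statistics, making the O(n^2) scan feasible at thousands of SNPs. Samples
missing at either SNP of a pair simply drop out of the cell counts.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .types import GenotypeStudy, InteractionMatrix

logger = logging.getLogger(__name__)

_MAX_ITER = 40
_TOL = 1e-10
_COEF_CAP = 25.0  # |beta| beyond this signals separation

# shared cell designs: genotype cells (a, b) in row-major order
_CELLS_PAIR = np.array(
    [[1.0, a, b, a * b] for a in (0, 1, 2) for b in (0, 1, 2)]
)
_CELLS_SINGLE = np.array([[1.0, a] for a in (0, 1, 2)])


def _newton_cells(
    X: np.ndarray, n1: np.ndarray, n0: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched logistic regression on cell-level sufficient statistics.

    ``X`` (C, k) is the shared cell design; ``n1``/``n0`` (B, C) are the
    per-model case and control counts per cell. Returns
    (coef (B,k), se (B,k), ok (B,)); ``ok`` is False for non-converged,
    separated or singular fits.
    """
    k = X.shape[1]
    beta = np.zeros((n1.shape[0], k))
    nt = (n0 + n1).astype(float)
    ridge = 1e-9 * np.eye(k)
    for _ in range(_MAX_ITER):
        eta = np.clip(beta @ X.T, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = (n1 - nt * mu) @ X
        hess = np.einsum("bc,ck,cj->bkj", nt * mu * (1.0 - mu), X, X) + ridge
        try:
            delta = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("bkj,bj->bk", np.linalg.pinv(hess), grad)
        np.clip(delta, -5.0, 5.0, out=delta)
        beta += delta
        if np.abs(delta).max() < _TOL:
            break
    eta = np.clip(beta @ X.T, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    grad = (n1 - nt * mu) @ X
    hess = np.einsum("bc,ck,cj->bkj", nt * mu * (1.0 - mu), X, X) + ridge
    ok = np.abs(grad).max(axis=1) < 1e-4 * np.maximum(nt.sum(axis=1), 1.0)
    ok &= np.abs(beta).max(axis=1) < _COEF_CAP
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(hess)
        var = np.einsum("bkk->bk", cov)
        se = np.sqrt(np.maximum(var, 0.0))
    ok &= np.isfinite(se).all(axis=1) & (se > 0).all(axis=1)
    return beta, se, ok


def _onehot_by_class(
    genotypes: np.ndarray, phenotype: np.ndarray
) -> dict[int, list[np.ndarray]]:
    """Per class, per genotype value, a samples x SNPs 0/1 indicator.

    Missing calls (negative codes) are zero everywhere, so any product of
    indicators counts only co-observed samples.
    """
    out = {}
    for cls in (0, 1):
        in_cls = phenotype == cls
        out[cls] = [
            ((genotypes == v) & in_cls[:, None]).astype(np.float64)
            for v in (0, 1, 2)
        ]
    return out


def regain(study: GenotypeStudy, pair_batch: int = 50_000_000) -> InteractionMatrix:
    """Pairwise-interaction matrix from logistic regression Wald tests.

    Off-diagonal strength is |z| of the product term of
    ``phenotype ~ g_i + g_j + g_i*g_j`` over samples non-missing at both
    SNPs; the diagonal is the univariate main-effect |z|. Non-convergent or
    separated fits contribute strength 0 / p 1 (logged). Benjamini-Hochberg
    adjustment runs once over all n(n-1)/2 interaction p-values.
    """
    y = study.phenotype
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes are required")
    p_snp = study.n_snps
    if p_snp < 2:
        raise ValueError("need at least two SNPs")
    g = study.genotypes
    missing = g < 0
    degenerate = np.array(
        [np.unique(g[~missing[:, k], k]).size < 2 for k in range(p_snp)]
    )

    hot = _onehot_by_class(g, y)

    # diagonal: univariate fits from per-SNP cell counts
    n1_diag = np.stack([hot[1][v].sum(axis=0) for v in range(3)], axis=1)
    n0_diag = np.stack([hot[0][v].sum(axis=0) for v in range(3)], axis=1)
    coef, se, ok = _newton_cells(_CELLS_SINGLE, n1_diag, n0_diag)
    zdiag = np.where(
        ok & ~degenerate,
        np.abs(coef[:, 1]) / np.where(se[:, 1] > 0, se[:, 1], 1.0),
        0.0,
    )

    # all pair cell counts via one-hot matrix products
    counts = {}
    for cls in (0, 1):
        ind = hot[cls]
        for a in range(3):
            for b in range(a, 3):
                m = ind[a].T @ ind[b]
                counts[(cls, a, b)] = m
                if a != b:
                    counts[(cls, b, a)] = m.T

    iu = np.triu_indices(p_snp, k=1)
    n_pairs = iu[0].size
    n1 = np.empty((n_pairs, 9))
    n0 = np.empty((n_pairs, 9))
    for c, (a, b) in enumerate((a, b) for a in range(3) for b in range(3)):
        n1[:, c] = counts[(1, a, b)][iu]
        n0[:, c] = counts[(0, a, b)][iu]

    G = np.zeros((p_snp, p_snp))
    P = np.ones((p_snp, p_snp))
    np.fill_diagonal(G, zdiag)

    z_all = np.zeros(n_pairs)
    p_all = np.ones(n_pairs)
    batch = max(1, pair_batch // max(p_snp, 1))
    n_bad = 0
    for s in range(0, n_pairs, batch):
        e = min(n_pairs, s + batch)
        coef, se, ok = _newton_cells(_CELLS_PAIR, n1[s:e], n0[s:e])
        ok &= ~(degenerate[iu[0][s:e]] | degenerate[iu[1][s:e]])
        z = np.where(ok, np.abs(coef[:, 3]) / np.where(se[:, 3] > 0, se[:, 3], 1.0), 0.0)
        z_all[s:e] = z
        p_all[s:e] = np.where(ok, 2.0 * norm.sf(z), 1.0)
        n_bad += int((~ok).sum())
    if n_bad:
        logger.warning(
            "regain: %d of %d pairwise fits were degenerate, separated or "
            "non-convergent; their strength was set to 0 (p=1)",
            n_bad,
            n_pairs,
        )
    G[iu] = z_all
    G[(iu[1], iu[0])] = z_all
    P[iu] = p_all
    P[(iu[1], iu[0])] = p_all

    q_flat = multipletests(p_all, method="fdr_bh")[1]
    Q = np.ones((p_snp, p_snp))
    Q[iu] = q_flat
    Q[(iu[1], iu[0])] = q_flat
    return InteractionMatrix(snp_ids=study.snp_ids, G=G, p=P, q=Q)


def _column_stochastic(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = G.shape[0]
    offdiag = G - np.diag(np.diag(G))
    d = offdiag.sum(axis=0)
    A = np.empty((n, n))
    nonzero = d > 0
    A[:, nonzero] = offdiag[:, nonzero] / d[nonzero]
    A[:, ~nonzero] = 1.0 / n
    trace = float(np.trace(G))
    u = np.diag(G) / trace if trace > 0 else np.full(n, 1.0 / n)
    return A, u


def snprank(
    im: InteractionMatrix,
    gamma: float = 0.85,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Damped eigenvector ranking of SNPs on the interaction matrix.

    The score vector is the fixed point of ``r = gamma * A r + (1-gamma) * u``
    where ``A`` is the off-diagonal part of G with columns normalised to
    their sums (zero columns redistribute uniformly) and the teleportation
    vector ``u`` is proportional to the main-effect diagonal,
    ``u_i = G_ii / trace(G)``. Scores are normalised to sum to one; ranks
    are by descending score with ties broken by SNP id.
    """
    G = np.asarray(im.G, dtype=float)
    if np.trace(G) <= 0:
        warnings.warn("snprank: trace(G) is zero; returning uniform scores")
    A, u = _column_stochastic(G)
    n = G.shape[0]
    r = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        r_new = gamma * (A @ r) + (1.0 - gamma) * u
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    r = r / r.sum()

    order = sorted(range(n), key=lambda i: (-r[i], im.snp_ids[i]))
    ranks = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return pd.DataFrame({"snp": im.snp_ids, "score": r, "rank": ranks})


def snprank_fixed_point(im: InteractionMatrix, gamma: float = 0.85) -> np.ndarray:
    """Dense linear-system solution of the snprank update (oracle route).

    Solves ``(I - gamma A) r = (1 - gamma) u`` directly and normalises —
    the exact fixed point that the power iteration approaches.
    """
    G = np.asarray(im.G, dtype=float)
    A, u = _column_stochastic(G)
    n = G.shape[0]
    r = np.linalg.solve(np.eye(n) - gamma * A, (1.0 - gamma) * u)
    return r / r.sum()


def select_top(ranks: pd.DataFrame, keep: int) -> list[str]:
    """Top ``keep`` SNP ids by rank (deterministic under the tie rule)."""
    if keep > len(ranks):
        raise ValueError(f"keep={keep} exceeds {len(ranks)} ranked SNPs")
    return list(ranks.sort_values("rank")["snp"].iloc[:keep])


def write_interactions(im: InteractionMatrix, out_dir: str) -> None:
    """Serialise as long-format TSV plus a sidecar main-effect diagonal."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    iu = np.triu_indices(im.n, k=1)
    ids = np.asarray(im.snp_ids)
    pd.DataFrame(
        {
            "snp_a": ids[iu[0]],
            "snp_b": ids[iu[1]],
            "strength": im.G[iu],
            "p": im.p[iu],
            "q": im.q[iu],
        }
    ).to_csv(os.path.join(out_dir, "interactions.tsv"), sep="\t", index=False)
    pd.DataFrame({"snp": ids, "main_effect": np.diag(im.G)}).to_csv(
        os.path.join(out_dir, "main_effects.tsv"), sep="\t", index=False
    )


def read_interactions(out_dir: str) -> InteractionMatrix:
    import os

    long = pd.read_csv(os.path.join(out_dir, "interactions.tsv"), sep="\t")
    diag = pd.read_csv(os.path.join(out_dir, "main_effects.tsv"), sep="\t")
    ids = list(diag["snp"])
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    G = np.zeros((n, n))
    P = np.ones((n, n))
    Q = np.ones((n, n))
    np.fill_diagonal(G, diag["main_effect"].to_numpy())
    ai = long["snp_a"].map(index).to_numpy()
    bi = long["snp_b"].map(index).to_numpy()
    G[ai, bi] = G[bi, ai] = long["strength"].to_numpy()
    P[ai, bi] = P[bi, ai] = long["p"].to_numpy()
    Q[ai, bi] = Q[bi, ai] = long["q"].to_numpy()
    return InteractionMatrix(snp_ids=ids, G=G, p=P, q=Q)
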