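"""Mutual-information regulatory network inference with DPI pruning.

A TF->target network is inferred from tumour expression in three steps:

1. plug-in mutual information between each TF and every other gene, on an
   equal-frequency binning of the rank-transformed vectors (robust to
   monotone transforms of expression);
2. a per-TF permutation null (the TF vector shuffled against all
   candidates, pooled) gives empirical p-values, Benjamini-Hochberg
   adjusted over all TF-candidate pairs, plus a bootstrap stability filter
   (the edge must clear the per-TF null threshold in a fraction of sample
   bootstraps);
3. data-processing-inequality pruning removes, in every closed
   TF-TF-target triplet, the weakest interaction (within a tolerance),
   keeping the dominant direct pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ExpressionStudy, RegulatoryNetwork

logger = logging.getLogger(__name__)


def _rank_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin index of each value.

    Ties share the bin of their smallest rank, so a constant vector falls
    entirely into bin 0 (and MI against anything is exactly zero).
    """
    n = x.size
    sorted_x = np.sort(x, kind="mergesort")
    min_rank = np.searchsorted(sorted_x, x, side="left")
    return (min_rank * bins) // n


def _mi_from_joint(counts: np.ndarray) -> np.ndarray:
    """MI in nats from joint count arrays of shape (..., B, B)."""
    n = counts.sum(axis=(-2, -1), keepdims=True).astype(float)
    p = counts / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(px) - np.log(py))
    return np.where(counts > 0, terms, 0.0).sum(axis=(-2, -1))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 6) -> float:
    """Plug-in mutual information (nats) on equal-frequency 2-D binning.

    Both vectors are rank-transformed before binning; a constant vector
    yields MI = 0 (all mass in one marginal bin).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3 * bins:
        raise ValueError(f"need at least 3*bins={3 * bins} observations")
    bx = _rank_bins(x, bins)
    by = _rank_bins(y, bins)
    counts = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(counts, (bx, by), 1)
    return float(max(0.0, _mi_from_joint(counts)))


def _mi_many(tf_bins: np.ndarray, gene_bins: np.ndarray, bins: int) -> np.ndarray:
    """MI between one binned vector and many binned rows at once."""
    g, n = gene_bins.shape
    codes = gene_bins * bins + tf_bins[None, :]
    offs = (np.arange(g)[:, None] * bins * bins + codes).ravel()
    counts = np.bincount(offs, minlength=g * bins * bins).reshape(g, bins, bins)
    return np.maximum(0.0, _mi_from_joint(counts))


def infer_edges(
    expr: ExpressionStudy,
    tf_list: list[str],
    n_perm: int = 1000,
    q_max: float = 0.01,
    n_boot: int = 100,
    stability_min: float = 0.95,
    bins: int = 6,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Permutation-significant, bootstrap-stable TF->candidate edges.

    Tumour samples are used. Per TF, the MI null is built by shuffling the
    TF's expression ``n_perm`` times against all candidates (pooled);
    empirical p-values are BH-adjusted over all pairs and an edge must also
    exceed the per-TF null threshold (the ``1 - q_max`` null quantile) in
    at least ``stability_min`` of ``n_boot`` sample bootstraps. With
    ``n_boot = 0`` the stability filter is skipped and flagged.
    """
    missing = [tf for tf in tf_list if tf not in expr.values.index]
    if missing:
        raise ValueError(f"TFs absent from the expression matrix: {missing[:5]}")
    samples = expr.samples_with_role("tumour")
    mat = expr.values.loc[:, samples]
    genes = list(mat.index)
    data = mat.to_numpy()
    n = data.shape[1]
    rng = np.random.default_rng(seed)

    all_bins = np.vstack([_rank_bins(row, bins) for row in data])
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for tf in sorted(tf_list):
        ti = gene_pos[tf]
        cand_idx = np.array([i for i in range(len(genes)) if i != ti])
        cand_bins = all_bins[cand_idx]
        tf_bins = all_bins[ti]
        mi_obs = _mi_many(tf_bins, cand_bins, bins)

        null = np.empty(n_perm * cand_idx.size)
        for p_i in range(n_perm):
            perm = rng.permutation(tf_bins)
            null[p_i * cand_idx.size : (p_i + 1) * cand_idx.size] = _mi_many(
                perm, cand_bins, bins
            )
        null.sort()
        # empirical p with add-one correction
        n_ge = null.size - np.searchsorted(null, mi_obs, side="left")
        pvals = (1.0 + n_ge) / (null.size + 1.0)
        threshold = float(np.quantile(null, 1.0 - q_max))

        if n_boot > 0:
            present = np.zeros(cand_idx.size)
            tf_raw = data[ti]
            cand_raw = data[cand_idx]
            for _ in range(n_boot):
                bs = rng.integers(0, n, size=n)
                tb = _rank_bins(tf_raw[bs], bins)
                cb = np.vstack([_rank_bins(row[bs], bins) for row in cand_raw])
                present += _mi_many(tb, cb, bins) > threshold
            stability = present / n_boot
        else:
            stability = np.ones(cand_idx.size)

        for k, ci in enumerate(cand_idx):
            rows.append((tf, genes[ci], float(mi_obs[k]), float(pvals[k]), float(stability[k])))

    table = pd.DataFrame(rows, columns=["tf", "target", "mi", "p", "stability"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    keep = table["q"] < q_max
    if n_boot > 0:
        keep &= table["stability"] >= stability_min
    edges = table.loc[keep, ["tf", "target", "mi", "p", "q", "stability"]].reset_index(
        drop=True
    )
    if n_boot == 0:
        logger.warning("infer_edges: bootstrap stability filter skipped (n_boot=0)")
    return RegulatoryNetwork(
        tfs=set(tf_list), edges=edges, stability_filtered=n_boot > 0
    )


def dpi_prune(net: RegulatoryNetwork, tolerance: float = 0.1) -> RegulatoryNetwork:
    """ARACNe-style data-processing-inequality pruning.

    For every triplet {TF1->target, TF2->target, TF1<->TF2 (either
    direction)}, the minimum-MI edge is marked for removal if its MI is
    below ``(1 - tolerance)`` times the second-smallest MI of the triplet.
    All triplets are evaluated on the original MI values in a single pass;
    marked edges are removed afterwards.
    """
    edges = net.edges
    mi = {}
    for tf, tg, m in zip(edges["tf"], edges["target"], edges["mi"]):
        mi[(tf, tg)] = m
    regulators: dict[str, list[str]] = {}
    for tf, tg in mi:
        regulators.setdefault(tg, []).append(tf)

    def tf_tf_edge(a: str, b: str):
        if (a, b) in mi:
            return (a, b)
        if (b, a) in mi:
            return (b, a)
        return None

    to_remove: set[tuple[str, str]] = set()
    for target, regs in regulators.items():
        regs_sorted = sorted(regs)
        for i in range(len(regs_sorted)):
            for j in range(i + 1, len(regs_sorted)):
                tf1, tf2 = regs_sorted[i], regs_sorted[j]
                if target in (tf1, tf2):
                    continue
                tt = tf_tf_edge(tf1, tf2)
                if tt is None:
                    continue
                triplet = [(tf1, target), (tf2, target), tt]
                vals = sorted((mi[e], e) for e in triplet)
                if vals[0][0] < (1.0 - tolerance) * vals[1][0]:
                    to_remove.add(vals[0][1])
    keep_mask = [
        (tf, tg) not in to_remove for tf, tg in zip(edges["tf"], edges["target"])
    ]
    return RegulatoryNetwork(
        tfs=set(net.tfs),
        edges=edges.loc[keep_mask].reset_index(drop=True),
        communities=net.communities,
        bowtie=net.bowtie,
        stability_filtered=net.stability_filtered,
    )


def regulon_summary(
    net: RegulatoryNetwork, subset: set[str] | list[str]
) -> tuple[float, float | None]:
    """Mean regulon size of ``subset`` TFs and of the complement TFs."""
    subset = set(subset)
    unknown = subset - net.tfs
    if unknown:
        raise ValueError(f"subset TFs not in the network: {sorted(unknown)[:5]}")
    regs = net.regulons
    sub_sizes = [len(regs.get(tf, set())) for tf in subset]
    comp = {tf for tf in regs if tf not in subset}
    comp_sizes = [len(regs[tf]) for tf in comp]
    mean_sub = float(np.mean(sub_sizes)) if sub_sizes else float("nan")
    mean_comp = float(np.mean(comp_sizes)) if comp_sizes else None
    return mean_sub, mean_comp


def degree_summary(net: RegulatoryNetwork) -> dict[str, float]:
    """Scale-free-style degree summary of the directed network.

    Reports the median total degree and the fraction of genes whose degree
    is below twice the median — the shape statistics used to describe
    hub-dominated regulatory maps.
    """
    deg: dict[str, int] = {}
    for tf, tg in zip(net.edges["tf"], net.edges["target"]):
        deg[tf] = deg.get(tf, 0) + 1
        deg[tg] = deg.get(tg, 0) + 1
    values = np.array(sorted(deg.values()))
    if values.size == 0:
        return {"median_degree": float("nan"), "frac_below_2x_median": float("nan")}
    med = float(np.median(values))
    return {
        "median_degree": med,
        "frac_below_2x_median": float((values < 2 * med).mean()),
    }


def write_grn(net: RegulatoryNetwork, out_dir: str) -> None:
    """Edge list TSV plus regulons as GMT (set name = TF)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    net.edges.to_csv(os.path.join(out_dir, "grn_edges.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "regulons.gmt"), "w") as fh:
        for tf, targets in sorted(net.regulons.items()):
            fh.write("\t".join([tf, "regulon"] + sorted(targets)) + "\n")
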