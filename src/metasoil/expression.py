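"""Expression indices, differential-expression screens, stemness screen.

The central statistic is the per-gene, per-sample Z-score against a
reference role: Z_tg = (E_tg - mean_c E_cg) / sd_c E_cg, comparing e.g.
each tumour sample against the control distribution of the gene. A gene's
*expression index* is the proportion of in-scope samples with |Z| above a
cut (default 1.96, the two-sided 5% normal point); a gene counts as
expressed when the index exceeds a threshold calibrated on random
pseudo-genes (the fixed default 0.35 reproduces the random-model
calibration used with a large tumour cohort). The same machinery with
roles swapped gives the metastasis expression index (metastasis samples
referenced to tumours).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionStudy

logger = logging.getLogger(__name__)

DEFAULT_INDEX_THRESHOLD = 0.35


def zscore_vs_reference(
    expr: ExpressionStudy, target_role: str, reference_role: str
) -> pd.DataFrame:
    """Per-gene Z of every target-role sample against the reference role.

    The reference SD uses the n-1 denominator. Genes with zero reference
    variance are excluded (logged).
    """
    targets = expr.samples_with_role(target_role)
    refs = expr.samples_with_role(reference_role)
    if not targets or not refs:
        raise ValueError(
            f"roles {target_role!r}/{reference_role!r} must both be present"
        )
    if len(refs) < 2:
        raise ValueError("need at least two reference samples")
    ref = expr.values[refs]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    ok = sd > 0
    if (~ok).any():
        logger.info(
            "zscore_vs_reference: dropped %d genes with zero reference variance: %s",
            int((~ok).sum()),
            list(expr.values.index[~ok][:5]),
        )
    z = expr.values.loc[ok, targets].sub(mu[ok], axis=0).div(sd[ok], axis=0)
    return z


def expression_index(z: pd.DataFrame, z_cut: float = 1.96) -> pd.DataFrame:
    """Proportion of in-scope samples with |Z| > z_cut, per gene."""
    index = (z.abs() > z_cut).mean(axis=1)
    return pd.DataFrame({"index": index})


def calibrate_index_threshold(
    expr: ExpressionStudy,
    n_random: int = 10_000,
    quantile: float = 0.95,
    z_cut: float = 1.96,
    seed: int = 0,
) -> float:
    """Random-pseudo-gene calibration of the expression-index threshold.

    Pseudo-genes are built by resampling expression values with replacement
    from the pooled matrix; the threshold is the requested quantile of
    their tumour-expression-index distribution, i.e. the index value that
    fewer than ``1 - quantile`` of random genes exceed.
    """
    tumour = expr.samples_with_role("tumour")
    control = expr.samples_with_role("control")
    if not tumour or not control:
        raise ValueError("tumour and control roles must both be present")
    rng = np.random.default_rng(seed)
    pool = expr.values.to_numpy().ravel()
    n_col = len(control) + len(tumour)
    draws = rng.choice(pool, size=(n_random, n_col), replace=True)
    ref = draws[:, : len(control)]
    tum = draws[:, len(control):]
    mu = ref.mean(axis=1, keepdims=True)
    sd = ref.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.inf
    idx = (np.abs((tum - mu) / sd) > z_cut).mean(axis=1)
    return float(np.quantile(idx, quantile))


def expressed_by_subtype(
    expr: ExpressionStudy,
    z: pd.DataFrame,
    threshold: float = DEFAULT_INDEX_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene, per-subtype expressed flags (strict ``index > threshold``).

    Subtypes with fewer than five samples are still scored but flagged
    low-confidence. Adds an ``all_subtypes`` column: expressed everywhere.
    """
    if expr.subtype is None:
        raise ValueError("subtype labels are required")
    sub = expr.subtype
    flags = {}
    low_conf = []
    for subtype in sorted(sub.unique()):
        cols = [s for s in z.columns if s in sub.index and sub[s] == subtype]
        if not cols:
            continue
        if len(cols) < 5:
            low_conf.append(subtype)
        flags[subtype] = (z[cols].abs() > 1.96).mean(axis=1) > threshold
    if low_conf:
        logger.warning(
            "expressed_by_subtype: low-confidence subtypes (<5 samples): %s", low_conf
        )
    out = pd.DataFrame(flags)
    out["all_subtypes"] = out.all(axis=1)
    return out


def differential_expression(
    expr: ExpressionStudy,
    group_a: str,
    group_b: str,
    lfc_min: float = 1.0,
    p_or_q_max: float = 0.01,
    adjust: str = "BH",
    strict_lfc: bool = True,
) -> pd.DataFrame:
    """Welch-t differential expression between two sample roles.

    Inputs are assumed log2-scale, so logFC is the plain group-mean
    difference. ``adjust`` is ``"BH"`` or ``"none"``; ``strict_lfc``
    controls whether the fold-change cut is strict (>) or not (>=), to
    mirror whichever spelling the screen at hand uses.
    """
    a_cols = expr.samples_with_role(group_a)
    b_cols = expr.samples_with_role(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least two samples per group")
    a = expr.values[a_cols].to_numpy()
    b = expr.values[b_cols].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # both groups constant and equal -> no evidence
    p = np.where(np.isnan(p), 1.0, p)
    if adjust == "BH":
        q = multipletests(p, method="fdr_bh")[1]
        crit = q
    elif adjust == "none":
        q = np.full_like(p, np.nan)
        crit = p
    else:
        raise ValueError(f"unknown adjust mode {adjust!r}")
    lfc_pass = np.abs(lfc) > lfc_min if strict_lfc else np.abs(lfc) >= lfc_min
    return pd.DataFrame(
        {
            "gene": expr.values.index,
            "logFC": lfc,
            "t": t,
            "p": p,
            "q": q,
            "pass": lfc_pass & (crit < p_or_q_max),
        }
    ).set_index("gene")


def stemness_screen(expr: ExpressionStudy, p_max: float = 1e-10) -> pd.DataFrame:
    """Genes whose tumour expression correlates with the stemness index.

    Pearson correlation over tumour samples, two-sided p from the t
    transform; constant genes are excluded. Returns genes with p < p_max.
    """
    if expr.stemness is None:
        raise ValueError("stemness index is required")
    tumour = expr.samples_with_role("tumour")
    s = expr.stemness[tumour].to_numpy(dtype=float)
    mat = expr.values[tumour].to_numpy(dtype=float)
    n = len(tumour)
    xs = mat - mat.mean(axis=1, keepdims=True)
    ss = s - s.mean()
    denom = np.sqrt((xs**2).sum(axis=1) * (ss**2).sum())
    ok = denom > 0
    r = np.zeros(mat.shape[0])
    r[ok] = (xs @ ss)[ok] / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(r**2 >= 1.0, 0.0, p)
    out = pd.DataFrame({"gene": expr.values.index, "r": r, "p": p}).set_index("gene")
    out = out[ok]
    return out[out["p"] < p_max]
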