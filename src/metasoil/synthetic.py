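"""Synthetic cohort generators.

Three generators emulate the data every downstream stage assumes:

* :func:`simulate_genotypes` — a case/control genotype panel with a uniform
  minor-allele-frequency spectrum, independent null SNPs, and planted SNP
  pairs whose *interaction* (not their marginal effects) drives the binary
  phenotype, mirroring an extreme-discordant-phenotype design in which
  single-variant association finds nothing;
* :func:`simulate_expression` — control/tumour/metastasis expression with
  planted TF->target regulons, dysregulated genes, a latent stemness factor
  and PAM50-style subtype labels;
* :func:`simulate_survival` — exponential event times whose hazard depends
  on the mean expression of a designated gene set, with independent
  censoring.

Each generator derives its own RNG stream from ``(config.seed, name)`` so
adding or re-running one generator never perturbs another's output.
"""

from __future__ import annotations

import json
import os
import zlib

import numpy as np
import pandas as pd

from .types import ExpressionStudy, GenotypeStudy, GroundTruth, SimulationConfig

_MAX_BATCHES = 500

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")
_SUBTYPE_P = (0.40, 0.20, 0.15, 0.15, 0.10)


def _rng(config: SimulationConfig, name: str) -> np.random.Generator:
    """One independent stream per generator, seeded by (seed, name hash)."""
    return np.random.default_rng([config.seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeStudy, GroundTruth]:
    """Generate a case/control genotype study with planted epistatic pairs.

    Null SNP genotypes are ``Binomial(2, MAF)`` independent of phenotype.
    The phenotype is drawn from a logistic model whose log-odds is::

        sum over planted pairs (i, j) of
            marginal_effect * (g_i + g_j)
            + ln(interaction_odds_ratio) * (g_i - 2 maf_i) * (g_j - 2 maf_j)

    The product term is mean-centred so each planted SNP has (in
    expectation) no marginal effect when ``marginal_effect`` is zero.
    Individuals are rejection-sampled until the requested case and control
    counts are reached, emulating a fixed extreme-phenotype design.
    """
    rng = _rng(config, "genotypes")
    n_snps = config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=n_snps)

    planted = rng.choice(n_snps, size=2 * config.n_epistatic_pairs, replace=False)
    pairs = [(int(planted[2 * k]), int(planted[2 * k + 1])) for k in range(config.n_epistatic_pairs)]

    n_needed = config.n_cases + config.n_controls
    beta_int = np.log(config.interaction_odds_ratio)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    batch = max(4 * n_needed, 64)
    for _ in range(_MAX_BATCHES):
        g = rng.binomial(2, mafs, size=(batch, n_snps)).astype(np.int8)
        eta = np.zeros(batch)
        for i, j in pairs:
            gi = g[:, i].astype(float)
            gj = g[:, j].astype(float)
            eta += config.marginal_effect * (gi + gj)
            eta += beta_int * (gi - 2 * mafs[i]) * (gj - 2 * mafs[j])
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for row, case in zip(g, is_case):
            if case and len(cases) < config.n_cases:
                cases.append(row)
            elif not case and len(controls) < config.n_controls:
                controls.append(row)
        if len(cases) >= config.n_cases and len(controls) >= config.n_controls:
            break
    else:
        short = "n_cases" if len(cases) < config.n_cases else "n_controls"
        raise RuntimeError(
            f"could not reach the requested {short} after {_MAX_BATCHES} sampling "
            "batches; interaction_odds_ratio/marginal_effect make one class too rare"
        )

    genotypes = np.vstack(cases + controls)
    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8), np.zeros(config.n_controls, dtype=np.int8)]
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n_needed)]

    # lay SNPs on chromosomes 1..22 in blocks, positions ascending in-block
    per_chrom = int(np.ceil(n_snps / 22))
    chrom = 1 + np.arange(n_snps) // per_chrom
    pos = 10_000 * (1 + np.arange(n_snps) % per_chrom)
    snp_table = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "maf": np.nan,
        }
    )
    study = GenotypeStudy(sample_ids, phenotype, genotypes, snp_table)
    study.recompute_maf()
    truth = GroundTruth(
        epistatic_pairs=[
            (study.snp_table["snp"].iat[i], study.snp_table["snp"].iat[j]) for i, j in pairs
        ]
    )
    return study, truth


def make_annotation(
    study: GenotypeStudy, n_genes: int, margin: int = 500
) -> pd.DataFrame:
    """Tile the study's SNPs with synthetic gene bodies.

    Consecutive SNPs on the same chromosome are grouped into gene bodies
    whose 1-based interval covers the group with ``margin`` bp of flank,
    giving the SNP-to-gene mapping stage something realistic to chew on.
    Gene ids share the ``G####`` namespace of the expression generator so a
    SNP-level finding can be carried into the regulatory analysis.
    """
    snps_per_gene = max(1, int(np.ceil(study.n_snps / n_genes)))
    rows = []
    gene_idx = 0
    i = 0
    tbl = study.snp_table
    while i < study.n_snps:
        chrom = tbl["chrom"].iat[i]
        j = i
        while j < study.n_snps and j - i < snps_per_gene and tbl["chrom"].iat[j] == chrom:
            j += 1
        start = max(1, int(tbl["pos"].iloc[i:j].min()) - margin)
        end = int(tbl["pos"].iloc[i:j].max()) + margin
        rows.append((f"G{(gene_idx % n_genes) + 1:04d}", chrom, start, end))
        gene_idx += 1
        i = j
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    # a gene id must not recur (duplicate ids would straddle chromosomes)
    return ann.drop_duplicates(subset="gene", keep="first").reset_index(drop=True)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate control/tumour/metastasis expression with planted structure.

    TF expression is Normal(10, 2) per sample; each target gene follows its
    TF linearly (sign drawn per edge) plus Gaussian noise; genes outside any
    regulon are independent noise. Dysregulated genes are shifted by
    ``dysregulation_shift`` control-SD units in tumour samples and twice
    that in metastasis samples. A latent stemness factor drives a designated
    gene subset and the per-sample stemness index.
    """
    rng = _rng(config, "expression")
    genes = _gene_ids(config.n_genes)
    tfs = genes[: config.n_tfs]
    non_tf = genes[config.n_tfs :]

    rlo, rhi = config.regulon_size_range
    sizes = rng.integers(rlo, rhi + 1, size=config.n_tfs)
    if sizes.sum() > len(non_tf):
        raise ValueError(
            f"regulon_size_range {config.regulon_size_range} infeasible: "
            f"needs {int(sizes.sum())} targets but only {len(non_tf)} non-TF genes"
        )
    pool = list(rng.permutation(non_tf))
    regulons: dict[str, set[str]] = {}
    cursor = 0
    for tf, size in zip(tfs, sizes):
        regulons[tf] = set(pool[cursor : cursor + int(size)])
        cursor += int(size)
    regulated = set().union(*regulons.values()) if regulons else set()

    n_c, n_t, n_m = (
        config.n_control_samples,
        config.n_tumour_samples,
        config.n_metastasis_samples,
    )
    samples = (
        [f"C{i + 1:04d}" for i in range(n_c)]
        + [f"T{i + 1:04d}" for i in range(n_t)]
        + [f"M{i + 1:04d}" for i in range(n_m)]
    )
    roles = pd.Series(["control"] * n_c + ["tumour"] * n_t + ["metastasis"] * n_m, index=samples)
    n_samples = len(samples)

    expr = pd.DataFrame(
        10.0 + 2.0 * rng.standard_normal((config.n_genes, n_samples)),
        index=genes,
        columns=samples,
    )
    # a shallow TF hierarchy: the first TF drives a few other TFs at
    # moderate coupling (r = 0.7, marginal SD kept at 2), giving the
    # inferred network TF-TF edges (closed DPI triplets) and a bow-tie
    # core of intermediate regulators; moderate coupling keeps the
    # indirect master->grand-target association the weakest member of its
    # triplet, which is what DPI assumes
    if config.tf_hierarchy and config.n_tfs >= 2:
        master = tfs[0]
        sub_tfs = tfs[1 : 1 + max(1, config.n_tfs // 3)]
        master_row = expr.loc[master].to_numpy()
        for tf in sub_tfs:
            expr.loc[tf] = (
                10.0
                + 0.7 * (master_row - 10.0)
                + 2.0 * np.sqrt(1.0 - 0.49) * rng.standard_normal(n_samples)
            )
        regulons[master] |= set(sub_tfs)
    tf_set = set(tfs)
    for tf in tfs:
        tf_row = expr.loc[tf].to_numpy()
        for target in sorted(regulons[tf]):
            if target in tf_set:
                continue  # hierarchy rows already drawn
            beta = config.regulon_beta * (1.0 if rng.random() < 0.5 else -1.0)
            noise = config.regulon_noise_sd * rng.standard_normal(n_samples)
            expr.loc[target] = (10.0 - beta * 10.0) + beta * tf_row + noise

    free = sorted(set(non_tf) - regulated)
    # stemness genes: coupled to a latent per-sample factor
    n_stem = min(20, max(0, len(free) - config.n_dysregulated))
    stem_genes = set(free[:n_stem])
    factor = rng.standard_normal(n_samples)
    for gene in sorted(stem_genes):
        expr.loc[gene] = 10.0 + 1.6 * factor + 1.2 * rng.standard_normal(n_samples)
    stemness = pd.Series(factor + 0.3 * rng.standard_normal(n_samples), index=samples)

    dys_pool = free[n_stem:]
    # half of the dysregulated genes sit inside regulons (dysregulation in
    # tumours is largely a regulated phenomenon); the tumour-wide constant
    # shift leaves within-role ranks, hence TF-target MI, untouched
    n_in_regulon = min(config.n_dysregulated // 2, len(regulated))
    dys_regulated = list(rng.permutation(sorted(regulated))[:n_in_regulon])
    n_free_needed = config.n_dysregulated - n_in_regulon
    if n_free_needed > len(dys_pool):
        raise ValueError(
            f"n_dysregulated={config.n_dysregulated} exceeds the available "
            f"{len(dys_pool)} free genes plus {len(regulated)} regulon targets"
        )
    dys_genes = set(dys_regulated) | set(dys_pool[:n_free_needed])
    dys_pool = dys_pool[n_free_needed:]
    tumour_cols = [s for s in samples if roles[s] == "tumour"]
    met_cols = [s for s in samples if roles[s] == "metastasis"]
    control_cols = [s for s in samples if roles[s] == "control"]
    for gene in sorted(dys_genes):
        sd = float(expr.loc[gene, control_cols].std(ddof=1))
        expr.loc[gene, tumour_cols] += config.dysregulation_shift * sd
        expr.loc[gene, met_cols] += 2.0 * config.dysregulation_shift * sd

    subtype = pd.Series(
        rng.choice(SUBTYPES, size=len(tumour_cols), p=_SUBTYPE_P), index=tumour_cols
    )

    hazard_pool = dys_pool or sorted(free)
    hazard_set = set(hazard_pool[: min(10, len(hazard_pool))])

    study = ExpressionStudy(values=expr, roles=roles, subtype=subtype, stemness=stemness)
    truth = GroundTruth(
        dysregulated_genes=dys_genes,
        true_regulons=regulons,
        hazard_gene_set=hazard_set,
        stemness_genes=stem_genes,
    )
    return study, truth


def simulate_survival(
    expression: ExpressionStudy, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Exponential survival for the tumour samples.

    The per-sample event rate is ``baseline_hazard * exp(coef * score)``
    where ``score`` is the standardized mean expression of the hazard gene
    set. Censoring is independent: a Bernoulli(``censoring_rate``) coin per
    sample, censored records truncated uniformly before their event time.
    Returns a DataFrame with columns ``sample, time, event``.
    """
    if not truth.hazard_gene_set <= set(expression.genes):
        missing = truth.hazard_gene_set - set(expression.genes)
        raise ValueError(f"hazard_gene_set genes absent from expression: {sorted(missing)[:5]}")
    rng = _rng(config, "survival")
    samples = expression.samples_with_role("tumour")
    sub = expression.values.loc[sorted(truth.hazard_gene_set), samples]
    score = sub.mean(axis=0).to_numpy()
    sd = score.std(ddof=0)
    score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    rate = config.baseline_hazard * np.exp(config.gene_set_hazard_coef * score)
    time = rng.exponential(1.0 / rate)
    censored = rng.random(len(samples)) < config.censoring_rate
    u = rng.random(len(samples))
    time = np.where(censored, time * u, time)
    return pd.DataFrame(
        {"sample": samples, "time": time, "event": (~censored).astype(int)}
    )


def write_study(
    out_dir: str | os.PathLike, config: SimulationConfig
) -> dict[str, str]:
    """Run all generators and write plain-text fixtures to ``out_dir``.

    Writes PLINK .bed/.bim/.fam, expression and sample-metadata TSVs, a
    survival TSV, a BED-like gene annotation, a TF list, and the ground
    truth as JSON. Returns the path of every artefact.
    """
    from .plink import write_bed

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    geno, geno_truth = simulate_genotypes(config)
    expr, expr_truth = simulate_expression(config)
    surv = simulate_survival(expr, expr_truth, config)

    prefix = os.path.join(out_dir, "cohort")
    write_bed(geno, prefix)

    expr.values.rename_axis("gene").to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
    meta = pd.DataFrame(
        {
            "sample": expr.values.columns,
            "role": expr.roles[expr.values.columns].to_numpy(),
            "subtype": [
                expr.subtype.get(s, "") if expr.subtype is not None else ""
                for s in expr.values.columns
            ],
            "stemness": expr.stemness[expr.values.columns].to_numpy(),
        }
    )
    meta.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)
    surv.to_csv(os.path.join(out_dir, "survival.tsv"), sep="\t", index=False)

    ann = make_annotation(geno, config.n_genes)
    # BED-like on disk: 0-based half-open
    bed = ann.assign(start=ann["start"] - 1)[["chrom", "start", "end", "gene"]]
    bed.to_csv(os.path.join(out_dir, "genes.bed"), sep="\t", index=False, header=False)

    with open(os.path.join(out_dir, "tfs.txt"), "w") as fh:
        for tf in sorted(expr_truth.true_regulons):
            fh.write(tf + "\n")

    truth = {
        "epistatic_pairs": [list(p) for p in geno_truth.epistatic_pairs],
        "dysregulated_genes": sorted(expr_truth.dysregulated_genes),
        "true_regulons": {k: sorted(v) for k, v in expr_truth.true_regulons.items()},
        "hazard_gene_set": sorted(expr_truth.hazard_gene_set),
        "stemness_genes": sorted(expr_truth.stemness_genes),
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)

    return {
        "bfile": prefix,
        "expression": os.path.join(out_dir, "expression.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "survival": os.path.join(out_dir, "survival.tsv"),
        "annotation": os.path.join(out_dir, "genes.bed"),
        "tfs": os.path.join(out_dir, "tfs.txt"),
        "truth": os.path.join(out_dir, "ground_truth.json"),
    }
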