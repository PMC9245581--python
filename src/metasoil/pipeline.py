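"""End-to-end orchestration with a run manifest and stage caching.

A plain-text INI configuration drives the chain
simulate -> qc -> interact -> epinet -> grn -> index -> module -> survive.
Every stage logs its parameters, hashes its inputs and outputs into a JSON
manifest, and is skipped on re-run when parameters and input hashes are
unchanged. The same seed therefore reproduces identical manifest hashes.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import epistasis, expression, genotype_qc, interaction, metastasis, plink
from . import regulatory, survival, synthetic
from .types import ExpressionStudy, SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "interact", "epinet", "grn", "index", "module", "survive"]

_KNOWN_KEYS: dict[str, set[str]] = {
    "global": {"seed", "out_dir"},
    "simulate": {
        "enabled", "n_cases", "n_controls", "n_snps", "n_epistatic_pairs",
        "interaction_odds_ratio", "marginal_effect", "n_genes", "n_tfs",
        "n_dysregulated", "dysregulation_shift", "censoring_rate",
        "baseline_hazard", "gene_set_hazard_coef", "n_control_samples",
        "n_tumour_samples", "n_metastasis_samples", "maf_min", "maf_max",
        "tf_hierarchy",
    },
    "qc": {
        "enabled", "snp_callrate", "sample_callrate", "hwe", "prune_r2",
        "prune_window", "prune_step", "relief_keep", "relief_k",
    },
    "interact": {"enabled", "gamma", "keep"},
    "epinet": {"enabled", "q", "window"},
    "grn": {"enabled", "perm", "boot", "stability", "q", "dpi_tol", "bins"},
    "index": {"enabled", "z", "threshold", "de_lfc", "de_q", "stemness_p"},
    "module": {"enabled", "iters", "enrich_q"},
    "survive": {"enabled", "n_random"},
}


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_config(path: str) -> dict[str, dict[str, str]]:
    """Parse and validate the INI run configuration."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    cfg: dict[str, dict[str, str]] = {}
    for section in parser.sections():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"unknown configuration section [{section}]")
        for key in parser[section]:
            if key not in _KNOWN_KEYS[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
        cfg[section] = dict(parser[section])
    return cfg


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = cfg.get("simulate", {})
    g = lambda k, d, cast: cast(sim.get(k, d))  # noqa: E731
    return SimulationConfig(
        n_cases=g("n_cases", 400, int),
        n_controls=g("n_controls", 400, int),
        n_snps=g("n_snps", 500, int),
        maf_range=(g("maf_min", 0.05, float), g("maf_max", 0.5, float)),
        n_epistatic_pairs=g("n_epistatic_pairs", 5, int),
        interaction_odds_ratio=g("interaction_odds_ratio", 3.0, float),
        marginal_effect=g("marginal_effect", 0.0, float),
        n_genes=g("n_genes", 300, int),
        n_tfs=g("n_tfs", 10, int),
        n_dysregulated=g("n_dysregulated", 30, int),
        dysregulation_shift=g("dysregulation_shift", 2.0, float),
        censoring_rate=g("censoring_rate", 0.3, float),
        baseline_hazard=g("baseline_hazard", 0.1, float),
        gene_set_hazard_coef=g("gene_set_hazard_coef", 1.0, float),
        n_control_samples=g("n_control_samples", 30, int),
        n_tumour_samples=g("n_tumour_samples", 100, int),
        n_metastasis_samples=g("n_metastasis_samples", 30, int),
        tf_hierarchy=str(sim.get("tf_hierarchy", "true")).lower() != "false",
        seed=seed,
    )


def read_expression_study(expr_path: str, meta_path: str) -> ExpressionStudy:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str}).set_index("sample")
    subtype = meta["subtype"].replace("", np.nan).dropna() if "subtype" in meta else None
    stemness = meta["stemness"] if "stemness" in meta else None
    return ExpressionStudy(
        values=values,
        roles=meta["role"],
        subtype=subtype,
        stemness=stemness,
    )


def run_pipeline(config_path: str) -> dict:
    """Execute the configured stages in dependency order; return manifest."""
    cfg = load_config(config_path)
    out_dir = cfg.get("global", {}).get("out_dir", "metasoil_run")
    seed = int(cfg.get("global", {}).get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)

    manifest_path = os.path.join(out_dir, "manifest.json")
    previous = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})
    manifest: dict = {"config": cfg, "seed": seed, "stages": {}}

    def enabled(stage: str) -> bool:
        return cfg.get(stage, {}).get("enabled", "true").lower() != "false"

    def run_stage(stage: str, params: dict, inputs: list[str], fn) -> None:
        if not enabled(stage):
            logger.info("stage %s disabled", stage)
            return
        in_hashes = {p: _hash_file(p) for p in inputs if os.path.exists(p)}
        prev = previous.get(stage)
        if (
            prev
            and prev.get("params") == {k: str(v) for k, v in params.items()}
            and prev.get("inputs") == in_hashes
            and all(os.path.exists(p) for p in prev.get("outputs", {}))
            and all(_hash_file(p) == h for p, h in prev.get("outputs", {}).items())
        ):
            logger.info("stage %s: cached, skipping", stage)
            manifest["stages"][stage] = dict(prev, cached=True)
            return
        logger.info("stage %s: running with %s", stage, params)
        outputs = fn()
        manifest["stages"][stage] = {
            "params": {k: str(v) for k, v in params.items()},
            "inputs": in_hashes,
            "outputs": {p: _hash_file(p) for p in outputs},
            "cached": False,
        }

    sim_dir = os.path.join(out_dir, "sim")
    paths = {
        "bfile": os.path.join(sim_dir, "cohort"),
        "expression": os.path.join(sim_dir, "expression.tsv"),
        "samples": os.path.join(sim_dir, "samples.tsv"),
        "survival": os.path.join(sim_dir, "survival.tsv"),
        "annotation": os.path.join(sim_dir, "genes.bed"),
        "tfs": os.path.join(sim_dir, "tfs.txt"),
        "truth": os.path.join(sim_dir, "ground_truth.json"),
    }

    # ---- simulate ----------------------------------------------------
    sim_conf = _sim_config(cfg, seed)
    def do_simulate():
        synthetic.write_study(sim_dir, sim_conf)
        return [paths["bfile"] + ext for ext in (".bed", ".bim", ".fam")] + [
            paths[k] for k in ("expression", "samples", "survival", "annotation", "tfs", "truth")
        ]
    run_stage("simulate", sim_conf.__dict__, [], do_simulate)

    # ---- qc ----------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    qc_prefix = os.path.join(out_dir, "qc", "cohort")
    qc_params = {
        "snp_callrate": float(qc_cfg.get("snp_callrate", 0.90)),
        "sample_callrate": float(qc_cfg.get("sample_callrate", 0.90)),
        "hwe": float(qc_cfg.get("hwe", 1e-6)),
        "prune_r2": float(qc_cfg.get("prune_r2", 0.5)),
        "prune_window": int(qc_cfg.get("prune_window", 50)),
        "prune_step": int(qc_cfg.get("prune_step", 5)),
        "relief_keep": int(qc_cfg.get("relief_keep", 0)),
        "relief_k": int(qc_cfg.get("relief_k", 10)),
    }
    def do_qc():
        os.makedirs(os.path.dirname(qc_prefix), exist_ok=True)
        study = plink.read_bed(paths["bfile"])
        study, report = genotype_qc.apply_qc(
            study, qc_params["snp_callrate"], qc_params["sample_callrate"], qc_params["hwe"]
        )
        study = genotype_qc.ld_prune(
            study, qc_params["prune_window"], qc_params["prune_step"], qc_params["prune_r2"]
        )
        if qc_params["relief_keep"] and qc_params["relief_keep"] < study.n_snps:
            study = genotype_qc.relief_filter(
                study, qc_params["relief_keep"], qc_params["relief_k"]
            )
        plink.write_bed(study, qc_prefix)
        with open(qc_prefix + ".qc.json", "w") as fh:
            json.dump(report.__dict__, fh, indent=1)
        return [qc_prefix + ext for ext in (".bed", ".bim", ".fam", ".qc.json")]
    run_stage(
        "qc", qc_params, [paths["bfile"] + ext for ext in (".bed", ".bim", ".fam")], do_qc
    )

    # ---- interact ----------------------------------------------------
    int_cfg = cfg.get("interact", {})
    int_dir = os.path.join(out_dir, "interact")
    int_params = {
        "gamma": float(int_cfg.get("gamma", 0.85)),
        "keep": int(int_cfg.get("keep", 0)),
    }
    def do_interact():
        study = plink.read_bed(qc_prefix)
        im = interaction.regain(study)
        interaction.write_interactions(im, int_dir)
        ranks = interaction.snprank(im, gamma=int_params["gamma"])
        ranks.to_csv(os.path.join(int_dir, "snprank.tsv"), sep="\t", index=False)
        keep = int_params["keep"] or len(ranks)
        top = interaction.select_top(ranks, min(keep, len(ranks)))
        with open(os.path.join(int_dir, "top_snps.txt"), "w") as fh:
            fh.write("\n".join(top) + "\n")
        return [
            os.path.join(int_dir, f)
            for f in ("interactions.tsv", "main_effects.tsv", "snprank.tsv", "top_snps.txt")
        ]
    run_stage("interact", int_params, [qc_prefix + ".bed"], do_interact)

    # ---- epinet ------------------------------------------------------
    epi_cfg = cfg.get("epinet", {})
    epi_dir = os.path.join(out_dir, "epinet")
    epi_params = {
        "q": float(epi_cfg.get("q", 0.01)),
        "window": int(epi_cfg.get("window", 1_000_000)),
    }
    def do_epinet():
        os.makedirs(epi_dir, exist_ok=True)
        im = interaction.read_interactions(int_dir)
        study = plink.read_bed(qc_prefix)
        ann = epistasis.load_annotation_bed(paths["annotation"])
        snp2gene, unassigned = epistasis.map_snps_to_genes(
            study.snp_table, ann, window=epi_params["window"]
        )
        net = epistasis.build_gene_network(im, snp2gene, q_max=epi_params["q"])
        central: list[str] = []
        if net.graph.number_of_edges() > 0:
            net = epistasis.link_communities(net)
            central = epistasis.top_central_genes(net, fraction=0.10)
        epistasis.write_network(net, epi_dir)
        with open(os.path.join(epi_dir, "central_genes.txt"), "w") as fh:
            fh.write("\n".join(central) + ("\n" if central else ""))
        with open(os.path.join(epi_dir, "summary.json"), "w") as fh:
            json.dump(
                {
                    "n_genes": net.graph.number_of_nodes(),
                    "n_links": net.graph.number_of_edges(),
                    "n_unassigned_snps": len(unassigned),
                },
                fh,
            )
        return [
            os.path.join(epi_dir, f)
            for f in ("epistasis_edges.tsv", "gene_centrality.tsv", "central_genes.txt", "summary.json")
        ]
    run_stage(
        "epinet",
        epi_params,
        [os.path.join(int_dir, "interactions.tsv"), paths["annotation"]],
        do_epinet,
    )

    # ---- grn ---------------------------------------------------------
    grn_cfg = cfg.get("grn", {})
    grn_dir = os.path.join(out_dir, "grn")
    grn_params = {
        "perm": int(grn_cfg.get("perm", 200)),
        "boot": int(grn_cfg.get("boot", 50)),
        "stability": float(grn_cfg.get("stability", 0.95)),
        "q": float(grn_cfg.get("q", 0.01)),
        "dpi_tol": float(grn_cfg.get("dpi_tol", 0.1)),
        "bins": int(grn_cfg.get("bins", 6)),
    }
    def do_grn():
        expr = read_expression_study(paths["expression"], paths["samples"])
        with open(paths["tfs"]) as fh:
            tfs = [line.strip() for line in fh if line.strip()]
        net = regulatory.infer_edges(
            expr,
            tfs,
            n_perm=grn_params["perm"],
            q_max=grn_params["q"],
            n_boot=grn_params["boot"],
            stability_min=grn_params["stability"],
            bins=grn_params["bins"],
            seed=seed,
        )
        net = regulatory.dpi_prune(net, tolerance=grn_params["dpi_tol"])
        regulatory.write_grn(net, grn_dir)
        return [os.path.join(grn_dir, f) for f in ("grn_edges.tsv", "regulons.gmt")]
    run_stage(
        "grn", grn_params, [paths["expression"], paths["samples"], paths["tfs"]], do_grn
    )

    # ---- index -------------------------------------------------------
    idx_cfg = cfg.get("index", {})
    idx_dir = os.path.join(out_dir, "index")
    idx_params = {
        "z": float(idx_cfg.get("z", 1.96)),
        "threshold": idx_cfg.get("threshold", "0.35"),
        "de_lfc": float(idx_cfg.get("de_lfc", 1.0)),
        "de_q": float(idx_cfg.get("de_q", 0.01)),
        "stemness_p": float(idx_cfg.get("stemness_p", 1e-10)),
    }
    def do_index():
        os.makedirs(idx_dir, exist_ok=True)
        expr = read_expression_study(paths["expression"], paths["samples"])
        z_t = expression.zscore_vs_reference(expr, "tumour", "control")
        tumour_index = expression.expression_index(z_t, z_cut=idx_params["z"])
        z_m = expression.zscore_vs_reference(expr, "metastasis", "tumour")
        met_index = expression.expression_index(z_m, z_cut=idx_params["z"])
        if idx_params["threshold"] == "auto":
            threshold = expression.calibrate_index_threshold(expr, seed=seed)
        else:
            threshold = float(idx_params["threshold"])
        tumour_index["expressed"] = tumour_index["index"] > threshold
        met_index["dysregulated"] = met_index["index"] > threshold
        de = expression.differential_expression(
            expr, "metastasis", "control",
            lfc_min=idx_params["de_lfc"], p_or_q_max=idx_params["de_q"],
        )
        stem = expression.stemness_screen(expr, p_max=idx_params["stemness_p"])
        seeds = metastasis.merge_seeds(
            set(de.index[de["pass"]]),
            set(stem.index),
            set(met_index.index[met_index["dysregulated"]]),
        )
        tumour_index.rename_axis("gene").to_csv(os.path.join(idx_dir, "tumour_index.tsv"), sep="\t")
        met_index.rename_axis("gene").to_csv(os.path.join(idx_dir, "metastasis_index.tsv"), sep="\t")
        de.to_csv(os.path.join(idx_dir, "de.tsv"), sep="\t")
        stem.to_csv(os.path.join(idx_dir, "stemness.tsv"), sep="\t")
        with open(os.path.join(idx_dir, "seeds.txt"), "w") as fh:
            fh.write("\n".join(sorted(seeds.union)) + "\n")
        with open(os.path.join(idx_dir, "seed_sizes.json"), "w") as fh:
            json.dump(seeds.sizes(), fh)
        return [
            os.path.join(idx_dir, f)
            for f in ("tumour_index.tsv", "metastasis_index.tsv", "de.tsv",
                      "stemness.tsv", "seeds.txt", "seed_sizes.json")
        ]
    run_stage(
        "index", idx_params, [paths["expression"], paths["samples"]], do_index
    )

    # ---- module ------------------------------------------------------
    mod_cfg = cfg.get("module", {})
    mod_dir = os.path.join(out_dir, "module")
    mod_params = {
        "iters": int(mod_cfg.get("iters", 200)),
        "enrich_q": float(mod_cfg.get("enrich_q", 0.001)),
    }
    def do_module():
        os.makedirs(mod_dir, exist_ok=True)
        edges = pd.read_csv(os.path.join(grn_dir, "grn_edges.tsv"), sep="\t")
        with open(paths["tfs"]) as fh:
            tfs = {line.strip() for line in fh if line.strip()}
        from .types import RegulatoryNetwork

        net = RegulatoryNetwork(tfs=tfs, edges=edges)
        with open(os.path.join(idx_dir, "seeds.txt")) as fh:
            seeds = {line.strip() for line in fh if line.strip()}
        seeds_in = seeds & net.nodes
        trace = pd.DataFrame(columns=["gene", "step", "p"])
        if seeds_in:
            trace = metastasis.diamond_expand(net, seeds_in, n_iter=mod_params["iters"])
        module_genes = seeds_in | set(trace["gene"])
        sub_edges = edges[
            edges["tf"].isin(module_genes) & edges["target"].isin(module_genes)
        ].reset_index(drop=True)
        sub = RegulatoryNetwork(tfs=tfs & module_genes, edges=sub_edges)
        bt = metastasis.bowtie(sub) if len(sub_edges) else pd.DataFrame(
            columns=["S_v", "T_v", "b", "core"]
        )
        gene_sets = metastasis.read_gmt(os.path.join(grn_dir, "regulons.gmt"))
        labels, enrich = ({}, pd.DataFrame())
        if len(sub_edges) and gene_sets:
            labels, enrich = metastasis.communities_and_enrichment(
                sub, gene_sets, q_max=mod_params["enrich_q"]
            )
        central_path = os.path.join(epi_dir, "central_genes.txt")
        central: list[str] = []
        if os.path.exists(central_path):
            with open(central_path) as fh:
                central = [line.strip() for line in fh if line.strip()]
        mapping = metastasis.map_to_grn(central, sub) if len(sub_edges) else {
            "mapped": set(), "tfs": set(), "targets_of_tfs": set()
        }
        trace.to_csv(os.path.join(mod_dir, "diamond_trace.tsv"), sep="\t", index=False)
        bt.to_csv(os.path.join(mod_dir, "bowtie.tsv"), sep="\t")
        enrich.to_csv(os.path.join(mod_dir, "enrichment.tsv"), sep="\t", index=False)
        with open(os.path.join(mod_dir, "summary.json"), "w") as fh:
            json.dump(
                {
                    "module_size": len(module_genes),
                    "n_tfs": len(sub.tfs),
                    "n_targets": len(set(sub_edges["target"]) - tfs),
                    "core_size": int(bt["core"].sum()) if len(bt) else 0,
                    "mapped_central": sorted(mapping["mapped"]),
                    "mapped_tfs": sorted(mapping["tfs"]),
                    "targets_of_mapped_tfs": sorted(mapping["targets_of_tfs"]),
                    "communities": {str(k): v for k, v in labels.items()},
                },
                fh,
                indent=1,
            )
        return [
            os.path.join(mod_dir, f)
            for f in ("diamond_trace.tsv", "bowtie.tsv", "enrichment.tsv", "summary.json")
        ]
    run_stage(
        "module",
        mod_params,
        [os.path.join(grn_dir, "grn_edges.tsv"), os.path.join(idx_dir, "seeds.txt")],
        do_module,
    )

    # ---- survive -----------------------------------------------------
    sur_cfg = cfg.get("survive", {})
    sur_dir = os.path.join(out_dir, "survive")
    sur_params = {"n_random": int(sur_cfg.get("n_random", 1000))}
    def do_survive():
        os.makedirs(sur_dir, exist_ok=True)
        expr = read_expression_study(paths["expression"], paths["samples"])
        surv = pd.read_csv(paths["survival"], sep="\t", dtype={"sample": str})
        with open(paths["truth"]) as fh:
            truth = json.load(fh)
        results = []
        sets = {"hazard_truth_set": truth["hazard_gene_set"]}
        regulons_path = os.path.join(grn_dir, "regulons.gmt")
        if os.path.exists(regulons_path):
            for tf, members in sorted(metastasis.read_gmt(regulons_path).items())[:3]:
                if members:
                    sets[f"regulon_{tf}"] = sorted(members)
        for name, genes in sets.items():
            try:
                res = survival.empirical_vs_random(
                    expr, genes, surv, n_random=sur_params["n_random"], seed=seed
                )
            except ValueError as exc:
                logger.warning("survive: %s skipped (%s)", name, exc)
                continue
            results.append(
                (name, len(res.gene_set), res.logrank_stat, res.p, res.empirical_p, res.n_random)
            )
        pd.DataFrame(
            results,
            columns=["gene_set", "size", "logrank_stat", "p", "empirical_p", "n_random"],
        ).to_csv(os.path.join(sur_dir, "survival_results.tsv"), sep="\t", index=False)
        return [os.path.join(sur_dir, "survival_results.tsv")]
    run_stage(
        "survive",
        sur_params,
        [paths["expression"], paths["survival"], paths["truth"]],
        do_survive,
    )

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
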