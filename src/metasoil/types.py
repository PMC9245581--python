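"""Shared domain containers.

Conventions used throughout the package:

* genotypes are additive minor-allele counts in ``{0, 1, 2}`` stored as
  ``int8`` with ``-1`` marking a missing call;
* phenotype is binary, ``1`` = case (low-risk patient who relapsed),
  ``0`` = control (high-risk patient who did not relapse);
* expression matrices are genes x samples DataFrames on a log-like
  continuous scale, with per-sample roles in
  ``{"control", "tumour", "metastasis"}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

PHENOTYPE_CASE = "relapsed_low_risk"
PHENOTYPE_CONTROL = "nonrelapsed_high_risk"

ROLES = ("control", "tumour", "metastasis")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generators.

    The defaults describe a desk-scale cohort: a balanced case/control
    genotype panel with a handful of planted purely-epistatic SNP pairs, an
    expression study with planted TF regulons and dysregulated genes, and
    exponential survival whose hazard tracks a designated gene set.
    """

    n_cases: int = 400
    n_controls: int = 400
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_epistatic_pairs: int = 5
    interaction_odds_ratio: float = 3.0
    marginal_effect: float = 0.0
    n_genes: int = 300
    n_tfs: int = 10
    regulon_size_range: tuple[int, int] = (8, 15)
    n_dysregulated: int = 30
    dysregulation_shift: float = 2.0
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1
    gene_set_hazard_coef: float = 1.0
    seed: int = 0
    # sample layout of the expression study
    n_control_samples: int = 30
    n_tumour_samples: int = 100
    n_metastasis_samples: int = 30
    # TF -> target linear model
    regulon_beta: float = 1.0
    regulon_noise_sd: float = 1.0
    # couple a few TFs under a master regulator (bow-tie-style core);
    # off by default: TF expression is then mutually independent
    tf_hierarchy: bool = False

    def __post_init__(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_snps": self.n_snps,
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_control_samples": self.n_control_samples,
            "n_tumour_samples": self.n_tumour_samples,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_epistatic_pairs < 0 or self.n_dysregulated < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError(f"censoring_rate must be in [0,1], got {self.censoring_rate}")
        if self.interaction_odds_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("interaction_odds_ratio and baseline_hazard must be positive")
        if 2 * self.n_epistatic_pairs > self.n_snps:
            raise ValueError("2 * n_epistatic_pairs must not exceed n_snps")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        rlo, rhi = self.regulon_size_range
        if not (1 <= rlo <= rhi):
            raise ValueError(f"invalid regulon_size_range {self.regulon_size_range}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study, for parameter-recovery tests."""

    epistatic_pairs: list[tuple[str, str]] = field(default_factory=list)
    dysregulated_genes: set[str] = field(default_factory=set)
    true_regulons: dict[str, set[str]] = field(default_factory=dict)
    hazard_gene_set: set[str] = field(default_factory=set)
    stemness_genes: set[str] = field(default_factory=set)


@dataclass
class GenotypeStudy:
    """Additive-coded case/control genotypes plus per-SNP metadata.

    ``snp_table`` columns: ``snp, chrom, pos, a1, a2, maf`` where ``a1`` is
    the minor allele and ``pos`` is 1-based.
    """

    sample_ids: list[str]
    phenotype: np.ndarray  # int8, 1 = case
    genotypes: np.ndarray  # (n_samples, n_snps) int8, -1 missing
    snp_table: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_table["snp"])

    def subset_snps(self, keep: np.ndarray | list[int]) -> "GenotypeStudy":
        keep = np.asarray(keep)
        return GenotypeStudy(
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype.copy(),
            genotypes=self.genotypes[:, keep].copy(),
            snp_table=self.snp_table.iloc[keep].reset_index(drop=True),
        )

    def subset_samples(self, keep: np.ndarray | list[int]) -> "GenotypeStudy":
        keep = np.asarray(keep)
        return GenotypeStudy(
            sample_ids=[self.sample_ids[i] for i in keep],
            phenotype=self.phenotype[keep].copy(),
            genotypes=self.genotypes[keep].copy(),
            snp_table=self.snp_table.copy().reset_index(drop=True),
        )

    def recompute_maf(self) -> None:
        """Refresh the ``maf`` column from non-missing genotypes."""
        g = self.genotypes
        mask = g >= 0
        with np.errstate(invalid="ignore"):
            freq = np.where(
                mask.sum(axis=0) > 0,
                np.where(g > 0, g, 0).sum(axis=0) / (2.0 * np.maximum(mask.sum(axis=0), 1)),
                np.nan,
            )
        self.snp_table["maf"] = np.minimum(freq, 1.0 - freq)


@dataclass
class InteractionMatrix:
    """Symmetric SNP x SNP matrix of epistatic interaction strengths.

    Off-diagonal ``G[i, j]`` is the absolute Wald z of the i x j product
    term in a pairwise logistic model; the diagonal holds each SNP's
    main-effect |z|. ``p`` carries two-sided interaction p-values and ``q``
    their Benjamini-Hochberg adjustment over all pairs.
    """

    snp_ids: list[str]
    G: np.ndarray
    p: np.ndarray
    q: np.ndarray

    @property
    def n(self) -> int:
        return len(self.snp_ids)


@dataclass
class ExpressionStudy:
    """Genes x samples expression with sample roles and optional annotations."""

    values: pd.DataFrame  # genes x samples
    roles: pd.Series  # per sample, in ROLES
    subtype: pd.Series | None = None  # per tumour sample
    stemness: pd.Series | None = None  # per sample

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.roles.index)
        if missing:
            raise ValueError(f"samples without a role label: {sorted(missing)[:5]}")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.values.columns if self.roles[s] == role]


@dataclass
class RegulatoryNetwork:
    """Directed TF->target network with regulons and topology annotations.

    ``edges`` columns: ``tf, target, mi, p, q, stability``. ``communities``
    and ``bowtie`` are filled by the metastasis-module stage.
    """

    tfs: set[str]
    edges: pd.DataFrame
    communities: dict[str, int] | None = None
    bowtie: pd.DataFrame | None = None
    stability_filtered: bool = True

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target"])

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["tf"]) | set(self.edges["target"])

    @property
    def regulons(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {tf: set() for tf in set(self.edges["tf"])}
        for tf, tg in zip(self.edges["tf"], self.edges["target"]):
            out[tf].add(tg)
        return out
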