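import numpy as np
import pandas as pd
import pytest

from metasoil.types import ExpressionStudy, GenotypeStudy, SimulationConfig


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_cases=60,
        n_controls=60,
        n_snps=50,
        n_epistatic_pairs=2,
        n_genes=80,
        n_tfs=5,
        regulon_size_range=(5, 8),
        n_dysregulated=10,
        n_control_samples=20,
        n_tumour_samples=50,
        n_metastasis_samples=15,
        seed=7,
    )


def make_study(genotypes: np.ndarray, phenotype: np.ndarray, **snp_cols) -> GenotypeStudy:
    """Hand-built genotype study with sensible defaults for metadata."""
    n_samples, n_snps = genotypes.shape
    table = pd.DataFrame(
        {
            "snp": snp_cols.get("snp", [f"rs{i}" for i in range(n_snps)]),
            "chrom": snp_cols.get("chrom", [1] * n_snps),
            "pos": snp_cols.get("pos", list(range(1000, 1000 + 100 * n_snps, 100))),
            "a1": "A",
            "a2": "G",
            "maf": np.nan,
        }
    )
    study = GenotypeStudy(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        phenotype=np.asarray(phenotype, dtype=np.int8),
        genotypes=np.asarray(genotypes, dtype=np.int8),
        snp_table=table,
    )
    study.recompute_maf()
    return study


def make_expression(values: np.ndarray, roles: list[str], genes=None, **extra) -> ExpressionStudy:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    kwargs = {}
    if "stemness" in extra:
        kwargs["stemness"] = pd.Series(extra["stemness"], index=samples)
    if "subtype" in extra:
        kwargs["subtype"] = pd.Series(extra["subtype"])
    return ExpressionStudy(
        values=pd.DataFrame(values, index=genes, columns=samples),
        roles=pd.Series(roles, index=samples),
        **kwargs,
    )
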