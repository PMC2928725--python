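"""Phenotype generation from two QTL genotypes under a cell-means model.

Each individual's trait value is the genotypic mean of its two-locus
genotype class plus independent standard-normal error:
``y_k = theta[g_A(k), g_B(k)] + e_k``, ``e_k ~ N(0, error_sd^2)``.
Phenotype units are residual-SD units, so a means table with range 1.6 is an
effect size of 1.6 SD between the extreme genotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalsim import GenotypeMatrix
from .models import GenotypeMeansTable

__all__ = ["PhenotypeConfig", "generate_phenotypes"]


@dataclass(frozen=True)
class PhenotypeConfig:
    table: GenotypeMeansTable
    qtl_a: int  # column index of locus A in the genotype matrix
    qtl_b: int  # column index of locus B
    error_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError("error_sd must be >= 0")


def generate_phenotypes(
    genotypes: GenotypeMatrix | np.ndarray, config: PhenotypeConfig
) -> np.ndarray:
    """Trait values for every individual; deterministic given the seed."""
    G = genotypes.genotypes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    ga = np.asarray(G[:, config.qtl_a])
    gb = np.asarray(G[:, config.qtl_b])
    for name, g in (("qtl_a", ga), ("qtl_b", gb)):
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(
                f"{name} column contains entries outside {{0, 1, 2}} or missing data"
            )
    rng = np.random.default_rng(config.seed)
    y = config.table.theta[ga, gb]
    if config.error_sd > 0:
        y = y + rng.normal(0.0, config.error_sd, size=y.shape)
    return y
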