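"""End-to-end driver: expression + genotypes + covariates -> sQTL calls.

Chains the preprocessing filters, the per-variant Hellinger pseudo-F test,
the adaptive gene-level permutation scheme, BH FDR over genes and the
retrieval of all significant variant-gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc import AssociationResult, map_gene
from .io import CovariateTable, ExpressionTable, GeneAnnotation, GenotypeTable
from .mtc import GeneLevelResult, SignificantPairSet, gene_empirical_p, significant_pairs
from .preprocess import (
    GeneSkipped,
    adjust_covariates,
    compute_ratios,
    filter_variants,
)


@dataclass
class MappingResult:
    """Everything one tissue-level mapping run produces."""

    assoc: list  # AssociationResult records
    genes: list  # GeneLevelResult records
    pairs: SignificantPairSet | None
    skipped: dict = field(default_factory=dict)  # gene_id -> reason


def map_tissue(
    expr: ExpressionTable,
    geno: GenotypeTable,
    genes: dict[str, GeneAnnotation],
    covariates: CovariateTable | None = None,
    mode: str = "approx",
    seed: int = 0,
    fdr: float = 0.05,
    b_min: int = 100,
    b_max: int = 1000,
    hit_target: int = 10,
    n_fit_perms: int = 100,
    n_homosc_perms: int = 999,
    window: int = 5000,
) -> MappingResult:
    """Map cis sQTLs for every gene of one tissue dataset.

    Genes failing the expression filters are recorded in ``skipped`` with a
    reason code; genes without testable variants are skipped silently (the
    empty variant set is a valid outcome). ``seed`` drives one random stream
    consumed gene by gene in a fixed order, so runs are reproducible.
    """
    rng = np.random.default_rng(seed)
    assoc_all: list[AssociationResult] = []
    gene_all: list[GeneLevelResult] = []
    skipped: dict[str, str] = {}
    expressed = set(expr.gene_id)
    for gene_id in sorted(genes):
        if gene_id not in expressed:
            continue
        ann = genes[gene_id]
        try:
            ratios = compute_ratios(expr, gene_id)
        except GeneSkipped as exc:
            skipped[gene_id] = exc.reason
            continue
        pheno = adjust_covariates(ratios, covariates)
        vset = filter_variants(geno, ann, ratios.samples, window=window)
        if len(vset) == 0:
            skipped[gene_id] = "no_testable_variants"
            continue
        assoc_all.extend(map_gene(
            pheno, vset, mode=mode, seed=rng,
            n_fit_perms=n_fit_perms, n_homosc_perms=n_homosc_perms,
        ))
        gres = gene_empirical_p(
            pheno, vset, seed=rng, b_min=b_min, b_max=b_max,
            hit_target=hit_target, n_fit_perms=n_fit_perms,
        )
        if gres is not None:
            gene_all.append(gres)
    pairs = significant_pairs(gene_all, assoc_all, fdr=fdr) if gene_all else None
    return MappingResult(assoc=assoc_all, genes=gene_all, pairs=pairs, skipped=skipped)
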