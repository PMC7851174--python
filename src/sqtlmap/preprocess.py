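"""From raw tables to the testable multivariate splicing phenotype.

For each gene with at least two annotated transcript isoforms:

* the gene is kept only if its TPM (sum of transcript TPMs) is >= 1 in at
  least 80% of the cohort (rounding up); samples below 1 TPM are dropped
  from that gene's analysis;
* transcripts below 0.1 TPM in every sample are removed;
* splicing ratios are the transcript TPMs divided by the post-filter
  transcript sum, so every retained row sums to 1 exactly;
* ratios are square-root transformed and known covariates are regressed out
  per transcript coordinate (ordinary least squares with intercept,
  categoricals one-hot encoded with the reference level dropped); on the
  sqrt scale the Hellinger distance is Euclidean, so residualisation
  preserves the distance geometry of the test.

Variants are restricted to the cis window (gene body plus 5 kb on each
side) and must be biallelic with MAF >= 0.01 and at least 10 samples in
every observed dosage group, evaluated on the gene's retained samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CovariateTable, ExpressionTable, GeneAnnotation, GenotypeTable

CIS_WINDOW = 5000
MIN_GENE_TPM = 1.0
MIN_EXPRESSED_FRACTION = 0.8
MIN_TRANSCRIPT_TPM = 0.1
MIN_MAF = 0.01
MIN_GROUP_SIZE = 10


class GeneSkipped(Exception):
    """Gene cannot be phenotyped; ``reason`` is a machine-readable code."""

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}")


@dataclass
class SplicingRatioMatrix:
    """Per-gene compositional phenotype: samples x transcripts, rows sum to 1."""

    gene_id: str
    samples: list
    transcripts: list
    ratios: np.ndarray
    dropped_samples: dict = field(default_factory=dict)
    dropped_transcripts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (len(self.samples), len(self.transcripts)):
            raise ValueError("ratio matrix shape mismatch")
        if len(self.transcripts) < 2:
            raise ValueError("need at least two transcripts")
        sums = self.ratios.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("retained rows must sum to 1 within 1e-9")


@dataclass
class AdjustedPhenotype:
    """Covariate-corrected sqrt-scale phenotype of one gene.

    ``matrix`` holds per-transcript OLS residuals of the sqrt-ratios;
    ``sqrt_grand_mean`` the per-transcript mean sqrt-ratio added back when
    converting to adjusted relative expression.
    """

    gene_id: str
    samples: list
    transcripts: list
    matrix: np.ndarray
    sqrt_grand_mean: np.ndarray


@dataclass
class TestableVariantSet:
    """Variants testable for one gene, dosages aligned to retained samples."""

    gene_id: str
    cis_window: tuple
    variants: dict  # variant_id -> int dosage vector (missing = -1)

    def items(self):
        return self.variants.items()

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------


def compute_ratios(expr: ExpressionTable, gene: str) -> SplicingRatioMatrix:
    """Filtered splicing-ratio matrix of ``gene`` (see module docstring)."""
    tpm = expr.gene_subset(gene)
    if tpm.shape[0] < 2:
        raise GeneSkipped(gene, "fewer_than_two_transcripts")
    samples = list(tpm.columns)
    mat = tpm.to_numpy(dtype=float)
    gene_tpm = mat.sum(axis=0)

    n = len(samples)
    n_expressed = int((gene_tpm >= MIN_GENE_TPM).sum())
    if n_expressed < int(np.ceil(MIN_EXPRESSED_FRACTION * n)):
        raise GeneSkipped(gene, "low_gene_expression")

    dropped_samples = {
        samples[i]: "gene_tpm_below_1" for i in np.flatnonzero(gene_tpm < MIN_GENE_TPM)
    }
    keep_s = gene_tpm >= MIN_GENE_TPM
    mat = mat[:, keep_s]
    kept_samples = [s for s, k in zip(samples, keep_s) if k]

    expressed_tx = (mat >= MIN_TRANSCRIPT_TPM).any(axis=1)
    dropped_tx = [t for t, k in zip(tpm.index, expressed_tx) if not k]
    mat = mat[expressed_tx]
    kept_tx = [t for t, k in zip(tpm.index, expressed_tx) if k]
    if len(kept_tx) < 2:
        raise GeneSkipped(gene, "fewer_than_two_transcripts_after_filtering")

    denom = mat.sum(axis=0)
    zero = denom <= 0
    if zero.any():
        for i in np.flatnonzero(zero):
            dropped_samples[kept_samples[i]] = "zero_transcript_sum"
        mat = mat[:, ~zero]
        kept_samples = [s for s, z in zip(kept_samples, zero) if not z]
        denom = denom[~zero]

    ratios = (mat / denom).T
    ratios = ratios / ratios.sum(axis=1, keepdims=True)  # exact row sums
    return SplicingRatioMatrix(
        gene_id=gene, samples=kept_samples, transcripts=kept_tx, ratios=ratios,
        dropped_samples=dropped_samples, dropped_transcripts=dropped_tx,
    )


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    """Intercept + numeric columns + one-hot categoricals (reference dropped),
    with collinear columns removed (warning)."""
    n = len(cov)
    blocks = [np.ones((n, 1))]
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(s, drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
    X = np.hstack(blocks)
    # drop collinear columns greedily, keeping the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - len(keep)} collinear covariate column(s)",
            stacklevel=2,
        )
    return X[:, keep]


def adjust_covariates(
    ratios: SplicingRatioMatrix, cov: CovariateTable | None = None
) -> AdjustedPhenotype:
    """Square-root transform and regress covariates out of each transcript.

    With no covariates the output is the centered sqrt-ratios. Residual
    columns are orthogonal to the covariate design (within numerical
    precision).
    """
    Z = np.sqrt(ratios.ratios)
    if cov is None or cov.table.shape[1] == 0:
        X = np.ones((Z.shape[0], 1))
    else:
        missing = set(ratios.samples) - set(cov.samples)
        if missing:
            raise ValueError(f"covariates missing for samples {sorted(missing)[:5]}")
        X = _design_matrix(cov.table.loc[ratios.samples])
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    return AdjustedPhenotype(
        gene_id=ratios.gene_id, samples=list(ratios.samples),
        transcripts=list(ratios.transcripts), matrix=resid,
        sqrt_grand_mean=Z.mean(axis=0),
    )


def adjusted_relative_expression(pheno: AdjustedPhenotype) -> np.ndarray:
    """Back-transform residuals to adjusted relative expression in [0, 1].

    Residuals are re-centred by the per-transcript grand mean sqrt-ratio,
    clipped at zero and squared: with no covariates this reproduces the raw
    splicing ratios exactly.
    """
    z = np.clip(pheno.matrix + pheno.sqrt_grand_mean, 0.0, None)
    return np.clip(z * z, 0.0, 1.0)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------


def passes_variant_rules(dosages: np.ndarray) -> bool:
    """MAF and group-size rules on non-missing dosages.

    MAF >= 0.01, every *observed* dosage group with >= 10 samples, and at
    least two observed groups (a monomorphic variant carries no contrast).
    """
    d = np.asarray(dosages)
    d = d[d >= 0]
    if len(d) == 0:
        return False
    maf = d.mean() / 2.0
    maf = min(maf, 1.0 - maf)
    if maf < MIN_MAF:
        return False
    counts = np.bincount(d, minlength=3)
    observed = counts[counts > 0]
    if len(observed) < 2:
        return False
    return bool((observed >= MIN_GROUP_SIZE).all())


def filter_variants(
    geno: GenotypeTable,
    gene: GeneAnnotation,
    retained_samples: list,
    window: int = CIS_WINDOW,
) -> TestableVariantSet:
    """Testable variants for one gene: cis window, MAF and group-size rules.

    The cis window is the gene body extended by ``window`` bp on both sides
    (strand ignored; the window is symmetric). Rules are evaluated on the
    gene's retained samples; the empty set is a valid result.
    """
    lo = max(0, gene.start - window)
    hi = gene.end + window
    sub = geno.subset_region(gene.chrom, lo, hi)
    dosages = sub.dosages[retained_samples]
    variants: dict[str, np.ndarray] = {}
    for variant_id, row in dosages.iterrows():
        d = row.to_numpy()
        if passes_variant_rules(d):
            variants[variant_id] = d.astype(np.int8)
    return TestableVariantSet(gene_id=gene.gene_id, cis_window=(lo, hi), variants=variants)
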