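"""Synthetic cohorts with the statistical structure the association test assumes.

The generator emulates, per gene, what the mapping pipeline consumes:

* biallelic genotypes drawn as Binomial(2, MAF) under Hardy-Weinberg;
* compositional splicing ratios drawn from a Dirichlet whose mean is
  shifted between genotype groups along a two-transcript contrast, so that
  the population MD (largest absolute difference of group mean ratios)
  equals the requested effect size exactly — the Dirichlet mean is linear in
  the shift, so the calibration is closed-form;
* transcript TPMs = ratios x a lognormal per-sample gene expression;
* optional nuisance covariates acting additively on the sqrt-ratio scale
  (the scale on which the pipeline removes them), renormalised back to
  compositions;
* multi-tissue effect-size tables with a tunable cross-tissue correlation,
  as fixtures for the sharing analytics.

Everything is driven by a single integer seed; identical specs produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import TranscriptStructure
from .io import CovariateTable, ExpressionTable, GeneAnnotation, GenotypeTable

GENE_SPACING = 100_000
GENE_LENGTH = 20_000
CHROM = "chr1"


@dataclass
class SimulationSpec:
    """Study conditions of a synthetic cohort.

    ``effect_md`` is the target MD (difference in mean ratios between the
    homozygous groups) of true sGenes; ``dirichlet_concentration`` controls
    biological noise around the group means (larger = tighter ratios);
    ``covariate_spec`` lists (name, kind, effect) with kind 'numeric' or
    'categorical' and effect the additive coefficient on the sqrt-ratio
    scale.
    """

    n_samples: int = 150
    n_genes: int = 100
    transcripts_per_gene: int = 3
    maf: float = 0.35
    effect_md: float = 0.2
    frac_sgenes: float = 0.2
    dirichlet_concentration: float = 50.0
    covariate_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not (0.0 <= self.effect_md <= 1.0):
            raise ValueError("effect_md must lie in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.transcripts_per_gene < 2:
            raise ValueError("transcripts_per_gene must be >= 2")
        if not (0.0 <= self.frac_sgenes <= 1.0):
            raise ValueError("frac_sgenes must lie in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stream])


def _gene_ids(spec: SimulationSpec) -> list[str]:
    return [f"gene{i:04d}" for i in range(spec.n_genes)]


def gene_annotations(spec: SimulationSpec) -> dict[str, GeneAnnotation]:
    """Gene bodies on one synthetic chromosome, evenly spaced."""
    out: dict[str, GeneAnnotation] = {}
    for i, gid in enumerate(_gene_ids(spec)):
        start = 10_000 + i * GENE_SPACING
        end = start + GENE_LENGTH
        txs = [
            TranscriptStructure(f"{gid}.t{t}", "+", [(start, end)])
            for t in range(spec.transcripts_per_gene)
        ]
        out[gid] = GeneAnnotation(gid, CHROM, start, end, "+", transcripts=txs)
    return out


def simulate_genotypes(spec: SimulationSpec) -> GenotypeTable:
    """One biallelic cis variant per gene, dosages ~ Binomial(2, MAF)."""
    rng = spec.rng(1)
    samples = [f"s{i:04d}" for i in range(spec.n_samples)]
    genes = gene_annotations(spec)
    ids, chroms, starts, ends, rows = [], [], [], [], []
    for gid, ann in genes.items():
        pos = (ann.start + ann.end) // 2
        ids.append(f"var_{gid}")
        chroms.append(ann.chrom)
        starts.append(pos)
        ends.append(pos + 1)
        rows.append(rng.binomial(2, spec.maf, size=spec.n_samples).astype(np.int8))
    dosages = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="variant_id"),
                           columns=samples)
    meta = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends,
         "ref": ["A"] * len(ids), "alt": ["G"] * len(ids)},
        index=dosages.index,
    )
    return GenotypeTable(dosages, meta)


def simulate_covariates(spec: SimulationSpec) -> CovariateTable:
    """Nuisance covariates per sample, as declared in ``covariate_spec``."""
    rng = spec.rng(2)
    samples = [f"s{i:04d}" for i in range(spec.n_samples)]
    cols: dict[str, np.ndarray | list] = {}
    for name, kind, _effect in spec.covariate_spec:
        if kind == "numeric":
            cols[name] = rng.normal(size=spec.n_samples)
        elif kind == "categorical":
            cols[name] = [f"l{v}" for v in rng.integers(0, 2, size=spec.n_samples)]
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return CovariateTable(pd.DataFrame(cols, index=pd.Index(samples, name="sample_id")))


def _group_mean_compositions(
    spec: SimulationSpec, rng: np.random.Generator, md: float
) -> np.ndarray:
    """Dirichlet means per dosage group (3 x T) with MD(group means) = md.

    The baseline composition gives the two effect transcripts equal mass, so
    a symmetric shift of +-md/2 along their contrast is always feasible; the
    remaining transcripts keep their (floored) Dirichlet draw.
    """
    T = spec.transcripts_per_gene
    q = rng.dirichlet(np.full(T, 5.0))
    q = (q + 0.05) / (1.0 + 0.05 * T)  # keep every isoform expressed
    order = np.argsort(q)[::-1]
    i, j = order[0], order[1]
    margin = 0.0 if md >= 1.0 else min(0.02, (1.0 - md) / 2)
    S = q[i] + q[j]
    S = max(S, md + 2 * margin)
    if T == 2 or S > 1.0:
        S = 1.0
    p0 = q * ((1.0 - S) / max(1e-12, 1.0 - (q[i] + q[j])))
    if T == 2:
        p0 = np.zeros(T)
    p0[i] = p0[j] = S / 2.0
    means = np.empty((3, T))
    contrast = np.zeros(T)
    contrast[i], contrast[j] = 1.0, -1.0
    for d in range(3):
        means[d] = p0 + (d - 1) * (md / 2.0) * contrast
    return np.clip(means, 0.0, 1.0)


def simulate_splicing(
    spec: SimulationSpec,
    genotypes: GenotypeTable,
    covariates: CovariateTable | None = None,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Transcript TPMs with genotype-dependent composition shifts.

    The first ``round(frac_sgenes * n_genes)`` genes are true sGenes with
    population MD equal to ``effect_md``; the rest are null (ratios
    independent of genotype). Returns the expression table and a truth table
    (gene_id, variant_id, is_sgene, target_md).
    """
    rng = spec.rng(3)
    samples = genotypes.samples
    n = len(samples)
    gene_ids = _gene_ids(spec)
    n_sgenes = int(round(spec.frac_sgenes * spec.n_genes))
    T = spec.transcripts_per_gene
    conc = spec.dirichlet_concentration

    cov_effects = []
    if covariates is not None and spec.covariate_spec:
        for name, kind, effect in spec.covariate_spec:
            col = covariates.table.loc[samples, name]
            x = (
                col.to_numpy(dtype=float)
                if kind == "numeric"
                else (col == sorted(col.unique())[-1]).to_numpy(dtype=float)
            )
            cov_effects.append((x, float(effect)))

    tx_rows, tpm_rows, truth = [], [], []
    for gi, gid in enumerate(gene_ids):
        is_sgene = gi < n_sgenes
        md = spec.effect_md if is_sgene else 0.0
        means = _group_mean_compositions(spec, rng, md)
        dose = genotypes.dosages.loc[f"var_{gid}", samples].to_numpy()
        dose_obs = np.where(dose < 0, 1, dose)  # missing treated as het for simulation
        ratios = np.empty((n, T))
        if md >= 1.0:
            ratios = means[dose_obs]
        else:
            for d in range(3):
                sel = dose_obs == d
                if sel.any():
                    ratios[sel] = rng.dirichlet(conc * means[d], size=int(sel.sum()))
        if cov_effects:
            order = np.argsort(means[1])[::-1]
            u = np.zeros(T)
            u[order[0]], u[order[1]] = 1.0, -1.0
            z = np.sqrt(ratios)
            for x, effect in cov_effects:
                z = z + effect * x[:, None] * u[None, :]
            z = np.clip(z, 0.0, None)
            ratios = z * z
            ratios = ratios / ratios.sum(axis=1, keepdims=True)
        gene_expr = rng.lognormal(mean=np.log(50.0), sigma=0.5, size=n)
        tpm = ratios * gene_expr[:, None]
        for t in range(T):
            tx_rows.append((f"{gid}.t{t}", gid))
            tpm_rows.append(tpm[:, t])
        truth.append({"gene_id": gid, "variant_id": f"var_{gid}",
                      "is_sgene": is_sgene, "target_md": md})

    tpm_df = pd.DataFrame(
        np.vstack(tpm_rows),
        index=pd.Index([t for t, _ in tx_rows], name="transcript_id"),
        columns=samples,
    )
    gene_map = pd.Series([g for _, g in tx_rows],
                         index=tpm_df.index, name="gene_id")
    expr = ExpressionTable(tpm=tpm_df, gene_id=gene_map)
    return expr, pd.DataFrame(truth)


def simulate_cohort(spec: SimulationSpec) -> dict:
    """Convenience bundle: genotypes, covariates, expression, truth, genes."""
    genotypes = simulate_genotypes(spec)
    covariates = simulate_covariates(spec) if spec.covariate_spec else None
    expr, truth = simulate_splicing(spec, genotypes, covariates)
    return {
        "genotypes": genotypes,
        "covariates": covariates,
        "expression": expr,
        "truth": truth,
        "genes": gene_annotations(spec),
    }


def simulate_multitissue_results(
    spec: SimulationSpec,
    n_tissues: int,
    sharing: float,
    n_pairs: int | None = None,
) -> list[pd.DataFrame]:
    """Per-tissue variant-gene result tables with correlated effect sizes.

    MD values across tissues follow a one-factor Gaussian model with
    pairwise correlation ``sharing``, mapped linearly into [0.05, 1] (the
    linear map preserves the Pearson correlation; clipping is negligible at
    the default location/scale). Each tissue also carries an FDR column and
    a significance flag at FDR < 0.05.
    """
    if not (0.0 <= sharing <= 1.0):
        raise ValueError("sharing must lie in [0, 1]")
    rng = spec.rng(4)
    if n_pairs is None:
        n_pairs = spec.n_genes
    z0 = rng.normal(size=n_pairs)
    pair_ids = [f"var{i:05d}" for i in range(n_pairs)]
    gene_ids = [f"gene{i:05d}" for i in range(n_pairs)]
    out = []
    for _t in range(n_tissues):
        if sharing >= 1.0:
            z = z0
        else:
            eps = rng.normal(size=n_pairs)
            z = np.sqrt(sharing) * z0 + np.sqrt(1.0 - sharing) * eps
        md = np.clip(0.25 + 0.06 * z, 0.05, 1.0)
        # significance independent of the effect size, so conditioning on
        # "significant in >= 1 tissue" does not attenuate the MD correlation
        fdr_q = rng.uniform(0.0, 1.0, size=n_pairs) ** 3
        out.append(pd.DataFrame({
            "variant_id": pair_ids,
            "gene_id": gene_ids,
            "md": md,
            "fdr_q": fdr_q,
            "significant": fdr_q < 0.05,
        }))
    return out


def _normal_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)
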