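"""Gene-level significance, FDR over genes, pair retrieval and replication.

Many variants in linkage disequilibrium are tested per gene, so nominal
p-values are not comparable across genes. An adaptive permutation scheme
characterises, per gene, the null distribution of the *minimum* nominal
p-value across its cis variants: phenotype rows are permuted jointly (the
same shuffle for every variant of the gene, preserving the LD structure of
the variant set), and the empirical gene-level p-value is
(1 + #{permutation minima <= observed minimum}) / (1 + B). Permutations stop
early once enough hits accumulate, since a precise p-value is only needed
near the significance boundary. A Beta distribution fitted to the
permutation minima refines the tail and supports quantile look-ups.

sGenes are called at a Benjamini-Hochberg FDR of 0.05 over gene-level
empirical p-values. All significant variant-gene pairs are then retrieved by
mapping a genome-wide empirical threshold back to a per-gene nominal
threshold through each gene's permutation-minimum distribution. Reported
pairs must additionally have MD >= 0.05 and pass the homoscedasticity screen
(failing pairs stay in the multiple-testing accounting but are never
reported significant).

Replication of one study's pairs in another is summarised by pi1 = 1 - pi0,
the estimated proportion of true positives among the replication p-values
(Storey's pi0 with a smoother over the lambda grid 0.05..0.95, or a
bootstrap selection for small inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assoc import AssociationResult, fitted_null_tail, _group_codes, _perm_f_batch
from .preprocess import AdjustedPhenotype, TestableVariantSet

MD_REPORT_MIN = 0.05


@dataclass
class GeneLevelResult:
    """Gene-level empirical p-value and derived significance calls."""

    gene_id: str
    p_min_observed: float
    empirical_p: float
    n_perms: int
    beta_params: tuple | None = None
    perm_minima: np.ndarray | None = field(default=None, metadata={"serialize": False})
    fdr_q: float = float("nan")
    nominal_threshold: float = float("nan")
    is_sgene: bool = False


@dataclass
class SignificantPairSet:
    """All reported variant-gene pairs plus the thresholds used."""

    pairs: pd.DataFrame
    p_t: float
    fdr: float


# ---------------------------------------------------------------------------
# adaptive permutation scheme
# ---------------------------------------------------------------------------


def gene_empirical_p(
    pheno: AdjustedPhenotype,
    variant_set: TestableVariantSet,
    seed: int | np.random.Generator = 0,
    b_min: int = 100,
    b_max: int = 1000,
    hit_target: int = 10,
    n_fit_perms: int = 100,
    fit_beta: bool = True,
) -> GeneLevelResult | None:
    """Empirical gene-level p-value via adaptive phenotype permutations.

    Returns ``None`` when the gene has no testable variants. Nominal
    p-values (observed and permuted) use each variant's pre-fitted
    Pearson-III null so that a permutation costs only one pseudo-F per
    variant.
    """
    from .assoc import hellinger_distance_matrix
    from .preprocess import passes_variant_rules

    if len(variant_set) == 0:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = hellinger_distance_matrix(pheno.matrix)
    W = D * D
    n = W.shape[0]

    variants = []
    for variant_id, dosages in variant_set.items():
        d = np.asarray(dosages)
        if not passes_variant_rules(d):
            continue
        variants.append((variant_id, d))
    if not variants:
        return None

    # observed minimum nominal p across variants (shared fitted nulls)
    tails, obs_p = [], []
    for variant_id, d in variants:
        keep = d >= 0
        _, codes = _group_codes(d[keep])
        counts = np.bincount(codes)
        Wv = W[np.ix_(keep, keep)] if not keep.all() else W
        sf = fitted_null_tail(Wv, codes, counts, n_fit_perms, rng)
        f_obs = _perm_f_batch(Wv, codes[None, :], counts)[0]
        tails.append((keep, codes, counts, sf))
        obs_p.append(float(sf(f_obs)))
    p_min_obs = float(min(obs_p))

    all_full = all(keep.all() for keep, *_ in tails)
    hits = 0
    b_done = 0
    minima: list[float] = []
    while b_done < b_max:
        b = min(b_min, b_max - b_done)
        perms = np.empty((b, n), dtype=np.int64)
        for i in range(b):
            perms[i] = rng.permutation(n)
        min_p = np.full(b, np.inf)
        if all_full:
            for (keep, codes, counts, sf) in tails:
                f_perm = _perm_f_batch(W, codes[perms], counts)
                min_p = np.minimum(min_p, sf(f_perm))
        else:
            for (keep, codes, counts, sf) in tails:
                idx = np.flatnonzero(keep)
                for i in range(b):
                    pi = perms[i][np.isin(perms[i], idx)]
                    Wp = W[np.ix_(pi, pi)]
                    f = _perm_f_batch(Wp, codes[None, :], counts)[0]
                    min_p[i] = min(min_p[i], float(sf(f)))
        minima.extend(min_p.tolist())
        hits += int(np.sum(min_p <= p_min_obs + 1e-15))
        b_done += b
        if b_done >= b_min and hits >= hit_target:
            break

    empirical_p = (1 + hits) / (1 + b_done)
    minima_arr = np.asarray(minima)
    beta_params = None
    if fit_beta and len(minima_arr) >= 20 and np.ptp(minima_arr) > 0:
        eps = 1e-12
        clipped = np.clip(minima_arr, eps, 1 - eps)
        try:
            a, b_, *_ = stats.beta.fit(clipped, floc=0, fscale=1)
            beta_params = (float(a), float(b_))
        except Exception:  # noqa: BLE001 - fit failures fall back to quantiles
            beta_params = None
    return GeneLevelResult(
        gene_id=pheno.gene_id, p_min_observed=p_min_obs,
        empirical_p=empirical_p, n_perms=b_done,
        beta_params=beta_params, perm_minima=minima_arr,
    )


# ---------------------------------------------------------------------------
# FDR and pair retrieval
# ---------------------------------------------------------------------------


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sgenes(gene_results: list[GeneLevelResult], fdr: float = 0.05) -> None:
    """Attach BH q-values and sGene calls (FDR <= ``fdr``) in place."""
    q = bh_fdr([g.empirical_p for g in gene_results])
    for g, qv in zip(gene_results, q):
        g.fdr_q = float(qv)
        g.is_sgene = bool(qv <= fdr)


def _nominal_threshold(gene: GeneLevelResult, p_t: float) -> float:
    """Nominal p corresponding to the genome-wide empirical threshold ``p_t``
    under this gene's permutation-minimum distribution."""
    if gene.beta_params is not None:
        a, b = gene.beta_params
        return float(stats.beta.ppf(p_t, a, b))
    return float(np.quantile(gene.perm_minima, p_t))


def significant_pairs(
    gene_results: list[GeneLevelResult],
    assoc_results: list[AssociationResult],
    fdr: float = 0.05,
    md_min: float = MD_REPORT_MIN,
) -> SignificantPairSet:
    """Retrieve all significant variant-gene pairs at gene-level FDR ``fdr``.

    The genome-wide empirical threshold p_t is the midpoint between the
    largest gene-level empirical p passing BH and the smallest failing; each
    sGene maps p_t back to a nominal threshold through its
    permutation-minimum distribution (Beta quantile when fitted, else the
    empirical quantile). Reported pairs satisfy nominal p <= threshold,
    MD >= ``md_min`` and the homoscedasticity screen (BH over all
    homoscedasticity p-values in the run; failing pairs flagged, never
    reported).
    """
    call_sgenes(gene_results, fdr=fdr)
    passing = [g.empirical_p for g in gene_results if g.is_sgene]
    failing = [g.empirical_p for g in gene_results if not g.is_sgene]
    if not passing:
        empty = pd.DataFrame(
            columns=["gene_id", "variant_id", "F", "p_nominal", "md",
                     "p_homoscedasticity", "heteroscedastic"]
        )
        return SignificantPairSet(pairs=empty, p_t=float("nan"), fdr=fdr)
    p_t = (max(passing) + min(failing)) / 2.0 if failing else (max(passing) + 1.0) / 2.0

    # homoscedasticity screen across every nominal test in the run
    hom_p = np.array([r.p_homoscedasticity for r in assoc_results], dtype=float)
    ok = ~np.isnan(hom_p)
    hetero = np.zeros(len(assoc_results), dtype=bool)
    if ok.any():
        q_hom = np.full(len(assoc_results), np.nan)
        q_hom[ok] = bh_fdr(hom_p[ok])
        hetero[ok] = q_hom[ok] <= 0.05

    thresholds = {}
    for g in gene_results:
        if g.is_sgene:
            g.nominal_threshold = _nominal_threshold(g, p_t)
            thresholds[g.gene_id] = g.nominal_threshold

    rows = []
    for r, het in zip(assoc_results, hetero):
        thr = thresholds.get(r.gene_id)
        if thr is None or not np.isfinite(r.p_nominal):
            continue
        if r.p_nominal <= thr and r.md >= md_min and not het:
            rows.append({
                "gene_id": r.gene_id, "variant_id": r.variant_id, "F": r.F,
                "p_nominal": r.p_nominal, "md": r.md,
                "p_homoscedasticity": r.p_homoscedasticity,
                "heteroscedastic": bool(het),
            })
    pairs = pd.DataFrame(
        rows, columns=["gene_id", "variant_id", "F", "p_nominal", "md",
                       "p_homoscedasticity", "heteroscedastic"],
    )
    return SignificantPairSet(pairs=pairs, p_t=float(p_t), fdr=fdr)


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------


def pi1(
    p,
    lambdas: np.ndarray | None = None,
    method: str = "smoother",
    seed: int = 0,
    n_boot: int = 100,
) -> float:
    """Proportion of true positives among replication p-values (1 - pi0).

    pi0(lambda) = #{p > lambda} / ((1 - lambda) n) over the grid
    lambda = 0.05..0.95; the smoother method extrapolates a cubic fit to
    lambda = 0.95, the bootstrap method (used automatically for n < 100)
    picks the lambda minimising the bootstrap MSE against the minimum
    pi0(lambda). The estimate is clamped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])

    if method == "bootstrap" or (method == "smoother" and p.size < 100):
        rng = np.random.default_rng(seed)
        pi0_min = pi0_l.min()
        mse = np.zeros_like(lambdas)
        for _ in range(n_boot):
            pb = rng.choice(p, size=p.size, replace=True)
            pi0_b = np.array([np.mean(pb > lam) / (1.0 - lam) for lam in lambdas])
            mse += (pi0_b - pi0_min) ** 2
        pi0 = pi0_l[int(np.argmin(mse))]
    elif method == "smoother":
        from scipy.interpolate import UnivariateSpline

        # cubic smoothing spline over pi0(lambda), evaluated at the grid end;
        # weights favour the stable low-lambda estimates
        w = 1.0 - lambdas
        spl = UnivariateSpline(lambdas, pi0_l, w=w, k=3,
                               s=float(len(lambdas)) * np.var(pi0_l) * 0.05)
        pi0 = float(spl(lambdas.max()))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return 1.0 - pi0
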