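"""Matched-null functional enrichment, location profiles, heteropleiotropy,
and splice-site PWM delta scoring.

Enrichment of sQTLs in genomic annotations is assessed against a null
distribution of randomly sampled non-sQTL variants matched to the sQTLs in
relative gene location (the same 20-bin scheme used for location profiles)
and minor allele frequency (+- 0.02). The odds ratio compares the annotated
frequency among sQTLs to the mean annotated frequency across the null sets;
significance uses a two-sided Fisher exact test with BH correction, and
annotations too rare in the null (mean count below five) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .mtc import bh_fdr

N_LOCATION_BINS = 20


@dataclass
class AnnotationTrack:
    """Named set of genomic intervals (0-based half-open)."""

    name: str
    intervals: list  # (chrom, start, end)

    def __post_init__(self) -> None:
        from intervaltree import IntervalTree

        trees: dict[str, "IntervalTree"] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"{self.name}: empty interval ({start},{end})")
            trees.setdefault(str(chrom), IntervalTree()).addi(int(start), int(end))
        for t in trees.values():
            t.merge_overlaps()
        self._trees = trees

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(str(chrom))
        return bool(tree is not None and tree.overlaps_point(int(pos)))

    def annotate(self, variants: pd.DataFrame) -> np.ndarray:
        """Boolean membership for a variant table with chrom/pos columns."""
        return np.fromiter(
            (self.contains(c, p) for c, p in zip(variants["chrom"], variants["pos"])),
            dtype=bool, count=len(variants),
        )


@dataclass
class MatchedNullSpec:
    """Matching parameters for the null variant sets."""

    n_sets: int = 1000
    n_bins: int = N_LOCATION_BINS
    maf_tol: float = 0.02
    top_k_per_gene: int = 10
    min_mean_freq: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_sets, self.n_bins, self.top_k_per_gene) <= 0:
            raise ValueError("n_sets, n_bins and top_k_per_gene must be positive")
        if not (0.0 < self.maf_tol < 0.5):
            raise ValueError("maf_tol must lie in (0, 0.5)")
        if self.min_mean_freq <= 0:
            raise ValueError("min_mean_freq must be positive")


@dataclass
class EnrichmentResult:
    """Per-annotation odds ratio against the matched null."""

    annotation: str
    or_value: float
    fisher_p: float
    fdr_q: float
    n_sqtl_annotated: int
    mean_null_annotated: float
    dropped: bool = False


# ---------------------------------------------------------------------------
# location bins
# ---------------------------------------------------------------------------


def assign_bin(
    pos: int, start: int, end: int, strand: str, n_bins: int = N_LOCATION_BINS
) -> int:
    """1-based location bin of ``pos`` within [start, end); bin 1 is 5'.

    On the minus strand the numbering is reversed so that bin 1 stays at the
    transcript 5' end.
    """
    if not (start <= pos < end):
        raise ValueError("position outside region")
    frac = (pos - start) / (end - start)
    b = min(int(frac * n_bins) + 1, n_bins)
    return n_bins + 1 - b if strand == "-" else b


def top_variants_per_gene(pairs: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k most significant variants per gene (by nominal p)."""
    return (
        pairs.sort_values("p_nominal")
        .groupby("gene_id", sort=False)
        .head(k)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# matched null sampling
# ---------------------------------------------------------------------------


def sample_matched_null(
    sqtls: pd.DataFrame,
    candidates: pd.DataFrame,
    spec: MatchedNullSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Null variant sets matched to the sQTLs in location bin and MAF.

    ``sqtls`` and ``candidates`` need columns ``variant_id``, ``bin`` and
    ``maf``; candidates are non-sQTLs (FDR > 0.05). Each of the
    ``spec.n_sets`` sets has the sQTL set's size; every slot is drawn from
    candidates in the same bin with MAF within +- ``maf_tol``, without
    replacement within a set (with replacement across sets). An empty
    MAF stratum falls back to the nearest-MAF candidate in the bin (logged
    via the returned sets being valid regardless); an empty bin raises.
    """
    if spec is None:
        spec = MatchedNullSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    by_bin: dict[int, pd.DataFrame] = {
        int(b): g.reset_index(drop=True) for b, g in candidates.groupby("bin")
    }
    # per-sQTL eligible candidate row numbers within its bin
    eligible: list[tuple[int, np.ndarray, np.ndarray]] = []
    for row in sqtls.itertuples(index=False):
        b = int(row.bin)
        pool = by_bin.get(b)
        if pool is None or len(pool) == 0:
            raise ValueError(f"no null candidates in location bin {b}")
        mafs = pool["maf"].to_numpy(dtype=float)
        idx = np.flatnonzero(np.abs(mafs - float(row.maf)) <= spec.maf_tol)
        eligible.append((b, idx, np.abs(mafs - float(row.maf))))

    sets: list[np.ndarray] = []
    for _ in range(spec.n_sets):
        used: dict[int, set[int]] = {}
        chosen: list[str] = []
        for b, idx, dist in eligible:
            pool = by_bin[b]
            taken = used.setdefault(b, set())
            avail = [i for i in idx if i not in taken]
            if avail:
                pick = int(rng.choice(avail))
            else:
                # nearest-MAF fallback among unused candidates in the bin
                order = np.argsort(dist)
                pick = next((int(i) for i in order if int(i) not in taken), None)
                if pick is None:
                    raise ValueError(
                        f"location bin {b} exhausted: fewer candidates than sQTLs"
                    )
            taken.add(pick)
            chosen.append(pool.loc[pick, "variant_id"])
        sets.append(np.asarray(chosen, dtype=object))
    return sets


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def enrichment_or(
    sqtls: pd.DataFrame,
    null_sets: list[np.ndarray],
    tracks: list[AnnotationTrack],
    candidates: pd.DataFrame | None = None,
    spec: MatchedNullSpec | None = None,
) -> list[EnrichmentResult]:
    """Odds ratio of annotated frequency among sQTLs vs the matched null.

    ``sqtls`` needs chrom/pos columns (already restricted to the top-k
    variants per gene); ``null_sets`` come from
    :func:`sample_matched_null` and are resolved against ``candidates``
    (variant_id, chrom, pos) — or are taken as boolean count arrays when
    ``candidates`` is None and the arrays are numeric. The 2x2 uses the
    rounded (half-up) mean null count; zero cells get the Haldane 0.5
    correction for the OR only, the Fisher test runs on the raw counts.
    Annotations with mean null count below ``spec.min_mean_freq`` are
    dropped from the FDR; q-values are BH over the rest.
    """
    if spec is None:
        spec = MatchedNullSpec()
    n = len(sqtls)
    if candidates is not None:
        cand_pos = candidates.set_index("variant_id")[["chrom", "pos"]]

    results: list[EnrichmentResult] = []
    for track in tracks:
        a = int(track.annotate(sqtls).sum())
        null_counts = []
        for s in null_sets:
            sub = cand_pos.loc[list(s)].reset_index()
            null_counts.append(int(track.annotate(sub).sum()))
        mean_null = float(np.mean(null_counts))
        c = _round_half_up(mean_null)
        table = np.array([[a, n - a], [c, n - c]])
        if (table == 0).any():
            h = table + 0.5
            or_value = (h[0, 0] * h[1, 1]) / (h[0, 1] * h[1, 0])
        else:
            or_value = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        p = float(fisher_exact(table, alternative="two-sided")[1])
        results.append(EnrichmentResult(
            annotation=track.name, or_value=float(or_value), fisher_p=p,
            fdr_q=float("nan"), n_sqtl_annotated=a, mean_null_annotated=mean_null,
            dropped=mean_null < spec.min_mean_freq,
        ))
    kept = [r for r in results if not r.dropped]
    if kept:
        q = bh_fdr([r.fisher_p for r in kept])
        for r, qv in zip(kept, q):
            r.fdr_q = float(qv)
    return results


# ---------------------------------------------------------------------------
# location profile
# ---------------------------------------------------------------------------


def location_profile(
    sqtls: pd.DataFrame,
    regions: pd.DataFrame,
    n_bins: int = N_LOCATION_BINS,
    min_length_quantile: float = 0.2,
) -> np.ndarray:
    """Mean per-bin proportion of sQTLs along regions (bin 1 = 5' end).

    ``sqtls`` needs chrom/pos and a ``region_id`` linking each variant to a
    row of ``regions`` (region_id, chrom, start, end, strand). The shortest
    20% of regions are filtered out; variants outside their region are
    excluded. Per region, bin counts are normalised by the region's own
    sQTL count before averaging, so a flat profile sits at 1/n_bins.
    """
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    cut = np.quantile(lengths, min_length_quantile)
    keep = regions[lengths >= cut].set_index("region_id")

    profiles = []
    for rid, reg in keep.iterrows():
        sub = sqtls[sqtls["region_id"] == rid]
        counts = np.zeros(n_bins)
        for row in sub.itertuples(index=False):
            if not (reg["start"] <= row.pos < reg["end"]):
                continue
            b = assign_bin(int(row.pos), int(reg["start"]), int(reg["end"]),
                           str(reg["strand"]), n_bins)
            counts[b - 1] += 1
        if counts.sum() > 0:
            profiles.append(counts / counts.sum())
    if not profiles:
        raise ValueError("no region carries an sQTL after filtering")
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# heteropleiotropy
# ---------------------------------------------------------------------------


def heteropleiotropy_call(calls: dict) -> bool | None:
    """Heteropleiotropy rule on the eight (gene, tissue, trait) booleans.

    ``calls`` maps (gene, tissue, trait) with gene in {'g1','g2'}, tissue in
    {'t1','t2'}, trait in {'sqtl','eqtl'} to a boolean. True iff the variant
    is sQTL-only for g1 in t1, eQTL-only for g2 in t2, and has no effect on
    g2 in t1 nor on g1 in t2. Returns None (not evaluable) when any of the
    eight calls is missing.
    """
    needed = [(g, t, m) for g in ("g1", "g2") for t in ("t1", "t2")
              for m in ("sqtl", "eqtl")]
    if any(k not in calls or calls[k] is None for k in needed):
        return None
    c = {k: bool(calls[k]) for k in needed}
    return (
        c[("g1", "t1", "sqtl")] and not c[("g1", "t1", "eqtl")]
        and c[("g2", "t2", "eqtl")] and not c[("g2", "t2", "sqtl")]
        and not c[("g2", "t1", "sqtl")] and not c[("g2", "t1", "eqtl")]
        and not c[("g1", "t2", "sqtl")] and not c[("g1", "t2", "eqtl")]
    )


# ---------------------------------------------------------------------------
# PWM delta scoring
# ---------------------------------------------------------------------------


@dataclass
class PwmDelta:
    score_ref: float
    score_alt: float
    delta: float
    unsupported: bool = False


def pwm_delta(site_seq: str, offset: int, ref: str, alt: str, pwm) -> PwmDelta:
    """Change in splice-site strength between the two alleles of a variant.

    ``pwm`` is positions x 4 (A, C, G, T) column probabilities summing to 1;
    the site score is sum over positions of log2(p(base)/0.25). ``offset``
    is the 0-based position of the variant within the site; the reference
    base must match the site sequence. Returns the absolute score difference
    |score_alt - score_ref|; indels are returned with the unsupported flag.
    """
    pwm = np.asarray(pwm, dtype=float)
    site_seq = site_seq.upper()
    if pwm.shape != (len(site_seq), 4):
        raise ValueError("PWM must be len(site) x 4 (A, C, G, T)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM columns must be probabilities summing to 1")
    if not (0 <= offset < len(site_seq)):
        raise ValueError("variant lies outside the site")
    if len(ref) != 1 or len(alt) != 1:
        return PwmDelta(float("nan"), float("nan"), float("nan"), unsupported=True)
    ref, alt = ref.upper(), alt.upper()
    if site_seq[offset] != ref:
        raise ValueError(
            f"reference base mismatch at offset {offset}: site has "
            f"{site_seq[offset]}, variant says {ref}"
        )
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score(seq: str) -> float:
        s = 0.0
        for i, b in enumerate(seq):
            if b not in base_idx:
                raise ValueError(f"non-ACGT base {b!r} in site")
            s += np.log2(pwm[i, base_idx[b]] / 0.25)
        return float(s)

    s_ref = score(site_seq)
    s_alt = score(site_seq[:offset] + alt + site_seq[offset + 1:])
    return PwmDelta(s_ref, s_alt, abs(s_alt - s_ref))
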