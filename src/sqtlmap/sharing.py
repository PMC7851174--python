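"""Cross-tissue sharing and tissue-specificity analytics.

Tissue result tables are DataFrames with columns ``variant_id``,
``gene_id``, ``md``, ``fdr_q`` and ``significant`` (one row per tested
variant-gene pair). Sharing between two tissues is measured three ways:

* Pearson correlation of MD effect sizes over pairs tested in both tissues
  and significant in at least one;
* Jaccard index of the significant-pair sets;
* a geometric centroid distance: for pairs tested in all tissues and
  significant in at least one, the mean (over pairs) of the summed (over
  genotype groups) Euclidean distances between the per-group centroids of
  the adjusted splicing phenotype — small distances mean high sharing.

Tissue specificity is 1 minus a tissue's mean similarity to the others.
Dendrograms built from sharing matrices are compared with Baker's Gamma,
the rank correlation of the merge stages at which leaf pairs combine, with
a label-shuffling permutation test. The tau index summarises how
tissue-restricted a per-tissue profile is (0 = uniform, 1 = one-tissue).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

NEGLOG_FDR_CAP = 300.0


def _pair_index(t: pd.DataFrame) -> pd.DataFrame:
    return t.set_index(["variant_id", "gene_id"])


def sharing_corr(t1: pd.DataFrame, t2: pd.DataFrame) -> float:
    """Pearson r of MD values over shared pairs significant in >= 1 tissue.

    Returns NaN (with a warning) when fewer than 3 such pairs exist.
    """
    a, b = _pair_index(t1), _pair_index(t2)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        warnings.warn("no variant-gene pairs tested in both tissues", stacklevel=2)
        return float("nan")
    a, b = a.loc[common], b.loc[common]
    keep = a["significant"].to_numpy() | b["significant"].to_numpy()
    if keep.sum() < 3:
        warnings.warn("fewer than 3 eligible pairs; correlation undefined", stacklevel=2)
        return float("nan")
    x = a.loc[keep, "md"].to_numpy(dtype=float)
    y = b.loc[keep, "md"].to_numpy(dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def jaccard_sharing(t1: pd.DataFrame, t2: pd.DataFrame) -> float:
    """Jaccard index of the significant-pair sets (0 when the union is empty)."""
    a = set(map(tuple, t1.loc[t1["significant"], ["variant_id", "gene_id"]].itertuples(index=False)))
    b = set(map(tuple, t2.loc[t2["significant"], ["variant_id", "gene_id"]].itertuples(index=False)))
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def pairwise_sharing(tissues: dict, metric: str = "md") -> pd.DataFrame:
    """Symmetric tissue x tissue similarity matrix (metric 'md' or 'jaccard')."""
    fn = {"md": sharing_corr, "jaccard": jaccard_sharing}[metric]
    names = list(tissues)
    m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            v = fn(tissues[a], tissues[b])
            m.loc[a, b] = m.loc[b, a] = v
    return m


def tissue_specificity(similarity: pd.DataFrame) -> pd.Series:
    """s_t = 1 - mean off-diagonal similarity of tissue t."""
    if similarity.shape[0] < 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError("need a square similarity matrix over >= 2 tissues")
    m = similarity.to_numpy(dtype=float)
    n = m.shape[0]
    off = (m.sum(axis=1) - np.diag(m)) / (n - 1)
    return pd.Series(1.0 - off, index=similarity.index, name="specificity")


# ---------------------------------------------------------------------------
# centroid distance
# ---------------------------------------------------------------------------


def centroid_set(adjusted: np.ndarray, dosages) -> dict:
    """Per-dosage-group centroids of an adjusted phenotype matrix.

    Returns {dosage: centroid vector} for the observed dosage groups of one
    variant-gene pair in one tissue; missing dosages (-1) are skipped.
    """
    out: dict[int, np.ndarray] = {}
    Y = np.asarray(adjusted, dtype=float)
    d = np.asarray(dosages)
    for k in (0, 1, 2):
        sel = d == k
        if sel.any():
            out[k] = Y[sel].mean(axis=0)
    return out


def centroid_distance(c1: dict, c2: dict) -> float:
    """Mean over pairs of summed per-genotype-group centroid distances.

    ``c1``/``c2`` map pair key -> {dosage k: centroid vector}; the pair
    universes must match. Pairs whose centroid dimensions differ between
    tissues (different transcript sets) are dropped with a log entry, as are
    pairs with a dosage group present in exactly one tissue; groups absent
    in both contribute 0.
    """
    if set(c1) != set(c2):
        raise ValueError("mismatched variant-gene pair universes")
    if not c1:
        raise ValueError("empty centroid sets")
    total = 0.0
    used = 0
    for pair in c1:
        g1, g2 = c1[pair], c2[pair]
        if set(g1) != set(g2):
            logger.info("pair %s dropped: genotype groups differ between tissues", pair)
            continue
        dims = {len(np.atleast_1d(v)) for v in g1.values()}
        dims |= {len(np.atleast_1d(v)) for v in g2.values()}
        if len(dims) != 1:
            logger.info("pair %s dropped: transcript sets differ between tissues", pair)
            continue
        s = 0.0
        for k in g1:
            s += float(np.linalg.norm(np.asarray(g1[k], float) - np.asarray(g2[k], float)))
        total += s
        used += 1
    if used == 0:
        raise ValueError("no comparable pairs between the two centroid sets")
    return total / used


def centroid_distance_matrix(centroids: dict) -> pd.DataFrame:
    """Tissue x tissue distance matrix from per-tissue CentroidSets."""
    names = list(centroids)
    m = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            v = centroid_distance(centroids[a], centroids[b])
            m.loc[a, b] = m.loc[b, a] = v
    return m


# ---------------------------------------------------------------------------
# clustering and dendrogram comparison
# ---------------------------------------------------------------------------


def cluster_tissues(distance: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Hierarchical clustering (scipy linkage) of a tissue distance matrix."""
    if distance.shape[0] < 2:
        raise ValueError("need at least two tissues")
    from scipy.spatial.distance import squareform

    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    return hierarchy.linkage(condensed, method=method)


def _merge_stages(linkage: np.ndarray, n_leaves: int) -> np.ndarray:
    """stage[i, j] = merge step (1-based) at which leaves i and j combine."""
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    stage = np.zeros((n_leaves, n_leaves), dtype=int)
    for step, (a, b, _h, _c) in enumerate(linkage, start=1):
        la, lb = members.pop(int(a)), members.pop(int(b))
        for i in la:
            for j in lb:
                stage[i, j] = stage[j, i] = step
        members[n_leaves + step - 1] = la + lb
    return stage


def bakers_gamma(
    linkage1: np.ndarray, linkage2: np.ndarray, n_leaves: int
) -> float:
    """Baker's Gamma: Spearman correlation of leaf-pair merge stages."""
    s1 = _merge_stages(linkage1, n_leaves)
    s2 = _merge_stages(linkage2, n_leaves)
    iu = np.triu_indices(n_leaves, k=1)
    rho = spearmanr(s1[iu], s2[iu]).statistic
    return float(rho)


def cluster_and_compare(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    method: str = "average",
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> dict:
    """Cluster two tissue distance matrices and compare the dendrograms.

    Returns linkages, Baker's Gamma and a permutation p-value obtained by
    shuffling the leaf labels of the second tree (topologies constant).
    Requires at least 4 shared leaves.
    """
    if list(d1.index) != list(d2.index):
        raise ValueError("leaf sets (and order) must match")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 leaves")
    l1 = cluster_tissues(d1, method=method)
    l2 = cluster_tissues(d2, method=method)
    s1 = _merge_stages(l1, n)
    s2 = _merge_stages(l2, n)
    iu = np.triu_indices(n, k=1)
    gamma = float(spearmanr(s1[iu], s2[iu]).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        sp = s2[np.ix_(perm, perm)]
        g = spearmanr(s1[iu], sp[iu]).statistic
        if g >= gamma - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_shuffles)
    return {"linkage1": l1, "linkage2": l2, "gamma": gamma, "p_value": p,
            "labels": list(d1.index)}


def to_newick(linkage: np.ndarray, labels: list) -> str:
    """Newick string of a scipy linkage (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# tau index
# ---------------------------------------------------------------------------


def tau_index(x) -> float:
    """tau = sum(1 - x_t/max(x)) / (n - 1) in [0, 1].

    0 for a uniform profile, 1 for a one-tissue profile. Requires
    non-negative values, n >= 2 and max(x) > 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D profile over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("profile values must be non-negative")
    mx = x.max()
    if mx <= 0:
        raise ValueError("all-zero profile: tau undefined")
    xhat = x / mx
    return float(np.sum(1.0 - xhat) / (len(x) - 1))


def tau_expression(median_expression) -> float:
    """tau on median gene expression per tissue."""
    return tau_index(median_expression)


def tau_splicing(fdr_per_tissue) -> float:
    """tau_s: tau on -log10(FDR) of the sGene per tissue (capped at 300)."""
    fdr = np.asarray(fdr_per_tissue, dtype=float)
    if (fdr <= 0).any():
        x = np.full(fdr.shape, NEGLOG_FDR_CAP)
        x[fdr > 0] = np.minimum(-np.log10(fdr[fdr > 0]), NEGLOG_FDR_CAP)
    else:
        x = np.minimum(-np.log10(fdr), NEGLOG_FDR_CAP)
    x = np.clip(x, 0.0, NEGLOG_FDR_CAP)
    return tau_index(x)


def percentile_filter(values: pd.Series, pct: float, top: bool = True) -> pd.Index:
    """Ids in the top (or bottom) ``pct`` percentile of ``values``."""
    if not (0 < pct < 100):
        raise ValueError("pct must be in (0, 100)")
    cut = np.percentile(values.to_numpy(dtype=float), 100 - pct if top else pct)
    mask = values >= cut if top else values <= cut
    return values.index[mask]
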