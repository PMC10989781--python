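"""Alpha diversity, phylogenetic beta diversity, ordination and design tests.

UniFrac is computed from an explicit branch x tip incidence decomposition
of the rooted tree: each branch contributes its length weighted by the
presence (unweighted) or abundance fraction (weighted) of the tip set it
subtends.  This formulation is exactly the brute-force branch enumeration
and vectorises over all sample pairs at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core_io import AsvTable, ValidationError, as_distance_matrix, \
    relative_abundance

__all__ = [
    "shannon", "alpha_diversity", "bray_curtis", "TreeIndex",
    "unweighted_unifrac", "weighted_unifrac", "pcoa", "OrdinationResult",
    "permanova", "PermanovaResult", "cap", "CapResult",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts_row) -> float:
    """Shannon index H = -sum p_i ln p_i, in nats."""
    x = np.asarray(counts_row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValidationError("cannot compute Shannon index of an empty row")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AsvTable):
    """Per-sample Shannon index and observed richness."""
    import pandas as pd
    H = [shannon(row) for row in table.counts]
    rich = (table.counts > 0).sum(axis=1)
    return pd.DataFrame({"shannon": H, "richness": rich},
                        index=table.sample_ids)


# ---------------------------------------------------------------------------
# Non-phylogenetic beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: AsvTable | np.ndarray, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/sum(x+y) on counts."""
    if isinstance(table, AsvTable):
        counts, ids = table.counts, table.sample_ids
    else:
        counts = np.asarray(table, float)
        ids = ids if ids is not None else [str(i) for i in range(len(counts))]
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero-sum sample in bray_curtis")
    return as_distance_matrix(squareform(pdist(counts, metric="braycurtis")),
                              ids)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

class TreeIndex:
    """Branch decomposition of a rooted tree over an ordered taxon list.

    ``incidence[b, j]`` is True when tip ``taxon_ids[j]`` descends through
    branch ``b``; ``lengths[b]`` is the branch length.  The root carries no
    branch.  Also exposes the cophenetic tip-to-tip distance matrix used
    by the nearest-taxon statistics.
    """

    def __init__(self, tree: TreeNode, taxon_ids):
        self.taxon_ids = list(taxon_ids)
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        tips = {t.name for t in tree.tips()}
        missing = [t for t in self.taxon_ids if t not in tips]
        if missing:
            raise ValidationError(f"taxa absent from tree: {missing[:5]}")
        if tips - set(self.taxon_ids):
            tree = tree.shear(self.taxon_ids)
        rows, lengths = [], []
        below: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(self.taxon_ids), dtype=bool)
                mask[pos[node.name]] = True
            else:
                mask = np.zeros(len(self.taxon_ids), dtype=bool)
                for child in node.children:
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node.parent is not None:  # root has no branch
                rows.append(mask)
                lengths.append(float(node.length or 0.0))
        self.incidence = np.array(rows)
        self.lengths = np.array(lengths)
        self._tree = tree

    def cophenetic(self) -> np.ndarray:
        """Tip-to-tip patristic distances, ordered like ``taxon_ids``."""
        dm = self._tree.tip_tip_distances(endpoints=self.taxon_ids)
        # skbio returns ids in requested order
        return np.asarray(dm.data)


def _tree_index(tree, taxon_ids) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree, taxon_ids)


def unweighted_unifrac(table: AsvTable, tree: TreeNode | TreeIndex
                       ) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length / total covered length.

    A branch is covered by a community when any tip below it is present;
    the distance is the length exclusive to one community divided by the
    length covered by either.
    """
    idx = _tree_index(tree, table.taxon_ids)
    presence = table.counts > 0
    covered = presence @ idx.incidence.T > 0          # samples x branches
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        both = covered & covered[i]
        either = covered | covered[i]
        union = either @ idx.lengths
        shared = both @ idx.lengths
        with np.errstate(invalid="ignore"):
            d = np.where(union > 0, (union - shared) / union, 0.0)
        out[i] = d
    return as_distance_matrix(out, table.sample_ids)


def weighted_unifrac(table: AsvTable, tree: TreeNode | TreeIndex,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac sum_b l_b |p_b^A - p_b^B| on abundance fractions.

    With ``normalized`` (the default) each pair is divided by its maximum
    attainable value sum_b l_b (p_b^A + p_b^B), bounding the distance to
    [0, 1] and making it comparable across sampling depths.
    """
    idx = _tree_index(tree, table.taxon_ids)
    rel = relative_abundance(table)
    pb = rel @ idx.incidence.T                        # samples x branches
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(pb - pb[i]) @ idx.lengths
        if normalized:
            denom = (pb + pb[i]) @ idx.lengths
            with np.errstate(invalid="ignore"):
                diff = np.where(denom > 0, diff / denom, 0.0)
        out[i] = diff
    return as_distance_matrix(out, table.sample_ids)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: np.ndarray      # samples x axes
    eigenvalues: np.ndarray      # all eigenvalues, non-increasing
    proportion_explained: np.ndarray
    sample_ids: list[str]


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues are reported as-is; ``proportion_explained`` is
    computed over the sum of positive eigenvalues only (no Cailliez
    correction).
    """
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = np.asarray(res.eigvals)
    coords = np.asarray(res.samples)
    pos = eig[eig > 1e-12]
    prop = np.where(eig > 1e-12, eig / pos.sum(), 0.0) if pos.size else \
        np.zeros_like(eig)
    return OrdinationResult(coords, eig, prop, list(dm.ids))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, membership: np.ndarray,
                     sizes: np.ndarray, sst: float):
    # SSW = sum_g (1_g' D2 1_g) / (2 n_g) via one matmul per call
    quad = np.einsum("ig,ij,jg->g", membership, d2, membership)
    ssw = (quad / (2.0 * sizes)).sum()
    ssb = sst - ssw
    n, g = d2.shape[0], sizes.size
    f = (ssb / (g - 1)) / (ssw / (n - g))
    return f, ssb / sst


def permanova(dm: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA (adonis) on a distance matrix.

    Pseudo-F from between/within sums of squared distances; the p-value
    counts free label permutations with F at least the observed value,
    with the +1 smoothing that bounds p below by 1/(n_permutations+1).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    counts = [np.sum(labels == g) for g in groups]
    if min(counts) < 2:
        raise ValidationError("every group needs at least two samples")
    d2 = np.asarray(dm.data) ** 2
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    membership = (labels[:, None] == groups[None, :]).astype(float)
    sizes = membership.sum(axis=0)
    f_obs, r2 = _permanova_stats(d2, membership, sizes, sst)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm, _ = _permanova_stats(d2, membership[perm], sizes, sst)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)


# ---------------------------------------------------------------------------
# CAP (canonical analysis of principal coordinates)
# ---------------------------------------------------------------------------

@dataclass
class CapResult:
    axes_used: int
    classification_success: float          # % correct leave-one-out
    constrained_inertia_fraction: float    # group-explained PCoA variance
    group_scores: np.ndarray               # samples x discriminant axes


def _loo_success(scores: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(solver="svd")
        try:
            lda.fit(scores[mask], labels[mask])
        except Exception:
            return np.nan
        correct += lda.predict(scores[i:i + 1])[0] == labels[i]
    return 100.0 * correct / n


def cap(dm: DistanceMatrix, labels, m_axes: int | None = None) -> CapResult:
    """Discriminant analysis on PCoA axes with leave-one-out validation.

    When ``m_axes`` is not given, the axis count maximising leave-one-out
    classification success is chosen (subject to m < n - g).  Because the
    printed "percent" of a CAP can mean either the success rate or the
    constrained inertia, both are reported.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n = len(labels)
    ord_res = pcoa(dm)
    n_pos = int((ord_res.eigenvalues > 1e-12).sum())
    max_m = min(n - len(groups) - 1, n_pos)
    if max_m < 1:
        raise ValidationError("too few samples for CAP")
    if m_axes is not None:
        if m_axes >= n - len(groups):
            raise ValidationError("m_axes must be < n_samples - n_groups")
        candidates = [min(m_axes, n_pos)]
    else:
        candidates = list(range(1, max_m + 1))
    best_m, best_succ = candidates[0], -1.0
    for m in candidates:
        succ = _loo_success(ord_res.coordinates[:, :m], labels)
        if np.isnan(succ):
            continue
        if succ > best_succ:
            best_m, best_succ = m, succ
    scores = ord_res.coordinates[:, :best_m]
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(scores, labels)
    disc = lda.transform(scores)
    # fraction of PCoA-score variance explained by group membership
    centered = scores - scores.mean(axis=0)
    total = (centered ** 2).sum()
    fitted = np.vstack([centered[labels == g].mean(axis=0)
                        for g in labels])
    frac = float((fitted ** 2).sum() / total) if total > 0 else 0.0
    return CapResult(best_m, float(best_succ), frac, disc)
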