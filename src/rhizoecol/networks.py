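"""Signed co-occurrence networks, their topology, and community cohesion.

SparCC infers taxon-taxon correlations from compositional counts via
log-ratio variances and the sparse basis-variance approximation; the
"inner" networks threshold those correlations per microhabitat x
grassland type.  "Outer" networks connect samples across compartments by
Spearman correlation of their taxon profiles.  Cohesion summarises, per
sample, how strongly its abundant taxa are embedded in positive or
negative pairwise associations after a taxon-shuffle null correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AsvTable, ValidationError, relative_abundance

__all__ = [
    "filter_taxa", "sparcc", "sparcc_pvalues", "build_network",
    "topology", "TopologySummary", "cohesion", "CohesionResult",
    "outer_network",
]


def filter_taxa(table: AsvTable, min_rel_abundance: float = 0.001
                ) -> AsvTable:
    """Keep taxa whose mean relative abundance exceeds the threshold."""
    rel = relative_abundance(table)
    keep = rel.mean(axis=0) > min_rel_abundance
    if not keep.any():
        raise ValidationError("relative-abundance filter removed every taxon")
    return table.select_taxa([t for t, k in zip(table.taxon_ids, keep) if k])


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _basis_correlations(frac: np.ndarray, exclusion_threshold: float,
                        n_exclusion_rounds: int) -> np.ndarray:
    """One SparCC pass: log-ratio variances -> basis variances -> rho.

    ``frac`` is samples x taxa fractions.  Strongly correlated pairs are
    iteratively removed from the basis-variance system and the system
    re-solved, so a few dominant associations do not bias the variance
    estimates of everything else.
    """
    logf = np.log(frac)
    d = logf.shape[1]
    # t[i, j] = var(log(x_i / x_j))
    v = logf.var(axis=0, ddof=1)
    cov = np.cov(logf.T)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    include = ~np.eye(d, dtype=bool)
    w = None
    for _ in range(n_exclusion_rounds + 1):
        deg = include.sum(axis=1)
        # T_i = sum_j t_ij over included partners ≈ deg_i * w_i + sum w_j
        A = include.astype(float)
        np.fill_diagonal(A, deg)
        T = (t * include).sum(axis=1)
        w, *_ = np.linalg.lstsq(A, T, rcond=None)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        masked = np.where(include, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
    return rho


def sparcc(table: AsvTable | np.ndarray, n_iterations: int = 20,
           exclusion_threshold: float = 0.8, n_exclusion_rounds: int = 10,
           seed: int = 0) -> np.ndarray:
    """SparCC compositional correlation estimate (median over Dirichlet
    resamples of the count-to-fraction step)."""
    counts = table.counts if isinstance(table, AsvTable) else \
        np.asarray(table)
    n, d = counts.shape
    if d < 4:
        raise ValidationError(
            "SparCC needs >= 4 taxa: the basis-variance system is "
            "unidentifiable below that")
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_iterations, d, d))
    for k in range(n_iterations):
        # Dirichlet posterior draw of fractions given counts (+1 prior)
        gamma = rng.standard_gamma(counts + 1.0)
        frac = gamma / gamma.sum(axis=1, keepdims=True)
        estimates[k] = _basis_correlations(frac, exclusion_threshold,
                                           n_exclusion_rounds)
    rho = np.median(estimates, axis=0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_pvalues(table: AsvTable | np.ndarray, r_observed: np.ndarray,
                   n_bootstrap: int = 100, n_iterations: int = 5,
                   seed: int = 0) -> np.ndarray:
    """Permutation pseudo-p-values for SparCC correlations.

    Each null dataset permutes every taxon's counts across samples
    independently, destroying all between-taxon association while
    preserving each taxon's marginal distribution; SparCC is recomputed
    and the two-sided pseudo-p for a pair is the +1-smoothed fraction of
    null |r| at least the observed |r|.
    """
    counts = (table.counts if isinstance(table, AsvTable)
              else np.asarray(table)).copy()
    n, d = counts.shape
    if n_bootstrap < 20:
        import logging
        logging.getLogger("rhizoecol").warning(
            "n_bootstrap < 20 gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    abs_obs = np.abs(r_observed)
    for b in range(n_bootstrap):
        null = np.empty_like(counts)
        for j in range(d):
            null[:, j] = counts[rng.permutation(n), j]
        r_null = sparcc(null, n_iterations=n_iterations,
                        seed=int(rng.integers(2 ** 31)))
        exceed += np.abs(r_null) >= abs_obs
    p = (exceed + 1.0) / (n_bootstrap + 1.0)
    np.fill_diagonal(p, 0.0)
    return p


# ---------------------------------------------------------------------------
# Network construction and topology
# ---------------------------------------------------------------------------

def build_network(r: np.ndarray, p: np.ndarray, node_ids,
                  r_threshold: float = 0.6, p_threshold: float = 0.05
                  ) -> nx.Graph:
    """Signed undirected network: edge iff |r| > r_threshold and
    p < p_threshold; edge weight keeps the sign; isolated nodes dropped."""
    r, p = np.asarray(r), np.asarray(p)
    if r.shape != p.shape:
        raise ValidationError("r and p matrices must be conformable")
    g = nx.Graph()
    node_ids = list(node_ids)
    d = len(node_ids)
    for i in range(d):
        for j in range(i + 1, d):
            if abs(r[i, j]) > r_threshold and p[i, j] < p_threshold:
                g.add_edge(node_ids[i], node_ids[j], weight=float(r[i, j]),
                           p=float(p[i, j]))
    return g


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_path_length: float
    diameter: int
    clustering_coefficient: float
    modularity: float
    cumulative_degree_distribution: dict[int, float] = field(
        default_factory=dict)


def topology(network: nx.Graph, seed: int = 0) -> TopologySummary:
    """Topology metrics of a signed network.

    Path metrics are computed on the unweighted skeleton of the largest
    connected component; clustering is the average local clustering over
    all nodes; modularity is Newman Q of the greedy (CNM) partition on
    absolute edge weights.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("empty network")
    absg = nx.Graph()
    absg.add_nodes_from(network.nodes)
    for u, v, data in network.edges(data=True):
        absg.add_edge(u, v, weight=abs(data.get("weight", 1.0)))
    comps = list(nx.connected_components(absg))
    giant = absg.subgraph(max(comps, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = nx.diameter(giant)
    else:
        apl, diam = 0.0, 0
    clustering = nx.average_clustering(absg)
    if absg.number_of_edges() > 0:
        communities = nx.community.greedy_modularity_communities(
            absg, weight="weight")
        q = nx.community.modularity(absg, communities, weight="weight")
    else:
        q = 0.0
    degrees = np.array([d for _, d in absg.degree()])
    cdd = {int(k): float((degrees >= k).mean())
           for k in range(0, degrees.max() + 1)} if degrees.size else {}
    return TopologySummary(absg.number_of_nodes(), absg.number_of_edges(),
                           float(apl), int(diam), float(clustering),
                           float(q), cdd)


# ---------------------------------------------------------------------------
# Cohesion
# ---------------------------------------------------------------------------

@dataclass
class CohesionResult:
    connectedness_pos: pd.Series
    connectedness_neg: pd.Series
    cohesion_pos: pd.Series       # per sample, >= 0
    cohesion_neg: pd.Series       # per sample, <= 0
    ratio: float                  # |mean negative| / mean positive
    corrected: pd.DataFrame | None = None   # null-corrected correlations

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cohesion_pos": self.cohesion_pos,
                             "cohesion_neg": self.cohesion_neg})


def cohesion(table: AsvTable | np.ndarray, n_null: int = 200, seed: int = 0
             ) -> CohesionResult:
    """Null-corrected cohesion (taxon-shuffle construction).

    Observed pairwise Pearson correlations between taxa are corrected by
    the mean correlation under a null that permutes each taxon's
    abundances across samples independently.  A taxon's positive
    (negative) connectedness is the mean of its positive (negative)
    corrected correlations with all partners; a sample's positive
    (negative) cohesion is its abundance-weighted sum of connectedness
    values.  The network-level ratio is |mean cohesion_neg| divided by
    mean cohesion_pos (NaN when positive cohesion is zero).
    """
    if isinstance(table, AsvTable):
        if table.n_samples < 10:
            raise ValidationError("cohesion needs >= 10 samples")
        sample_ids = table.sample_ids
        taxon_ids = table.taxon_ids
        rel_raw = relative_abundance(table)
    else:
        # a pre-computed abundance matrix is used as-is (no closure)
        rel_raw = np.asarray(table, float)
        if rel_raw.shape[0] < 10:
            raise ValidationError("cohesion needs >= 10 samples")
        sample_ids = [f"sample_{i + 1}" for i in range(rel_raw.shape[0])]
        taxon_ids = [f"taxon_{j + 1}" for j in range(rel_raw.shape[1])]
    # canonical sample order: the Monte-Carlo null (hence the ratio) is
    # then exactly invariant to the input row order
    order = np.argsort(sample_ids)
    inverse = np.argsort(order)
    rel = rel_raw[order]
    sd = rel.std(axis=0)
    usable = sd > 0
    if not usable.all():
        import logging
        logging.getLogger("rhizoecol").warning(
            "excluding %d zero-variance taxa from cohesion",
            int((~usable).sum()))
    X = rel[:, usable]
    taxa = [t for t, u in zip(taxon_ids, usable) if u]
    obs = np.corrcoef(X.T)
    rng = np.random.default_rng(seed)
    n, d = X.shape
    null_mean = np.zeros((d, d))
    for _ in range(n_null):
        shuffled = np.empty_like(X)
        for j in range(d):
            shuffled[:, j] = X[rng.permutation(n), j]
        null_mean += np.corrcoef(shuffled.T)
    null_mean /= n_null
    corrected = obs - null_mean
    np.fill_diagonal(corrected, 0.0)
    pos = np.where(corrected > 0, corrected, np.nan)
    neg = np.where(corrected < 0, corrected, np.nan)
    with np.errstate(invalid="ignore"):
        conn_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        conn_neg = np.nan_to_num(np.nanmean(neg, axis=1))
    coh_pos = (X @ conn_pos)[inverse]
    coh_neg = (X @ conn_neg)[inverse]
    mean_pos = coh_pos.mean()
    ratio = float(abs(coh_neg.mean()) / mean_pos) if mean_pos > 0 else \
        float("nan")
    ids = sample_ids
    return CohesionResult(
        pd.Series(conn_pos, index=taxa),
        pd.Series(conn_neg, index=taxa),
        pd.Series(coh_pos, index=ids),
        pd.Series(coh_neg, index=ids),
        ratio,
        pd.DataFrame(corrected, index=taxa, columns=taxa),
    )


# ---------------------------------------------------------------------------
# Outer (cross-compartment, sample-level) networks
# ---------------------------------------------------------------------------

def outer_network(tables: dict[str, AsvTable], r_threshold: float = 0.6,
                  p_threshold: float = 0.01) -> nx.Graph:
    """Sample-level Spearman network across compartments.

    Only cross-compartment sample pairs are tested: Spearman correlation
    of their shared-taxon abundance profiles, thresholded like the inner
    networks.  Nodes carry a ``compartment`` attribute.
    """
    habitats = list(tables)
    taxa = tables[habitats[0]].taxon_ids
    g = nx.Graph()
    profiles = {}
    for h in habitats:
        t = tables[h]
        if t.taxon_ids != taxa:
            raise ValidationError("tables must share the taxon universe")
        rel = relative_abundance(t)
        for k, sid in enumerate(t.sample_ids):
            node = f"{h}:{sid}"
            profiles[node] = rel[k]
            g.add_node(node, compartment=h)
    nodes = list(profiles)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            na, nb = nodes[a], nodes[b]
            if g.nodes[na]["compartment"] == g.nodes[nb]["compartment"]:
                continue
            xa, xb = profiles[na], profiles[nb]
            shared = (xa > 0) | (xb > 0)
            if shared.sum() < 3:
                import logging
                logging.getLogger("rhizoecol").warning(
                    "pair %s-%s has <3 shared taxa; skipped", na, nb)
                continue
            rho, p = stats.spearmanr(xa[shared], xb[shared])
            if np.isfinite(rho) and abs(rho) > r_threshold and \
                    p < p_threshold:
                g.add_edge(na, nb, weight=float(rho), p=float(p))
    return g
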