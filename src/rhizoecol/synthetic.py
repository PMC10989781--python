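"""Synthetic communities with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery test that
needs data whose generating process is known exactly.  This module builds:

* neutrally assembled local communities under the Sloan model (each local
  relative abundance a Beta draw around the metacommunity abundance with
  concentration ``N*m``),
* niche-filtered communities along an environmental gradient with
  phylogenetically conserved (Brownian) optima,
* compositional count data with a known log-basis correlation matrix,
* sink communities that are explicit mixtures of source profiles, and
* a four-microhabitat soil-root continuum with progressively stronger,
  nested taxon filtering.

All generators are pure functions of ``(cfg, seed)``: identical counts on
every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .core_io import AsvTable, SampleMetadata, ValidationError

__all__ = [
    "SimulationConfig", "SyntheticDataset", "simulate_phylogeny",
    "metacommunity_logseries", "simulate_neutral_communities",
    "simulate_niche_communities", "simulate_correlated_compositions",
    "simulate_source_sink", "simulate_continuum",
]


@dataclass
class SimulationConfig:
    """Parameters of the community generators.

    ``depth`` is reads per sample, ``m`` the Sloan migration rate (the
    probability that a death in the local community is replaced by an
    immigrant), ``niche_breadth`` the Gaussian tolerance in gradient
    units, ``gradient`` a per-sample MAP-like covariate.
    """

    n_taxa: int = 50
    n_samples: int = 200
    depth: int = 1000
    m: float = 0.1
    niche_breadth: float = 1.0
    selection_strength: float = 1.0
    gradient: np.ndarray | None = None
    basis_correlation: np.ndarray | None = None
    logseries_theta: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples < 2 or self.depth < 2:
            raise ValidationError("n_taxa, n_samples and depth must be >= 2")
        if not (0 < self.m <= 1):
            raise ValidationError("migration rate m must lie in (0, 1]")
        if self.niche_breadth <= 0:
            raise ValidationError("niche breadth sigma must be > 0")
        if self.selection_strength < 0:
            raise ValidationError("selection_strength must be >= 0")
        if self.basis_correlation is not None:
            c = np.asarray(self.basis_correlation, float)
            if not np.allclose(np.diag(c), 1.0):
                raise ValidationError("basis correlation needs unit diagonal")
            if np.abs(c).max() > 1 + 1e-12:
                raise ValidationError("correlation entries must lie in [-1,1]")
            if not np.allclose(c, c.T):
                raise ValidationError("basis correlation must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValidationError("basis correlation must be PSD")


@dataclass
class SyntheticDataset:
    """A generated table/tree/metadata triple plus the generating truth."""

    table: AsvTable
    tree: TreeNode | None
    metadata: SampleMetadata | None
    truth: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phylogeny and metacommunity
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_taxa: int, seed: int = 0,
                       birth_rate: float = 1.0) -> TreeNode:
    """Yule (pure-birth) tree with ``n_taxa`` tips labelled ASV_1..ASV_n.

    Fully bifurcating and rooted: 2*n_taxa - 1 nodes in total.  Waiting
    times between speciations are exponential with rate ``birth_rate``
    times the number of extant lineages; branch lengths are strictly
    positive.
    """
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=None)
    tips = [root]
    # grow: at each event split a uniformly chosen extant tip
    birth_times = {id(root): 0.0}
    now = 0.0
    while len(tips) < n_taxa:
        now += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips.pop(rng.integers(len(tips)))
        left, right = TreeNode(), TreeNode()
        parent.extend([left, right])
        parent.length = (now - birth_times[id(parent)]
                         if parent.parent is not None else None)
        birth_times[id(left)] = birth_times[id(right)] = now
        tips.extend([left, right])
    now += rng.exponential(1.0 / (birth_rate * len(tips)))
    order = rng.permutation(n_taxa)
    for k, tip in enumerate(tips):
        tip.length = max(now - birth_times[id(tip)], 1e-9)
        tip.name = f"ASV_{order[k] + 1}"
    root.length = None
    return root


def metacommunity_logseries(n_taxa: int, seed: int = 0,
                            theta: float = 0.995) -> np.ndarray:
    """Skewed metacommunity relative abundances from a Fisher log-series.

    Neutral-model fitting needs rare taxa; the log-series is the abundance
    structure neutral theory itself predicts for the source pool.
    """
    rng = np.random.default_rng(seed)
    raw = stats.logser.rvs(theta, size=n_taxa, random_state=rng).astype(float)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# Neutral assembly
# ---------------------------------------------------------------------------

def simulate_neutral_communities(cfg: SimulationConfig,
                                 p: np.ndarray | None = None
                                 ) -> SyntheticDataset:
    """Local communities under the Sloan neutral model.

    For each sample the relative abundance of taxon ``j`` is drawn from
    ``Beta(N*m*p_j, N*m*(1-p_j))`` — the stationary distribution of the
    neutral birth-death-immigration process — renormalised across taxa,
    then reads are drawn multinomially at the configured depth.  The
    recorded truth is the migration rate ``m`` and the metacommunity
    vector ``p``.
    """
    rng = np.random.default_rng(cfg.seed)
    if p is None:
        p = metacommunity_logseries(cfg.n_taxa, seed=cfg.seed,
                                    theta=cfg.logseries_theta)
    p = np.asarray(p, float)
    if abs(p.sum() - 1) > 1e-9:
        raise ValidationError("metacommunity abundances must sum to 1")
    nm = cfg.depth * cfg.m
    a = np.clip(nm * p, 1e-12, None)
    b = np.clip(nm * (1 - p), 1e-12, None)
    rel = rng.beta(a, b, size=(cfg.n_samples, cfg.n_taxa))
    rel = rel / rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.depth, row) for row in rel])
    table = _table_from_counts(counts)
    tree = simulate_phylogeny(cfg.n_taxa, seed=cfg.seed + 1)
    meta = _default_metadata(table.sample_ids)
    return SyntheticDataset(table, tree, meta,
                            truth={"m": cfg.m, "N": cfg.depth, "p": p})


# ---------------------------------------------------------------------------
# Niche filtering along a gradient
# ---------------------------------------------------------------------------

def brownian_tip_traits(tree: TreeNode, seed: int = 0,
                        rate: float = 1.0) -> dict[str, float]:
    """Evolve a trait on the tree by Brownian motion (root value 0).

    Increments along each branch are N(0, rate * branch_length); tip
    values are therefore phylogenetically conserved.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + rng.normal(
            0.0, np.sqrt(max(rate * bl, 1e-12)))
        if node.is_tip():
            out[node.name] = values[id(node)]
    return out


def simulate_niche_communities(cfg: SimulationConfig,
                               p: np.ndarray | None = None
                               ) -> SyntheticDataset:
    """Gaussian environmental filtering with Brownian (conserved) optima.

    Expected relative abundance of taxon ``j`` in sample ``i`` is
    proportional to ``p_j * exp(-(g_i - o_j)^2 / (2 sigma^2)) ** s`` with
    ``s`` the selection strength (``s = 0`` reduces exactly to sampling
    the metacommunity).  Counts are multinomial at the configured depth.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_phylogeny(cfg.n_taxa, seed=cfg.seed + 1)
    if p is None:
        p = metacommunity_logseries(cfg.n_taxa, seed=cfg.seed,
                                    theta=cfg.logseries_theta)
    traits = brownian_tip_traits(tree, seed=cfg.seed + 2)
    taxon_ids = [f"ASV_{j + 1}" for j in range(cfg.n_taxa)]
    optima = np.array([traits[t] for t in taxon_ids])
    # place the gradient across the span of the evolved optima
    if cfg.gradient is None:
        gradient = np.linspace(optima.min(), optima.max(), cfg.n_samples)
    else:
        gradient = np.asarray(cfg.gradient, float)
        if gradient.shape != (cfg.n_samples,):
            raise ValidationError("gradient length must equal n_samples")
    kernel = np.exp(-((gradient[:, None] - optima[None, :]) ** 2)
                    / (2 * cfg.niche_breadth ** 2))
    weights = p[None, :] * kernel ** cfg.selection_strength
    weights = weights / weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.depth, row) for row in weights])
    table = _table_from_counts(counts, taxon_ids=taxon_ids)
    meta = _default_metadata(table.sample_ids)
    meta.frame["MAP"] = gradient[[table.sample_ids.index(s)
                                  for s in table.sample_ids]]
    return SyntheticDataset(
        table, tree, meta,
        truth={"optima": dict(zip(taxon_ids, optima)),
               "sigma": cfg.niche_breadth, "gradient": gradient,
               "selection_strength": cfg.selection_strength, "p": p})


# ---------------------------------------------------------------------------
# Correlated compositions (SparCC ground truth)
# ---------------------------------------------------------------------------

def simulate_correlated_compositions(cfg: SimulationConfig,
                                     log_mean: np.ndarray | None = None,
                                     log_sd: float = 1.0) -> SyntheticDataset:
    """Compositional counts whose log-basis abundances have a known
    correlation matrix.

    Basis abundances are log-normal: log-abundances drawn multivariate
    normal with the configured correlation (scaled by ``log_sd``), then
    exponentiated, closed to proportions and sampled multinomially.
    """
    if cfg.basis_correlation is None:
        corr = np.eye(cfg.n_taxa)
    else:
        corr = np.asarray(cfg.basis_correlation, float)
        if corr.shape != (cfg.n_taxa, cfg.n_taxa):
            raise ValidationError("basis correlation shape must match n_taxa")
    rng = np.random.default_rng(cfg.seed)
    if log_mean is None:
        log_mean = np.zeros(cfg.n_taxa)
    cov = corr * log_sd ** 2
    # eigendecomposition root tolerates the semi-definite boundary
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((cfg.n_samples, cfg.n_taxa))
    log_basis = log_mean[None, :] + z @ root.T
    basis = np.exp(log_basis)
    props = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.depth, row) for row in props])
    table = _table_from_counts(counts)
    return SyntheticDataset(table, None, None,
                            truth={"basis_correlation": corr})


# ---------------------------------------------------------------------------
# Source / sink mixtures
# ---------------------------------------------------------------------------

def simulate_source_sink(source_profiles: np.ndarray,
                         mixing_proportions,
                         depth: int = 10_000,
                         n_sinks: int = 10,
                         seed: int = 0,
                         unknown_profile: np.ndarray | None = None):
    """Sinks that are known multinomial mixtures of source profiles.

    ``mixing_proportions`` must be non-negative with sum <= 1; any
    remainder is drawn from ``unknown_profile`` (a held-out profile,
    generated disjoint-in-expectation if not supplied).  Returns
    ``(sources: AsvTable, sinks: AsvTable, truth)``.
    """
    rng = np.random.default_rng(seed)
    profiles = np.asarray(source_profiles, float)
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    props = np.asarray(mixing_proportions, float)
    if (props < 0).any():
        raise ValidationError("mixing proportions must be >= 0")
    if props.sum() > 1 + 1e-12:
        raise ValidationError("mixing proportions must sum to <= 1")
    if props.shape[0] != profiles.shape[0]:
        raise ValidationError("one mixing proportion per source required")
    n_src, n_taxa = profiles.shape
    unknown_frac = 1.0 - props.sum()
    if unknown_profile is None:
        unknown_profile = rng.dirichlet(np.full(n_taxa, 0.2))
    mixture = props @ profiles + unknown_frac * unknown_profile
    src_counts = np.vstack([rng.multinomial(depth, pr) for pr in profiles])
    sink_counts = np.vstack([rng.multinomial(depth, mixture)
                             for _ in range(n_sinks)])
    taxa = [f"ASV_{j + 1}" for j in range(n_taxa)]
    sources = AsvTable([f"source_{k + 1}" for k in range(n_src)], taxa,
                       src_counts)
    sinks = AsvTable([f"sink_{k + 1}" for k in range(n_sinks)], taxa,
                     sink_counts)
    truth = {"mixing_proportions": props, "unknown": unknown_frac}
    return sources, sinks, truth


# ---------------------------------------------------------------------------
# Soil-root continuum
# ---------------------------------------------------------------------------

def simulate_continuum(cfg: SimulationConfig,
                       retain_fractions=(0.6, 0.3, 0.1),
                       n_sites: int | None = None,
                       carryover: float = 0.3) -> SyntheticDataset:
    """Four-microhabitat continuum with nested taxon filtering.

    Soil samples are drawn from the metacommunity; rhizosphere,
    rhizoplane and endosphere communities retain nested, progressively
    smaller taxon subsets (fractions ``f1 > f2 > f3``) with abundances
    renormalised, so richness and Shannon diversity decline from soil to
    endosphere.  Each root compartment additionally receives a
    ``carryover`` fraction of its parent compartment's expected profile —
    the colonisation cascade soil → rhizosphere → rhizoplane →
    endosphere — so the inner compartments are genuinely derived from
    their neighbours, not just subsets.  Retained sets and the carryover
    are recorded as truth.
    """
    f = tuple(float(x) for x in retain_fractions)
    if not (0 < f[2] < f[1] < f[0] <= 1):
        raise ValidationError(
            "retain fractions must be strictly decreasing within (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n_sites = n_sites or max(cfg.n_samples // 4, 2)
    p = metacommunity_logseries(cfg.n_taxa, seed=cfg.seed,
                                theta=cfg.logseries_theta)
    taxa = [f"ASV_{j + 1}" for j in range(cfg.n_taxa)]
    # nested subsets biased toward abundant taxa (roots select colonisers,
    # and abundant soil taxa are likelier to reach the root surface)
    order = rng.permutation(cfg.n_taxa)
    rank = np.argsort(np.argsort(-p[order]))
    keep_sets = []
    for frac in f:
        k = max(int(round(frac * cfg.n_taxa)), 2)
        keep_sets.append(set(order[np.argsort(rank)[:k]]))
    if not (0 <= carryover < 1):
        raise ValidationError("carryover must lie in [0, 1)")
    habitats = ("soil", "rhizosphere", "rhizoplane", "endosphere")
    # expected per-compartment profiles: filtered + parent carryover
    profiles = [p.copy()]
    for h in range(1, 4):
        mask = np.zeros(cfg.n_taxa, bool)
        mask[list(keep_sets[h - 1])] = True
        filtered = np.where(mask, p, 0.0)
        filtered = filtered / filtered.sum()
        prof = (1.0 - carryover) * filtered + carryover * profiles[h - 1]
        profiles.append(prof)
    rows, sample_ids, hab_col, site_col = [], [], [], []
    for site in range(n_sites):
        for h, habitat in enumerate(habitats):
            # mild site-level lognormal wobble so samples are not iid
            wobble = rng.lognormal(0.0, 0.3, cfg.n_taxa)
            weights = profiles[h] * wobble
            weights = weights / weights.sum()
            rows.append(rng.multinomial(cfg.depth, weights))
            sample_ids.append(f"S{site + 1}_{habitat}")
            hab_col.append(habitat)
            site_col.append(f"site_{site + 1}")
    table = AsvTable.from_dataframe(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa))
    meta = pd.DataFrame({"microhabitat": hab_col, "site_id": site_col},
                        index=sample_ids).loc[table.sample_ids]
    tree = simulate_phylogeny(cfg.n_taxa, seed=cfg.seed + 1)
    truth = {"retain_fractions": f, "carryover": carryover,
             "retained": {h: sorted(taxa[j] for j in s)
                          for h, s in zip(habitats[1:], keep_sets)}}
    return SyntheticDataset(table, tree, SampleMetadata(meta), truth)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _table_from_counts(counts: np.ndarray, taxon_ids=None) -> AsvTable:
    n_samples, n_taxa = counts.shape
    taxon_ids = taxon_ids or [f"ASV_{j + 1}" for j in range(n_taxa)]
    sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
    return AsvTable.from_dataframe(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids))


def _default_metadata(sample_ids) -> SampleMetadata:
    return SampleMetadata(pd.DataFrame(index=list(sample_ids)))
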