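"""Community assembly inference: phylogenetic and taxonomic null models
plus the Sloan neutral community model.

The partitioning logic follows the two-stage null-model framework used
throughout microbial community ecology: the beta nearest taxon index
(βNTI, a standardised deviate of abundance-weighted βMNTD against a
tip-shuffling null) detects phylogenetically structured selection, and the
Bray-Curtis Raup-Crick index (RC_bray, a probabilistic-assembly null)
separates dispersal processes from drift among the pairs selection does
not explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .core_io import AsvTable, ValidationError, as_distance_matrix, \
    relative_abundance
from .diversity import TreeIndex, _tree_index

__all__ = [
    "beta_mntd", "bnti", "rc_bray", "classify_process", "process_summary",
    "fit_neutral_model", "NeutralFit", "PROCESSES", "assembly_table",
]

PROCESSES = ("variable selection", "homogeneous selection",
             "dispersal limitation", "homogenizing dispersal", "undominated")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# beta-MNTD and beta-NTI
# ---------------------------------------------------------------------------

def _beta_mntd_matrix(rel: np.ndarray, presence: np.ndarray,
                      coph: np.ndarray) -> np.ndarray:
    """Abundance-weighted βMNTD for all sample pairs.

    For the directed value A→B each taxon in A contributes its relative
    abundance times the cophenetic distance to its nearest taxon in B;
    the symmetric statistic is the mean of the two directions.
    """
    n_samples, n_taxa = rel.shape
    # nearest[b, i] = distance from taxon i to the closest taxon of sample b
    big = np.inf
    nearest = np.empty((n_samples, n_taxa))
    for b in range(n_samples):
        cols = coph[:, presence[b]]
        nearest[b] = cols.min(axis=1) if cols.shape[1] else big
    directed = rel @ nearest.T          # [a, b] = sum_i w_ai * nearest_b(i)
    return (directed + directed.T) / 2.0


def beta_mntd(table: AsvTable, tree: TreeNode | TreeIndex,
              weighted: bool = True) -> DistanceMatrix:
    """Abundance-weighted mean nearest-taxon phylogenetic distance."""
    idx = _tree_index(tree, table.taxon_ids)
    presence = table.counts > 0
    if (presence.sum(axis=1) == 0).any():
        raise ValidationError("community with zero taxa")
    rel = relative_abundance(table) if weighted else \
        presence / presence.sum(axis=1, keepdims=True)
    coph = idx.cophenetic()
    return as_distance_matrix(_beta_mntd_matrix(rel, presence, coph),
                              table.sample_ids)


def bnti(table: AsvTable, tree: TreeNode | TreeIndex, n_null: int = 999,
         seed: int = 0, weighted: bool = True) -> DistanceMatrix:
    """Beta nearest taxon index: (obs - mean_null)/sd_null per pair.

    The null shuffles taxon labels across all tree tips each iteration,
    breaking the phylogeny-abundance association while preserving the
    topology, branch lengths and abundance structure.  Pairs whose null
    spread is zero get NaN with a warning.
    """
    idx = _tree_index(tree, table.taxon_ids)
    presence = table.counts > 0
    rel = relative_abundance(table) if weighted else \
        presence / presence.sum(axis=1, keepdims=True)
    coph = idx.cophenetic()
    obs = _beta_mntd_matrix(rel, presence, coph)
    rng = np.random.default_rng(seed)
    n_taxa = table.n_taxa
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_matrix(rel, presence,
                                 coph[np.ix_(perm, perm)])
        delta = null - mean
        mean += delta / (k + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd == 0] = np.nan
    if np.isnan(z[np.triu_indices_from(z, 1)]).any():
        import logging
        logging.getLogger("rhizoecol").warning(
            "some pairs have zero null spread; βNTI reported as missing")
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    dm = DistanceMatrix(np.zeros_like(z), ids=table.sample_ids)
    dm.data[:] = z  # deviates may be negative; bypass dissimilarity checks
    return dm


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _null_communities(rng, occupancy_w, abundance_w, richness, depth,
                      n_null):
    """Probabilistic null assembly: draw the observed richness of taxa
    with probability proportional to occupancy (each drawn taxon starts
    with one individual, so the null richness matches exactly), then fill
    to the observed depth with probability proportional to metacommunity
    abundance."""
    n_taxa = occupancy_w.size
    # Gumbel top-k gives seeded weighted sampling without replacement,
    # vectorised across null iterations
    gumbel = rng.gumbel(size=(n_null, n_taxa))
    keys = np.log(occupancy_w)[None, :] + gumbel
    chosen = np.argsort(keys, axis=1)[:, -richness:]
    base = np.zeros((n_null, n_taxa), dtype=np.int64)
    rows = np.repeat(np.arange(n_null), richness)
    base[rows, chosen.ravel()] = 1
    probs = base * abundance_w[None, :]
    probs = probs / probs.sum(axis=1, keepdims=True)
    return base + rng.multinomial(max(depth - richness, 0), probs)


def rc_bray(table: AsvTable, n_null: int = 999, seed: int = 0,
            return_raw: bool = False, pairs=None,
            occupancy_weights: np.ndarray | None = None,
            abundance_weights: np.ndarray | None = None) -> DistanceMatrix:
    """Raup-Crick index on Bray-Curtis, rescaled to [-1, 1].

    For each sample pair, null community pairs are assembled from the
    table-wide metacommunity (occupancy-weighted richness draw, then
    abundance-weighted multinomial fill to the observed depth); RC is the
    fraction of null Bray-Curtis values below the observed one (ties
    counted half), mapped to [-1, 1] by 2*(RC - 0.5).

    ``pairs`` optionally restricts evaluation to the given (i, j) sample
    index pairs (others reported as 0).  Metacommunity weights default to
    the table-wide occupancy and summed relative abundance; a regional
    species pool known from outside the table can be supplied explicitly.
    """
    if table.n_samples < 2:
        raise ValidationError("RC_bray needs at least two samples")
    counts = table.counts
    if abundance_weights is None:
        abund = counts.sum(axis=0).astype(float)
        abund_w = abund / abund.sum()
    else:
        abund_w = np.asarray(abundance_weights, float)
        abund_w = abund_w / abund_w.sum()
    occupancy = ((counts > 0).mean(axis=0) if occupancy_weights is None
                 else np.asarray(occupancy_weights, float))
    occ_w = np.clip(occupancy, 1e-12, None)
    richness = (counts > 0).sum(axis=1)
    depth = counts.sum(axis=1)
    n = table.n_samples
    rng = np.random.default_rng(seed)
    obs_bc = squareform(pdist(counts, metric="braycurtis"))
    raw = np.zeros((n, n))
    if pairs is None:
        # pre-draw null communities per sample, reused across its pairs
        nulls = [
            _null_communities(rng, occ_w, abund_w, int(richness[i]),
                              int(depth[i]), n_null)
            for i in range(n)
        ]
        pair_iter = [(i, j, nulls[i], nulls[j])
                     for i in range(n) for j in range(i + 1, n)]
    else:
        pair_iter = [
            (i, j,
             _null_communities(rng, occ_w, abund_w, int(richness[i]),
                               int(depth[i]), n_null),
             _null_communities(rng, occ_w, abund_w, int(richness[j]),
                               int(depth[j]), n_null))
            for i, j in pairs
        ]
    for i, j, ni, nj in pair_iter:
        ni, nj = ni.astype(float), nj.astype(float)
        mins = np.minimum(ni, nj).sum(axis=1)
        sums = ni.sum(axis=1) + nj.sum(axis=1)
        null_bc = 1.0 - 2.0 * mins / sums
        less = (null_bc < obs_bc[i, j] - 1e-12).sum()
        ties = (np.abs(null_bc - obs_bc[i, j]) <= 1e-12).sum()
        raw[i, j] = raw[j, i] = (less + 0.5 * ties) / n_null
    rescaled = 2.0 * (raw - 0.5)
    np.fill_diagonal(rescaled, 0.0)
    out = DistanceMatrix(np.zeros_like(rescaled), ids=table.sample_ids)
    out.data[:] = np.clip(raw, 0, 1) if return_raw else rescaled
    return out


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------

def classify_process(bnti_value: float, rc_value: float,
                     bnti_threshold: float = BNTI_THRESHOLD,
                     rc_threshold: float = RC_THRESHOLD) -> str:
    """Assign the five-way ecological process category for one pair.

    Deterministic selection when |βNTI| exceeds the threshold (positive:
    variable, negative: homogeneous selection); otherwise RC_bray decides
    between dispersal limitation (+), homogenizing dispersal (-) and the
    undominated (drift) remainder.  Boundary values count as stochastic.
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        return "unclassified"
    if bnti_value > bnti_threshold:
        return "variable selection"
    if bnti_value < -bnti_threshold:
        return "homogeneous selection"
    if rc_value > rc_threshold:
        return "dispersal limitation"
    if rc_value < -rc_threshold:
        return "homogenizing dispersal"
    return "undominated"


def assembly_table(bnti_dm: DistanceMatrix, rc_dm: DistanceMatrix
                   ) -> pd.DataFrame:
    """Per-pair βNTI, RC_bray and process category as a tidy frame."""
    ids = list(bnti_dm.ids)
    if list(rc_dm.ids) != ids:
        raise ValidationError("βNTI and RC matrices must share sample order")
    recs = []
    b, r = np.asarray(bnti_dm.data), np.asarray(rc_dm.data)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            recs.append((ids[i], ids[j], b[i, j], r[i, j],
                         classify_process(b[i, j], r[i, j])))
    return pd.DataFrame(recs, columns=["sample_a", "sample_b", "bnti",
                                       "rc_bray", "process"])


def process_summary(results: pd.DataFrame, grouping: pd.Series | None = None
                    ) -> pd.DataFrame:
    """Percentage of sample pairs per process, overall or per group.

    When grouping is given, a pair belongs to a group only if both of its
    samples carry the same group label; empty groups are omitted with a
    warning.  Percentages sum to 100 per row.
    """
    frames = {}
    if grouping is None:
        frames["all"] = results
    else:
        for g in pd.unique(grouping):
            members = set(grouping[grouping == g].index)
            sub = results[results["sample_a"].isin(members)
                          & results["sample_b"].isin(members)]
            if len(sub) == 0:
                import logging
                logging.getLogger("rhizoecol").warning(
                    "group %s has no classified pairs; omitted", g)
                continue
            frames[g] = sub
    rows = {}
    for g, sub in frames.items():
        classified = sub[sub["process"] != "unclassified"]
        counts = classified["process"].value_counts()
        total = counts.sum()
        rows[g] = {p: 100.0 * counts.get(p, 0) / total for p in PROCESSES}
    return pd.DataFrame(rows).T[list(PROCESSES)]


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NeutralFit:
    """Fit of the Sloan neutral model to occurrence frequencies.

    ``m`` is the estimated migration rate, ``N`` the mean community size
    in reads, ``r2`` the coefficient of determination of predicted versus
    observed frequency, and ``per_taxon`` carries p (metacommunity mean
    relative abundance), observed and predicted frequency with the 95%
    binomial envelope.
    """

    m: float
    N: float
    r2: float
    detection_limit: float
    per_taxon: pd.DataFrame


def _predicted_frequency(p: np.ndarray, N: float, m: float,
                         d: float) -> np.ndarray:
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(d, np.clip(a, 1e-12, None),
                                np.clip(b, 1e-12, None))


def fit_neutral_model(table: AsvTable, detection_limit: float | None = None,
                      community_size: float | None = None) -> NeutralFit:
    """Least-squares fit of the Sloan neutral model.

    The model predicts a taxon's occurrence frequency across local
    communities from its metacommunity relative abundance ``p`` via
    ``1 - BetaCDF(d; N m p, N m (1-p))``, with ``N`` the mean sample
    depth and ``d`` the detection limit.  The default ``d = ln 2 / N`` is
    the relative abundance at which binomial sampling at depth N detects
    a taxon with probability one half, so the hard-threshold prediction
    stays consistent with read-sampled counts (``d = 1/N`` overstates the
    limit and biases m upward).  ``m`` is estimated by bounded least
    squares over taxa.
    """
    if table.n_samples < 10:
        raise ValidationError("neutral fit needs at least 10 samples")
    rel = relative_abundance(table)
    p = rel.mean(axis=0)
    freq_obs = (table.counts > 0).mean(axis=0)
    N = (float(community_size) if community_size is not None
         else float(table.counts.sum(axis=1).mean()))
    d = detection_limit if detection_limit is not None else np.log(2.0) / N
    if np.all(freq_obs >= 1.0):
        raise ValidationError(
            "all taxa occur in every sample; neutral fit is degenerate")

    def sse(m):
        return ((freq_obs - _predicted_frequency(p, N, m, d)) ** 2).sum()

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    m_hat = float(res.x)
    pred = _predicted_frequency(p, N, m_hat, d)
    sst = ((freq_obs - freq_obs.mean()) ** 2).sum()
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan
    half = 1.96 * np.sqrt(np.clip(pred * (1 - pred), 0, None)
                          / table.n_samples)
    per_taxon = pd.DataFrame({
        "p": p, "freq_obs": freq_obs, "freq_pred": pred,
        "ci_lower": np.clip(pred - half, 0, 1),
        "ci_upper": np.clip(pred + half, 0, 1),
    }, index=table.taxon_ids)
    return NeutralFit(m_hat, N, float(r2), float(d), per_taxon)
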