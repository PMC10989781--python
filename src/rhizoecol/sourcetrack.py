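"""Bayesian attribution of sink communities to source environments.

Implements the collapsed Gibbs sampler of the classic microbial
source-tracking model: every read in a sink carries a latent source
assignment (one of the known source environments or an explicit
"unknown" source whose taxon profile is learned from the reads assigned
to it); each sweep resamples every assignment from its conditional,

    P(z_i = v | ...) ∝ P(taxon_i | v) * (n_v^(-i) + beta),

where for a known source P(taxon|v) uses the fixed source counts with a
Dirichlet pseudocount ``alpha1`` and for the unknown source the counts
currently assigned to it with pseudocount ``alpha2``.  Posterior mean
mixing proportions are averaged over retained sweeps and restarts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .core_io import AsvTable, ValidationError, relative_abundance

__all__ = ["gibbs_attribution", "pairwise_similarity_matrix"]


@njit(cache=True)
def _gibbs_sweeps(taxa, z, src_counts, src_totals, assigned_counts,
                  n_assigned, alpha1, alpha2, beta, n_taxa, burn_in,
                  n_draws, thin, rand_seq, out_props):
    """Collapsed Gibbs sweeps over read assignments.

    ``assigned_counts[v, t]`` tracks sink reads of taxon t currently
    assigned to environment v (the last row is the unknown source); for a
    known source these counts join the fixed training counts in its
    multinomial, as the full conditional requires.
    """
    n_reads = taxa.shape[0]
    n_src = src_counts.shape[0]
    n_env = n_src + 1
    probs = np.empty(n_env)
    r = 0
    draw = 0
    total_sweeps = burn_in + n_draws * thin
    for sweep in range(total_sweeps):
        for i in range(n_reads):
            t = taxa[i]
            old = z[i]
            n_assigned[old] -= 1
            assigned_counts[old, t] -= 1
            acc = 0.0
            for v in range(n_src):
                pt = (src_counts[v, t] + assigned_counts[v, t] + alpha1) / \
                     (src_totals[v] + n_assigned[v] + alpha1 * n_taxa)
                probs[v] = pt * (n_assigned[v] + beta)
                acc += probs[v]
            pt = (assigned_counts[n_src, t] + alpha2) / \
                 (n_assigned[n_src] + alpha2 * n_taxa)
            probs[n_src] = pt * (n_assigned[n_src] + beta)
            acc += probs[n_src]
            u = rand_seq[r] * acc
            r += 1
            new = 0
            cum = probs[0]
            while cum < u and new < n_env - 1:
                new += 1
                cum += probs[new]
            z[i] = new
            n_assigned[new] += 1
            assigned_counts[new, t] += 1
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            for v in range(n_env):
                out_props[draw, v] = n_assigned[v] / n_reads
            draw += 1
    return draw


def _rarefy_reads(row: np.ndarray, depth: int, rng) -> np.ndarray:
    reads = np.repeat(np.arange(row.size), row)
    if reads.size <= depth:
        return reads
    return rng.choice(reads, size=depth, replace=False)


def gibbs_attribution(sources: AsvTable, sinks: AsvTable,
                      alpha1: float = 0.001, alpha2: float = 0.1,
                      beta: float = 10.0, n_restarts: int = 10,
                      burn_in: int = 100, n_draws: int = 10, thin: int = 10,
                      rarefaction_depth: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Posterior mean source proportions for every sink sample.

    ``sources`` has one row per source environment; ``sinks`` one row per
    sink sample over the same taxon universe.  Sinks are rarefied to
    ``rarefaction_depth`` assignments for tractability.  Returns a frame
    indexed by sink id with one column per source id plus ``unknown`` and
    matching ``sd_*`` columns (posterior standard deviations); rows sum
    to 1.
    """
    if sources.taxon_ids != sinks.taxon_ids:
        raise ValidationError("sources and sinks must share the taxon order")
    if sources.n_samples < 1:
        raise ValidationError("at least one source environment required")
    src_counts = sources.counts.astype(np.float64)
    src_totals = src_counts.sum(axis=1)
    if (src_totals == 0).any():
        raise ValidationError("empty source environment")
    n_taxa = sources.n_taxa
    n_src = sources.n_samples
    rng = np.random.default_rng(seed)
    env_names = list(sources.sample_ids) + ["unknown"]
    rows = []
    for s_idx, sink_id in enumerate(sinks.sample_ids):
        reads = _rarefy_reads(sinks.counts[s_idx], rarefaction_depth, rng)
        reads = np.ascontiguousarray(reads.astype(np.int64))
        all_draws = []
        for _ in range(n_restarts):
            z = rng.integers(0, n_src + 1, size=reads.size).astype(np.int64)
            n_assigned = np.bincount(z, minlength=n_src + 1).astype(np.float64)
            assigned = np.zeros((n_src + 1, n_taxa))
            for v in range(n_src + 1):
                assigned[v] = np.bincount(reads[z == v], minlength=n_taxa)
            total_sweeps = burn_in + n_draws * thin
            rand_seq = rng.random(total_sweeps * reads.size)
            out = np.zeros((n_draws, n_src + 1))
            _gibbs_sweeps(reads, z, src_counts, src_totals, assigned,
                          n_assigned, alpha1, alpha2, beta, n_taxa,
                          burn_in, n_draws, thin, rand_seq, out)
            all_draws.append(out)
        draws = np.vstack(all_draws)
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0)
        rows.append((sink_id, mean, sd))
    data = {name: [r[1][k] for r in rows] for k, name in enumerate(env_names)}
    data.update({f"sd_{name}": [r[2][k] for r in rows]
                 for k, name in enumerate(env_names)})
    return pd.DataFrame(data, index=[r[0] for r in rows])


def pairwise_similarity_matrix(tables: dict[str, AsvTable],
                               collapse_sources: bool = True,
                               seed: int = 0, **gibbs_kwargs) -> pd.DataFrame:
    """Mean attribution of each microhabitat (as sink) to the others.

    For every habitat, its samples are treated as sinks and each other
    habitat contributes one source profile (samples summed when
    ``collapse_sources``).  Returns sink habitat x (source habitat +
    unknown) mean proportions; rows sum to 1.
    """
    habitats = [h for h, t in tables.items() if t.n_samples > 0]
    if len(habitats) < 2:
        raise ValidationError("need at least two microhabitats")
    taxa = tables[habitats[0]].taxon_ids
    out = {}
    for k, sink_h in enumerate(habitats):
        src_rows, src_ids = [], []
        for src_h in habitats:
            if src_h == sink_h:
                continue
            t = tables[src_h]
            if t.taxon_ids != taxa:
                raise ValidationError("tables must share the taxon universe")
            profile = t.counts.sum(axis=0) if collapse_sources else \
                t.counts.sum(axis=0)
            src_rows.append(profile)
            src_ids.append(src_h)
        sources = AsvTable(src_ids, list(taxa), np.array(src_rows))
        attr = gibbs_attribution(sources, tables[sink_h], seed=seed + k,
                                 **gibbs_kwargs)
        mean = attr[src_ids + ["unknown"]].mean(axis=0)
        out[sink_h] = mean
    df = pd.DataFrame(out).T
    return df.reindex(columns=habitats + ["unknown"]).fillna(0.0)
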