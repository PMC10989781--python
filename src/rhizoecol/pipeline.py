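"""End-to-end pipeline orchestration with a validated TOML config.

A run executes the stages in dependency order (diversity → ordination
stats → environmental association → differential abundance → source
tracking → assembly processes → networks) on a table/tree/metadata
triple, writing each stage's artifacts plus a manifest (input hashes,
effective parameters, per-stage seeds, package version) into the output
directory.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so any stage can be re-run in isolation.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (AsvTable, SampleMetadata, ValidationError, align,
                      read_asv_table, read_metadata, read_tree,
                      write_distance_matrix)
from .diversity import alpha_diversity, bray_curtis, cap, pcoa, permanova, \
    unweighted_unifrac, weighted_unifrac
from .assembly import assembly_table, bnti, fit_neutral_model, \
    process_summary, rc_bray
from .diffabund import count_enriched_depleted, nb_wald_test
from .networks import build_network, cohesion, filter_taxa, sparcc, \
    sparcc_pvalues, topology
from .sourcetrack import pairwise_similarity_matrix

logger = logging.getLogger("rhizoecol")

STAGES = ("diversity", "ordination", "permanova", "diffabund",
          "sourcetrack", "assembly", "network")

_KNOWN_KEYS = {
    "": {"table", "tree", "metadata", "output_dir", "seed", "stages"},
    "diversity": {"metric"},
    "permanova": {"n_permutations", "factor"},
    "diffabund": {"reference", "alpha"},
    "assembly": {"n_null", "group_by", "detection_limit"},
    "network": {"min_rel_abundance", "r_threshold", "p_threshold",
                "n_iterations", "n_bootstrap"},
    "sourcetrack": {"rarefaction_depth", "n_restarts"},
    "ordination": {},
}


@dataclass
class PipelineConfig:
    table: str
    metadata: str
    tree: str | None = None
    output_dir: str = "rhizoecol_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        top = {k: v for k, v in raw.items() if not isinstance(v, dict)}
        sections = {k: v for k, v in raw.items() if isinstance(v, dict)}
        _check_keys("", top.keys())
        for sec, vals in sections.items():
            if sec not in _KNOWN_KEYS:
                raise ValidationError(
                    f"unknown config section {sec!r}"
                    + _suggest(sec, _KNOWN_KEYS.keys()))
            _check_keys(sec, vals.keys())
        stages = top.get("stages", list(STAGES))
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stages: {sorted(bad)}")
        return cls(table=top["table"], metadata=top["metadata"],
                   tree=top.get("tree"),
                   output_dir=top.get("output_dir", "rhizoecol_run"),
                   seed=int(top.get("seed", 0)), stages=list(stages),
                   params=sections)


def _suggest(key, pool) -> str:
    close = difflib.get_close_matches(str(key), [str(p) for p in pool], 1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _check_keys(section: str, keys) -> None:
    known = _KNOWN_KEYS[section]
    for k in keys:
        if k not in known:
            where = f"section [{section}]" if section else "config"
            raise ValidationError(
                f"unknown key {k!r} in {where}"
                + _suggest(k, known | (set() if section else
                                       set(_KNOWN_KEYS) - {""})))


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stage order fixed)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx])
               .generate_state(1)[0] % (2 ** 31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages and return the output directory."""
    for path in [config.table, config.metadata] + (
            [config.tree] if config.tree else []):
        if not Path(path).exists():
            raise ValidationError(f"input file missing: {path}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_asv_table(config.table)
    metadata = read_metadata(config.metadata)
    tree = read_tree(config.tree) if config.tree else None
    table, tree, metadata, report = align(table, tree, metadata)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {p: _sha256(p) for p in
                   [config.table, config.metadata]
                   + ([config.tree] if config.tree else [])},
        "alignment": {"dropped_taxa": len(report.dropped_taxa),
                      "dropped_samples": report.dropped_samples},
        "stages": {},
    }
    habitat = metadata.frame.get("microhabitat")
    for stage in config.stages:
        params = dict(config.params.get(stage, {}))
        seed = stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            _run_stage(stage, table, tree, metadata, habitat, params, seed,
                       out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][stage] = {"status": "ok", "seed": seed,
                                     "params": params}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _run_stage(stage, table, tree, metadata, habitat, params, seed, out):
    if stage == "diversity":
        alpha_diversity(table).to_csv(out / "alpha_diversity.tsv", sep="\t")
        write_distance_matrix(bray_curtis(table), out / "bray_curtis.tsv")
        if tree is not None:
            write_distance_matrix(unweighted_unifrac(table, tree),
                                  out / "unweighted_unifrac.tsv")
            write_distance_matrix(weighted_unifrac(table, tree),
                                  out / "weighted_unifrac.tsv")
    elif stage == "ordination":
        dm = bray_curtis(table)
        res = pcoa(dm)
        pd.DataFrame(res.coordinates[:, :10], index=res.sample_ids).to_csv(
            out / "pcoa_coordinates.tsv", sep="\t")
        (out / "pcoa_eigenvalues.json").write_text(json.dumps({
            "eigenvalues": res.eigenvalues[:10].tolist(),
            "proportion_explained": res.proportion_explained[:10].tolist()}))
    elif stage == "permanova":
        factor = params.get("factor", "microhabitat")
        labels = metadata.frame[factor]
        res = permanova(bray_curtis(table), labels,
                        n_permutations=int(params.get("n_permutations", 999)),
                        seed=seed)
        cap_res = cap(bray_curtis(table), labels)
        (out / "permanova.json").write_text(json.dumps({
            "factor": factor, "pseudo_F": res.pseudo_F, "R2": res.R2,
            "p_value": res.p_value,
            "cap_classification_success": cap_res.classification_success,
            "cap_constrained_inertia":
                cap_res.constrained_inertia_fraction}))
    elif stage == "diffabund":
        if habitat is None:
            raise ValidationError("diffabund needs a microhabitat column")
        res = nb_wald_test(table, habitat,
                           reference=params.get("reference", "soil"),
                           cutoff=float(params.get("alpha", 0.01)))
        res.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        count_enriched_depleted(res).to_csv(
            out / "enriched_depleted_counts.tsv", sep="\t", index=False)
    elif stage == "sourcetrack":
        if habitat is None:
            raise ValidationError("sourcetrack needs a microhabitat column")
        tables = {h: table.select_samples(
            habitat[habitat == h].index.tolist())
            for h in pd.unique(habitat)}
        sim = pairwise_similarity_matrix(
            tables, seed=seed,
            rarefaction_depth=int(params.get("rarefaction_depth", 1000)),
            n_restarts=int(params.get("n_restarts", 10)))
        sim.to_csv(out / "source_attribution.tsv", sep="\t")
    elif stage == "assembly":
        n_null = int(params.get("n_null", 999))
        if tree is None:
            raise ValidationError("assembly needs a phylogeny")
        b = bnti(table, tree, n_null=n_null, seed=seed)
        r = rc_bray(table, n_null=n_null, seed=seed + 1)
        pairs = assembly_table(b, r)
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        grouping = (metadata.frame[params["group_by"]]
                    if "group_by" in params else habitat)
        process_summary(pairs, grouping).to_csv(
            out / "assembly_summary.tsv", sep="\t")
        fit = fit_neutral_model(
            table, detection_limit=params.get("detection_limit"))
        (out / "neutral_fit.json").write_text(json.dumps({
            "m": fit.m, "N": fit.N, "R2": fit.r2,
            "detection_limit": fit.detection_limit}))
        fit.per_taxon.to_csv(out / "neutral_fit_per_taxon.tsv", sep="\t")
    elif stage == "network":
        filtered = filter_taxa(table, float(params.get("min_rel_abundance",
                                                       0.001)))
        r = sparcc(filtered, n_iterations=int(params.get("n_iterations", 20)),
                   seed=seed)
        p = sparcc_pvalues(filtered, r,
                           n_bootstrap=int(params.get("n_bootstrap", 100)),
                           seed=seed + 1)
        net = build_network(r, p, filtered.taxon_ids,
                            r_threshold=float(params.get("r_threshold", 0.6)),
                            p_threshold=float(params.get("p_threshold",
                                                         0.05)))
        edges = [(u, v, d["weight"], d["p"]) for u, v, d in
                 net.edges(data=True)]
        pd.DataFrame(edges, columns=["source", "target", "weight", "p"]
                     ).to_csv(out / "network_edges.tsv", sep="\t",
                              index=False)
        summary: dict = {"n_nodes": 0, "n_edges": 0}
        if net.number_of_nodes() > 0:
            topo = topology(net, seed=seed)
            summary = {k: (v if not isinstance(v, dict) else v)
                       for k, v in topo.__dict__.items()}
        coh = cohesion(filtered, seed=seed + 2)
        summary["cohesion_ratio"] = coh.ratio
        (out / "network_summary.json").write_text(
            json.dumps(summary, default=float))
    else:  # pragma: no cover
        raise ValidationError(f"unknown stage {stage!r}")
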