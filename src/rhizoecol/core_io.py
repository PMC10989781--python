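"""Shared data structures and I/O for the pipeline.

The universal inputs are an ASV count table (samples x taxa), a rooted
phylogeny whose tips cover the taxa, and a per-sample metadata table with
the experimental design (microhabitat, grassland type, host plant, site)
and numeric environmental covariates (MAP, MAT, altitude, SOC, TN, NO3,
pH, BD, AGB, BGB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rhizoecol")

MICROHABITATS = ("soil", "rhizosphere", "rhizoplane", "endosphere")
GRASSLAND_TYPES = ("desert", "temperate", "warm-temperate")
COVARIATE_NAMES = ("MAP", "MAT", "altitude", "SOC", "TN", "NO3", "pH", "BD",
                   "AGB", "BGB")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# AsvTable
# ---------------------------------------------------------------------------

@dataclass
class AsvTable:
    """Integer read-count matrix, samples x taxa.

    Invariants enforced at construction: non-negative integer counts, no
    duplicate sample or taxon identifiers, and every retained sample has a
    positive total count.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray  # (n_samples, n_taxa), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                bad = np.argwhere(self.counts != rounded)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"taxon {self.taxon_ids[bad[1]]!r}")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicated taxon identifiers")
        if (self.counts.sum(axis=1) == 0).any():
            empty = [s for s, t in
                     zip(self.sample_ids, self.counts.sum(axis=1)) if t == 0]
            raise ValidationError(f"samples with zero total count: {empty}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drop_empty: bool = True
                       ) -> "AsvTable":
        """Build a table from a samples x taxa DataFrame.

        Zero-sum samples and zero-sum taxa are dropped with a warning when
        ``drop_empty`` is set (the constructor rejects empty samples).
        """
        counts = df.to_numpy()
        sample_ids = [str(s) for s in df.index]
        taxon_ids = [str(t) for t in df.columns]
        if drop_empty:
            row_ok = counts.sum(axis=1) > 0
            col_ok = counts.sum(axis=0) > 0
            if not row_ok.all():
                dropped = [s for s, ok in zip(sample_ids, row_ok) if not ok]
                logger.warning("dropping zero-sum samples: %s", dropped)
            if not col_ok.all():
                dropped = [t for t, ok in zip(taxon_ids, col_ok) if not ok]
                logger.warning("dropping %d zero-sum taxa", len(dropped))
            counts = counts[np.ix_(row_ok, col_ok)]
            sample_ids = [s for s, ok in zip(sample_ids, row_ok) if ok]
            taxon_ids = [t for t, ok in zip(taxon_ids, col_ok) if ok]
        return cls(sample_ids, taxon_ids, counts)

    def select_samples(self, ids) -> "AsvTable":
        # keeps the full taxon set (zero-sum taxa allowed) so subsets of a
        # table remain comparable over a shared taxon universe
        idx = [self.sample_ids.index(s) for s in ids]
        return AsvTable(list(ids), list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, ids) -> "AsvTable":
        idx = [self.taxon_ids.index(t) for t in ids]
        return AsvTable(list(self.sample_ids), list(ids),
                        self.counts[:, idx])


def read_asv_table(path, fmt: str = "tsv", taxa_as_rows: bool = True
                   ) -> AsvTable:
    """Read an ASV count table from TSV or BIOM 2.1 (HDF5).

    The TSV dialect defaults to the common QIIME export orientation: taxa
    as rows, samples as columns, first column taxon IDs.  Zero-sum samples
    and taxa are dropped with a logged warning.
    """
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValidationError(f"malformed table {path}: {exc}") from exc
        if df.columns.duplicated().any() or df.index.duplicated().any():
            raise ValidationError(f"duplicated identifiers in {path}")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise ValidationError(
                    f"non-numeric count in column {col!r}, "
                    f"row {bad.index[0]!r}")
        if taxa_as_rows:
            df = df.T
        if (df.to_numpy() < 0).any():
            arr = df.to_numpy()
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, "
                f"taxon {df.columns[j]!r}")
        return AsvTable.from_dataframe(df)
    if fmt == "biom":
        import biom
        tab = biom.load_table(str(path))
        df = tab.to_dataframe(dense=True).T  # biom stores taxa x samples
        return AsvTable.from_dataframe(df)
    raise ValueError(f"unknown table format {fmt!r}")


def write_asv_table(table: AsvTable, path, fmt: str = "tsv") -> None:
    """Write a table as TSV (taxa as rows) or BIOM 2.1."""
    if fmt == "tsv":
        df = table.to_dataframe().T
        df.index.name = "#ASV_ID"
        df.to_csv(path, sep="\t")
    elif fmt == "biom":
        import biom
        import h5py
        tab = biom.Table(table.counts.T.astype(float), table.taxon_ids,
                         table.sample_ids)
        with h5py.File(str(path), "w") as fh:
            tab.to_hdf5(fh, generated_by="rhizoecol")
    else:
        raise ValueError(f"unknown table format {fmt!r}")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path=None, newick: str | None = None,
              root_at_midpoint: bool = False) -> TreeNode:
    """Read a rooted Newick tree and validate it.

    Missing branch lengths are replaced by 0 with a warning.  A basal
    trifurcation is accepted only with ``root_at_midpoint``; tip-label
    duplication is an error.
    """
    if newick is not None:
        import io
        tree = TreeNode.read(io.StringIO(newick))
    else:
        tree = TreeNode.read(str(path))
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError("negative branch length")
    if n_missing:
        logger.warning("replaced %d missing branch lengths with 0", n_missing)
    if len(tree.children) > 2:
        if not root_at_midpoint:
            raise ValidationError(
                "tree root is a trifurcation (unrooted tree); pass "
                "root_at_midpoint=True to midpoint-root it")
        tree = tree.root_at_midpoint()
    tree.length = None
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample design factors and numeric environmental covariates.

    ``frame`` is indexed by sample id.  Categorical columns (microhabitat,
    grassland_type, host_plant, site_id) are matched case-insensitively on
    read; covariates may be missing (NaN) but missingness is explicit.
    """

    frame: pd.DataFrame

    CATEGORICAL = ("microhabitat", "grassland_type", "host_plant", "site_id")

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicated sample identifiers in metadata")
        if "microhabitat" in self.frame:
            vals = set(self.frame["microhabitat"].dropna())
            bad = vals - set(MICROHABITATS)
            if bad:
                raise ValidationError(f"unknown microhabitat values: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def covariates(self, names=None) -> pd.DataFrame:
        names = list(names) if names is not None else [
            c for c in COVARIATE_NAMES if c in self.frame]
        return self.frame[names].astype(float)

    def group_labels(self, column: str) -> pd.Series:
        return self.frame[column]


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    lower = {c.lower(): c for c in df.columns}
    renames = {}
    for want in SampleMetadata.CATEGORICAL + COVARIATE_NAMES:
        if want not in df.columns and want.lower() in lower:
            renames[lower[want.lower()]] = want
    df = df.rename(columns=renames)
    for col in SampleMetadata.CATEGORICAL:
        if col in df:
            df[col] = df[col].astype(str).str.strip().str.lower().replace(
                {"warm-temperate": "warm-temperate"})
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    out = metadata.frame.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# DistanceMatrix helpers
# ---------------------------------------------------------------------------

from skbio import DistanceMatrix  # noqa: E402  (re-exported container)


def as_distance_matrix(values: np.ndarray, ids) -> DistanceMatrix:
    """Validate and wrap a square dissimilarity matrix.

    Enforces symmetry within 1e-12, an exactly zero diagonal and
    non-negative entries.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValidationError("distance matrix not symmetric within 1e-12")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    if (values < 0).any():
        raise ValidationError("negative dissimilarity")
    return DistanceMatrix(values, ids=[str(i) for i in ids])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return as_distance_matrix(df.to_numpy(), list(df.index))


# ---------------------------------------------------------------------------
# Alignment and normalisation
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    dropped_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    pruned_tips: list[str] = field(default_factory=list)


def align(table: AsvTable, tree: TreeNode | None = None,
          metadata: SampleMetadata | None = None):
    """Restrict table/tree/metadata to their common samples and taxa.

    Taxa are intersected with the tree tips (tree pruned to the shared
    set); samples are intersected with the metadata index.  Idempotent.
    Returns ``(table, tree, metadata, report)``.
    """
    report = AlignmentReport()
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        shared = [t for t in table.taxon_ids if t in tips]
        if not shared:
            raise ValidationError("no taxa shared between table and tree")
        report.dropped_taxa = [t for t in table.taxon_ids if t not in tips]
        report.pruned_tips = sorted(tips - set(shared))
        if report.dropped_taxa:
            logger.warning("dropping %d taxa absent from tree",
                           len(report.dropped_taxa))
            table = table.select_taxa(shared)
        if report.pruned_tips:
            tree = tree.shear(shared)
            tree.length = None
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        shared_s = [s for s in table.sample_ids if s in meta_ids]
        if not shared_s:
            raise ValidationError("no samples shared between table and metadata")
        report.dropped_samples = [s for s in table.sample_ids
                                  if s not in meta_ids]
        if report.dropped_samples:
            logger.warning("dropping samples without metadata: %s",
                           report.dropped_samples)
            table = table.select_samples(shared_s)
        metadata = SampleMetadata(metadata.frame.loc[table.sample_ids])
    return table, tree, metadata, report


def relative_abundance(table: AsvTable | np.ndarray) -> np.ndarray:
    """Row-normalise counts to per-sample relative abundances."""
    counts = table.counts if isinstance(table, AsvTable) else np.asarray(table)
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    if (totals == 0).any():
        raise ValidationError("zero-sum sample in relative_abundance")
    return counts / totals


def rarefy(table: AsvTable, depth: int, seed: int = 0) -> AsvTable:
    """Optional fixed-seed rarefaction (sensitivity analysis only).

    Samples shallower than ``depth`` are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = row.sum()
        if total < depth:
            logger.warning("dropping sample %s (depth %d < %d)",
                           sid, total, depth)
            continue
        reads = np.repeat(np.arange(table.n_taxa), row)
        sub = rng.choice(reads, size=depth, replace=False)
        rows.append(np.bincount(sub, minlength=table.n_taxa))
        keep.append(sid)
    if not rows:
        raise ValidationError("no sample reaches the rarefaction depth")
    return AsvTable.from_dataframe(
        pd.DataFrame(np.array(rows), index=keep, columns=table.taxon_ids))
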