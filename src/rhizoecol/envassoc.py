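"""Statistics relating community structure to environmental covariates.

Distance-based redundancy analysis (db-RDA) regresses the PCoA embedding
of a community distance matrix on numeric covariates; variance
partitioning splits the adjusted explained variance among the climate,
edaphic and plant covariate groups by inclusion-exclusion over partial
fits; random-forest permutation importance ranks covariates as
predictors of an ordination axis; plus the simple regression and
rank-correlation summaries used alongside them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .core_io import SampleMetadata, ValidationError
from .diffabund import _bh_adjust
from .diversity import pcoa

logger = logging.getLogger("rhizoecol")

__all__ = ["dbrda", "DbrdaResult", "variance_partition", "VpaResult",
           "rf_importance", "distance_to_reference_regression",
           "env_spearman"]


# ---------------------------------------------------------------------------
# db-RDA
# ---------------------------------------------------------------------------

@dataclass
class DbrdaResult:
    constrained_fraction: float       # R2 of the constrained ordination
    adjusted_r2: float
    p_value: float
    axis_scores: np.ndarray           # samples x constrained axes
    vif: pd.Series
    dropped: list[str] = field(default_factory=list)


def _embedding(dm: DistanceMatrix) -> np.ndarray:
    """PCoA axes scaled by sqrt(eigenvalue); negative axes excluded."""
    res = pcoa(dm)
    keep = res.eigenvalues > 1e-12
    return res.coordinates[:, keep]


def _constrained_r2(Y: np.ndarray, X: np.ndarray) -> float:
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    total = (Yc ** 2).sum()
    return float((fitted ** 2).sum() / total) if total > 0 else 0.0


def _adjust_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; may be slightly negative, reported as computed."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from the inverse correlation matrix."""
    Z = (X - X.mean()) / X.std(ddof=0)
    R = Z.corr().to_numpy()
    try:
        inv = np.linalg.inv(R)
        vif = np.diag(inv)
    except np.linalg.LinAlgError:
        vif = np.full(X.shape[1], np.inf)
    return pd.Series(vif, index=X.columns)


def dbrda(dm: DistanceMatrix, covariates: pd.DataFrame,
          n_permutations: int = 999, seed: int = 0,
          vif_threshold: float = 10.0, drop_collinear: bool = False
          ) -> DbrdaResult:
    """Distance-based redundancy analysis with a permutation test.

    The PCoA embedding (positive-eigenvalue axes) is regressed on the
    centred covariates; the constrained fraction is the share of the
    embedded variance the covariates explain, tested by permuting the
    covariate rows.  Constant covariates are dropped with a warning;
    covariates whose VIF exceeds the threshold are flagged (and, with
    ``drop_collinear``, removed one at a time with refitting).
    """
    X = covariates.astype(float).copy()
    dropped = []
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        logger.warning("dropping constant covariates: %s", const)
        X = X.drop(columns=const)
        dropped += const
    if X.shape[1] == 0:
        raise ValidationError("no usable covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("fewer samples than covariates")
    if X.isna().any().any():
        raise ValidationError("covariates must be complete-case")
    vif = compute_vif(X) if X.shape[1] > 1 else pd.Series(
        1.0, index=X.columns)
    if drop_collinear:
        while (vif > vif_threshold).any() and X.shape[1] > 1:
            worst = vif.idxmax()
            logger.warning("dropping collinear covariate %s (VIF %.1f)",
                           worst, vif[worst])
            X = X.drop(columns=worst)
            dropped.append(worst)
            vif = compute_vif(X) if X.shape[1] > 1 else pd.Series(
                1.0, index=X.columns)
    flagged = vif[vif > vif_threshold]
    if len(flagged):
        logger.warning("high-VIF covariates flagged: %s",
                       dict(flagged.round(1)))
    Y = _embedding(dm)
    Xv = X.to_numpy()
    r2 = _constrained_r2(Y, Xv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(Xv.shape[0])
        if _constrained_r2(Y, Xv[perm]) >= r2:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    # constrained axis scores: SVD of the fitted values
    Yc = Y - Y.mean(axis=0)
    Xc = Xv - Xv.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    k = min(X.shape[1], (s > 1e-10).sum())
    return DbrdaResult(r2, _adjust_r2(r2, len(Y), X.shape[1]), float(p),
                       u[:, :k] * s[:k], vif, dropped)


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VpaResult:
    """Adjusted-R2 partition among three covariate groups.

    ``fractions`` holds the 7 Venn fractions keyed by frozenset of group
    names plus the residual under ``"residual"``; unique fractions can be
    slightly negative (an adjusted-R2 artifact) and are reported as
    computed.  Everything sums to 1 exactly.
    """

    fractions: dict
    group_r2: dict

    def unique(self, group: str) -> float:
        return self.fractions[frozenset([group])]

    @property
    def residual(self) -> float:
        return self.fractions["residual"]


def variance_partition(dm: DistanceMatrix, groups: dict[str, list[str]],
                       covariates: pd.DataFrame, seed: int = 0) -> VpaResult:
    """Partition community variance among covariate groups (typically
    climate, edaphic and plant traits) by inclusion-exclusion of
    adjusted-R2 values over all subset fits."""
    names = list(groups)
    if len(names) != 3:
        raise ValidationError("variance partitioning expects three groups")
    all_cols: list[str] = []
    for g, cols in groups.items():
        if not cols:
            raise ValidationError(f"group {g!r} is empty")
        overlap = set(cols) & set(all_cols)
        if overlap:
            raise ValidationError(f"covariates in two groups: {overlap}")
        all_cols += list(cols)
    Y = _embedding(dm)
    n = len(Y)

    def adj(cols):
        X = covariates[list(cols)].to_numpy(float)
        return _adjust_r2(_constrained_r2(Y, X), n, X.shape[1])

    A, B, C = names
    r = {
        frozenset([A]): adj(groups[A]),
        frozenset([B]): adj(groups[B]),
        frozenset([C]): adj(groups[C]),
        frozenset([A, B]): adj(groups[A] + groups[B]),
        frozenset([A, C]): adj(groups[A] + groups[C]),
        frozenset([B, C]): adj(groups[B] + groups[C]),
        frozenset([A, B, C]): adj(groups[A] + groups[B] + groups[C]),
    }
    # solve the full-rank Venn system (7 fits, 7 cells) in one pass
    labels = ["a", "b", "c", "d", "e", "f", "g"]
    # membership of each Venn cell in each subset-fit
    cells_in = {
        frozenset([A]): ["a", "d", "f", "g"],
        frozenset([B]): ["b", "d", "e", "g"],
        frozenset([C]): ["c", "e", "f", "g"],
        frozenset([A, B]): ["a", "b", "d", "e", "f", "g"],
        frozenset([A, C]): ["a", "c", "d", "e", "f", "g"],
        frozenset([B, C]): ["b", "c", "d", "e", "f", "g"],
        frozenset([A, B, C]): labels,
    }
    M = np.array([[1.0 if cell in cells else 0.0 for cell in labels]
                  for cells in cells_in.values()])
    rhs = np.array([r[k] for k in cells_in])
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    vals = dict(zip(labels, sol))
    fractions = {
        frozenset([A]): vals["a"], frozenset([B]): vals["b"],
        frozenset([C]): vals["c"], frozenset([A, B]): vals["d"],
        frozenset([B, C]): vals["e"], frozenset([A, C]): vals["f"],
        frozenset([A, B, C]): vals["g"],
    }
    explained = M[-1] @ sol
    fractions["residual"] = 1.0 - explained
    return VpaResult(fractions, {tuple(sorted(k)): v for k, v in r.items()})


# ---------------------------------------------------------------------------
# Random-forest importance
# ---------------------------------------------------------------------------

def rf_importance(response: np.ndarray, covariates: pd.DataFrame,
                  n_trees: int = 1000, mtry: int | None = None,
                  seed: int = 0, n_repeats: int = 10) -> pd.DataFrame:
    """Random-forest permutation importance of each covariate.

    Fits a regression forest (``mtry`` defaults to p/3 features per
    split) and reports the mean increase in squared error when each
    covariate is permuted, ranked descending.  Deterministic for a fixed
    seed.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if covariates.shape[1] == 0:
        raise ValidationError("no covariates supplied")
    if len(response) < 20:
        raise ValidationError("random-forest importance needs >= 20 samples")
    p = covariates.shape[1]
    mtry = mtry if mtry is not None else max(p // 3, 1)
    rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                               random_state=seed, n_jobs=1)
    X = covariates.to_numpy(float)
    y = np.asarray(response, float)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=n_repeats,
                                 random_state=seed,
                                 scoring="neg_mean_squared_error")
    out = pd.DataFrame({
        "importance": imp.importances_mean,
        "importance_sd": imp.importances_std,
    }, index=covariates.columns).sort_values("importance", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Distance-to-reference regression and Spearman screens
# ---------------------------------------------------------------------------

def distance_to_reference_regression(dm: DistanceMatrix,
                                     metadata: SampleMetadata,
                                     reference_sample: str,
                                     covariate: str = "MAP",
                                     stratify_by: str | None = None
                                     ) -> pd.DataFrame:
    """OLS of distance-to-a-reference-sample on a covariate.

    One row per stratum (or a single ``all`` row): slope, intercept, R2
    and the two-sided p of the slope.
    """
    ids = list(dm.ids)
    if reference_sample not in ids:
        raise ValidationError(f"reference sample {reference_sample!r} "
                              "absent from distance matrix")
    ref_idx = ids.index(reference_sample)
    dist = np.asarray(dm.data)[ref_idx]
    frame = metadata.frame.loc[[i for i in ids]]
    cov = frame[covariate].astype(float).to_numpy()
    strata = (frame[stratify_by] if stratify_by else
              pd.Series("all", index=frame.index))
    rows = []
    for g in pd.unique(strata):
        mask = (strata == g).to_numpy()
        mask[ref_idx] = False
        x, y = cov[mask], dist[mask]
        if np.nanstd(x) == 0:
            raise ValidationError(
                f"covariate {covariate!r} constant in stratum {g!r}")
        res = stats.linregress(x, y)
        rows.append((g, res.slope, res.intercept, res.rvalue ** 2,
                     res.pvalue, mask.sum()))
    return pd.DataFrame(rows, columns=["stratum", "slope", "intercept",
                                       "r2", "p_value", "n"])


def env_spearman(values: pd.DataFrame, covariates: pd.DataFrame,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Spearman rho and two-sided p for every (quantity, covariate) pair.

    Cells with p > alpha are flagged non-significant (unadjusted, the
    masking rule the figure uses) and BH q-values are reported alongside
    for transparency.  Requires >= 5 paired observations per pair.
    """
    rows = []
    for q in values.columns:
        for c in covariates.columns:
            pair = pd.concat([values[q], covariates[c]], axis=1).dropna()
            if len(pair) < 5:
                raise ValidationError(
                    f"fewer than 5 paired observations for ({q}, {c})")
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((q, c, rho, p))
    out = pd.DataFrame(rows, columns=["quantity", "covariate", "rho", "p"])
    out["q_bh"] = _bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] <= alpha
    return out
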