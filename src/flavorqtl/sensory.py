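"""Metabolic/sensory preprocessing, PCA summary and random-forest models.

Preprocessing follows the metabolomics convention used throughout the
analysis: abundances are log2 transformed ("2log") after half-minimum
replacement of zeros, then each compound is centered by its trial mean on the
log scale (equivalently: divided by the trial geometric mean on the raw
scale), which removes multiplicative batch effects between trials exactly.

The sensory-attribute models are regression forests with out-of-bag (OOB)
permutation importance: for each compound the increase in OOB mean squared
error after permuting that compound's values, averaged over trees and
standardized by the standard deviation of the per-tree differences.  The
sign (directionality) of each compound's effect is the sign of its Pearson
correlation with the attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import trait_columns


@dataclass
class PreprocessConfig:
    log_base: float = 2.0
    zero_handling: str = "half-minimum"  # zeros -> half the compound's min positive
    center_by: str = "trial-mean-log"  # or "trial-mean-raw" (division on raw scale)

    def __post_init__(self):
        if self.log_base <= 1:
            raise ValueError("log base must be > 1")
        if self.center_by not in ("trial-mean-log", "trial-mean-raw", "none"):
            raise ValueError(f"unknown centering {self.center_by}")


def preprocess_profiles(
    table: pd.DataFrame,
    cfg: PreprocessConfig = PreprocessConfig(),
    compounds=None,
) -> pd.DataFrame:
    """Log-transform and trial-center compound abundance columns."""
    out = table.copy()
    compounds = compounds or trait_columns(table)
    logb = np.log(cfg.log_base)
    for col in compounds:
        x = out[col].to_numpy(dtype=float)
        if np.nanmin(x) < 0:
            raise ValueError(f"{col}: negative abundance")
        pos = x[np.isfinite(x) & (x > 0)]
        if cfg.zero_handling == "half-minimum" and pos.size:
            x = np.where(x == 0, pos.min() / 2.0, x)
        if cfg.center_by == "trial-mean-raw":
            for t, rows in out.groupby("trial").groups.items():
                ridx = out.index.get_indexer(rows)
                mu = np.nanmean(x[ridx])
                x[ridx] = x[ridx] / mu
        x = np.log(x) / logb
        if cfg.center_by == "trial-mean-log":
            for t, rows in out.groupby("trial").groups.items():
                ridx = out.index.get_indexer(rows)
                x[ridx] = x[ridx] - np.nanmean(x[ridx])
        out[col] = x
    return out


# ---------------------------------------------------------------------------
# PCA


def pca_summary(matrix, n_components: int | None = None):
    """PCA of a (rows x columns) matrix with column-mean imputation.

    Returns (scores, loadings, variance_fractions); loadings have orthonormal
    columns and ``scores @ loadings.T + column_means`` reconstructs the
    (imputed) data at full rank.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("PCA needs a matrix with at least 2 rows and columns")
    col_means = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    if inds[0].size:
        X = X.copy()
        X[inds] = np.take(col_means, inds[1])
    mu = X.mean(axis=0)
    Xc = X - mu
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    k = n_components or len(s)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    return scores, loadings, frac[:k]


# ---------------------------------------------------------------------------
# random forest with signed OOB permutation importance


@dataclass
class RFConfig:
    n_trees: int = 500
    n_permutations: int = 500  # permutation draws, distributed over trees
    max_features: float = 1 / 3
    min_oob: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1 or self.n_trees < 1:
            raise ValueError("n_trees and n_permutations must be >= 1")


@dataclass
class ImportanceRecord:
    attribute: str
    compound: str
    importance: float  # standardized mean OOB-MSE increase
    sign: str  # "+" | "-"
    pearson_r: float


@dataclass
class RFSensoryResult:
    attribute: str
    records: list
    variance_explained: float  # OOB R^2 of the forest

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "attribute": r.attribute,
                    "compound": r.compound,
                    "importance": r.importance,
                    "sign": r.sign,
                    "pearson_r": r.pearson_r,
                }
                for r in self.records
            ]
        )

    def ranked(self) -> list:
        return sorted(self.records, key=lambda r: -r.importance)


def rf_sensory_model(
    attribute,
    chemicals: pd.DataFrame,
    cfg: RFConfig = RFConfig(),
    attribute_name: str = "attribute",
) -> RFSensoryResult:
    """Regression forest of one sensory attribute on compound abundances.

    Importance per compound: mean over trees of (OOB MSE after permuting the
    compound among that tree's OOB samples - OOB MSE before), divided by the
    standard deviation of the per-tree differences scaled by sqrt(n_trees).
    The requested number of permutation draws is distributed over trees
    (ceil(n_permutations / n_trees) per tree).  Fully seeded.
    """
    from sklearn.ensemble import RandomForestRegressor

    y = np.asarray(attribute, dtype=float)
    X = chemicals.to_numpy(dtype=float)
    names = list(chemicals.columns)
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    n, p = X.shape
    if n < 30:
        raise ValueError("need at least 30 observations")
    if np.std(y) == 0:
        raise ValueError("attribute is constant")

    rng = np.random.default_rng(cfg.seed)
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=max(1, int(np.floor(p * cfg.max_features))) if cfg.max_features < 1 else cfg.max_features,
        bootstrap=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X, y)

    n_perm_per_tree = int(np.ceil(cfg.n_permutations / cfg.n_trees))
    diffs = np.zeros((cfg.n_trees, p))
    used = np.zeros(cfg.n_trees, dtype=bool)
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)
    samples_per_tree = forest.estimators_samples_  # computed once; property is O(forest)
    for t, tree in enumerate(forest.estimators_):
        sampled = samples_per_tree[t]
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        k = int(oob.sum())
        if k < cfg.min_oob:
            continue
        used[t] = True
        Xo = X[oob]
        yo = y[oob]
        base_pred = tree.predict(Xo)
        oob_pred_sum[oob] += base_pred
        oob_pred_cnt[oob] += 1
        mse0 = float(np.mean((yo - base_pred) ** 2))
        # one batched predict per tree: p x n_perm permuted copies stacked
        blocks = []
        for j in range(p):
            for _ in range(n_perm_per_tree):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xo[:, j])
                blocks.append(Xp)
        preds = tree.predict(
            np.ascontiguousarray(np.vstack(blocks), dtype=np.float32),
            check_input=False,
        ).reshape(p, n_perm_per_tree, k)
        mse = ((yo[None, None, :] - preds) ** 2).mean(axis=2).mean(axis=1)
        diffs[t] = mse - mse0

    n_used = int(used.sum())
    if n_used == 0:
        raise ValueError("no tree had enough out-of-bag samples")
    d = diffs[used]
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        importance = np.where(sd_d > 0, mean_d / (sd_d / np.sqrt(n_used)), 0.0)

    records = []
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            r = 0.0
        else:
            r = float(stats.pearsonr(X[:, j], y)[0])
        records.append(
            ImportanceRecord(
                attribute=attribute_name,
                compound=name,
                importance=float(importance[j]),
                sign="+" if r >= 0 else "-",
                pearson_r=r,
            )
        )
    have = oob_pred_cnt > 0
    oob_pred = oob_pred_sum[have] / oob_pred_cnt[have]
    ss_res = float(np.sum((y[have] - oob_pred) ** 2))
    ss_tot = float(np.sum((y[have] - y[have].mean()) ** 2))
    var_explained = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return RFSensoryResult(attribute_name, records, var_explained)


def importance_table(results: list[RFSensoryResult]) -> pd.DataFrame:
    """Attributes x compounds table of signed standardized importances."""
    frames = []
    for res in results:
        for r in res.records:
            frames.append(
                {
                    "attribute": r.attribute,
                    "compound": r.compound,
                    "signed_importance": r.importance if r.sign == "+" else -r.importance,
                }
            )
    df = pd.DataFrame(frames)
    return df.pivot(index="attribute", columns="compound", values="signed_importance")
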