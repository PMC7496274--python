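"""Marker-trait association scans and QTL-map summarization.

Three models are provided:

* diversity panel: ``y = type + marker + error`` by OLS, two-sided t-test on
  the marker dosage coefficient (type = cherry vs round/beef by default);
* F2 half diallel: ``y = cross.genotype + rin + marker + error`` — the REML
  mixed model of :mod:`flavorqtl.model`, all crosses simultaneously, with the
  four parental allele-count columns entering under a sum-to-zero constraint
  and tested by a basis-invariant Wald chi-square (df = estimable rank <= 3);
* F6 RILs: per-cross ``y = marker + error`` OLS with a two-sided t-test,
  never pooled across crosses.

A Kruskal-Wallis marker/trait association (tie-corrected) supports the
fine-mapping analyses.  Significant results (Log P above threshold) are
summarized into 5-Mbp physical bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import ParentalDosageMatrix, RinDesign
from .io import MISSING, GenotypeMatrix, trait_columns
from .model import HalfDiallelMixedLM, logp_from_p, sum_to_zero_basis

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    logp_threshold: float = 3.5
    bin_size_bp: int = 5_000_000
    min_informative_n: int = 10
    aggregate: bool = True  # genotype means before scanning
    dp_type_levels: int = 2  # cherry vs round/beef; 3 keeps beef separate
    logp_cap: float = 300.0
    # F2 Wald reference: "kr" = Kenward-Roger small-sample F (calibrated),
    # "chi2" = plug-in chi-square on the estimable rank
    wald_reference: str = "kr"
    # fixed per-cross intercepts: orthogonalize the marker test against
    # between-cross mean differences (genome-wide genetic architecture would
    # otherwise leak into the marker term at unlinked markers)
    cross_fixed_effects: bool = True

    def __post_init__(self):
        if self.logp_threshold <= 0 or self.bin_size_bp <= 0:
            raise ValueError("threshold and bin size must be positive")


@dataclass
class AssociationResult:
    """One marker x trait association."""

    trait: str
    marker: str
    chrom: str
    pos_bp: int
    model: str  # DP | F2-diallel | F6-cross | KW
    statistic: float
    df: int
    p: float
    logp: float
    effects: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    r2: float = float("nan")
    n_effective: int = 0
    cross: str = ""
    note: str = ""


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "trait": r.trait, "marker": r.marker, "chrom": r.chrom,
            "pos_bp": r.pos_bp, "model": r.model, "cross": r.cross,
            "statistic": r.statistic, "df": r.df, "p": r.p, "logp": r.logp,
            "r2": r.r2, "n": r.n_effective, "note": r.note,
        }
        for k, v in r.effects.items():
            row[f"effect_{k}"] = v
        for k, v in r.ses.items():
            row[f"se_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_genotype_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Unweighted genotype means over non-missing replicates (per experiment
    aggregation before scanning)."""
    meta_cols = [c for c in ("cross", "generation", "fruit_type") if c in traits.columns]
    tcols = trait_columns(traits)
    grouped = traits.groupby("genotype_id", sort=False)
    means = grouped[tcols].mean()
    meta = grouped[meta_cols].first() if meta_cols else None
    out = means if meta is None else pd.concat([meta, means], axis=1)
    out = out.reset_index()
    out["trial"] = "pooled"
    return out


# ---------------------------------------------------------------------------
# F2 half-diallel mixed-model scan


def scan_f2(
    traits: pd.DataFrame,
    M: ParentalDosageMatrix,
    rin: RinDesign | None,
    config: ScanConfig = ScanConfig(),
    traits_subset=None,
) -> list[AssociationResult]:
    """Mixed-model scan of all crosses simultaneously.

    ``traits`` rows are matched to the encoded population by ``genotype_id``;
    replicated tables are first aggregated to genotype means.  Markers
    informative in zero crosses are skipped with a reason; per-marker REML is
    warm-started from the previous marker's variance components.
    """
    if config.aggregate and traits["genotype_id"].duplicated().any():
        traits = aggregate_genotype_means(traits)
    order = {g: i for i, g in enumerate(M.individuals["genotype_id"])}
    missing_ids = [g for g in traits["genotype_id"] if g not in order]
    if missing_ids:
        raise ValueError(f"traits contain unknown genotypes: {missing_ids[:5]}")
    traits = traits.iloc[
        np.argsort([order[g] for g in traits["genotype_id"]])
    ].reset_index(drop=True)
    idx = np.array([order[g] for g in traits["genotype_id"]])

    crosses_all = M.individuals["cross"].to_numpy()[idx]
    if config.cross_fixed_effects:
        labels = list(dict.fromkeys(crosses_all))
        base_cols = [(crosses_all == c).astype(float) for c in labels]
        base_names = [f"cross:{c}" for c in labels]
    else:
        base_cols = [np.ones(len(traits))]
        base_names = ["intercept"]
    if rin is not None and rin.k:
        base_cols.append(rin.matrix[idx])
        base_names.extend(rin.names)
    base = np.column_stack(base_cols)
    C = sum_to_zero_basis(4)
    mk_names = [f"marker_c{j + 1}" for j in range(C.shape[1])]
    founder_ids = list(M.founder_ids)

    tcols = traits_subset or trait_columns(traits)
    results = []
    for trait in tcols:
        y_all = traits[trait].to_numpy(dtype=float)
        warm = None
        for j in range(M.n_markers):
            res = _f2_one_marker(
                trait, j, y_all, M, idx, crosses_all, base, base_names,
                C, mk_names, founder_ids, config, warm,
            )
            if res is None:
                continue
            result, warm = res
            results.append(result)
    return results


def _f2_one_marker(
    trait, j, y_all, M, idx, crosses_all, base, base_names, C, mk_names,
    founder_ids, config, warm,
):
    mm = M.markers
    info = M.informative[idx, j]
    ok = info & np.isfinite(y_all)
    n_eff = int(ok.sum())
    marker = str(mm.marker_ids[j])
    common = dict(
        trait=trait, marker=marker, chrom=str(mm.chrom[j]),
        pos_bp=int(mm.pos_bp[j]), model="F2-diallel",
    )
    if n_eff == 0:
        return (
            AssociationResult(**common, statistic=np.nan, df=0, p=np.nan,
                              logp=np.nan, n_effective=0,
                              note="skipped: informative in zero crosses"),
            warm,
        )
    if n_eff < config.min_informative_n:
        return (
            AssociationResult(**common, statistic=np.nan, df=0, p=np.nan,
                              logp=np.nan, n_effective=n_eff,
                              note="skipped: below min_informative_n"),
            warm,
        )
    rows = np.flatnonzero(ok)
    Xm = M.counts[idx[rows], j, :].astype(float) @ C
    X = np.column_stack([base[rows], Xm])
    model = HalfDiallelMixedLM(
        y_all[rows], X, crosses_all[rows], exog_names=base_names + mk_names
    )
    start = None
    if warm is not None and warm[0] == tuple(model.cross_order):
        start = warm[1]
    fit = model.fit(start=start, polish=False)
    warm_out = (tuple(model.cross_order), fit.vc.as_array(model.cross_order))
    mcols = np.arange(X.shape[1] - C.shape[1], X.shape[1])
    if config.wald_reference == "kr":
        statv, df, p, _ = fit.kenward_roger_test(mcols)
    else:
        statv, df, p = fit.wald_test(mcols)
    r2 = fit.partial_r2(mcols)
    theta = fit.params[mcols]
    cov_t = fit.cov_params()[np.ix_(mcols, mcols)]
    beta = C @ theta
    beta_se = np.sqrt(np.clip(np.diag(C @ cov_t @ C.T), 0.0, None))
    effects = {f: float(b) for f, b in zip(founder_ids, beta)}
    ses = {f: float(s) for f, s in zip(founder_ids, beta_se)}
    result = AssociationResult(
        **common, statistic=float(statv), df=int(df),
        p=float(p), logp=logp_from_p(p, config.logp_cap), effects=effects,
        ses=ses, r2=r2, n_effective=n_eff,
        note="" if fit.converged else "non-convergence",
    )
    return result, warm_out


# ---------------------------------------------------------------------------
# diversity-panel scan


def scan_dp(
    traits: pd.DataFrame,
    G: GenotypeMatrix,
    config: ScanConfig = ScanConfig(),
    traits_subset=None,
) -> list[AssociationResult]:
    """OLS scan with fruit-type correction, t-test on the dosage coefficient."""
    if "fruit_type" not in traits.columns:
        raise ValueError("diversity-panel scan requires a fruit_type column")
    if config.aggregate and traits["genotype_id"].duplicated().any():
        traits = aggregate_genotype_means(traits)
    traits = traits.reset_index(drop=True)
    order = {s: i for i, s in enumerate(G.samples)}
    unknown = [g for g in traits["genotype_id"] if g not in order]
    if unknown:
        raise ValueError(f"traits contain unknown samples: {unknown[:5]}")
    idx = np.array([order[g] for g in traits["genotype_id"]])
    ftype = traits["fruit_type"].astype(str).to_numpy()
    if config.dp_type_levels == 2:
        type_cols = [(ftype == "cherry").astype(float)]
    else:
        type_cols = [(ftype == "cherry").astype(float), (ftype == "beef").astype(float)]

    mm = G.markers
    results = []
    tcols = traits_subset or trait_columns(traits)
    for trait in tcols:
        y_all = traits[trait].to_numpy(dtype=float)
        for j in range(G.n_markers):
            g = G.dosage[idx, j].astype(float)
            g[G.dosage[idx, j] == MISSING] = np.nan
            ok = np.isfinite(y_all) & np.isfinite(g)
            common = dict(
                trait=trait, marker=str(mm.marker_ids[j]), chrom=str(mm.chrom[j]),
                pos_bp=int(mm.pos_bp[j]), model="DP",
            )
            n_eff = int(ok.sum())
            if n_eff < config.min_informative_n:
                results.append(AssociationResult(
                    **common, statistic=np.nan, df=0, p=np.nan, logp=np.nan,
                    n_effective=n_eff, note="skipped: too few observations"))
                continue
            if np.nanstd(g[ok]) == 0:
                results.append(AssociationResult(
                    **common, statistic=np.nan, df=0, p=np.nan, logp=np.nan,
                    n_effective=n_eff, note="skipped: monomorphic"))
                continue
            X = np.column_stack(
                [np.ones(n_eff)] + [t[ok] for t in type_cols] + [g[ok]]
            )
            res = _ols_t_last(y_all[ok], X)
            if res is None:
                results.append(AssociationResult(
                    **common, statistic=np.nan, df=0, p=np.nan, logp=np.nan,
                    n_effective=n_eff, note="skipped: collinear design"))
                continue
            beta, se, tstat, dfres, p, r2p = res
            results.append(AssociationResult(
                **common, statistic=float(tstat), df=int(dfres), p=float(p),
                logp=logp_from_p(p, config.logp_cap),
                effects={"marker": float(beta)}, ses={"marker": float(se)},
                r2=r2p, n_effective=n_eff))
    return results


def _ols_t_last(y, X):
    """OLS with a two-sided t-test on the last column; partial R^2 reported."""
    import statsmodels.api as sm

    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        return None
    fit = sm.OLS(y, X).fit()
    beta = fit.params[-1]
    se = fit.bse[-1]
    tstat = fit.tvalues[-1]
    dfres = int(fit.df_resid)
    pval = fit.pvalues[-1]
    r2p = float(tstat**2 / (tstat**2 + dfres)) if dfres > 0 else float("nan")
    return beta, se, tstat, dfres, pval, r2p


# ---------------------------------------------------------------------------
# F6 per-cross scan


def scan_f6(
    traits: pd.DataFrame,
    G: GenotypeMatrix,
    config: ScanConfig = ScanConfig(),
    traits_subset=None,
) -> list[AssociationResult]:
    """Per-cross simple regression scan; crosses are never pooled."""
    if "cross" not in traits.columns:
        raise ValueError("F6 scan requires a cross column")
    if config.aggregate and traits["genotype_id"].duplicated().any():
        traits = aggregate_genotype_means(traits)
    traits = traits.reset_index(drop=True)
    order = {s: i for i, s in enumerate(G.samples)}
    idx = np.array([order[g] for g in traits["genotype_id"]])
    mm = G.markers
    results = []
    tcols = traits_subset or trait_columns(traits)
    for cross, sub in traits.groupby("cross", sort=False):
        sub_idx = idx[sub.index.to_numpy()]
        for trait in tcols:
            y_all = sub[trait].to_numpy(dtype=float)
            for j in range(G.n_markers):
                g = G.dosage[sub_idx, j].astype(float)
                g[G.dosage[sub_idx, j] == MISSING] = np.nan
                ok = np.isfinite(y_all) & np.isfinite(g)
                n_eff = int(ok.sum())
                common = dict(
                    trait=trait, marker=str(mm.marker_ids[j]),
                    chrom=str(mm.chrom[j]), pos_bp=int(mm.pos_bp[j]),
                    model="F6-cross",
                )
                if n_eff < 3:
                    results.append(AssociationResult(
                        **common, statistic=np.nan, df=0, p=np.nan, logp=np.nan,
                        n_effective=n_eff, cross=str(cross),
                        note="skipped: fewer than 3 informative individuals"))
                    continue
                if np.std(g[ok]) == 0:
                    results.append(AssociationResult(
                        **common, statistic=np.nan, df=0, p=np.nan, logp=np.nan,
                        n_effective=n_eff, cross=str(cross),
                        note="skipped: monomorphic"))
                    continue
                X = np.column_stack([np.ones(n_eff), g[ok]])
                res = _ols_t_last(y_all[ok], X)
                if res is None:
                    continue
                beta, se, tstat, dfres, p, _ = res
                # for simple regression, R^2 is the squared Pearson correlation
                r = np.corrcoef(g[ok], y_all[ok])[0, 1]
                results.append(AssociationResult(
                    **common, statistic=float(tstat), df=int(dfres), p=float(p),
                    logp=logp_from_p(p, config.logp_cap),
                    effects={"marker": float(beta)}, ses={"marker": float(se)},
                    r2=float(r * r), n_effective=n_eff, cross=str(cross)))
    return results


# ---------------------------------------------------------------------------
# Kruskal-Wallis association


def kruskal_wallis_assoc(
    values,
    classes,
    trait: str = "trait",
    marker: str = "marker",
    chrom: str = "",
    pos_bp: int = 0,
) -> AssociationResult:
    """Tie-corrected Kruskal-Wallis marker/trait association."""
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=object)
    ok = np.isfinite(values)
    values, classes = values[ok], classes[ok]
    labels = pd.unique(classes)
    groups = [values[classes == c] for c in labels]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 non-empty classes")
    k = len(groups)
    if np.all(values == values[0]):
        h, p = 0.0, 1.0  # all observations tied
    else:
        h, p = stats.kruskal(*groups)
    return AssociationResult(
        trait=trait, marker=marker, chrom=chrom, pos_bp=pos_bp, model="KW",
        statistic=float(h), df=k - 1, p=float(p), logp=logp_from_p(p),
        n_effective=int(values.size),
    )


# ---------------------------------------------------------------------------
# QTL map


def cross_type_code(cross: str) -> str:
    """RR/CC/CR tag from a 'AxB' cross label (C* cherry, R* round parents)."""
    if "x" not in cross:
        return cross
    pa, pb = cross.split("x", 1)
    code = "".join(sorted((pa[:1].upper(), pb[:1].upper())))
    return {"CC": "CC", "RR": "RR", "CR": "CR"}.get(code, code)


def summarize_qtl_map(
    results: list[AssociationResult], config: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    """Significant associations binned on the physical map.

    Keeps logp > threshold only; bin index = floor(pos / bin_size); per
    trait x chrom x bin the maximum Log P and the contributing cross tags.
    """
    rows = []
    for r in results:
        if not np.isfinite(r.logp) or r.logp <= config.logp_threshold:
            continue
        b = int(r.pos_bp // config.bin_size_bp)
        rows.append(
            {
                "trait": r.trait, "chrom": r.chrom, "bin": b,
                "bin_start_bp": b * config.bin_size_bp + 1,
                "bin_end_bp": (b + 1) * config.bin_size_bp,
                "logp": r.logp, "marker": r.marker, "model": r.model,
                "tag": cross_type_code(r.cross) if r.cross else r.model,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["trait", "chrom", "bin", "bin_start_bp", "bin_end_bp",
                     "max_logp", "best_marker", "crosses"]
        )
    df = pd.DataFrame(rows)
    out = []
    for (trait, chrom, b), grp in df.groupby(["trait", "chrom", "bin"], sort=True):
        best = grp.loc[grp["logp"].idxmax()]
        out.append(
            {
                "trait": trait, "chrom": chrom, "bin": b,
                "bin_start_bp": int(best["bin_start_bp"]),
                "bin_end_bp": int(best["bin_end_bp"]),
                "max_logp": float(best["logp"]),
                "best_marker": best["marker"],
                "crosses": ",".join(sorted(set(grp["tag"]))),
            }
        )
    return pd.DataFrame(out)
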