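"""Reproducible validation experiments for the half-diallel pipeline.

Each experiment regenerates its own synthetic study (founders, crosses,
traits) at the reference design scale — a four-founder half diallel with
50 F2 genotypes per cross unless stated otherwise — runs the estimator under
test, and returns the measured quantity.  These functions back both the test
suite and the acceptance summary script.

Reference constants hold the worked-example inputs: the diversity panel
composition (18 cherry + 55 round + 21 beef commercial hybrids) and the mean
fruit leucine contents of gene-edited mutant vs wild-type plants
(0.125 vs 0.032 mg per g fresh weight).
"""

from __future__ import annotations

import numpy as np

from .encoding import build_rin_design, encode_parental_dosage
from .io import QTLRegion
from .model import HalfDiallelMixedLM
from .scan import ScanConfig, scan_f2
from .simulate import (
    CrossPlan,
    TraitArchitecture,
    make_founders,
    simulate_germplasm,
    simulate_population,
    simulate_traits,
)

#: commercial diversity panel composition by fruit type
DP_TYPE_COUNTS = {"cherry": 18, "round": 55, "beef": 21}

#: mean fruit leucine content, mg per g fresh weight
LEUCINE_MG_PER_G = {"mutant": 0.125, "wild_type": 0.032}


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means (e.g. mutant vs wild-type metabolite level)."""
    if mean_b == 0:
        raise ValueError("reference mean is zero")
    return mean_a / mean_b


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def _standard_design(seed: int, n_markers_per_chrom=15, n_chrom=6,
                     n_per_cross=50, chrom_len=50_000_000):
    founders = make_founders(
        n_markers_per_chrom, [chrom_len] * n_chrom, seed=_sub_seed(seed, 1)
    )
    plan = CrossPlan(crosses=founders.half_diallel(), generation="F2",
                     n_per_cross=n_per_cross)
    return founders, plan


# ---------------------------------------------------------------------------


def null_type1_experiment(n_reps: int = 1000, seed: int = 0,
                          n_per_cross: int = 50, alpha: float = 0.05) -> dict:
    """Empirical type-I rate of the F2 mixed-model scan under the generative
    null (no QTL, heterogeneous per-cross background variances).

    Genotypes are simulated once; ``n_reps`` independent null traits are each
    tested at one fixed informative marker.
    """
    founders, plan = _standard_design(seed, n_per_cross=n_per_cross)
    pop = simulate_population(founders, plan, 2.0, seed=_sub_seed(seed, 2))
    M = encode_parental_dosage(pop)
    rin = build_rin_design(pop)
    j = int(np.argmax(M.informative.sum(axis=0)))
    Msub = M.subset_markers(np.arange(M.n_markers) == j)

    rng = np.random.default_rng(_sub_seed(seed, 3))
    crosses = list(pop.cross_parents)
    sds = dict(zip(crosses, (0.5, 0.8, 1.0, 1.2, 0.6, 1.5)))
    bg = np.array([sds[c] for c in pop.cross])
    cfg = ScanConfig(min_informative_n=30)
    base = pop.individuals.copy()
    hits = 0
    for rep in range(n_reps):
        y = rng.normal(0, 1, pop.n) * bg + rng.normal(0, 1, pop.n)
        traits = base.assign(y=y)
        (res,) = scan_f2(traits, Msub, rin, cfg)
        if res.p < alpha:
            hits += 1
    return {"rate": hits / n_reps, "n": n_reps, "alpha": alpha}


def qtl_recovery_experiment(n_reps: int = 100, seed: int = 0,
                            effect: float = 1.0, n_per_cross: int = 50,
                            n_chrom: int = 12, n_markers_per_chrom: int = 15,
                            window_bp: int = 5_000_000) -> dict:
    """Planted single-founder QTL: genome-wide localization rate of the F2
    scan and bias of the recovered parental effect vector.

    The QTL sits at a marker where one founder (C085) carries a private
    allele, with a +``effect``-SD additive effect per inherited allele.
    Returns the hit rate (top marker within ``window_bp``), the per-founder
    bias of the sum-to-zero effect estimates over replicates, and the mean
    reported SE.
    """
    founders = make_founders(
        n_markers_per_chrom, [50_000_000] * n_chrom, seed=_sub_seed(seed, 4)
    )
    hap = founders.haplotypes
    c085 = founders.founder_index("C085")
    others = [i for i in range(4) if i != c085]
    private = np.flatnonzero(
        (hap[c085] != hap[others[0]])
        & (hap[c085] != hap[others[1]])
        & (hap[c085] != hap[others[2]])
    )
    qj = int(private[len(private) // 2])
    qmk = str(founders.marker_map.marker_ids[qj])
    qchrom = founders.marker_map.chrom[qj]
    qpos = founders.marker_map.pos_bp[qj]
    plan = CrossPlan(crosses=founders.half_diallel(), generation="F2",
                     n_per_cross=n_per_cross)
    cfg = ScanConfig(min_informative_n=30)

    hits = 0
    est, ses = [], []
    order = ("C074", "C085", "R075", "R104")
    for rep in range(n_reps):
        pop = simulate_population(founders, plan, 2.0, seed=_sub_seed(seed, 10 + rep))
        M = encode_parental_dosage(pop)
        rin = build_rin_design(pop)
        arch = TraitArchitecture(
            name="y", qtls={qmk: {"C085": effect}},
            cross_background_sd=0.5, residual_sd=1.0,
        )
        traits = simulate_traits(pop, arch, seed=_sub_seed(seed, 5000 + rep))
        res = scan_f2(traits, M, rin, cfg)
        tested = [r for r in res if np.isfinite(r.logp)]
        best = max(tested, key=lambda r: r.logp)
        if best.chrom == qchrom and abs(best.pos_bp - qpos) <= window_bp:
            hits += 1
        at = next(r for r in res if r.marker == qmk)
        est.append([at.effects[f] for f in order])
        ses.append([at.ses[f] for f in order])
    est, ses = np.asarray(est), np.asarray(ses)
    truth = np.array([0.0, effect, 0.0, 0.0])
    truth_centered = truth - truth.mean()  # the estimable (sum-to-zero) target
    bias = est.mean(axis=0) - truth_centered
    return {
        "hit_rate": hits / n_reps,
        "n": n_reps,
        "bias": dict(zip(order, bias)),
        "mean_se": dict(zip(order, ses.mean(axis=0))),
        "max_bias_over_se": float(np.max(np.abs(bias) / ses.mean(axis=0))),
    }


def rin_contrast_experiment(n_reps: int = 100, seed: int = 0,
                            n_per_cross: int = 50,
                            link_window_bp: int = 10_000_000) -> dict:
    """False-positive rate at rin-linked markers with and without the rin
    nuisance term, under planted rin effects and no QTL."""
    founders, plan = _standard_design(seed, n_per_cross=n_per_cross)
    mm = founders.marker_map
    rin_j = mm.index_of(founders.rin_marker)
    linked = (
        (mm.chrom == mm.chrom[rin_j])
        & (np.abs(mm.pos_bp - mm.pos_bp[rin_j]) <= link_window_bp)
    )
    cfg = ScanConfig(min_informative_n=30)
    hits_with = hits_without = 0
    for rep in range(n_reps):
        pop = simulate_population(founders, plan, 2.0, seed=_sub_seed(seed, 20 + rep))
        M = encode_parental_dosage(pop).subset_markers(linked)
        rin = build_rin_design(pop)
        arch = TraitArchitecture(
            name="y", rin_additive=1.0, rin_dominance=0.5,
            cross_background_sd=0.5, residual_sd=1.0,
        )
        traits = simulate_traits(pop, arch, seed=_sub_seed(seed, 7000 + rep))
        lw = [r.logp for r in scan_f2(traits, M, rin, cfg) if np.isfinite(r.logp)]
        lwo = [r.logp for r in scan_f2(traits, M, None, cfg) if np.isfinite(r.logp)]
        if lw and max(lw) > cfg.logp_threshold:
            hits_with += 1
        if lwo and max(lwo) > cfg.logp_threshold:
            hits_without += 1
    return {
        "fpr_with_term": hits_with / n_reps,
        "fpr_without_term": hits_without / n_reps,
        "n": n_reps,
    }


def ssd_physics_experiment(seed: int = 0, n_lines: int = 500) -> dict:
    """F6 single-seed-descent heterozygosity vs the closed form (1/2)^5 and
    the two-point recombinant fraction vs the Haldane map value."""
    founders = make_founders(12, [50_000_000] * 4, seed=_sub_seed(seed, 30))
    plan = CrossPlan(crosses=[("C074", "C085")], generation="F6",
                     n_per_cross=n_lines)
    pop = simulate_population(founders, plan, 2.0, seed=_sub_seed(seed, 31))
    mm = founders.marker_map
    diff = founders.haplotypes[0] != founders.haplotypes[1]
    picks = []
    for c in mm.chromosomes():
        idx = np.flatnonzero((mm.chrom == c) & diff)
        if idx.size:
            picks.append(int(idx[0]))
    het = (pop.geno.dosage[:, picks] == 1).astype(float)
    p0 = 0.5**5
    n_draws = het.size
    se = float(np.sqrt(p0 * (1 - p0) / n_draws))

    plan2 = CrossPlan(crosses=[("C074", "C085")], generation="F2",
                      n_per_cross=2000)
    pop2 = simulate_population(founders, plan2, 2.0, seed=_sub_seed(seed, 32))
    idx = np.flatnonzero(mm.chrom == "ch01")
    j0, j1 = int(idx[0]), int(idx[len(idx) // 2])
    d_mbp = (mm.pos_bp[j1] - mm.pos_bp[j0]) / 1e6
    r_exp = 0.5 * (1 - np.exp(-2 * 2.0 * d_mbp / 100))
    rec = (pop2.origins[:, :, j0] != pop2.origins[:, :, j1]).astype(float)
    return {
        "heterozygosity": float(het.mean()),
        "expected_heterozygosity": p0,
        "het_se": se,
        "n_het_draws": n_draws,
        "recombinant_fraction": float(rec.mean()),
        "haldane_expected": float(r_exp),
        "rec_se": float(np.sqrt(r_exp * (1 - r_exp) / rec.size)),
    }


def encoder_identity_experiment(seed: int = 0, n_per_cross: int = 84) -> dict:
    """Fraction of informative entries where the inferred parental dosage
    equals the tracked truth (~500 F2 over the half diallel)."""
    from .encoding import truth_parental_dosage

    founders, plan = _standard_design(seed, n_per_cross=n_per_cross)
    pop = simulate_population(founders, plan, 2.0, seed=_sub_seed(seed, 40))
    M = encode_parental_dosage(pop)
    T = truth_parental_dosage(pop)
    inf = M.informative
    agree = float((M.counts[inf] == T.counts[inf]).all(axis=-1).mean())
    return {"agreement": agree, "n_individuals": pop.n,
            "n_informative_entries": int(inf.sum())}


def haplotype_recovery_experiment(seed: int = 0, n_accessions: int = 500,
                                  mixture: float = 0.6) -> dict:
    """Planted founder-mixture proportion recovered from the germplasm
    representation frequencies."""
    from .haplotypes import call_region_haplotypes, representation_frequencies

    founders = make_founders(12, [50_000_000] * 6, seed=_sub_seed(seed, 50))
    regions = [
        QTLRegion(c, 1, founders.chrom_lengths_bp[c], label=str(c))
        for c in founders.marker_map.chromosomes()
    ]
    panel = simulate_germplasm(founders, mixture, n_accessions,
                               seed=_sub_seed(seed, 51), regions=regions)
    ht = call_region_haplotypes(panel.geno, regions, founders)
    freq, median = representation_frequencies(ht)
    return {
        "median_pct": median,
        "planted_pct": 100 * mixture,
        "n": n_accessions,
        "per_region_pct": freq["representation_pct"].tolist(),
    }


def rf_recovery_experiment(n_seeds: int = 20, seed: int = 0, n: int = 273,
                           n_compounds: int = 20,
                           weights=(2.0, -1.0)) -> dict:
    """Planted signed linear weights recovered by the forest importance.

    Two compounds carry weights (+2, -1) on the log2 scale, the rest are
    inert; a run succeeds when both carriers rank in the importance top 3
    with the planted signs and every inert compound ranks below them on
    average.
    """
    from .sensory import RFConfig, rf_sensory_model
    import pandas as pd

    successes = 0
    inert_below = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 60 + s))
        X = pd.DataFrame(
            rng.lognormal(0, 1, (n, n_compounds)),
            columns=[f"c{j}" for j in range(n_compounds)],
        )
        logX = np.log2(X.to_numpy())
        y = weights[0] * logX[:, 0] + weights[1] * logX[:, 1] + rng.normal(0, 1, n)
        res = rf_sensory_model(
            y, np.log2(X), RFConfig(n_trees=500, n_permutations=500,
                                    seed=_sub_seed(seed, 90 + s)),
        )
        ranked = res.ranked()
        top3 = {r.compound: r for r in ranked[:3]}
        ok = (
            "c0" in top3 and top3["c0"].sign == "+"
            and "c1" in top3 and top3["c1"].sign == "-"
        )
        if ok:
            successes += 1
        imp = {r.compound: r.importance for r in res.records}
        inert_mean = np.mean([imp[f"c{j}"] for j in range(2, n_compounds)])
        inert_below.append(inert_mean < min(imp["c0"], imp["c1"]))
    return {
        "recovery_rate": successes / n_seeds,
        "inert_below_rate": float(np.mean(inert_below)),
        "n": n_seeds,
    }


def reml_oracle_experiment(seed: int = 0) -> dict:
    """Distance between the REML fit and two independent oracles: the
    closed-form balanced one-way ANOVA estimators, and a brute-force grid
    plus local refinement of the restricted likelihood."""
    import itertools

    from scipy import optimize

    rng = np.random.default_rng(_sub_seed(seed, 70))
    g = np.repeat(np.arange(10), 3)
    y = rng.normal(0, 1, 10)[g] + rng.normal(0, 0.8, 30)
    res = HalfDiallelMixedLM(
        y, np.ones((30, 1)), np.repeat("c1", 30),
        genotype_id=np.array([f"g{i}" for i in g]),
    ).fit()
    yb = y.reshape(10, 3).mean(axis=1)
    msb = 3 * np.var(yb, ddof=1)
    msw = ((y.reshape(10, 3) - yb[:, None]) ** 2).sum() / 20
    sg = max((msb - msw) / 3, 0.0)
    err_closed = max(abs(res.vc.sigma2_e - msw), abs(res.vc.sigma2_g["c1"] - sg))

    cross = np.repeat(["a", "b", "c"], 10)
    y2 = np.concatenate([rng.normal(0, s, 10) for s in (0.6, 1.2, 2.0)])
    X2 = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
    model = HalfDiallelMixedLM(y2, X2, cross)
    fit = model.fit()
    grid = np.geomspace(0.01, 20, 20)
    best, best_ll = None, -np.inf
    for v in itertools.product(grid, repeat=3):
        ll = model.loglike_restricted(np.array(v))
        if ll > best_ll:
            best, best_ll = np.array(v), ll
    refined = optimize.minimize(
        lambda v: -model.loglike_restricted(v), best, method="Nelder-Mead",
        bounds=[(1e-10, None)] * 3,
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000},
    )
    err_grid = float(np.max(np.abs(fit.vc.as_array(model.cross_order) - refined.x)))
    return {"closed_form_max_abs_err": float(err_closed),
            "grid_max_abs_err": err_grid}
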