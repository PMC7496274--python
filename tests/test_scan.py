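"""Association scans: DP OLS, F6 per-cross, Kruskal-Wallis, QTL map."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flavorqtl.io import GenotypeMatrix, MarkerMap
from flavorqtl.scan import (
    AssociationResult,
    ScanConfig,
    aggregate_genotype_means,
    kruskal_wallis_assoc,
    results_to_frame,
    scan_dp,
    scan_f2,
    scan_f6,
    summarize_qtl_map,
)


def _panel(rng, n=40, m=6):
    mm = MarkerMap([f"m{j}" for j in range(m)], ["ch1"] * m,
                   (np.arange(m) + 1) * 1_000_000)
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    dosage[:, m - 1] = 1  # monomorphic marker
    G = GenotypeMatrix(dosage, [f"s{i}" for i in range(n)], mm)
    traits = pd.DataFrame(
        {
            "genotype_id": G.samples,
            "cross": "panel",
            "trial": "T1",
            "generation": "DP",
            "fruit_type": rng.choice(["cherry", "round", "beef"], n),
        }
    )
    return G, traits


class TestScanDP:
    def test_exact_linear_trait_hits_logp_cap(self):
        rng = np.random.default_rng(60)
        G, traits = _panel(rng)
        traits["y"] = 2.0 * G.dosage[:, 0]
        res = scan_dp(traits, G, ScanConfig(min_informative_n=5))
        r0 = next(r for r in res if r.marker == "m0")
        assert r0.effects["marker"] == pytest.approx(2.0, abs=1e-8)
        assert r0.logp == 300.0  # noiseless fit reported at the cap

    def test_monomorphic_marker_skipped(self):
        rng = np.random.default_rng(61)
        G, traits = _panel(rng)
        traits["y"] = rng.normal(0, 1, len(traits))
        res = scan_dp(traits, G, ScanConfig(min_informative_n=5))
        r = next(r for r in res if r.marker == "m5")
        assert "monomorphic" in r.note and np.isnan(r.p)

    def test_t_statistic_matches_textbook_ols_formula(self):
        """8-sample toy: t equals the hand-computed OLS formula."""
        g = np.array([0, 0, 1, 1, 2, 2, 1, 0], dtype=np.int8)
        ftype = ["cherry"] * 4 + ["round"] * 4
        y = np.array([1.0, 1.4, 2.1, 2.0, 3.2, 2.9, 1.9, 1.1])
        mm = MarkerMap(["m0"], ["ch1"], [100])
        G = GenotypeMatrix(g[:, None], [f"s{i}" for i in range(8)], mm)
        traits = pd.DataFrame(
            {"genotype_id": G.samples, "fruit_type": ftype, "y": y}
        )
        res = scan_dp(traits, G, ScanConfig(min_informative_n=5))
        X = np.column_stack([np.ones(8), np.array(ftype) == "cherry", g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (8 - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[2, 2])
        t_hand = beta[2] / se
        assert res[0].statistic == pytest.approx(t_hand, abs=1e-10)

    def test_requires_fruit_type(self):
        rng = np.random.default_rng(62)
        G, traits = _panel(rng)
        traits["y"] = 1.0
        with pytest.raises(ValueError, match="fruit_type"):
            scan_dp(traits.drop(columns="fruit_type"), G)


class TestScanF6:
    def _ril(self, rng, n_per_cross=30):
        m = 5
        mm = MarkerMap([f"m{j}" for j in range(m)], ["ch1"] * m,
                       (np.arange(m) + 1) * 1_000_000)
        dosage = rng.choice([0, 2], size=(2 * n_per_cross, m)).astype(np.int8)
        G = GenotypeMatrix(dosage, [f"r{i}" for i in range(2 * n_per_cross)], mm)
        traits = pd.DataFrame(
            {
                "genotype_id": G.samples,
                "cross": ["cc"] * n_per_cross + ["rr"] * n_per_cross,
                "trial": "T1",
                "generation": "F6",
                "fruit_type": "round",
                "y": rng.normal(0, 1, 2 * n_per_cross)
                + 0.8 * dosage[:, 1],
            }
        )
        return G, traits

    def test_r2_is_squared_pearson_within_cross(self):
        rng = np.random.default_rng(63)
        G, traits = self._ril(rng)
        res = scan_f6(traits, G)
        for r in res:
            if not np.isfinite(r.p):
                continue
            sub = traits[traits["cross"] == r.cross]
            g = G.dosage[[G.sample_index(s) for s in sub["genotype_id"]],
                         G.markers.index_of(r.marker)]
            rho = np.corrcoef(g, sub["y"])[0, 1]
            assert r.r2 == pytest.approx(rho**2, abs=1e-10)

    def test_crosses_never_pooled(self):
        """Permuting trait values within one cross leaves the other cross's
        results bit-identical."""
        rng = np.random.default_rng(64)
        G, traits = self._ril(rng)
        res1 = scan_f6(traits, G)
        shuffled = traits.copy()
        rr = shuffled["cross"] == "rr"
        shuffled.loc[rr, "y"] = rng.permutation(shuffled.loc[rr, "y"].to_numpy())
        res2 = scan_f6(shuffled, G)
        cc1 = results_to_frame([r for r in res1 if r.cross == "cc"])
        cc2 = results_to_frame([r for r in res2 if r.cross == "cc"])
        pd.testing.assert_frame_equal(cc1, cc2)

    def test_small_cross_skipped(self):
        rng = np.random.default_rng(65)
        G, traits = self._ril(rng, n_per_cross=30)
        traits.loc[traits["cross"] == "rr", "y"] = np.nan
        traits.loc[traits.index[-2:], "y"] = 1.0
        res = scan_f6(traits, G)
        rr = [r for r in res if r.cross == "rr"]
        assert all("fewer than 3" in r.note for r in rr)

    def test_planted_r2_recovered_in_sampling_band(self):
        """A RIL QTL explaining ~30% of variance at n=100 estimates R^2 in
        [0.2, 0.4] in most replicates."""
        rng = np.random.default_rng(66)
        hit = 0
        n_rep = 40
        for rep in range(n_rep):
            g = rng.choice([0, 2], size=100)
            beta = np.sqrt(0.3 / 0.7 / np.var(g))
            y = beta * g + rng.normal(0, 1, 100)
            mm = MarkerMap(["m0"], ["ch1"], [100])
            G = GenotypeMatrix(g.astype(np.int8)[:, None],
                               [f"r{i}" for i in range(100)], mm)
            traits = pd.DataFrame(
                {"genotype_id": G.samples, "cross": "cc", "y": y}
            )
            res = scan_f6(traits, G)
            if 0.2 <= res[0].r2 <= 0.4:
                hit += 1
        assert hit >= int(0.9 * n_rep) - 4


class TestKruskalWallis:
    def test_hand_computed_rank_sum_example(self):
        """Groups {1,2,3} vs {4,5,6}: H = 12/(N(N+1)) * sum R^2/n - 3(N+1)."""
        res = kruskal_wallis_assoc([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert res.statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21,
                                              abs=1e-10)
        assert res.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_all_tied_gives_h0_p1(self):
        res = kruskal_wallis_assoc([2.0, 2.0, 2.0, 2.0], list("aabb"))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_assoc([1, 2, 3], list("aaa"))

    def test_p_matches_exhaustive_permutation(self):
        """Toy P agrees with the exact permutation distribution of H within
        the chi-square approximation error at n=12."""
        from itertools import combinations

        rng = np.random.default_rng(67)
        values = np.concatenate([rng.normal(1.0, 1, 6), rng.normal(0, 1, 6)])
        labels = np.array(["a"] * 6 + ["b"] * 6)
        obs = kruskal_wallis_assoc(values, labels)
        hs = []
        for comb in combinations(range(12), 6):
            lab = np.array(["b"] * 12)
            lab[list(comb)] = "a"
            hs.append(kruskal_wallis_assoc(values, lab).statistic)
        perm_p = np.mean([h >= obs.statistic - 1e-12 for h in hs])
        assert abs(perm_p - obs.p) < 0.05


class TestAggregation:
    def test_genotype_means_unweighted_over_replicates(self):
        traits = pd.DataFrame(
            {
                "genotype_id": ["g1", "g1", "g2"],
                "cross": ["c", "c", "c"],
                "trial": ["T1", "T2", "T1"],
                "generation": ["F2"] * 3,
                "fruit_type": ["cherry"] * 3,
                "y": [1.0, 3.0, 5.0],
            }
        )
        out = aggregate_genotype_means(traits)
        assert out.loc[out["genotype_id"] == "g1", "y"].iloc[0] == 2.0
        assert len(out) == 2


class TestQtlMap:
    def _res(self, logp, pos=52_660_000, cross=""):
        return AssociationResult(
            trait="PHET", marker="m", chrom="ch04", pos_bp=pos, model="F6-cross",
            statistic=1.0, df=1, p=10.0 ** -logp, logp=logp, cross=cross,
        )

    def test_threshold_is_strict(self):
        cfg = ScanConfig()
        assert len(summarize_qtl_map([self._res(3.49)], cfg)) == 0
        assert len(summarize_qtl_map([self._res(3.51)], cfg)) == 1

    def test_5mbp_binning(self):
        """52.66 Mbp falls in the [50, 55) Mbp bin."""
        out = summarize_qtl_map([self._res(5.0)], ScanConfig())
        assert out["bin"].iloc[0] == 10
        assert out["bin_start_bp"].iloc[0] == 50_000_001
        assert out["bin_end_bp"].iloc[0] == 55_000_000

    def test_empty_results_empty_map(self):
        assert len(summarize_qtl_map([], ScanConfig())) == 0

    def test_max_logp_and_cross_tags(self):
        rows = [
            self._res(4.0, cross="C074xC085"),
            self._res(6.0, cross="R075xR104"),
            self._res(5.0, pos=53_000_000, cross="C074xR104"),
        ]
        out = summarize_qtl_map(rows, ScanConfig())
        assert len(out) == 1
        assert out["max_logp"].iloc[0] == 6.0
        assert out["crosses"].iloc[0] == "CC,CR,RR"


class TestScanF2Contract:
    def test_uninformative_marker_skipped_with_reason(self, f2_pop, encoded,
                                                      rin_design):
        f = f2_pop.founders
        mono = np.flatnonzero(~encoded.informative.any(axis=0))
        traits = pd.DataFrame(
            {
                "genotype_id": f2_pop.ids,
                "cross": f2_pop.cross,
                "trial": "T1",
                "generation": "F2",
                "fruit_type": "round",
                "y": np.random.default_rng(1).normal(0, 1, f2_pop.n),
            }
        )
        res = scan_f2(traits, encoded, rin_design, ScanConfig(min_informative_n=30))
        by_marker = {r.marker: r for r in res}
        for j in mono:
            r = by_marker[str(f.marker_map.marker_ids[j])]
            assert "zero crosses" in r.note
        tested = [r for r in res if np.isfinite(r.logp)]
        assert len(tested) > 0
        for r in tested[:10]:
            assert 0 < r.p <= 1 and r.logp >= 0 and r.df >= 1
            assert abs(sum(r.effects.values())) < 1e-6  # sum-to-zero reporting
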