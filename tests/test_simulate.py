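"""Simulator physics: founders, meiosis, SSD, traits, sensory, germplasm."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flavorqtl.io import QTLRegion
from flavorqtl.simulate import (
    CrossPlan,
    FounderSet,
    SensoryMap,
    TraitArchitecture,
    make_founders,
    simulate_germplasm,
    simulate_population,
    simulate_sensory,
    simulate_traits,
)


class TestMakeFounders:
    def test_shape_sortedness_homozygosity(self):
        f = make_founders(10, [1_000_000], seed=7)
        assert len(f.founder_ids) == 4
        assert f.haplotypes.shape == (4, 10)
        assert set(np.unique(f.haplotypes)) <= {0, 1}
        pos = f.marker_map.pos_bp
        assert np.all(np.diff(pos) > 0)

    def test_full_difference_fraction_makes_every_marker_polymorphic(self):
        f = make_founders(200, [1_000_000], seed=3, pair_diff_fraction=1.0)
        assert (f.haplotypes.min(axis=0) != f.haplotypes.max(axis=0)).all()

    def test_pair_difference_fraction_default(self):
        f = make_founders(2000, [10_000_000], seed=5, pair_diff_fraction=0.4)
        fracs = [
            (f.haplotypes[i] != f.haplotypes[j]).mean()
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        assert np.allclose(fracs, 0.4, atol=0.05)

    def test_seed_determinism(self):
        a = make_founders([5, 7], [1_000_000, 2_000_000], seed=11)
        b = make_founders([5, 7], [1_000_000, 2_000_000], seed=11)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.marker_map == b.marker_map
        assert a.rin_marker == b.rin_marker

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_founders(0, [1000], seed=1)
        with pytest.raises(ValueError):
            make_founders(5, [0], seed=1)
        with pytest.raises(ValueError):
            make_founders([5, 5], [1000], seed=1)

    def test_founderset_invariants_enforced(self):
        f = make_founders(5, [1000], seed=1)
        with pytest.raises(ValueError):
            FounderSet(("a", "b", "c"), f.haplotypes[:3], f.marker_map,
                       f.chrom_lengths_bp, f.rin_marker, "a")


class TestMeiosis:
    def test_zero_recombination_gives_intact_founder_chromosomes(self, founders6):
        plan = CrossPlan(crosses=[("C074", "C085")], generation="F2", n_per_cross=20)
        pop = simulate_population(founders6, plan, recomb_rate_cM_per_Mbp=0.0, seed=1)
        mm = founders6.marker_map
        for c in mm.chromosomes():
            idx = np.flatnonzero(mm.chrom == c)
            o = pop.origins[:, :, idx]
            # each haplotype is a single founder along the whole chromosome
            assert (o == o[:, :, :1]).all()

    def test_f2_segregation_1_2_1(self, founders6):
        """F2 genotype counts at an informative marker are consistent with
        the exact 1:2:1 multinomial expectation (chi-square GOF, alpha=.01)."""
        plan = CrossPlan(crosses=[("C074", "R104")], generation="F2", n_per_cross=2000)
        pop = simulate_population(founders6, plan, 2.0, seed=9)
        diff = founders6.haplotypes[0] != founders6.haplotypes[3]
        j = int(np.flatnonzero(diff)[2])
        g = pop.geno.dosage[:, j]
        counts = np.bincount(g, minlength=3)
        chi2 = stats.chisquare(counts, f_exp=[500, 1000, 500]).pvalue
        assert chi2 > 0.01

    def test_f6_ssd_heterozygosity(self, founders6):
        """Per-locus F6 heterozygote fraction ~ (1/2)^5 within 3 binomial SEs
        over independent line x unlinked-locus draws."""
        plan = CrossPlan(crosses=[("C074", "C085")], generation="F6", n_per_cross=500)
        pop = simulate_population(founders6, plan, 2.0, seed=12)
        mm = founders6.marker_map
        diff = founders6.haplotypes[0] != founders6.haplotypes[1]
        # one informative marker per chromosome: independent across lines/chroms
        picks = []
        for c in mm.chromosomes():
            idx = np.flatnonzero((mm.chrom == c) & diff)
            if idx.size:
                picks.append(idx[0])
        het = (pop.geno.dosage[:, picks] == 1).astype(float)
        n = het.size
        p0 = 0.5**5
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(het.mean() - p0) < 3 * se

    def test_haldane_recombinant_fraction(self, founders6):
        """Pairwise recombinant fraction converges to the Haldane map value."""
        plan = CrossPlan(crosses=[("C074", "C085")], generation="F2", n_per_cross=3000)
        rate = 2.0
        pop = simulate_population(founders6, plan, rate, seed=13)
        mm = founders6.marker_map
        idx = np.flatnonzero(mm.chrom == "ch01")
        j0, j1 = idx[0], idx[len(idx) // 2]
        d_mbp = (mm.pos_bp[j1] - mm.pos_bp[j0]) / 1e6
        r_exp = 0.5 * (1 - np.exp(-2 * rate * d_mbp / 100))
        o = pop.origins
        rec = (o[:, :, j0] != o[:, :, j1]).astype(float)  # per gamete
        n = rec.size
        se = np.sqrt(r_exp * (1 - r_exp) / n)
        assert abs(rec.mean() - r_exp) < 4 * se

    def test_mendelian_consistency_alleles_trace_to_origins(self, f2_pop):
        """Every offspring allele equals the tracked founder's allele."""
        f = f2_pop.founders
        m = f.n_markers
        alleles = f.haplotypes[f2_pop.origins, np.arange(m)[None, None, :]]
        assert np.array_equal(alleles.sum(axis=1).astype(np.int8), f2_pop.geno.dosage)
        # origins only reference the cross's two parents
        for label, (pa, pb) in f2_pop.cross_parents.items():
            rows = f2_pop.cross == label
            allowed = {f.founder_index(pa), f.founder_index(pb)}
            assert set(np.unique(f2_pop.origins[rows])) <= allowed

    def test_rin_selection_removes_all_mutant_carriers(self, founders6):
        plan = CrossPlan(
            crosses=[("R075", "R104")], generation="F6", n_per_cross=60,
            rin_selection=True,
        )
        pop = simulate_population(founders6, plan, 2.0, seed=14)
        assert (pop.rin_dosage() == 0).all()
        # without selection, carriers are common
        plan2 = CrossPlan(crosses=[("R075", "R104")], generation="F6", n_per_cross=60)
        pop2 = simulate_population(founders6, plan2, 2.0, seed=14)
        assert (pop2.rin_dosage() > 0).any()

    def test_seed_determinism_and_errors(self, founders6):
        plan = CrossPlan(crosses=[("C074", "C085")], generation="F2", n_per_cross=5)
        a = simulate_population(founders6, plan, 2.0, seed=3)
        b = simulate_population(founders6, plan, 2.0, seed=3)
        assert np.array_equal(a.origins, b.origins)
        with pytest.raises(ValueError, match="unknown parent"):
            simulate_population(
                founders6,
                CrossPlan(crosses=[("C074", "nope")], generation="F2", n_per_cross=2),
                2.0, seed=1,
            )
        with pytest.raises(ValueError, match="rate"):
            simulate_population(founders6, plan, -1.0, seed=1)


class TestTraits:
    def test_zero_effects_zero_sds_gives_baseline_exactly(self, f2_pop):
        arch = TraitArchitecture(name="t", baseline=3.25)
        tr = simulate_traits(f2_pop, arch, seed=1)
        assert (tr["t"] == 3.25).all()

    def test_single_qtl_trait_affine_in_allele_count(self, f2_pop):
        f = f2_pop.founders
        mk = str(f.marker_map.marker_ids[5])
        arch = TraitArchitecture(name="t", baseline=1.0, qtls={mk: {"C085": 1.0}})
        tr = simulate_traits(f2_pop, arch, seed=1)
        j = f.marker_map.index_of(mk)
        count = (f2_pop.origins[:, :, j] == f.founder_index("C085")).sum(axis=1)
        assert np.allclose(tr["t"].to_numpy(), 1.0 + count)

    def test_cross_background_sds_recovered(self, founders6):
        plan = CrossPlan(
            crosses=[("C074", "C085"), ("C074", "R075"), ("C074", "R104")],
            generation="F2", n_per_cross=500,
        )
        pop = simulate_population(founders6, plan, 2.0, seed=15)
        sds = dict(zip(pop.cross_parents, (0.5, 1.0, 2.0)))
        arch = TraitArchitecture(name="t", cross_background_sd=sds)
        tr = simulate_traits(pop, arch, seed=2)
        for cross, sd in sds.items():
            sample_sd = tr.loc[tr["cross"] == cross, "t"].std()
            assert abs(sample_sd - sd) / sd < 0.15

    def test_unknown_qtl_marker_rejected(self, f2_pop):
        arch = TraitArchitecture(name="t", qtls={"nope": {"C085": 1.0}})
        with pytest.raises(KeyError):
            simulate_traits(f2_pop, arch, seed=1)

    def test_trial_batch_factor_multiplies_metabolite(self, f2_pop):
        arch = TraitArchitecture(
            name="m", baseline=2.0, metabolite=True,
            trial_factors={"T1": 1.0, "T2": 3.0},
        )
        tr = simulate_traits(f2_pop, arch, seed=1, replicates=2, trials=["T1", "T2"])
        t1 = tr.loc[tr["trial"] == "T1", "m"].to_numpy()
        t2 = tr.loc[tr["trial"] == "T2", "m"].to_numpy()
        assert np.allclose(t1, 4.0)  # 2**baseline
        assert np.allclose(t2, 12.0)


class TestSensory:
    def _metab(self, f2_pop, seed=4):
        archs = [
            TraitArchitecture(name="PHET", baseline=5.0, cross_background_sd=1.0,
                              metabolite=True),
            TraitArchitecture(name="SUC", baseline=3.0, cross_background_sd=1.0,
                              metabolite=True),
        ]
        return simulate_traits(f2_pop, archs, seed=seed)

    def test_noiseless_single_compound_is_rank_identical(self, f2_pop):
        tr = self._metab(f2_pop)
        smap = SensoryMap({"sweet": {"weights": {"PHET": 1.0}, "noise_sd": 0.0}})
        out = simulate_sensory(tr, smap, seed=1)
        assert np.allclose(out["sweet"], np.log2(out["PHET"]))

    def test_zero_weights_noise_only_uncorrelated(self, f2_pop):
        tr = self._metab(f2_pop)
        smap = SensoryMap(
            {"a": {"weights": {"PHET": 0.0, "SUC": 0.0}, "noise_sd": 1.0}}
        )
        # zero weights must still be declared; an all-zero map is caught at
        # the dataclass level only when empty
        out = simulate_sensory(tr, smap, seed=2)
        for comp in ("PHET", "SUC"):
            r = np.corrcoef(out["a"], np.log2(out[comp]))[0, 1]
            assert abs(r) < 0.15

    def test_determinism_and_missing_compound(self, f2_pop):
        tr = self._metab(f2_pop)
        smap = SensoryMap({"s": {"weights": {"PHET": 1.0}, "noise_sd": 0.5}})
        a = simulate_sensory(tr, smap, seed=3)
        b = simulate_sensory(tr, smap, seed=3)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(KeyError):
            simulate_sensory(tr, SensoryMap({"s": {"weights": {"XX": 1.0}}}), seed=1)
        with pytest.raises(ValueError):
            SensoryMap({"s": {"weights": {}}})


class TestGermplasm:
    def test_extreme_mixtures(self, founders6):
        regions = [QTLRegion("ch01", 1, 50_000_000, "r1")]
        all_f = simulate_germplasm(founders6, 1.0, 40, seed=5, regions=regions)
        none_f = simulate_germplasm(founders6, 0.0, 40, seed=5, regions=regions)
        mm = founders6.marker_map
        idx = np.flatnonzero(mm.region_mask(regions[0]))
        fref = 2 * founders6.haplotypes[:, idx]
        for pop, expect in ((all_f, True), (none_f, False)):
            geno = pop.geno.dosage[:, idx]
            matches = (geno[:, None, :] == fref[None, :, :]).all(axis=2).any(axis=1)
            assert matches.all() == expect and matches.any() == expect

    def test_truth_recorded_and_proportion_close(self, founders6):
        regions = [QTLRegion("ch01", 1, 50_000_000, "r1")]
        pop = simulate_germplasm(founders6, 0.6, 400, seed=6, regions=regions)
        truth = pop.extras["germplasm_truth"]
        frac = (truth["founder"] != "").mean()
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 400)

    def test_invalid_proportion(self, founders6):
        with pytest.raises(ValueError):
            simulate_germplasm(founders6, 1.5, 10, seed=1)
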