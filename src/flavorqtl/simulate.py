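"""Synthetic half-diallel populations, traits, sensory attributes and germplasm.

The generator mirrors the structure the association models assume: four fully
homozygous founder inbreds genotyped on a dense SNP map, six half-diallel
crosses producing F2 progeny and single-seed-descent F6 RILs, a ripening
mutant (*rin*-like) carried homozygously by one founder and selected against
during line development, founder-allelic QTL effects, per-cross polygenic
background variance, multiplicative trial batch factors on metabolite
abundances, sensory attributes driven by weighted log-scale metabolite
combinations, and a germplasm panel mixing founder and novel haplotypes.

Meiosis uses the Haldane model: crossover counts are Poisson with mean equal
to the chromosome map length (cM/Mbp rate x physical length), crossover
positions uniform, no interference.  The founder origin of every transmitted
allele is tracked and retained as ground truth for the encoder and
fine-mapping oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerMap, QTLRegion

DEFAULT_FOUNDERS = ("C074", "C085", "R075", "R104")
DEFAULT_RIN_CARRIER = "R075"

#: fruit type of each default founder (C* are cherry cultivars, R* round)
FOUNDER_FRUIT_TYPE = {"C074": "cherry", "C085": "cherry", "R075": "round", "R104": "round"}


# ---------------------------------------------------------------------------
# founders


@dataclass
class FounderSet:
    """Four homozygous founder inbreds with one binary allele per marker."""

    founder_ids: tuple
    haplotypes: np.ndarray  # (4, n_markers) int8, one allele per marker
    marker_map: MarkerMap
    chrom_lengths_bp: dict
    rin_marker: str
    rin_carrier: str = DEFAULT_RIN_CARRIER

    def __post_init__(self):
        self.founder_ids = tuple(self.founder_ids)
        if len(self.founder_ids) != 4:
            raise ValueError("a half diallel needs exactly 4 founders")
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (4, len(self.marker_map)):
            raise ValueError("haplotypes must be (4, n_markers)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1 (homozygous inbreds)")
        if self.rin_carrier not in self.founder_ids:
            raise ValueError(f"rin carrier {self.rin_carrier} not a founder")
        self.marker_map.index_of(self.rin_marker)  # validate

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    @property
    def rin_genotype(self) -> dict:
        """Mutant-allele dosage per founder (carrier is homozygous mutant)."""
        return {f: (2 if f == self.rin_carrier else 0) for f in self.founder_ids}

    def founder_index(self, founder_id: str) -> int:
        return self.founder_ids.index(founder_id)

    def genotype_matrix(self) -> GenotypeMatrix:
        """Founders as diploid homozygous samples (dosage 0 or 2)."""
        return GenotypeMatrix(2 * self.haplotypes, list(self.founder_ids), self.marker_map)

    def half_diallel(self) -> list[tuple[str, str]]:
        """All 6 unordered founder pairs."""
        ids = self.founder_ids
        return [(ids[i], ids[j]) for i in range(4) for j in range(i + 1, 4)]


def make_founders(
    n_markers_per_chrom,
    chrom_lengths_bp,
    seed: int,
    pair_diff_fraction: float = 0.4,
    founder_ids=DEFAULT_FOUNDERS,
    rin_chrom_index: int | None = None,
) -> FounderSet:
    """Draw a founder set with a sorted physical map.

    ``pair_diff_fraction`` is the expected fraction of markers at which any
    unordered founder pair differs.  Polymorphic markers receive a uniformly
    drawn non-constant allele pattern over the four founders; such a pattern
    separates a given pair with probability 8/14, so the per-marker
    polymorphism probability is ``min(1, fraction * 14/8)`` (the per-pair
    fraction saturates at 4/7 — with two alleles and four founders some pair
    always shares an allele).

    The ripening-mutant locus is placed at the marker closest to the middle
    of chromosome 5 (``rin_chrom_index=4``) when at least five chromosomes
    exist, else the middle of the last chromosome.
    """
    chrom_lengths_bp = [int(x) for x in np.atleast_1d(chrom_lengths_bp)]
    n_chrom = len(chrom_lengths_bp)
    if np.isscalar(n_markers_per_chrom):
        counts = [int(n_markers_per_chrom)] * n_chrom
    else:
        counts = [int(x) for x in n_markers_per_chrom]
    if len(counts) != n_chrom:
        raise ValueError("marker counts and chromosome lengths differ in length")
    if any(c < 1 for c in counts):
        raise ValueError("need at least one marker per chromosome")
    if any(l < 1 for l in chrom_lengths_bp):
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 <= pair_diff_fraction <= 1.0:
        raise ValueError("pair_diff_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    chrom_names = [f"ch{c + 1:02d}" for c in range(n_chrom)]
    mids, chroms, poss = [], [], []
    for cname, length, count in zip(chrom_names, chrom_lengths_bp, counts):
        if count > length:
            raise ValueError(f"{cname}: more markers than base pairs")
        pos = np.sort(rng.choice(length, size=count, replace=False)) + 1
        poss.extend(pos.tolist())
        chroms.extend([cname] * count)
        mids.extend(f"{cname}_m{k + 1:04d}" for k in range(count))
    marker_map = MarkerMap(mids, chroms, poss)
    m = len(marker_map)

    p_poly = min(1.0, pair_diff_fraction * 14.0 / 8.0)
    polymorphic = rng.random(m) < p_poly
    haplotypes = np.zeros((4, m), dtype=np.int8)
    # constant markers: all founders share a random allele
    haplotypes[:, :] = rng.integers(0, 2, size=m, dtype=np.int8)[None, :]
    n_poly = int(polymorphic.sum())
    if n_poly:
        # uniformly draw non-constant patterns (1..14) over the 4 founders
        codes = rng.integers(1, 15, size=n_poly)
        pattern = ((codes[:, None] >> np.arange(4)[None, :]) & 1).astype(np.int8)
        haplotypes[:, polymorphic] = pattern.T

    chrom_lengths = dict(zip(chrom_names, chrom_lengths_bp))
    if rin_chrom_index is None:
        rin_chrom_index = 4 if n_chrom >= 5 else n_chrom - 1
    rin_chrom = chrom_names[rin_chrom_index]
    cmask = marker_map.chrom == rin_chrom
    cpos = marker_map.pos_bp[cmask]
    mid = chrom_lengths[rin_chrom] // 2
    rin_marker = marker_map.marker_ids[cmask][np.argmin(np.abs(cpos - mid))]
    return FounderSet(
        founder_ids=tuple(founder_ids),
        haplotypes=haplotypes,
        marker_map=marker_map,
        chrom_lengths_bp=chrom_lengths,
        rin_marker=str(rin_marker),
    )


# ---------------------------------------------------------------------------
# cross plan / population


@dataclass
class CrossPlan:
    """Which crosses to make, to which generation, and with what selection."""

    crosses: list  # list of (parentA, parentB)
    generation: str = "F2"  # F1 | F2 | F6
    n_per_cross: int = 50
    rin_selection: bool = False
    ssd_generations: int = 4  # selfings F2 -> F6

    def __post_init__(self):
        if self.generation not in ("F1", "F2", "F6"):
            raise ValueError("generation must be F1, F2 or F6")
        if self.n_per_cross < 1:
            raise ValueError("n_per_cross must be >= 1")
        if self.generation == "F6" and self.ssd_generations < 1:
            raise ValueError("ssd_generations must be >= 1 for F6")


def cross_label(parent_a: str, parent_b: str) -> str:
    return f"{parent_a}x{parent_b}"


def cross_fruit_type(parent_a: str, parent_b: str) -> str:
    ta = FOUNDER_FRUIT_TYPE.get(parent_a, "round" if parent_a.startswith("R") else "cherry")
    tb = FOUNDER_FRUIT_TYPE.get(parent_b, "round" if parent_b.startswith("R") else "cherry")
    return "cherry" if ta == tb == "cherry" else "round"


class Population:
    """Individuals with cross/generation labels, dosages and (optionally)
    simulator-tracked founder origin of every allele."""

    def __init__(
        self,
        geno: GenotypeMatrix,
        individuals: pd.DataFrame,
        cross_parents: dict,
        founders: FounderSet | None = None,
        origins: np.ndarray | None = None,
        extras: dict | None = None,
    ):
        if len(individuals) != geno.n_samples:
            raise ValueError("individual table does not match genotype matrix")
        if origins is not None:
            origins = np.asarray(origins, dtype=np.int8)
            if origins.shape != (geno.n_samples, 2, geno.n_markers):
                raise ValueError("origins must be (n, 2, n_markers)")
        self.geno = geno
        self.individuals = individuals.reset_index(drop=True)
        self.cross_parents = dict(cross_parents)
        self.founders = founders
        self.origins = origins
        self.extras = extras or {}

    @property
    def n(self) -> int:
        return self.geno.n_samples

    @property
    def markers(self) -> MarkerMap:
        return self.geno.markers

    @property
    def ids(self) -> np.ndarray:
        return self.individuals["genotype_id"].to_numpy()

    @property
    def cross(self) -> np.ndarray:
        return self.individuals["cross"].to_numpy()

    def rin_dosage(self) -> np.ndarray:
        """Tracked mutant-allele count at the rin locus per individual."""
        if self.origins is None or self.founders is None:
            raise ValueError("rin dosage requires origin-tracked population")
        j = self.markers.index_of(self.founders.rin_marker)
        carrier = self.founders.founder_index(self.founders.rin_carrier)
        return (self.origins[:, :, j] == carrier).sum(axis=1).astype(np.int8)

    def origin_counts(self) -> np.ndarray:
        """Truth (n, n_markers, 4): alleles inherited from each founder."""
        if self.origins is None:
            raise ValueError("population is not origin-tracked")
        counts = np.zeros((self.n, self.geno.n_markers, 4), dtype=np.int8)
        for f in range(4):
            counts[:, :, f] = (self.origins == f).sum(axis=1)
        return counts


class _Meiosis:
    """Gamete formation over a physical map under the Haldane model."""

    def __init__(self, founders: FounderSet, recomb_rate_cM_per_Mbp: float):
        if recomb_rate_cM_per_Mbp < 0:
            raise ValueError("recombination rate must be >= 0")
        self.rate = recomb_rate_cM_per_Mbp
        mm = founders.marker_map
        self.chroms = []
        for c in mm.chromosomes():
            idx = np.flatnonzero(mm.chrom == c)
            length = founders.chrom_lengths_bp[c]
            morgans = self.rate * (length / 1e6) / 100.0
            self.chroms.append((idx, mm.pos_bp[idx].astype(float), float(length), morgans))

    def gamete(self, rng: np.random.Generator, origins2: np.ndarray) -> np.ndarray:
        """One gamete's origin row from a diploid parent's (2, m) origins."""
        m = origins2.shape[1]
        out = np.empty(m, dtype=np.int8)
        for idx, pos, length, morgans in self.chroms:
            k = rng.poisson(morgans)
            start = rng.integers(0, 2)
            if k == 0:
                hap = np.full(len(idx), start)
            else:
                bp = np.sort(rng.uniform(0.0, length, size=k))
                hap = (start + np.searchsorted(bp, pos)) % 2
            out[idx] = origins2[hap, idx]
        return out

    def self_(self, rng, origins2: np.ndarray) -> np.ndarray:
        return np.stack([self.gamete(rng, origins2), self.gamete(rng, origins2)])


def simulate_population(
    founders: FounderSet,
    plan: CrossPlan,
    recomb_rate_cM_per_Mbp: float = 2.0,
    seed: int = 0,
    trial: str = "T1",
) -> Population:
    """Simulate the half-diallel F1/F2/F6 populations with origin tracking.

    F2 individuals are independent selfings of the cross F1; F6 RILs descend
    from distinct F2 plants by single-seed descent (one random selfed seed per
    generation).  With ``plan.rin_selection``, in crosses containing the rin
    carrier, mutant-homozygous F2 plants never enter SSD and only
    wild-type-homozygous F5 plants produce F6 seed (failed lines are redrawn
    from the same F2 plant).
    """
    for pa, pb in plan.crosses:
        for p in (pa, pb):
            if p not in founders.founder_ids:
                raise ValueError(f"unknown parent {p!r}")
    rng = np.random.default_rng(seed)
    meiosis = _Meiosis(founders, recomb_rate_cM_per_Mbp)
    m = founders.n_markers
    rin_j = founders.marker_map.index_of(founders.rin_marker)
    carrier_idx = founders.founder_index(founders.rin_carrier)

    all_origins, rows = [], []
    cross_parents = {}
    for pa, pb in plan.crosses:
        label = cross_label(pa, pb)
        cross_parents[label] = (pa, pb)
        ftype = cross_fruit_type(pa, pb)
        ia, ib = founders.founder_index(pa), founders.founder_index(pb)
        f1 = np.stack([np.full(m, ia, dtype=np.int8), np.full(m, ib, dtype=np.int8)])
        selectable = plan.rin_selection and founders.rin_carrier in (pa, pb)
        for i in range(plan.n_per_cross):
            if plan.generation == "F1":
                ind = f1.copy()
            else:
                ind = _advance_line(
                    rng, meiosis, f1, plan, selectable, rin_j, carrier_idx
                )
            all_origins.append(ind)
            rows.append(
                {
                    "genotype_id": f"{label}_{plan.generation}_{i + 1:03d}",
                    "cross": label,
                    "trial": trial,
                    "generation": plan.generation,
                    "fruit_type": ftype,
                }
            )

    origins = np.stack(all_origins)  # (n, 2, m)
    alleles = founders.haplotypes[origins, np.arange(m)[None, None, :]]
    dosage = alleles.sum(axis=1).astype(np.int8)
    geno = GenotypeMatrix(
        dosage, [r["genotype_id"] for r in rows], founders.marker_map
    )
    return Population(geno, pd.DataFrame(rows), cross_parents, founders, origins)


def _advance_line(rng, meiosis, f1, plan, selectable, rin_j, carrier_idx, max_tries=200):
    """One F2 plant, optionally advanced by SSD to F6 under rin selection."""

    def mutant_dosage(ind):
        return int((ind[:, rin_j] == carrier_idx).sum())

    for _ in range(max_tries):
        f2 = meiosis.self_(rng, f1)
        if plan.generation == "F2":
            return f2
        if selectable and mutant_dosage(f2) == 2:
            continue  # mutant-homozygous F2 plants never enter SSD
        for _ in range(max_tries):
            cur = f2
            for _ in range(plan.ssd_generations - 1):  # F2 -> F5
                cur = meiosis.self_(rng, cur)
            if selectable and mutant_dosage(cur) != 0:
                continue  # only wild-type-homozygous F5 plants give F6 seed
            return meiosis.self_(rng, cur)
        # SSD never fixed wild type (possible from a heterozygous F2): new F2
    raise RuntimeError("rin selection failed to produce a line")


# ---------------------------------------------------------------------------
# traits


@dataclass
class TraitArchitecture:
    """Generative architecture of one trait.

    ``qtls`` maps marker id -> {founder id: additive effect per inherited
    allele, in trait SD units}.  ``rin_additive``/``rin_dominance`` follow the
    F2 coding (additive on mutant dosage - 1; dominance indicator for
    heterozygotes) and apply only to individuals with tracked rin genotypes.
    ``cross_background_sd`` is the per-cross polygenic SD (scalar or mapping
    cross label -> SD).  Metabolite traits are exponentiated onto a positive
    abundance scale (2**value) and multiplied by the trial batch factor.
    """

    name: str = "trait"
    baseline: float = 0.0
    qtls: dict = field(default_factory=dict)
    rin_additive: float = 0.0
    rin_dominance: float = 0.0
    cross_background_sd: object = 0.0
    residual_sd: float = 0.0
    trial_factors: dict = field(default_factory=dict)
    metabolite: bool = False

    def __post_init__(self):
        for mk, eff in self.qtls.items():
            for f, e in eff.items():
                if not np.isfinite(e):
                    raise ValueError(f"non-finite effect for {mk}/{f}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if any(v <= 0 for v in self.trial_factors.values()):
            raise ValueError("trial factors must be > 0")

    def background_sd(self, cross: str) -> float:
        if isinstance(self.cross_background_sd, dict):
            return float(self.cross_background_sd.get(cross, 0.0))
        return float(self.cross_background_sd)


def simulate_traits(
    pop: Population,
    archs,
    seed: int = 0,
    replicates: int = 1,
    trials=None,
) -> pd.DataFrame:
    """Simulate trait values for every individual (optionally replicated).

    The genetic value (QTL + rin + per-cross background) is drawn once per
    individual; each replicate adds an independent residual and is assigned to
    a trial whose batch factor multiplies metabolite abundances.
    """
    if isinstance(archs, TraitArchitecture):
        archs = [archs]
    if trials is None:
        trials = [f"T{r + 1}" for r in range(replicates)] if replicates > 1 else ["T1"]
    if len(trials) not in (1, replicates):
        raise ValueError("trials must have length 1 or `replicates`")
    rng = np.random.default_rng(seed)
    n = pop.n
    counts = pop.origin_counts() if pop.origins is not None else None
    rin_dos = pop.rin_dosage() if pop.origins is not None else None
    crosses = pop.cross

    base = pop.individuals.loc[
        pop.individuals.index.repeat(replicates)
    ].reset_index(drop=True)
    rep_trial = [trials[r % len(trials)] for r in range(replicates)]
    base["trial"] = np.tile(rep_trial, n)

    for arch in archs:
        genetic = np.full(n, float(arch.baseline))
        for mk, eff in arch.qtls.items():
            j = pop.markers.index_of(mk)  # raises for unknown marker
            if counts is None:
                raise ValueError("QTL effects need an origin-tracked population")
            for f_label, e in eff.items():
                fi = pop.founders.founder_index(f_label)
                genetic += e * counts[:, j, fi]
        if arch.rin_additive or arch.rin_dominance:
            if rin_dos is None:
                raise ValueError("rin effects need tracked rin genotypes")
            genetic += arch.rin_additive * (rin_dos - 1.0)
            genetic += arch.rin_dominance * (rin_dos == 1)
        bg_sd = np.array([arch.background_sd(c) for c in crosses])
        genetic += rng.normal(0.0, 1.0, size=n) * bg_sd

        values = np.repeat(genetic, replicates)
        values = values + rng.normal(0.0, 1.0, size=values.size) * arch.residual_sd
        if arch.metabolite:
            factors = np.array(
                [float(arch.trial_factors.get(t, 1.0)) for t in base["trial"]]
            )
            values = np.exp2(values) * factors
        base[arch.name] = values
    return base


# ---------------------------------------------------------------------------
# sensory attributes


@dataclass
class SensoryMap:
    """Sensory attributes as (noisy, optionally linked) weighted combinations
    of log2 compound abundances."""

    attributes: dict  # name -> dict(weights={compound: w}, noise_sd=..., link=None)

    def __post_init__(self):
        for name, spec in self.attributes.items():
            if not spec.get("weights"):
                raise ValueError(f"attribute {name}: needs at least one weight")


def simulate_sensory(traits: pd.DataFrame, smap: SensoryMap, seed: int = 0) -> pd.DataFrame:
    """Append sensory attribute columns driven by metabolite columns."""
    rng = np.random.default_rng(seed)
    out = traits.copy()
    for name, spec in smap.attributes.items():
        weights = spec["weights"]
        missing = [c for c in weights if c not in traits.columns]
        if missing:
            raise KeyError(f"attribute {name}: missing compounds {missing}")
        signal = np.zeros(len(traits))
        for compound, w in weights.items():
            vals = traits[compound].to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"compound {compound} has non-positive abundances")
            signal += w * np.log2(vals)
        link = spec.get("link")
        if link is not None:
            signal = np.asarray(link(signal), dtype=float)
        out[name] = signal + rng.normal(0.0, spec.get("noise_sd", 0.0), size=len(traits))
    return out


# ---------------------------------------------------------------------------
# germplasm panel


def simulate_germplasm(
    founders: FounderSet,
    founder_mixture,
    n_accessions: int,
    seed: int = 0,
    regions: list[QTLRegion] | None = None,
    novel_mutation_rate: float = 0.3,
    fruit_type_probs=(18 / 94, 55 / 94, 21 / 94),
) -> Population:
    """A germplasm panel: per region, each accession carries a founder
    haplotype (homozygously) with the planted probability, else a novel
    mutated haplotype guaranteed to mismatch every founder in that region.

    ``founder_mixture`` is a proportion in [0, 1], scalar or mapping region
    label -> proportion.  Outside the designated regions accessions carry
    mutated founder mosaics.  The planted per-region founder assignment is
    stored in ``extras['germplasm_truth']``.
    """
    mm = founders.marker_map
    if regions is None:
        regions = [
            QTLRegion(c, 1, founders.chrom_lengths_bp[c], label=str(c))
            for c in mm.chromosomes()
        ]
    def mixture_for(region):
        if isinstance(founder_mixture, dict):
            p = float(founder_mixture[region.label])
        else:
            p = float(founder_mixture)
        if not 0.0 <= p <= 1.0:
            raise ValueError("founder mixture proportion must be in [0, 1]")
        return p

    rng = np.random.default_rng(seed)
    m = founders.n_markers
    hap = np.empty((n_accessions, m), dtype=np.int8)
    truth_rows = []
    # genome-wide base: mutated copy of a random founder per accession
    base_founder = rng.integers(0, 4, size=n_accessions)
    hap[:] = founders.haplotypes[base_founder]
    flip = rng.random((n_accessions, m)) < novel_mutation_rate
    hap ^= flip.astype(np.int8)

    region_masks = [mm.region_mask(r) for r in regions]
    for region, mask in zip(regions, region_masks):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"region {region.label or region.chrom}: no markers")
        p = mixture_for(region)
        takes_founder = rng.random(n_accessions) < p
        which = rng.integers(0, 4, size=n_accessions)
        founder_region = founders.haplotypes[:, idx]
        for i in range(n_accessions):
            if takes_founder[i]:
                hap[i, idx] = founder_region[which[i]]
                truth_rows.append(
                    {
                        "accession": i,
                        "region": region.label or region.chrom,
                        "founder": founders.founder_ids[which[i]],
                    }
                )
            else:
                # re-mutate until the region haplotype matches no founder
                for _ in range(100):
                    if not (hap[i, idx] == founder_region).all(axis=1).any():
                        break
                    k = rng.integers(0, idx.size)
                    hap[i, idx[k]] ^= 1
                truth_rows.append(
                    {"accession": i, "region": region.label or region.chrom, "founder": ""}
                )

    dosage = (2 * hap).astype(np.int8)  # homozygous accessions
    samples = [f"acc{i + 1:04d}" for i in range(n_accessions)]
    types = rng.choice(["cherry", "round", "beef"], size=n_accessions, p=fruit_type_probs)
    individuals = pd.DataFrame(
        {
            "genotype_id": samples,
            "cross": "germplasm",
            "trial": "panel",
            "generation": "panel",
            "fruit_type": types,
        }
    )
    geno = GenotypeMatrix(dosage, samples, mm)
    extras = {"germplasm_truth": pd.DataFrame(truth_rows), "regions": regions}
    return Population(geno, individuals, {}, founders, origins=None, extras=extras)


# ---------------------------------------------------------------------------
# population persistence (VCF + TSV + npz origins)


def save_population(pop: Population, out_dir, meta: dict | None = None) -> list:
    """Write a population to a directory (VCF genotypes, TSV individuals,
    founder set and tracked origins); returns the file list."""
    import os

    from .io import write_genotypes, write_marker_map, write_trait_table

    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def p(name):
        paths.append(os.path.join(out_dir, name))
        return paths[-1]

    write_genotypes(pop.geno, p("genotypes.vcf"), meta=meta)
    write_marker_map(pop.markers, p("markers.tsv"), meta=meta)
    write_trait_table(pop.individuals, p("individuals.tsv"), meta=meta)
    info = {
        "cross_parents": pop.cross_parents,
        "founders": None,
    }
    if pop.founders is not None:
        f = pop.founders
        info["founders"] = {
            "founder_ids": list(f.founder_ids),
            "haplotypes": f.haplotypes.tolist(),
            "chrom_lengths_bp": f.chrom_lengths_bp,
            "rin_marker": f.rin_marker,
            "rin_carrier": f.rin_carrier,
        }
    with open(p("population.json"), "w") as fh:
        json.dump(info, fh, indent=1)
    if pop.origins is not None:
        # plain .npy: byte-deterministic (zip containers embed timestamps)
        np.save(p("origins.npy"), pop.origins)
    return paths


def load_population(out_dir) -> Population:
    import os

    from .io import read_genotypes, read_trait_table

    geno, markers = read_genotypes(os.path.join(out_dir, "genotypes.vcf"))
    individuals = read_trait_table(os.path.join(out_dir, "individuals.tsv"))
    with open(os.path.join(out_dir, "population.json")) as fh:
        info = json.load(fh)
    founders = None
    if info.get("founders"):
        fi = info["founders"]
        founders = FounderSet(
            founder_ids=tuple(fi["founder_ids"]),
            haplotypes=np.asarray(fi["haplotypes"], dtype=np.int8),
            marker_map=markers,
            chrom_lengths_bp=fi["chrom_lengths_bp"],
            rin_marker=fi["rin_marker"],
            rin_carrier=fi["rin_carrier"],
        )
    origins = None
    npy = os.path.join(out_dir, "origins.npy")
    if os.path.exists(npy):
        origins = np.load(npy)
    return Population(
        geno,
        individuals,
        {k: tuple(v) for k, v in info["cross_parents"].items()},
        founders,
        origins,
    )


# ---------------------------------------------------------------------------
# truth serialization


def write_truth_json(path, **objects) -> None:
    """Serialize planted-truth objects (origins, effects, plans) to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, QTLRegion):
            return {"chrom": o.chrom, "start_bp": o.start_bp, "end_bp": o.end_bp, "label": o.label}
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        if isinstance(o, MarkerMap):
            return o.to_frame().to_dict(orient="list")
        return str(o)

    with open(path, "w") as fh:
        json.dump(objects, fh, default=default, indent=1)
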