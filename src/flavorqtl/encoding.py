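"""Parental-origin marker encoding and the rin nuisance design.

For each marker the F2 scan needs an n x 4 matrix M whose entry (i, j) is the
number of alleles individual i inherited from founder j.  With homozygous
inbred founders this is uniquely determined from the offspring alt-allele
dosage wherever a cross's two parents carry different alleles; markers
monomorphic within a cross are uninformative for that cross and masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING
from .simulate import FounderSet, Population

logger = logging.getLogger(__name__)


@dataclass
class ParentalDosageMatrix:
    """Per-marker founder allele counts with informativeness masks.

    ``counts``: (n, n_markers, 4) int8 — alleles inherited from each founder
    (zero for founders not parental to the individual's cross, and at masked
    entries).  ``informative``: (n, n_markers) bool — True where the count row
    is determined (parents differ and the genotype call is present).
    """

    counts: np.ndarray
    informative: np.ndarray
    cross_informative: dict  # cross label -> (n_markers,) bool
    founder_ids: tuple
    individuals: pd.DataFrame
    markers: object  # MarkerMap
    provenance: str  # "inferred" | "tracked-truth"

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def subset_markers(self, mask) -> "ParentalDosageMatrix":
        """Restrict to a marker subset (boolean mask over the map)."""
        mask = np.asarray(mask, dtype=bool)
        from .io import MarkerMap

        sub = self.markers.to_frame().loc[mask]
        new_map = MarkerMap(sub["marker_id"], sub["chrom"], sub["pos_bp"])
        return ParentalDosageMatrix(
            self.counts[:, mask],
            self.informative[:, mask],
            {c: v[mask] for c, v in self.cross_informative.items()},
            self.founder_ids,
            self.individuals,
            new_map,
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long TSV-ready form: marker, individual, founder, count, informative."""
        n, m, _ = self.counts.shape
        ii, jj, ff = np.nonzero(self.counts)
        rows = pd.DataFrame(
            {
                "marker": self.markers.marker_ids[jj],
                "individual": self.individuals["genotype_id"].to_numpy()[ii],
                "founder": np.asarray(self.founder_ids, dtype=object)[ff],
                "count": self.counts[ii, jj, ff],
                "informative": self.informative[ii, jj],
            }
        )
        return rows


def encode_parental_dosage(pop: Population, founders: FounderSet | None = None) -> ParentalDosageMatrix:
    """Infer the four-column parental allele-count matrix from dosages.

    At markers where a cross's two (homozygous) parents differ, the counts
    follow from Mendelian arithmetic on the offspring dosage; monomorphic
    markers are masked uninformative for that cross.  Missing genotype calls
    are masked per entry.
    """
    founders = founders or pop.founders
    if founders is None:
        raise ValueError("founder set required")
    n, m = pop.n, pop.geno.n_markers
    counts = np.zeros((n, m, 4), dtype=np.int8)
    informative = np.zeros((n, m), dtype=bool)
    cross_informative = {}
    crosses = pop.cross
    for label, (pa, pb) in pop.cross_parents.items():
        rows = np.flatnonzero(crosses == label)
        if rows.size == 0:
            continue
        ia, ib = founders.founder_index(pa), founders.founder_index(pb)
        aA = founders.haplotypes[ia].astype(np.int16)
        aB = founders.haplotypes[ib].astype(np.int16)
        diff = aA != aB
        cross_informative[label] = diff.copy()
        g = pop.geno.dosage[rows].astype(np.int16)  # (k, m)
        present = g != MISSING
        ok = diff[None, :] & present
        # alleles from parent A: g where A carries alt, 2-g where A carries ref
        from_a = np.where(aA[None, :] == 1, g, 2 - g)
        from_a = np.where(ok, from_a, 0)
        from_b = np.where(ok, 2 - from_a, 0)
        counts[rows[:, None], np.arange(m)[None, :], ia] = from_a.astype(np.int8)
        counts[rows[:, None], np.arange(m)[None, :], ib] = from_b.astype(np.int8)
        informative[rows] = ok
        n_missing = int((diff[None, :] & ~present).sum())
        if n_missing:
            logger.info("cross %s: %d informative calls missing, masked", label, n_missing)
    unknown = set(crosses) - set(pop.cross_parents)
    if unknown:
        raise ValueError(f"individuals with unknown cross: {sorted(unknown)}")
    return ParentalDosageMatrix(
        counts,
        informative,
        cross_informative,
        founders.founder_ids,
        pop.individuals,
        pop.markers,
        provenance="inferred",
    )


def truth_parental_dosage(pop: Population) -> ParentalDosageMatrix:
    """The simulator-tracked origin counts as a ParentalDosageMatrix (oracle)."""
    if pop.origins is None:
        raise ValueError("population is not origin-tracked")
    counts = pop.origin_counts()
    informative = np.ones(counts.shape[:2], dtype=bool)
    return ParentalDosageMatrix(
        counts,
        informative,
        {},
        pop.founders.founder_ids,
        pop.individuals,
        pop.markers,
        provenance="tracked-truth",
    )


# ---------------------------------------------------------------------------
# rin design


@dataclass
class RinDesign:
    """Fixed nuisance design for the ripening mutant.

    One (intercept, additive, dominance) column triple per cross containing
    the carrier parent, zeroed outside those crosses.  Additive code is
    mutant dosage - 1 (-1/0/+1); dominance is the heterozygote indicator.
    """

    matrix: np.ndarray  # (n, k)
    names: list
    indicator: np.ndarray  # (n,) 1 for carrier crosses
    additive: np.ndarray  # (n,) in {-1, 0, +1}, 0 outside carrier crosses
    dominance: np.ndarray  # (n,) in {0, 1}, 0 outside carrier crosses

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def build_rin_design(
    pop: Population,
    rin_marker: str | None = None,
    carrier: str | None = None,
    mutant_dosage: np.ndarray | None = None,
) -> RinDesign:
    """Build the rin correction design from tracked or observed genotypes.

    The mutant-allele dosage is taken from (in order of precedence) the
    ``mutant_dosage`` argument, the simulator-tracked origins, or the
    genotype at ``rin_marker`` counted relative to the carrier's allele.
    """
    founders = pop.founders
    if founders is None and mutant_dosage is None:
        raise ValueError("founder set or explicit mutant dosage required")
    carrier = carrier or (founders.rin_carrier if founders else None)
    if founders is not None and carrier not in founders.founder_ids:
        raise ValueError(f"carrier {carrier!r} not in founder set")
    rin_marker = rin_marker or (founders.rin_marker if founders else None)

    n = pop.n
    if mutant_dosage is not None:
        dos = np.asarray(mutant_dosage, dtype=float)
    elif pop.origins is not None:
        j = pop.markers.index_of(rin_marker)
        ci = founders.founder_index(carrier)
        dos = (pop.origins[:, :, j] == ci).sum(axis=1).astype(float)
    else:
        j = pop.markers.index_of(rin_marker)
        allele = founders.haplotypes[founders.founder_index(carrier), j]
        g = pop.geno.dosage[:, j].astype(float)
        g[g == MISSING] = np.nan
        dos = g if allele == 1 else 2.0 - g

    crosses = pop.cross
    carrier_crosses = [
        c for c, (pa, pb) in pop.cross_parents.items() if carrier in (pa, pb)
    ]
    indicator = np.isin(crosses, carrier_crosses).astype(float)
    a = np.where(indicator == 1, dos - 1.0, 0.0)
    d = np.where(indicator == 1, (dos == 1).astype(float), 0.0)
    cols, names = [], []
    for c in carrier_crosses:
        in_c = (crosses == c).astype(float)
        cols.extend([in_c, in_c * a, in_c * d])
        names.extend([f"rin:{c}", f"rin_a:{c}", f"rin_d:{c}"])
    matrix = np.column_stack(cols) if cols else np.zeros((n, 0))
    return RinDesign(matrix, names, indicator, a, d)
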