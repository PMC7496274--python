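"""QTL-region haplotype construction and founder representation frequencies.

A region haplotype is the ordered concatenation of genotype symbols (alt
dosage 0/1/2, "." for missing) at the region's markers.  An accession counts
as carrying a founder haplotype in a region iff its string matches some
founder string at every non-missing position (missing positions are
wildcards); founders, being homozygous, have strings over {0, 2} only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, QTLRegion
from .simulate import FounderSet

logger = logging.getLogger(__name__)

_SYMBOL = {0: "0", 1: "1", 2: "2", MISSING: "."}


def filter_markers(G: GenotypeMatrix, max_missing_fraction: float = 0.23) -> GenotypeMatrix:
    """Drop markers whose missing-call rate exceeds the threshold."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = G.missing_fraction()
    keep = frac <= max_missing_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_markers: removed %d/%d markers above missing rate %.3g",
            removed, G.n_markers, max_missing_fraction,
        )
    if not keep.any():
        raise ValueError("all markers removed by the missing-rate filter")
    return G.subset_markers(keep)


@dataclass
class HaplotypeTable:
    """Per-region haplotype strings for accessions and founder references."""

    regions: list  # QTLRegion
    accession_ids: list
    haplotypes: dict  # region label -> list[str] aligned to accession_ids
    founder_haplotypes: dict  # region label -> {founder id: str}
    callable_mask: dict  # region label -> (n,) bool
    min_call: float

    def region_labels(self) -> list:
        return [r.label or f"{r.chrom}:{r.start_bp}-{r.end_bp}" for r in self.regions]


def call_region_haplotypes(
    G: GenotypeMatrix,
    regions: list[QTLRegion],
    founders: FounderSet,
    min_call: float = 0.8,
) -> HaplotypeTable:
    """Build haplotype strings over each region's markers.

    Accessions whose fraction of non-missing region calls is below
    ``min_call`` are flagged uncallable and excluded from frequency
    denominators.
    """
    mm = G.markers
    haplotypes, founder_haps, callable_mask = {}, {}, {}
    for region in regions:
        label = region.label or f"{region.chrom}:{region.start_bp}-{region.end_bp}"
        mask = mm.region_mask(region)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"region {label}: contains no retained markers")
        sub = G.dosage[:, idx]
        strings = ["".join(_SYMBOL[int(x)] for x in row) for row in sub]
        haplotypes[label] = strings
        callable_mask[label] = (sub != MISSING).mean(axis=1) >= min_call
        # founder references over the *retained* region markers, matched by id
        fidx = [founders.marker_map.index_of(mid) for mid in mm.marker_ids[idx]]
        fh = {}
        for fi, fid in enumerate(founders.founder_ids):
            fh[fid] = "".join(
                _SYMBOL[int(2 * founders.haplotypes[fi, j])] for j in fidx
            )
        founder_haps[label] = fh
    return HaplotypeTable(
        regions=list(regions),
        accession_ids=list(G.samples),
        haplotypes=haplotypes,
        founder_haplotypes=founder_haps,
        callable_mask=callable_mask,
        min_call=min_call,
    )


def _matches(acc: str, ref: str) -> bool:
    """Exact genotype-string match with missing positions as wildcards."""
    return all(a == "." or a == b for a, b in zip(acc, ref))


def representation_frequencies(ht: HaplotypeTable) -> tuple[pd.DataFrame, float]:
    """Founder-haplotype representation per region (%) and the median.

    Returns a per-region frame (total representation and per-founder
    breakdown over callable accessions) and the median total representation
    across regions; regions with an empty denominator are reported as NA and
    excluded from the median.
    """
    rows = []
    totals = []
    for region, label in zip(ht.regions, ht.region_labels()):
        strings = ht.haplotypes[label]
        callable_ = ht.callable_mask[label]
        founder_haps = ht.founder_haplotypes[label]
        denom = int(np.sum(callable_))
        row = {"region": label, "n_callable": denom}
        if denom == 0:
            row["representation_pct"] = float("nan")
            for fid in founder_haps:
                row[f"pct_{fid}"] = float("nan")
            rows.append(row)
            continue
        represented = 0
        per_founder = {fid: 0 for fid in founder_haps}
        # report founder haplotype collisions (identical strings) once
        seen = {}
        for fid, ref in founder_haps.items():
            if ref in seen:
                logger.info("region %s: founders %s and %s share a haplotype",
                            label, seen[ref], fid)
            seen[ref] = fid
        for ok, acc in zip(callable_, strings):
            if not ok:
                continue
            hit = False
            for fid, ref in founder_haps.items():
                if _matches(acc, ref):
                    per_founder[fid] += 1
                    hit = True
            if hit:
                represented += 1
        pct = 100.0 * represented / denom
        row["representation_pct"] = pct
        for fid, cnt in per_founder.items():
            row[f"pct_{fid}"] = 100.0 * cnt / denom
        totals.append(pct)
        rows.append(row)
    median = float(np.median(totals)) if totals else float("nan")
    return pd.DataFrame(rows), median
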