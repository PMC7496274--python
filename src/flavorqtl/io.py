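"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every position is a 1-based inclusive base-pair coordinate.
BED is the only half-open, 0-based surface: a BED line ``chrom  s  e`` maps to
the internal interval ``[s + 1, e]`` and back.  Fine-mapping intervals whose
endpoints are printed in Mbp are handled by :meth:`QTLRegion.from_mbp`, which
treats the endpoints as exact continuous coordinates (54.52 Mbp = 54,520,000 bp).

Genotypes are stored as alt-allele dosages (0, 1, 2) with ``-1`` for missing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for missing genotype calls


# ---------------------------------------------------------------------------
# marker map


class MarkerMap:
    """Physical marker map: marker id, chromosome and 1-based bp position.

    Markers are kept sorted by (chromosome, position); ids must be unique and
    positions strictly increasing within a chromosome.
    """

    def __init__(self, marker_id, chrom, pos_bp):
        df = pd.DataFrame(
            {
                "marker_id": np.asarray(marker_id, dtype=object),
                "chrom": np.asarray(chrom, dtype=object),
                "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            }
        )
        if len(df) == 0:
            raise ValueError("marker map must contain at least one marker")
        if df["marker_id"].duplicated().any():
            dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        if (df["pos_bp"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")
        # stable sort preserves input chromosome order
        order = np.lexsort((df["pos_bp"].to_numpy(),
                            pd.factorize(df["chrom"])[0]))
        df = df.iloc[order].reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("duplicate positions within a chromosome")
        self._df = df
        self._index = {m: i for i, m in enumerate(df["marker_id"])}

    # -- basic accessors ----------------------------------------------------
    def __len__(self):
        return len(self._df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self._df["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self._df["pos_bp"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id}") from None

    def __contains__(self, marker_id):
        return marker_id in self._index

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self._df["chrom"]))

    def region_mask(self, region: "QTLRegion") -> np.ndarray:
        """Boolean mask of markers falling inside ``region`` (inclusive)."""
        return (
            (self.chrom == region.chrom)
            & (self.pos_bp >= region.start_bp)
            & (self.pos_bp <= region.end_bp)
        )

    def __eq__(self, other):
        return isinstance(other, MarkerMap) and self._df.equals(other._df)


# ---------------------------------------------------------------------------
# genotype matrix


class GenotypeMatrix:
    """Individuals x markers matrix of alt-allele dosages (0/1/2, -1 missing)."""

    def __init__(self, dosage: np.ndarray, samples, markers: MarkerMap):
        dosage = np.asarray(dosage, dtype=np.int8)
        samples = list(samples)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if dosage.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(markers)} markers"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or -1 (missing)")
        self.dosage = dosage
        self.samples = samples
        self.markers = markers
        self._sample_index = {s: i for i, s in enumerate(samples)}

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_markers(self):
        return len(self.markers)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls (used by filter_markers)."""
        return (self.dosage == MISSING).mean(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        sub = self.markers.to_frame().loc[mask]
        new_map = MarkerMap(sub["marker_id"], sub["chrom"], sub["pos_bp"])
        return GenotypeMatrix(self.dosage[:, mask], self.samples, new_map)

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeMatrix)
            and self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.dosage, other.dosage)
        )


# ---------------------------------------------------------------------------
# QTL regions


@dataclass(frozen=True)
class QTLRegion:
    """Physical interval, 1-based inclusive endpoints."""

    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"region {self.label or self.chrom}: end {self.end_bp} < start {self.start_bp}"
            )

    @classmethod
    def from_mbp(cls, chrom: str, start_mbp: float, end_mbp: float, label: str = "") -> "QTLRegion":
        """Region from Mbp endpoints treated as exact continuous coordinates."""
        return cls(chrom, int(round(start_mbp * 1e6)), int(round(end_mbp * 1e6)), label)

    @property
    def width_bp(self) -> int:
        """Inclusive base count of the interval."""
        return self.end_bp - self.start_bp + 1

    def overlaps(self, other: "QTLRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def read_regions(bed_path) -> list[QTLRegion]:
    """Read a BED3+ file into 1-based inclusive :class:`QTLRegion` objects."""
    regions = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: BED needs >= 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if e < s:
                raise ValueError(f"{bed_path}:{lineno}: end {e} < start {s}")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(QTLRegion(chrom, s + 1, e, label))
    return regions


def write_regions(regions: list[QTLRegion], bed_path, header: bool = True) -> None:
    with open(bed_path, "w") as fh:
        if header:
            fh.write(f"#flavorqtl={__version__}\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.label}\n")


# ---------------------------------------------------------------------------
# trait tables

#: columns every trait table carries; remaining columns are numeric traits
TRAIT_META_COLUMNS = ("genotype_id", "cross", "trial", "generation", "fruit_type")


def trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in TRAIT_META_COLUMNS]


def read_trait_table(tsv_path) -> pd.DataFrame:
    """Read a trait TSV (tab-separated, '.'/'NA'/'' = missing)."""
    df = pd.read_csv(
        tsv_path, sep="\t", comment="#", na_values=["NA", "."], keep_default_na=True
    )
    if "genotype_id" not in df.columns:
        raise ValueError("trait table must have a 'genotype_id' column")
    if df["genotype_id"].isna().any() or (df["genotype_id"].astype(str) == "").any():
        raise ValueError("genotype_id must be non-empty")
    key_cols = [c for c in ("genotype_id", "trial") if c in df.columns]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        dups = df.loc[dup, key_cols].drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"duplicate genotype_id x trial rows: {dups[:10]}")
    for col in trait_columns(df):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_trait_table(table: pd.DataFrame, tsv_path, meta: dict | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(_meta_comment(meta))
        table.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_marker_map(tsv_path) -> MarkerMap:
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return MarkerMap(df["marker_id"], df["chrom"], df["pos_bp"])


def write_marker_map(markers: MarkerMap, tsv_path, meta: dict | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(_meta_comment(meta))
        markers.to_frame().to_csv(fh, sep="\t", index=False)


def _meta_comment(meta: dict | None) -> str:
    fields = {"tool": f"flavorqtl {__version__}"}
    if meta:
        fields.update(meta)
    inner = " ".join(f"{k}={v}" for k, v in fields.items())
    return f"# {inner}\n"


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (for output provenance)."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# VCF


def write_genotypes(
    geno: GenotypeMatrix,
    vcf_path,
    phased: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields.

    ``phased``: optional (n_samples, n_markers, 2) array of per-allele codes;
    when given, genotypes are emitted phased ("|") using those alleles,
    otherwise unphased dosage genotypes ("0/1" for dosage 1).
    """
    m = geno.markers
    fields = {"tool": f"flavorqtl {__version__}"}
    if meta:
        fields.update(meta)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k, v in fields.items():
            fh.write(f"##{k}={v}\n")
        for c in m.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        gt_unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(geno.n_markers):
            cols = [
                str(m.chrom[j]),
                str(m.pos_bp[j]),
                str(m.marker_ids[j]),
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if phased is not None:
                for i in range(geno.n_samples):
                    if geno.dosage[i, j] == MISSING:
                        cols.append(".|.")
                    else:
                        a, b = phased[i, j]
                        cols.append(f"{a}|{b}")
            else:
                cols.extend(gt_unphased[int(d)] for d in geno.dosage[:, j])
            fh.write("\t".join(cols) + "\n")


def read_genotypes(vcf_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a VCF v4.2 into a dosage matrix and marker map.

    Multiallelic records are skipped with a logged warning; "./." becomes
    missing; heterozygote phase/order is collapsed to dosage.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error path
        raise ValueError(f"cannot open VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, mids, chroms, poss = [], [], [], []
    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            if len(variant.ALT) != 1:
                logger.warning(
                    "skipping multiallelic record %s at %s:%d",
                    variant.ID, variant.CHROM, variant.POS,
                )
                continue
            dos = np.full(len(samples), MISSING, dtype=np.int8)
            for i, g in enumerate(variant.genotypes):
                alleles = [a for a in g[:-1] if a >= 0]
                if len(alleles) == 2:
                    dos[i] = sum(1 for a in alleles if a == 1)
            rows.append(dos)
            mids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
            chroms.append(variant.CHROM)
            poss.append(variant.POS)
    except Exception as exc:
        raise ValueError(
            f"malformed VCF {vcf_path} near record {record_no + 1}: {exc}"
        ) from exc
    if not rows:
        raise ValueError(f"no biallelic records in {vcf_path}")
    # sort records the same way MarkerMap does so columns stay aligned
    chrom_codes = pd.factorize(np.asarray(chroms, dtype=object))[0]
    order = np.lexsort((np.asarray(poss), chrom_codes))
    markers = MarkerMap(
        [mids[i] for i in order], [chroms[i] for i in order], [poss[i] for i in order]
    )
    dosage = np.stack([rows[i] for i in order], axis=1)
    return GenotypeMatrix(dosage, samples, markers), markers
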