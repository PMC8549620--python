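"""Core in-memory containers shared by all pipeline stages.

The pipeline operates on four kinds of data: phased haplotypes, per-SNP
local-ancestry dosages (expected donor-haplotype copy number in [0, 2]),
a recombination map, and gene annotations.  All coordinates are 1-based
inclusive internally; BED I/O converts at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # missing allele code in haplotype matrices


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome labels: numeric body first, then text."""
    m = re.match(r"(?:chr)?(\d+)$", str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, str(chrom))


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with per-SNP metadata.

    Attributes
    ----------
    chrom, pos_bp : arrays of length n_snps
        Chromosome label and 1-based physical position per SNP; positions are
        strictly increasing within each chromosome.
    alleles : (n_snps, 2) array of str
        Allele coding per SNP.  Column 0 is the 0-coded allele (reference or
        ancestral), column 1 the 1-coded allele (alternate or derived).
    hap_matrix : (n_haplotypes, n_snps) int8 array
        0/1 allele states; ``MISSING`` (-1) marks missing calls.  Haplotypes
        2i and 2i+1 belong to individual i.
    sample_ids : list of str
        One identifier per individual (two haplotypes each).
    phased : bool
        True only if every genotype carries phase information.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray
    hap_matrix: np.ndarray
    sample_ids: list
    phased: bool = True
    snp_ids: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.hap_matrix = np.asarray(self.hap_matrix, dtype=np.int8)
        if self.snp_ids is not None:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)

    @property
    def n_snps(self) -> int:
        return self.hap_matrix.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.hap_matrix.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2

    def validate(self) -> None:
        if self.n_haplotypes % 2 != 0:
            raise ValueError("haplotype count must be even (two per individual)")
        if self.n_haplotypes != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must equal 2 x individuals")
        vals = np.unique(self.hap_matrix)
        if not np.isin(vals, [MISSING, 0, 1]).all():
            raise ValueError("hap_matrix entries must be in {0, 1, missing}")
        for c in set(self.chrom.tolist()):
            p = self.pos_bp[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def chromosomes(self) -> list:
        return sorted(set(self.chrom.tolist()), key=chrom_sort_key)

    def take_snps(self, index) -> "HaplotypePanel":
        """Subset SNP-wise, preserving order."""
        index = np.asarray(index)
        return HaplotypePanel(
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            alleles=np.asarray(self.alleles)[index],
            hap_matrix=self.hap_matrix[:, index],
            sample_ids=list(self.sample_ids),
            phased=self.phased,
            snp_ids=None if self.snp_ids is None else self.snp_ids[index],
        )

    def genotype_dosage(self) -> np.ndarray:
        """Per-individual alternate-allele count (n_individuals, n_snps).

        Genotypes with a missing haplotype are NaN.
        """
        h = self.hap_matrix.astype(float)
        h[self.hap_matrix == MISSING] = np.nan
        return h[0::2] + h[1::2]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the 1-coded allele per SNP, missing calls excluded."""
        obs = self.hap_matrix != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (self.hap_matrix == 1).sum(axis=0) / np.maximum(n, 1), np.nan)


@dataclass
class AncestryDosageMatrix:
    """Per-individual, per-SNP donor-ancestry dosage in [0, 2] (ELAI-style)."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    dosage: np.ndarray  # (n_individuals, n_snps) float
    individual_ids: list
    donor_label: str = "donor"
    snp_ids: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def validate(self, tol: float = 1e-6) -> None:
        if self.dosage.shape != (len(self.individual_ids), len(self.pos_bp)):
            raise ValueError("dosage shape inconsistent with ids / SNP info")
        if (self.dosage < -tol).any() or (self.dosage > 2 + tol).any():
            raise ValueError("dosage outside [0, 2] beyond tolerance")

    def individual_admixture(self) -> np.ndarray:
        """Genome-wide donor admixture proportion per individual (dosage/2)."""
        return self.dosage.mean(axis=1) / 2.0


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map.

    ``rate_cM_per_Mb[i]`` applies on the interval from ``pos_bp[i]`` to the
    next map point of the same chromosome; ``cumulative_cM`` is the genetic
    position at each map point (0 at the first point of each chromosome).
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    rate_cM_per_Mb: np.ndarray
    cumulative_cM: np.ndarray = field(default=None)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.rate_cM_per_Mb = np.asarray(self.rate_cM_per_Mb, dtype=float)
        if (self.rate_cM_per_Mb < 0).any():
            raise ValueError("recombination rates must be >= 0")
        if self.cumulative_cM is None:
            self.cumulative_cM = self._compute_cumulative()
        else:
            self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=float)

    def _compute_cumulative(self) -> np.ndarray:
        cum = np.zeros(len(self.pos_bp))
        for c in self.chromosomes():
            idx = np.flatnonzero(self.chrom == c)
            p = self.pos_bp[idx]
            r = self.rate_cM_per_Mb[idx]
            seg = r[:-1] * np.diff(p) / 1e6
            cum[idx[1:]] = np.cumsum(seg)
        return cum

    def chromosomes(self) -> list:
        return sorted(set(self.chrom.tolist()), key=chrom_sort_key)

    def _chrom_slice(self, chrom):
        idx = np.flatnonzero(self.chrom == chrom)
        if len(idx) == 0:
            raise KeyError(f"chromosome {chrom!r} absent from recombination map")
        return idx

    def rate_at(self, chrom, positions) -> tuple[np.ndarray, np.ndarray]:
        """Enclosing-interval rate for each position; second array flags
        positions outside the map range (assigned the boundary interval)."""
        idx = self._chrom_slice(chrom)
        p = self.pos_bp[idx]
        r = self.rate_cM_per_Mb[idx]
        positions = np.asarray(positions, dtype=np.int64)
        j = np.searchsorted(p, positions, side="right") - 1
        outside = (j < 0) | (positions > p[-1])
        j = np.clip(j, 0, len(p) - 1)
        # last map point has no forward interval: use the preceding interval's rate
        if len(p) > 1:
            j = np.minimum(j, len(p) - 2)
        return r[j], outside

    def genetic_position(self, chrom, positions) -> np.ndarray:
        """Genetic position (cM) by linear interpolation under constant
        per-interval rates; positions beyond the map extrapolate at the
        boundary interval's rate."""
        idx = self._chrom_slice(chrom)
        p = self.pos_bp[idx]
        cum = self.cumulative_cM[idx]
        rate, _ = self.rate_at(chrom, positions)
        positions = np.asarray(positions, dtype=np.int64)
        j = np.clip(np.searchsorted(p, positions, side="right") - 1, 0, len(p) - 1)
        if len(p) > 1:
            j = np.minimum(j, len(p) - 2)
        return cum[j] + rate * (positions - p[j]) / 1e6


_BIOTYPES = {"protein_coding", "lncRNA", "other"}


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based inclusive) with a coarse biotype."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start_bp > end_bp")
        if self.biotype not in _BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: biotype {self.biotype!r} not in {_BIOTYPES}")

    def overlaps(self, chrom, start_bp, end_bp) -> bool:
        return self.chrom == chrom and self.start_bp <= end_bp and self.end_bp >= start_bp

    def distance_to(self, chrom, pos) -> float:
        """bp distance from a SNP to the nearest gene boundary; 0 inside."""
        if self.chrom != chrom:
            return np.inf
        if self.start_bp <= pos <= self.end_bp:
            return 0
        return self.start_bp - pos if pos < self.start_bp else pos - self.end_bp


@dataclass
class AncestryBlock:
    """A maximal run of consecutive SNPs with outlying hybrid ancestry."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    mean_ancestry: float
    block_type: str = "overrepresented"  # or "desert"
    scope: str = "per_chromosome"  # or "global"
    start_idx: int | None = None  # global SNP indices into the source profile
    end_idx: int | None = None  # inclusive

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
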