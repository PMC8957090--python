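"""Core in-memory containers for variants, genotypes and haplotypes.

Coordinate conventions
----------------------
``VariantTable.pos`` keeps the VCF's 1-based physical coordinates.  Every
*derived* interval in the package (analysis windows, ROH segments, selected
regions, BED output) is 0-based half-open, matching BED.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1``
(:data:`MISSING`) for missing calls.  Haplotypes are binary with 1 meaning
"derived under the current ancestral polarity": when ``ancestral_is_ref`` is
true for a variant, the alt allele is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

MISSING: int = -1

_NUCS = frozenset("ACGT")


@dataclass
class VariantTable:
    """Biallelic SNP records, sorted by (chrom, pos).

    Parameters
    ----------
    chrom : array of str
        Chromosome identifier per variant; variants of one chromosome are
        contiguous.
    pos : array of int
        1-based physical coordinate (bp), strictly increasing within each
        chromosome.
    ref, alt : array of single characters
        Reference/alternate alleles; exactly two distinct nucleotides.
    ancestral_is_ref : array of bool
        Polarity flag: True when the reference allele is ancestral.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral_is_ref: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)
        n = len(self.pos)
        for arr, name in ((self.chrom, "chrom"), (self.ref, "ref"),
                          (self.alt, "alt"), (self.ancestral_is_ref, "ancestral_is_ref")):
            if len(arr) != n:
                raise DataError(f"VariantTable field {name!r} has length {len(arr)}, expected {n}")
        if n and np.any(self.ref == self.alt):
            raise DataError("VariantTable: ref == alt at some variant")
        for c in self.chroms():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"VariantTable: positions not strictly increasing on {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def take(self, idx) -> "VariantTable":
        return VariantTable(self.chrom[idx], self.pos[idx], self.ref[idx],
                            self.alt[idx], self.ancestral_is_ref[idx])


@dataclass
class GenotypeMatrix:
    """samples x variants matrix of alt-allele dosages with missingness."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise DataError("GenotypeMatrix.values must be 2-D (samples x variants)")
        if self.values.shape[0] != len(self.sample_ids):
            raise DataError("GenotypeMatrix: sample_ids length does not match rows")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("GenotypeMatrix: entries must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing genotypes.

        Variants with no non-missing calls get frequency nan.
        """
        ok = self.values != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        alt = np.where(ok, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def take_variants(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, idx], list(self.sample_ids))


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: (2 x samples) rows x variants columns.

    Rows ``2i`` and ``2i+1`` are the two haplotypes of sample ``i``.  Allele 1
    is derived under the current polarity.
    """

    alleles: np.ndarray
    positions: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise DataError("HaplotypePanel.alleles must be 2-D")
        if self.alleles.shape[0] % 2:
            raise DataError("HaplotypePanel needs two rows per sample")
        if self.alleles.shape[1] != len(self.positions):
            raise DataError("HaplotypePanel: positions length mismatch")
        if self.alleles.size and self.alleles.max() > 1:
            raise DataError("HaplotypePanel: alleles must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def to_genotypes(self, sample_ids: list[str] | None = None) -> GenotypeMatrix:
        g = self.alleles[0::2].astype(np.int8) + self.alleles[1::2].astype(np.int8)
        ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(self.n_samples)]
        return GenotypeMatrix(g, ids)

    def take_variants(self, idx) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles[:, idx], self.positions[idx], self.phased)


@dataclass
class ChromSizes:
    """Chromosome lengths (bp) with an autosome flag per chromosome."""

    sizes: dict[str, int]
    autosome: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sizes.values()):
            raise DataError("ChromSizes: lengths must be positive")
        for c in self.sizes:
            # default: sex/organellar names are not autosomes
            self.autosome.setdefault(
                c, c.removeprefix("chr").upper() not in {"X", "Y", "MT", "M", "W", "Z"})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    @property
    def l_auto(self) -> int:
        """Total autosome length — the F_ROH denominator."""
        return sum(v for c, v in self.sizes.items() if self.autosome[c])
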