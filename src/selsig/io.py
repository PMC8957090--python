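"""VCF and tabular I/O plus the standard variant filters.

Reading uses cyvcf2; writing emits minimal standards-conformant VCF 4.2 text.
Only biallelic SNPs are loaded; multi-allelic records and indels are dropped
(the analysis operates on a `bcftools view -m 2 -M 2`-style panel).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import MISSING, ChromSizes, GenotypeMatrix, HaplotypePanel, VariantTable
from .errors import DataError, VcfParseError

log = logging.getLogger(__name__)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def read_vcf(path, phased_required: bool = False):
    """Load biallelic SNPs from a VCF.

    Parameters
    ----------
    path : str or Path
        VCF file (plain or bgzipped) with a GT FORMAT field.
    phased_required : bool
        If True, raise unless every genotype is phased.

    Returns
    -------
    (VariantTable, GenotypeMatrix, HaplotypePanel | None)
        The haplotype panel is returned only when every genotype is phased
        and no call is missing; otherwise ``None``.
    """
    import cyvcf2

    path = str(path)
    try:
        vcf = cyvcf2.VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    geno_rows, hap_rows = [], []
    all_phased = True
    any_missing = False
    i = -1
    try:
        for i, rec in enumerate(vcf):
            if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
                continue  # multi-allelic or indel
            if rec.REF == rec.ALT[0]:
                continue
            gts = rec.genotypes  # [[a1, a2, phased], ...]
            row = np.empty(len(samples), dtype=np.int8)
            hap = np.empty(2 * len(samples), dtype=np.int8)
            for s, g in enumerate(gts):
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    row[s] = MISSING
                    hap[2 * s] = hap[2 * s + 1] = -1
                    any_missing = True
                else:
                    row[s] = a1 + a2
                    hap[2 * s], hap[2 * s + 1] = a1, a2
                if not g[2]:
                    all_phased = False
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(rec.ALT[0])
            geno_rows.append(row)
            hap_rows.append(hap)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"parse error in {path!r} near record {i + 2}: {exc}") from exc

    if phased_required and not all_phased:
        raise DataError(f"{path!r}: phased genotypes required but unphased GT present")

    n = len(poss)
    vt = VariantTable(np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
                      np.array(refs, dtype=object), np.array(alts, dtype=object),
                      np.ones(n, dtype=bool))
    gm = GenotypeMatrix(
        np.array(geno_rows, dtype=np.int8).T.reshape(len(samples), n), samples)
    hp = None
    if n and all_phased and not any_missing:
        hp = HaplotypePanel(np.array(hap_rows, dtype=np.uint8).T, vt.pos, phased=True)
    return vt, gm, hp


def write_vcf(vt: VariantTable, path, gm: GenotypeMatrix | None = None,
              hp: HaplotypePanel | None = None, sizes: ChromSizes | None = None) -> None:
    """Write a VariantTable plus genotypes or phased haplotypes as VCF 4.2."""
    if gm is None and hp is None:
        raise DataError("write_vcf needs a GenotypeMatrix or a HaplotypePanel")
    if gm is not None and gm.n_variants != vt.n_variants:
        raise DataError("write_vcf: genotype matrix width does not match variants")
    if hp is not None and hp.n_variants != vt.n_variants:
        raise DataError("write_vcf: haplotype panel width does not match variants")

    if hp is not None:
        n_samples = hp.n_samples
        ids = gm.sample_ids if gm is not None else [f"S{i}" for i in range(n_samples)]
    else:
        n_samples = gm.n_samples
        ids = gm.sample_ids

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=selsig\n")
        if sizes is not None:
            for c, ln in sizes.sizes.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in vt.chroms():
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j in range(vt.n_variants):
            fields = [str(vt.chrom[j]), str(vt.pos[j]), ".", str(vt.ref[j]),
                      str(vt.alt[j]), ".", "PASS", ".", "GT"]
            if hp is not None:
                col = hp.alleles[:, j]
                fields += [f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_samples)]
            else:
                gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                fields += [gt_map[int(g)] for g in gm.values[:, j]]
            fh.write("\t".join(fields) + "\n")


def filter_variants(vt: VariantTable, gm: GenotypeMatrix,
                    maf_min: float = 0.01, miss_max: float = 0.2) -> np.ndarray:
    """Keep-mask: MAF >= maf_min and missing fraction <= miss_max.

    MAF is computed from non-missing allele counts only (PLINK behaviour).
    Variants with every call missing are removed.
    """
    if gm.n_variants != vt.n_variants:
        raise DataError("filter_variants: dimensions inconsistent")
    miss = gm.missing_mask().mean(axis=0) if gm.n_samples else np.zeros(vt.n_variants)
    p = gm.alt_freq()
    maf = np.fmin(p, 1.0 - p)  # fmin: nan (all-missing) stays nan
    keep = (np.nan_to_num(maf, nan=-1.0) >= maf_min) & (miss <= miss_max)
    if vt.n_variants and not keep.any():
        warnings.warn("filter_variants removed every variant", stacklevel=2)
    return keep


def tstv_ratio(vt: VariantTable) -> float:
    """Transition/transversion ratio; nan when there is no transversion."""
    pairs = [frozenset((r, a)) for r, a in zip(vt.ref, vt.alt)]
    ts = sum(p in _TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        log.warning("tstv_ratio undefined: zero transversions")
        return float("nan")
    return ts / tv


def read_chrom_sizes(path) -> ChromSizes:
    """Read a 2- or 3-column TSV: chrom, length[, autosome flag]."""
    sizes: dict[str, int] = {}
    auto: dict[str, bool] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: line {ln}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
            if len(parts) >= 3:
                auto[parts[0]] = parts[2].strip().lower() in {"1", "true", "yes", "autosome"}
    if not sizes:
        raise DataError(f"{path}: empty chromosome-sizes file")
    return ChromSizes(sizes, auto)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for c, ln in sizes.sizes.items():
            fh.write(f"{c}\t{ln}\t{int(sizes.autosome[c])}\n")


def read_groups(path) -> dict[str, str]:
    """Read sample group labels from a TSV: sample<TAB>group."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: line {ln}: expected sample<TAB>group")
            groups[parts[0]] = parts[1]
    return groups


def subset(vt: VariantTable, gm: GenotypeMatrix | None = None,
           hp: HaplotypePanel | None = None, mask: np.ndarray | None = None):
    """Apply a variant keep-mask consistently across the three containers."""
    if mask is None:
        raise DataError("subset: mask required")
    out = [vt.take(mask)]
    out.append(gm.take_variants(mask) if gm is not None else None)
    out.append(hp.take_variants(mask) if hp is not None else None)
    return tuple(out)
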