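"""EHH decay, integrated haplotype homozygosity and the iHS scan.

For a core SNP and one of its alleles, EHH at a marker distance x is the
probability that two randomly drawn carrier haplotypes are identical over
the whole stretch from the core out to x:

    EHH(x) = sum_g C(k_g, 2) / C(n_c, 2)

where the carriers partition into extended-haplotype groups of sizes k_g.
iHH integrates the decay curve (trapezoid over physical distance) outward on
both sides until EHH first drops below ``cutoff``, truncating the final
segment at the linear-interpolated crossing.  The unstandardized score is
uihs = ln(iHH_ancestral / iHH_derived); standardization subtracts the mean
and divides by the SD within derived-allele-frequency bins, and cores with
|z| >= 3 are called selected.

Cores whose EHH is still above the cutoff at a chromosome edge or at an
inter-marker gap larger than ``max_gap_bp`` have an under-estimated integral
("truncated") and are excluded by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .containers import HaplotypePanel, VariantTable
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class EhhCurve:
    """EHH decay of one core allele in one direction.

    ``offsets`` are absolute bp distances from the core, starting at 0 where
    EHH = 1 by definition.  ``truncated`` is True when the curve hit a
    chromosome edge or an oversized gap before falling below the cutoff.
    """

    core: int
    allele: str  # "derived" | "ancestral"
    direction: str  # "upstream" | "downstream"
    offsets: np.ndarray
    ehh: np.ndarray
    truncated: bool


@numba.njit(cache=True)
def _walk(H, positions, core, carriers, step, cutoff, max_gap_bp,
          out_off, out_ehh):  # pragma: no cover - exercised via _ehh_decay
    n_c = carriers.size
    pairs_total = n_c * (n_c - 1) / 2.0
    rows = carriers.copy()
    ids = np.zeros(n_c, dtype=np.int64)
    m = n_c          # active (non-singleton-group) haplotypes
    g = 1            # number of groups among active haplotypes
    out_off[0] = 0
    out_ehh[0] = 1.0
    k = 1
    j = core
    last_pos = positions[core]
    n_var = H.shape[1]
    truncated = True  # until EHH drops below cutoff
    while True:
        j += step
        if j < 0 or j >= n_var:
            break  # chromosome edge
        if abs(positions[j] - last_pos) > max_gap_bp:
            break
        last_pos = positions[j]
        counts = np.zeros(2 * g, dtype=np.int64)
        for i in range(m):
            counts[ids[i] * 2 + H[rows[i], j]] += 1
        pairs = 0
        for c in counts:
            pairs += c * (c - 1)
        ehh = pairs / 2.0 / pairs_total
        out_off[k] = abs(positions[j] - positions[core])
        out_ehh[k] = ehh
        k += 1
        if ehh < cutoff:
            truncated = False
            break
        # compact: drop singleton groups (they can never pair up again)
        remap = np.full(2 * g, -1, dtype=np.int64)
        g_new = 0
        m_new = 0
        for i in range(m):
            key = ids[i] * 2 + H[rows[i], j]
            if counts[key] > 1:
                if remap[key] < 0:
                    remap[key] = g_new
                    g_new += 1
                rows[m_new] = rows[i]
                ids[m_new] = remap[key]
                m_new += 1
        m, g = m_new, g_new
    return k, truncated


def _ehh_decay(H: np.ndarray, positions: np.ndarray, core: int, carriers: np.ndarray,
               step: int, cutoff: float, max_gap_bp: int):
    """Walk outward from ``core`` (step +1/-1) computing EHH per marker.

    Returns (offsets, ehh, truncated).  EHH at each marker is
    sum_g C(k_g,2) / C(n_c,2) over extended-haplotype groups of the core
    carriers; the walk stops below ``cutoff``, at the chromosome edge, or at
    an inter-marker gap above ``max_gap_bp``.
    """
    n_var = H.shape[1]
    out_off = np.empty(n_var + 1, dtype=np.int64)
    out_ehh = np.empty(n_var + 1, dtype=np.float64)
    k, truncated = _walk(np.ascontiguousarray(H), np.ascontiguousarray(positions),
                         core, np.ascontiguousarray(carriers, dtype=np.int64),
                         step, cutoff, max_gap_bp, out_off, out_ehh)
    return out_off[:k].copy(), out_ehh[:k].copy(), truncated


def ehh(hp: HaplotypePanel, core: int, allele: str = "derived",
        direction: str = "downstream", cutoff: float = 0.05,
        max_gap_bp: int = 200_000) -> EhhCurve:
    """EHH decay curve for one allele of a core SNP in one direction."""
    if not hp.phased:
        raise DataError("ehh requires a phased panel")
    if allele not in ("derived", "ancestral"):
        raise DataError("allele must be 'derived' or 'ancestral'")
    if direction not in ("upstream", "downstream"):
        raise DataError("direction must be 'upstream' or 'downstream'")
    want = 1 if allele == "derived" else 0
    carriers = np.flatnonzero(hp.alleles[:, core] == want)
    if carriers.size < 2:
        raise DataError(f"ehh: fewer than 2 carriers of the {allele} allele at core {core}")
    step = -1 if direction == "upstream" else 1
    offsets, values, truncated = _ehh_decay(
        hp.alleles, hp.positions, core, carriers, step, cutoff, max_gap_bp)
    return EhhCurve(core, allele, direction, offsets, values, truncated)


def _integrate(offsets: np.ndarray, values: np.ndarray, cutoff: float,
               truncated: bool) -> tuple[float, bool]:
    """Trapezoid integral of one decay curve up to the cutoff crossing."""
    if truncated:
        # integrate what we have; caller decides whether to keep the record
        return float(np.trapezoid(values, offsets)), True
    # last point is the first one below cutoff: truncate at the crossing
    x0, x1 = offsets[-2], offsets[-1]
    e0, e1 = values[-2], values[-1]
    x_cross = x0 + (e0 - cutoff) / (e0 - e1) * (x1 - x0) if e0 > e1 else x0
    area = float(np.trapezoid(values[:-1], offsets[:-1]))
    area += 0.5 * (e0 + cutoff) * (x_cross - x0)
    return area, False


def ihh(hp: HaplotypePanel, core: int, allele: str = "derived",
        cutoff: float = 0.05, max_gap_bp: int = 200_000) -> tuple[float, bool]:
    """Integrated EHH of one core allele, both directions summed.

    Returns (integral in bp, truncated flag).
    """
    total = 0.0
    trunc = False
    for direction in ("upstream", "downstream"):
        c = ehh(hp, core, allele, direction, cutoff, max_gap_bp)
        a, t = _integrate(c.offsets, c.ehh, cutoff, c.truncated)
        total += a
        trunc |= t
    return total, trunc


def ihs_scan(hp: HaplotypePanel, vt: VariantTable, maf_min: float = 0.05,
             cutoff: float = 0.05, max_gap_bp: int = 200_000,
             keep_truncated: bool = False) -> pd.DataFrame:
    """Unstandardized iHS for every eligible core SNP.

    Eligible: MAF >= maf_min and >= 2 carriers of each allele.  Truncated or
    undefined cores are dropped (count logged) unless ``keep_truncated``.
    """
    if not hp.phased:
        raise DataError("ihs_scan requires a phased panel")
    rows = []
    n_dropped = 0
    for chrom in vt.chroms():
        on = np.flatnonzero(vt.chrom == chrom)
        sub = hp.take_variants(on)
        daf = sub.derived_freq()
        maf = np.minimum(daf, 1 - daf)
        n_hap = sub.n_haplotypes
        for j in np.flatnonzero(maf >= maf_min):
            n_der = int(round(daf[j] * n_hap))
            if n_der < 2 or n_hap - n_der < 2:
                continue
            ihh_d, t_d = _ihh_both(sub, j, 1, cutoff, max_gap_bp)
            ihh_a, t_a = _ihh_both(sub, j, 0, cutoff, max_gap_bp)
            truncated = t_d or t_a
            if (truncated and not keep_truncated) or ihh_d <= 0 or ihh_a <= 0:
                n_dropped += 1
                continue
            rows.append((chrom, int(vt.pos[on[j]]), int(on[j]), float(daf[j]),
                         ihh_d, ihh_a, float(np.log(ihh_a / ihh_d)), truncated))
    if n_dropped:
        log.info("ihs_scan: dropped %d truncated/undefined core(s)", n_dropped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "variant_index", "daf",
                                       "ihh_d", "ihh_a", "uihs", "truncated"])


def _ihh_both(hp: HaplotypePanel, core: int, want: int, cutoff: float,
              max_gap_bp: int) -> tuple[float, bool]:
    carriers = np.flatnonzero(hp.alleles[:, core] == want)
    total, trunc = 0.0, False
    for step in (-1, 1):
        offsets, values, t = _ehh_decay(hp.alleles, hp.positions, core, carriers,
                                        step, cutoff, max_gap_bp)
        a, t2 = _integrate(offsets, values, cutoff, t)
        total += a
        trunc |= t2
    return total, trunc


def standardize_ihs(records: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Add z: uihs centred and scaled within derived-allele-frequency bins.

    Equal-width bins on [0, 1]; occupied bins with < 2 records are merged
    with their nearest occupied neighbour.
    """
    if records.empty:
        out = records.copy()
        out["z"] = np.array([], dtype=float)
        return out
    daf = records["daf"].to_numpy()
    u = records["uihs"].to_numpy()
    b = np.minimum((daf * n_bins).astype(int), n_bins - 1)
    # merge sparse bins into nearest occupied neighbour until all have >= 2
    while True:
        occupied, counts = np.unique(b, return_counts=True)
        sparse = occupied[counts < 2]
        if sparse.size == 0:
            break
        others = occupied[counts >= 2]
        if others.size == 0:
            raise DataError("standardize_ihs: no bin with >= 2 records")
        for sb in sparse:
            target = others[np.argmin(np.abs(others - sb))]
            b[b == sb] = target
    z = np.empty_like(u)
    for bb in np.unique(b):
        m = b == bb
        sd = u[m].std(ddof=0)
        if sd == 0:
            raise DataError("standardize_ihs: zero-variance bin")
        z[m] = (u[m] - u[m].mean()) / sd
    out = records.copy()
    out["z"] = z
    return out


def select_cores(records: pd.DataFrame, z_thresh: float = 3.0) -> pd.DataFrame:
    """Flag cores with |z| >= z_thresh (inclusive)."""
    if "z" not in records.columns:
        raise DataError("select_cores: records must be standardized first")
    out = records.copy()
    out["selected"] = np.abs(out["z"].to_numpy()) >= z_thresh if len(out) else \
        np.array([], dtype=bool)
    return out
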