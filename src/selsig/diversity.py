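"""Per-individual heterozygosity, ROH / F_ROH, heterozygote-excess Ne and LD decay.

ROH detection follows the PLINK scanning-window scheme: windows of
``win_snp`` consecutive SNPs are classified homozygous when they contain at
most ``win_het`` heterozygous and ``win_miss`` missing calls; a SNP belongs
to a run when at least ``hit_threshold`` of the windows spanning it are
homozygous; maximal flagged runs are emitted subject to length, SNP-count,
gap and density conditions.

The effective-size estimator inverts the heterozygote excess: with Selander's
index D (weighted across loci), Ne = 1/(2D) + 1/(2(D+1)); D <= 0 yields
Ne = +inf.  Expected heterozygosity uses Levene's small-sample correction
2*p*q*2N/(2N-1) by default, which makes D unbiased under exact HWE sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, ChromSizes, GenotypeMatrix, HaplotypePanel, VariantTable
from .errors import DataError

log = logging.getLogger(__name__)


def het_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygosity (N_nonmissing - N_homozygous) / N_nonmissing.

    Samples with no non-missing genotype get nan (flagged via log warning).
    """
    ok = gm.values != MISSING
    n_nm = ok.sum(axis=1)
    n_het = (gm.values == 1).sum(axis=1)
    if np.any(n_nm == 0):
        log.warning("het_rate undefined for %d all-missing sample(s)", int((n_nm == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_nm > 0, n_het / np.maximum(n_nm, 1), np.nan)


@dataclass
class RohParams:
    """Scanning-window ROH parameters (PLINK-style defaults)."""

    win_snp: int = 50
    win_het: int = 1
    win_miss: int = 5
    hit_threshold: float = 0.05
    min_length_kb: float = 1000.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 1000.0
    min_snp_per_roh: int = 50


@dataclass
class RohSegment:
    """One run of homozygosity (0-based half-open bp)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _flag_snps(het: np.ndarray, miss: np.ndarray, p: RohParams) -> np.ndarray:
    """Boolean per-SNP flag from the scanning-window hit fraction."""
    v = len(het)
    w = p.win_snp
    if v < w:
        return np.zeros(v, dtype=bool)
    kern = np.ones(w)
    het_in = np.convolve(het.astype(float), kern, mode="valid")
    miss_in = np.convolve(miss.astype(float), kern, mode="valid")
    hom_win = (het_in <= p.win_het) & (miss_in <= p.win_miss)  # per window start
    # SNP i is spanned by window starts in [i-w+1, i] clipped to [0, v-w]
    cum = np.concatenate([[0], np.cumsum(hom_win)])
    lo = np.clip(np.arange(v) - w + 1, 0, v - w)
    hi = np.clip(np.arange(v), 0, v - w)
    hits = cum[hi + 1] - cum[lo]
    spans = hi - lo + 1
    return hits / spans >= p.hit_threshold


def detect_roh(vt: VariantTable, gm: GenotypeMatrix,
               params: RohParams | None = None) -> list[RohSegment]:
    """Scanning-window ROH calls for every sample, sorted by (sample, chrom, start)."""
    p = params or RohParams()
    out: list[RohSegment] = []
    for chrom in vt.chroms():
        on = vt.chrom == chrom
        pos = vt.pos[on]
        if len(pos) < p.win_snp:
            log.info("detect_roh: %s has %d SNPs < window of %d; skipped",
                     chrom, len(pos), p.win_snp)
            continue
        sub = gm.values[:, on]
        for si, sample in enumerate(gm.sample_ids):
            row = sub[si]
            flags = _flag_snps(row == 1, row == MISSING, p)
            out.extend(_runs_to_segments(sample, chrom, pos, flags, p))
    out.sort(key=lambda s: (s.sample_id, s.chrom, s.start))
    return out


def _runs_to_segments(sample, chrom, pos, flags, p: RohParams):
    segs = []
    i = 0
    v = len(flags)
    max_gap = p.max_gap_kb * 1000.0
    while i < v:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < v and flags[j + 1] and (pos[j + 1] - pos[j]) <= max_gap:
            j += 1
        start, end = int(pos[i] - 1), int(pos[j])  # 0-based half-open
        n_snps = j - i + 1
        length = end - start
        if (length >= p.min_length_kb * 1000.0
                and n_snps >= p.min_snp_per_roh
                and length / n_snps <= p.min_density_kb_per_snp * 1000.0):
            segs.append(RohSegment(sample, chrom, start, end, n_snps))
        i = j + 1
    return segs


def f_roh(segments: list[RohSegment], sizes: ChromSizes,
          sample_ids: list[str] | None = None) -> dict[str, float]:
    """Genomic inbreeding F_ROH = total autosomal ROH length / L_auto per sample."""
    if not sizes.sizes:
        raise DataError("f_roh: empty ChromSizes")
    l_auto = sizes.l_auto
    if l_auto == 0:
        raise DataError("f_roh: no autosomes in ChromSizes")
    totals: dict[str, int] = {s: 0 for s in (sample_ids or [])}
    for seg in segments:
        totals.setdefault(seg.sample_id, 0)
        if seg.chrom in sizes.sizes and sizes.autosome[seg.chrom]:
            totals[seg.sample_id] += seg.length
    return {s: t / l_auto for s, t in totals.items()}


@dataclass
class NeEstimate:
    """Heterozygote-excess effective size with jackknife CI."""

    d_mean: float
    ne: float
    ci_low: float
    ci_high: float
    n_loci_used: int
    d_se: float = float("nan")


def _ne_from_d(d: float) -> float:
    if d <= 0:
        return float("inf")
    return 1.0 / (2.0 * d) + 1.0 / (2.0 * (d + 1.0))


def ne_het_excess(gm: GenotypeMatrix, maf_min: float = 0.05,
                  levene: bool = True) -> NeEstimate:
    """Heterozygote-excess Ne from a genotype panel.

    Per locus j with N_j non-missing diploids: H_obs is the observed
    heterozygote fraction, H_exp = 2*p*q (Levene-corrected by 2N_j/(2N_j-1)
    by default), D_j = (H_obs - H_exp)/H_exp.  The panel-wide D is the
    weighted mean with w_j = N_j*(n_j - 1)/n_j (n_j = 2 alleles), and
    Ne = 1/(2D) + 1/(2(D+1)).  The 95% CI is a leave-one-locus-out jackknife
    on D mapped through the (monotone decreasing) Ne transform.
    """
    ok = gm.values != MISSING
    n_j = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, gm.values, 0).sum(axis=0) / np.maximum(2 * n_j, 1)
        h_obs = (gm.values == 1).sum(axis=0) / np.maximum(n_j, 1)
    maf = np.minimum(p, 1 - p)
    use = (n_j >= 2) & (maf >= maf_min)
    k = int(use.sum())
    if k < 2:
        raise DataError(f"ne_het_excess: only {k} qualifying loci (need >= 2)")
    n_j, p, h_obs = n_j[use], p[use], h_obs[use]
    h_exp = 2.0 * p * (1.0 - p)
    if levene:
        h_exp = h_exp * (2.0 * n_j) / (2.0 * n_j - 1.0)
    d_j = (h_obs - h_exp) / h_exp
    w_j = n_j * (2 - 1) / 2.0  # n_j * (n_alleles-1)/n_alleles, biallelic
    sw, swd = w_j.sum(), (w_j * d_j).sum()
    d_mean = swd / sw
    # leave-one-out jackknife on the weighted mean
    d_loo = (swd - w_j * d_j) / (sw - w_j)
    se = np.sqrt((k - 1) / k * ((d_loo - d_loo.mean()) ** 2).sum())
    d_lo, d_hi = d_mean - 1.96 * se, d_mean + 1.96 * se
    return NeEstimate(d_mean=float(d_mean), ne=_ne_from_d(d_mean),
                      ci_low=_ne_from_d(d_hi), ci_high=_ne_from_d(d_lo),
                      n_loci_used=k, d_se=float(se))


def ld_r2_decay(hp: HaplotypePanel, max_dist_bp: int = 300_000,
                bin_width_bp: int = 25_000) -> pd.DataFrame:
    """Binned mean r^2 between locus pairs as a function of distance.

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)) over phased
    haplotypes; monomorphic loci are skipped.
    """
    if not hp.phased:
        raise DataError("ld_r2_decay requires a phased panel")
    A = hp.alleles.astype(np.float64)
    pos = hp.positions
    n = A.shape[0]
    pA = A.mean(axis=0)
    poly = (pA > 0) & (pA < 1)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    idx = np.flatnonzero(poly)
    for a_i, i in enumerate(idx):
        js = idx[a_i + 1:]
        js = js[pos[js] - pos[i] <= max_dist_bp]
        if js.size == 0:
            continue
        pab = (A[:, i][:, None] * A[:, js]).mean(axis=0)
        num = (pab - pA[i] * pA[js]) ** 2
        den = pA[i] * (1 - pA[i]) * pA[js] * (1 - pA[js])
        r2 = num / den
        b = np.minimum(((pos[js] - pos[i]) // bin_width_bp).astype(int), n_bins - 1)
        np.add.at(sums, b, r2)
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_low": np.arange(n_bins) * bin_width_bp,
        "dist_high": (np.arange(n_bins) + 1) * bin_width_bp,
        "mean_r2": mean,
        "n_pairs": counts,
    })


def roh_to_bed(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.sample_id, s.n_snps) for s in segments],
        columns=["chrom", "start", "end", "sample", "n_snps"])
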