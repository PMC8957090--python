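"""Windowed Tajima's D with empirical-quantile window selection.

D contrasts mean pairwise diversity (pi) with Watterson's theta (S/a1); the
variance constants follow Tajima (1989).  Windows are fixed-width, anchored
at coordinate 0 of each chromosome and non-overlapping.  Per-site diversity
is computed from allele frequencies as 2*p*q*n/(n-1) with n the non-missing
allele count at the site, which equals the mean pairwise Hamming distance
exactly when no data are missing.

The variance constants use the fixed panel size n = 2 * n_samples even when
some genotypes are missing (per-site frequencies still use non-missing
counts); this matches common windowed implementations and is recorded in
output metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, ChromSizes, GenotypeMatrix, HaplotypePanel, VariantTable
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's variance normalisation."""

    a1: float
    a2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise DataError(f"Tajima's D needs >= 4 sequences, got {n}")
        i = np.arange(1, n)
        a1 = float((1.0 / i).sum())
        a2 = float((1.0 / i**2).sum())
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        return cls(a1=a1, a2=a2, e1=c1 / a1, e2=c2 / (a1**2 + a2))


def tajimas_d(s: int, pi: float, n: int) -> float:
    """Tajima's D from segregating-site count S, summed diversity pi and
    sequence count n.  S = 0 is undefined and returns nan."""
    if n < 4:
        raise DataError(f"tajimas_d: n must be >= 4, got {n}")
    if s < 0:
        raise DataError("tajimas_d: S must be non-negative")
    if s == 0:
        return float("nan")
    c = TajimaConstants.for_n(n)
    var = c.e1 * s + c.e2 * s * (s - 1)
    return float((pi - s / c.a1) / np.sqrt(var))


def _site_freqs(gm: GenotypeMatrix | None, hp: HaplotypePanel | None):
    """(alt/derived frequency, non-missing allele count) per site."""
    if hp is not None:
        n = np.full(hp.n_variants, hp.n_haplotypes)
        return hp.derived_freq(), n, hp.n_haplotypes
    ok = gm.values != MISSING
    n = 2 * ok.sum(axis=0)
    alt = np.where(ok, gm.values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n, 2 * gm.n_samples


def window_stats(vt: VariantTable, gm: GenotypeMatrix | None = None,
                 hp: HaplotypePanel | None = None,
                 sizes: ChromSizes | None = None,
                 window_bp: int = 50_000, min_sites: int = 3) -> pd.DataFrame:
    """Per-window S, pi, Watterson's theta and Tajima's D.

    Windows are [k*w, (k+1)*w) per chromosome (0-based half-open).  With
    ``sizes`` given, every window of each chromosome is emitted (possibly
    empty); otherwise windows run to the last variant.  D is nan for windows
    with S < min_sites.
    """
    if (gm is None) == (hp is None):
        raise DataError("window_stats: supply exactly one of gm/hp")
    p, n_site, n_fixed = _site_freqs(gm, hp)
    c = TajimaConstants.for_n(n_fixed)
    with np.errstate(invalid="ignore"):
        seg = (p > 0) & (p < 1) & (n_site >= 2)
        per_site_pi = np.where(seg, 2.0 * p * (1 - p) * n_site / np.maximum(n_site - 1, 1), 0.0)

    rows = []
    for chrom in vt.chroms():
        on = vt.chrom == chrom
        pos0 = vt.pos[on] - 1  # 0-based
        widx = pos0 // window_bp
        if sizes is not None:
            if chrom not in sizes:
                raise DataError(f"window_stats: {chrom!r} missing from ChromSizes")
            n_win = int(np.ceil(sizes[chrom] / window_bp))
        else:
            n_win = int(widx.max()) + 1 if len(pos0) else 0
        n_snps = np.bincount(widx, minlength=n_win)
        s_w = np.bincount(widx, weights=seg[on].astype(float), minlength=n_win)
        pi_w = np.bincount(widx, weights=per_site_pi[on], minlength=n_win)
        for k in range(n_win):
            s_k = int(s_w[k])
            d = tajimas_d(s_k, pi_w[k], n_fixed) if s_k >= max(min_sites, 1) else float("nan")
            rows.append((chrom, k, k * window_bp, (k + 1) * window_bp,
                         int(n_snps[k]), s_k, pi_w[k], s_k / c.a1, d))
    return pd.DataFrame(rows, columns=["chrom", "window_index", "start", "end",
                                       "n_snps", "S", "pi", "theta_w", "d"])


def select_windows(stats: pd.DataFrame, tail: float = 0.01):
    """Empirical-quantile tail selection of windows by Tajima's D.

    Returns (boolean selected mask aligned with ``stats``, low, high): windows
    with defined d <= low or >= high quantile (linear interpolation; ties at
    the threshold included).  A degenerate all-equal distribution selects
    nothing and warns.
    """
    d = stats["d"].to_numpy(dtype=float)
    defined = ~np.isnan(d)
    n_def = int(defined.sum())
    need = int(np.ceil(1.0 / tail))
    if n_def < need:
        raise DataError(f"select_windows: {n_def} defined windows < minimum {need}")
    low = float(np.quantile(d[defined], tail))
    high = float(np.quantile(d[defined], 1.0 - tail))
    if low == high:
        warnings.warn("select_windows: degenerate D distribution; nothing selected",
                      stacklevel=2)
        return np.zeros(len(stats), dtype=bool), low, high
    sel = defined & ((d <= low) | (d >= high))
    return sel, low, high
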