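"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (pair enumeration, literal
constant formulas, exact integer hypergeometric enumeration) and must stay
independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


# --- Tajima's D from scratch -------------------------------------------------

def tajima_oracle(haps: np.ndarray) -> tuple[int, float, float]:
    """(S, pi, D) for a binary haplotype matrix (rows = haplotypes).

    pi is the mean pairwise Hamming distance over all C(n,2) haplotype pairs;
    the constants are evaluated literally from their definitions.
    """
    n, m = haps.shape
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((haps[i] != haps[j]).sum()))
    pi = sum(diffs) / len(diffs)
    counts = haps.sum(axis=0)
    s = int(((counts > 0) & (counts < n)).sum())
    if s == 0:
        return 0, pi, float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    d = (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))
    return s, pi, d


# --- EHH / iHH by literal pair enumeration -----------------------------------

def ehh_oracle(H: np.ndarray, positions: np.ndarray, core: int, allele: int,
               step: int, cutoff: float, max_gap: int):
    """(offsets, ehh values, truncated) by enumerating haplotype pairs.

    At each marker outward, EHH is the fraction of carrier pairs identical
    over every marker from the core to that marker (inclusive).
    """
    carriers = [h for h in range(H.shape[0]) if H[h, core] == allele]
    n_c = len(carriers)
    pairs = [(a, b) for i, a in enumerate(carriers) for b in carriers[i + 1:]]
    offsets, values = [0], [1.0]
    truncated = True
    j = core
    span = [core]
    last = positions[core]
    while True:
        j += step
        if j < 0 or j >= H.shape[1]:
            break
        if abs(int(positions[j]) - int(last)) > max_gap:
            break
        last = positions[j]
        span.append(j)
        same = 0
        for a, b in pairs:
            if all(H[a, c] == H[b, c] for c in span):
                same += 1
        e = same / len(pairs)
        offsets.append(abs(int(positions[j]) - int(positions[core])))
        values.append(e)
        if e < cutoff:
            truncated = False
            break
    return np.array(offsets), np.array(values), truncated


def ihh_oracle(offsets, values, cutoff: float, truncated: bool) -> float:
    """Trapezoid area up to the linear-interpolated cutoff crossing."""
    area = 0.0
    for i in range(1, len(offsets)):
        x0, x1 = offsets[i - 1], offsets[i]
        e0, e1 = values[i - 1], values[i]
        if not truncated and i == len(offsets) - 1:
            # final sub-cutoff segment: cut at the crossing
            x_cross = x0 + (e0 - cutoff) / (e0 - e1) * (x1 - x0) if e0 > e1 else x0
            area += 0.5 * (e0 + cutoff) * (x_cross - x0)
        else:
            area += 0.5 * (e0 + e1) * (x1 - x0)
    return area


def uihs_oracle(H, positions, core, cutoff=0.05, max_gap=200_000):
    """ln(iHH_ancestral / iHH_derived) by pair enumeration; None if either
    integral is truncated or degenerate."""
    out = {}
    for name, allele in (("d", 1), ("a", 0)):
        total = 0.0
        trunc = False
        for step in (-1, 1):
            off, val, t = ehh_oracle(H, positions, core, allele, step, cutoff, max_gap)
            total += ihh_oracle(off, val, cutoff, t)
            trunc |= t
        if trunc or total <= 0:
            return None
        out[name] = total
    return math.log(out["a"] / out["d"])


# --- Fisher's exact test by exact integer enumeration ------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided p for [[a,b],[c,d]] by exact integer hypergeometric sums."""
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    denom = math.comb(r1 + r2, c1)
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / denom


# --- Interval overlap by all-pairs check -------------------------------------

def overlap_oracle(regions, genes):
    """Per-region captured gene-id sets by exhaustive all-pairs comparison."""
    out = []
    for (rc, rs, re) in regions:
        hit = set()
        for gid, gc, gs, ge in genes:
            if gc == rc and gs < re and ge > rs:
                hit.add(gid)
        out.append(hit)
    return out
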