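"""Synthetic data generators.

The centrepiece is a discrete-generation diploid Wright-Fisher forward
simulator with per-generation Poisson mutation on the integer-bp grid
(collisions re-drawn, so every site stays biallelic — an infinite-sites
approximation) and Poisson-count uniform-position crossovers.  Because every
polymorphism arises as a tracked mutation, ancestral/derived polarity of the
output panel is exact, which is what the haplotype-based selection statistics
need.

Selection is additive: genotype fitnesses 1, 1 + s/2, 1 + s for dosages
0/1/2 of the beneficial allele.  Sweep runs inject a single copy after
burn-in, condition on non-loss by restarting from the saved burn-in state,
and stop once the beneficial allele reaches the requested frequency.

Also provided: genotype panels with a prescribed heterozygote excess
(Selander's D), implanted homozygous tracts, and two-group case/control
panels with frequency-shifted causal loci — each generator mirrors one
downstream estimator so that parameter recovery can be tested end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np

from .containers import MISSING, GenotypeMatrix, HaplotypePanel, VariantTable
from .errors import DataError

log = logging.getLogger(__name__)

_MAX_SWEEP_RESTARTS = 10_000


@dataclass
class SimConfig:
    """Parameters of one Wright-Fisher run.

    Defaults give a desk-scale stand-in for a sheep-like resequencing
    panel: theta = 4*N*mu = 2e-4 per bp (roughly one segregating site per kb
    in a sample of 80 haplotypes) and rho = 4*N*rec = 8e-5 per bp, so that
    haplotype structure stays resolvable at this population size.
    """

    seed: int
    n_diploids: int = 200
    chrom_length: int = 1_000_000
    mu: float = 2.5e-7
    rec: float = 1e-7
    s: float = 0.0
    sweep_pos: int | None = None
    burnin_generations: int | None = None
    post_sweep_freq_target: float = 0.8
    chrom_name: str = "1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataError("SimConfig: seed is mandatory")
        if self.n_diploids < 2 or self.chrom_length <= 0:
            raise DataError("SimConfig: need >=2 diploids and positive chrom_length")
        if min(self.mu, self.rec) < 0 or self.s < 0:
            raise DataError("SimConfig: rates must be >= 0")
        if not 0 < self.post_sweep_freq_target <= 1:
            raise DataError("SimConfig: post_sweep_freq_target must be in (0, 1]")
        if self.sweep_pos is None:
            self.sweep_pos = self.chrom_length // 2
        if self.burnin_generations is None:
            self.burnin_generations = 10 * self.n_diploids


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each synthetic dataset."""

    sweep_pos: int | None = None
    sweep_freq: float | None = None
    roh_tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    causal: dict[int, tuple[float, float]] = field(default_factory=dict)  # idx -> (f_ctrl, f_case)


@numba.njit(cache=True)
def _evolve_kernel(H, positions, S, L, mu, rec, max_gen, s, sweep_pos, target, seed):
    """Run up to ``max_gen`` Wright-Fisher generations in place.

    ``H``/``positions`` are capacity-sized buffers whose first ``S`` columns
    are live, sorted by position.  With ``s > 0`` the allele at ``sweep_pos``
    is under additive selection (fitness 1, 1+s/2, 1+s) and the loop stops
    when it is lost (status 1) or reaches ``target`` frequency (status 2);
    status 0 means the generation budget ran out.  Returns
    (H, positions, S, status, freq).
    """
    np.random.seed(seed)
    n_hap = H.shape[0]
    n_dip = n_hap // 2
    lam_rec = rec * L
    lam_mut = n_hap * mu * L
    B = np.empty_like(H)
    posB = np.empty_like(positions)
    cdf = np.empty(n_dip)
    status = 0
    freq = 0.0
    for _ in range(max_gen):
        # --- selection weights (cdf over diploid parents) ---
        tot = 0.0
        if s > 0.0:
            j = np.searchsorted(positions[:S], sweep_pos)
            if j >= S or positions[j] != sweep_pos:
                status = 1
                break
            for i in range(n_dip):
                tot += 1.0 + 0.5 * s * (H[2 * i, j] + H[2 * i + 1, j])
                cdf[i] = tot
        # --- reproduction into B ---
        for i in range(n_hap):
            if s > 0.0:
                p = np.searchsorted(cdf, np.random.random() * tot)
                if p >= n_dip:
                    p = n_dip - 1
            else:
                p = np.random.randint(n_dip)
            hap = np.random.randint(2)
            r0 = 2 * p + hap
            r1 = 2 * p + 1 - hap
            k = np.random.poisson(lam_rec) if lam_rec > 0.0 else 0
            if k == 0:
                B[i, :S] = H[r0, :S]
            else:
                cuts = np.sort(np.random.randint(1, L + 1, k))
                ci = 0
                cur = 0
                for c in range(S):
                    pc = positions[c]
                    while ci < k and cuts[ci] < pc:
                        ci += 1
                        cur ^= 1
                    B[i, c] = H[r0, c] if cur == 0 else H[r1, c]
        # --- new mutations (unique positions, infinite-sites on the grid) ---
        n_mut = np.random.poisson(lam_mut) if lam_mut > 0.0 else 0
        m_pos = np.empty(n_mut, dtype=np.int64)
        m_row = np.empty(n_mut, dtype=np.int64)
        got = 0
        while got < n_mut:
            cand = np.random.randint(1, L + 1)
            j = np.searchsorted(positions[:S], cand)
            if j < S and positions[j] == cand:
                continue
            dup = False
            for t in range(got):
                if m_pos[t] == cand:
                    dup = True
                    break
            if dup:
                continue
            m_pos[got] = cand
            m_row[got] = np.random.randint(n_hap)
            got += 1
        order = np.argsort(m_pos)
        # --- prune fixed/lost and merge mutations back into H (sorted) ---
        if S + n_mut > H.shape[1]:
            newcap = 2 * (S + n_mut) + 16
            H2 = np.empty((n_hap, newcap), dtype=np.uint8)
            pos2 = np.empty(newcap, dtype=np.int64)
            H2[:, :S] = H[:, :S]
            pos2[:S] = positions[:S]
            H, positions = H2, pos2
            B2 = np.empty((n_hap, newcap), dtype=np.uint8)
            pos2b = np.empty(newcap, dtype=np.int64)
            B2[:, :S] = B[:, :S]
            pos2b[:S] = posB[:S]
            B, posB = B2, pos2b
        out = 0
        mi = 0
        protect = sweep_pos if s > 0.0 else np.int64(-1)
        for c in range(S):
            cnt = 0
            for r in range(n_hap):
                cnt += B[r, c]
            if 0 < cnt < n_hap or positions[c] == protect:
                while mi < n_mut and m_pos[order[mi]] < positions[c]:
                    for r in range(n_hap):
                        H[r, out] = 0
                    H[m_row[order[mi]], out] = 1
                    posB[out] = m_pos[order[mi]]
                    mi += 1
                    out += 1
                for r in range(n_hap):
                    H[r, out] = B[r, c]
                posB[out] = positions[c]
                out += 1
        while mi < n_mut:
            for r in range(n_hap):
                H[r, out] = 0
            H[m_row[order[mi]], out] = 1
            posB[out] = m_pos[order[mi]]
            mi += 1
            out += 1
        S = out
        positions[:S] = posB[:S]
        # --- sweep bookkeeping ---
        if s > 0.0:
            j = np.searchsorted(positions[:S], sweep_pos)
            if j >= S or positions[j] != sweep_pos:
                status = 1
                break
            cnt = 0
            for r in range(n_hap):
                cnt += H[r, j]
            freq = cnt / n_hap
            if cnt == 0:
                status = 1
                break
            if freq >= target:
                status = 2
                break
    return H, positions, S, status, freq


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def evolve_panel(alleles: np.ndarray, positions: np.ndarray, chrom_length: int,
                 mu: float, rec: float, generations: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Drift an existing haplotype panel forward; used for calibration tests."""
    order = np.argsort(positions, kind="stable")
    H = np.ascontiguousarray(np.asarray(alleles, dtype=np.uint8)[:, order])
    pos = np.ascontiguousarray(np.asarray(positions, dtype=np.int64)[order])
    S = H.shape[1]
    H, pos, S, _, _ = _evolve_kernel(H, pos, S, chrom_length, mu, rec, generations,
                                     0.0, np.int64(-1), 1.0, _kernel_seed(rng))
    return H[:, :S].copy(), pos[:S].copy()


def simulate_wright_fisher(cfg: SimConfig):
    """Run the forward simulation described by ``cfg``.

    Returns
    -------
    (VariantTable, HaplotypePanel, TruthRecord)
        Segregating sites only, sorted by position; the panel is phased and
        exactly polarized (allele 1 = derived).
    """
    rng = np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_diploids
    L = cfg.chrom_length
    cap = max(64, int(8 * cfg.mu * L * n_hap * np.log(n_hap)))  # ~4x equilibrium S
    H = np.zeros((n_hap, cap), dtype=np.uint8)
    positions = np.zeros(cap, dtype=np.int64)
    S = 0

    H, positions, S, _, _ = _evolve_kernel(
        H, positions, S, L, cfg.mu, cfg.rec, cfg.burnin_generations,
        0.0, np.int64(-1), 1.0, _kernel_seed(rng))

    truth = TruthRecord()
    if cfg.s > 0:
        # drop any standing variant occupying the sweep site, then inject
        live = positions[:S]
        occupied = np.flatnonzero(live == cfg.sweep_pos)
        if occupied.size:
            log.info("removing standing variant at sweep_pos %d", cfg.sweep_pos)
            keep = np.ones(S, dtype=bool)
            keep[occupied] = False
            live = live[keep]
            H[:, :keep.sum()] = H[:, :S][:, keep]
            S = int(keep.sum())
            positions[:S] = live
        snap_H, snap_pos, snap_s = H[:, :S].copy(), positions[:S].copy(), S
        max_gen = 200 * cfg.n_diploids  # safety cap per attempt
        for attempt in range(_MAX_SWEEP_RESTARTS):
            j_ins = int(np.searchsorted(snap_pos, cfg.sweep_pos))
            H = np.zeros((n_hap, cap), dtype=np.uint8)
            positions = np.zeros(cap, dtype=np.int64)
            H[:, :j_ins] = snap_H[:, :j_ins]
            H[:, j_ins + 1:snap_s + 1] = snap_H[:, j_ins:]
            H[:, j_ins] = 0
            H[int(rng.integers(0, n_hap)), j_ins] = 1
            positions[:j_ins] = snap_pos[:j_ins]
            positions[j_ins] = cfg.sweep_pos
            positions[j_ins + 1:snap_s + 1] = snap_pos[j_ins:]
            S = snap_s + 1
            H, positions, S, status, freq = _evolve_kernel(
                H, positions, S, L, cfg.mu, cfg.rec, max_gen,
                cfg.s, np.int64(cfg.sweep_pos), cfg.post_sweep_freq_target,
                _kernel_seed(rng))
            if status == 2:
                truth.sweep_pos = cfg.sweep_pos
                truth.sweep_freq = float(freq)
                break
        else:
            raise DataError(
                f"sweep failed to establish in {_MAX_SWEEP_RESTARTS} restarts; "
                "increase s or n_diploids")
        if attempt:
            log.info("sweep established after %d restart(s)", attempt)

    # final tidy: segregating sites only (the swept site is kept while
    # segregating; at fixation it is monomorphic and drops out)
    H = H[:, :S]
    positions = positions[:S]
    counts = H.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < n_hap)
    H, positions = np.ascontiguousarray(H[:, seg]), positions[seg]

    n_var = len(positions)
    anc = rng.choice(np.array(list("ACGT")), size=n_var)
    vt = VariantTable(np.full(n_var, cfg.chrom_name, dtype=object), positions,
                      anc.astype(object), _derived_alleles(anc, rng).astype(object),
                      np.ones(n_var, dtype=bool))
    hp = HaplotypePanel(H, positions.copy(), phased=True)
    return vt, hp, truth


_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _derived_alleles(anc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Derived bases with a 2:1 transition bias (realistic Ts/Tv flavour)."""
    out = np.empty(len(anc), dtype=object)
    is_ts = rng.random(len(anc)) < 2.0 / 3.0
    pick = rng.integers(0, 2, size=len(anc))
    for i, a in enumerate(anc):
        out[i] = _TS_PARTNER[a] if is_ts[i] else _TV_PARTNERS[a][pick[i]]
    return out


def sample_individuals(hp: HaplotypePanel, n_diploids: int,
                       rng: np.random.Generator) -> HaplotypePanel:
    """Draw a diploid sample from a simulated population panel.

    Monomorphic-in-sample columns are dropped so the result is again a panel
    of segregating sites.
    """
    if n_diploids > hp.n_samples:
        raise DataError("sample_individuals: sample larger than population")
    pick = rng.choice(hp.n_samples, size=n_diploids, replace=False)
    rows = np.empty(2 * n_diploids, dtype=np.int64)
    rows[0::2], rows[1::2] = 2 * pick, 2 * pick + 1
    A = hp.alleles[rows]
    seg = (A.sum(axis=0) > 0) & (A.sum(axis=0) < 2 * n_diploids)
    return HaplotypePanel(A[:, seg], hp.positions[seg], phased=True)


def sample_hwe_genotypes(freqs, n: int, d_excess: float = 0.0,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Genotype panel with heterozygote frequency (1 + D) * 2pq per locus.

    The homozygote classes share the remaining mass in proportion to their
    Hardy-Weinberg expectations, so D is exactly Selander's index of the
    generating distribution.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise DataError("sample_hwe_genotypes: freqs must lie in (0,1)")
    if d_excess <= -1:
        raise DataError("sample_hwe_genotypes: d_excess must exceed -1")
    p = freqs
    q = 1.0 - p
    p_het = (1.0 + d_excess) * 2 * p * q
    if np.any(p_het > 1):
        raise DataError("sample_hwe_genotypes: (1+D)*2pq exceeds 1 at some locus")
    hom_mass = 1.0 - p_het
    p_aa = hom_mass * q**2 / (p**2 + q**2)   # dosage 0
    p_bb = hom_mass * p**2 / (p**2 + q**2)   # dosage 2
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random((n, len(p)))
    g = (u >= p_aa).astype(np.int8) + (u >= p_aa + p_het).astype(np.int8)
    return GenotypeMatrix(g, [f"S{i}" for i in range(n)])


def _merge_tracts(tracts):
    tracts = sorted(tracts)
    merged = [list(tracts[0])]
    for t in tracts[1:]:
        if t[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t[1])
        else:
            merged.append(list(t))
    return [tuple(t) for t in merged]


def implant_roh(vt: VariantTable, gm: GenotypeMatrix,
                tracts: dict[str, list[tuple[str, int, int]]],
                sizes=None) -> GenotypeMatrix:
    """Force homozygosity inside per-sample tracts (0-based half-open bp).

    Heterozygous (and missing) calls inside a tract become homozygous for the
    locally more common allele; calls outside tracts are untouched.
    """
    values = gm.values.copy()
    p = gm.alt_freq()
    major_hom = np.where(np.nan_to_num(p) >= 0.5, 2, 0).astype(np.int8)
    idx_of = {s: i for i, s in enumerate(gm.sample_ids)}
    for sample, t_list in tracts.items():
        if sample not in idx_of:
            raise DataError(f"implant_roh: unknown sample {sample!r}")
        if not t_list:
            continue
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in t_list:
            if end <= start or start < 0:
                raise DataError(f"implant_roh: bad tract [{start},{end}) on {chrom}")
            if sizes is not None and (chrom not in sizes or end > sizes[chrom]):
                raise DataError(f"implant_roh: tract [{start},{end}) beyond end of {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        row = idx_of[sample]
        for chrom, ts in by_chrom.items():
            merged = _merge_tracts(ts)
            if len(merged) < len(ts):
                log.info("implant_roh: merged overlapping tracts for %s on %s", sample, chrom)
            on_chrom = vt.chrom == chrom
            pos0 = vt.pos - 1  # 0-based
            for start, end in merged:
                inside = on_chrom & (pos0 >= start) & (pos0 < end)
                col = values[row, inside]
                fix = (col == 1) | (col == MISSING)
                col[fix] = major_hom[inside][fix]
                values[row, inside] = col
    return GenotypeMatrix(values, list(gm.sample_ids))


def make_case_control(vt: VariantTable, base_freqs, causal: dict[int, float] | set,
                      delta: float, n_case: int, n_control: int, seed: int):
    """Two-group HWE genotype panel with frequency-shifted causal loci.

    ``causal`` is a set of variant indices (or an index->shift mapping; plain
    sets use ``delta`` for every locus).  Controls are drawn at ``base_freqs``;
    cases at ``base_freq + shift`` for causal loci.
    """
    if n_case < 2 or n_control < 2:
        raise DataError("make_case_control: group sizes must be >= 2")
    base = np.asarray(base_freqs, dtype=np.float64)
    if len(base) != vt.n_variants:
        raise DataError("make_case_control: base_freqs length mismatch")
    shifts = dict(causal) if isinstance(causal, dict) else {i: delta for i in causal}
    case_freq = base.copy()
    for i, d in shifts.items():
        case_freq[i] = base[i] + d
        if not 0 < case_freq[i] < 1:
            raise DataError(f"make_case_control: shifted frequency outside (0,1) at locus {i}")
    rng = np.random.default_rng(seed)
    g_case = rng.binomial(2, case_freq, size=(n_case, len(base))).astype(np.int8)
    g_ctrl = rng.binomial(2, base, size=(n_control, len(base))).astype(np.int8)
    ids = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_control)]
    gm = GenotypeMatrix(np.vstack([g_case, g_ctrl]), ids)
    labels = {s: ("case" if s.startswith("case") else "control") for s in ids}
    truth = TruthRecord(causal={i: (float(base[i]), float(case_freq[i])) for i in shifts})
    return gm, labels, truth
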