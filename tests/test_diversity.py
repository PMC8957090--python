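import numpy as np
import pytest

from selsig import diversity
from selsig.containers import MISSING, ChromSizes, GenotypeMatrix, HaplotypePanel, VariantTable
from selsig.diversity import RohParams, RohSegment, _ne_from_d
from selsig.errors import DataError
from selsig.simulate import implant_roh, sample_hwe_genotypes


def _vt_grid(n, spacing):
    return VariantTable(np.full(n, "1", dtype=object), (np.arange(n) + 1) * spacing,
                        np.full(n, "A", dtype=object), np.full(n, "G", dtype=object),
                        np.ones(n, dtype=bool))


# --- heterozygosity ----------------------------------------------------------

def test_het_rate():
    vals = np.array([
        [0, 1, 2, 1, MISSING],   # 2 het / 4 non-missing
        [0, 0, 2, 2, 2],         # all homozygous
        [1, 1, 1, 1, 1],         # all heterozygous
        [MISSING] * 5,           # undefined
    ], dtype=np.int8)
    gm = GenotypeMatrix(vals, list("abcd"))
    h = diversity.het_rate(gm)
    assert h[0] == pytest.approx(0.5)
    assert h[1] == 0.0
    assert h[2] == 1.0
    assert np.isnan(h[3])
    assert np.all((h[:3] >= 0) & (h[:3] <= 1))


# --- ROH ---------------------------------------------------------------------

def test_detect_roh_fully_heterozygous_empty():
    vt = _vt_grid(500, 10_000)
    gm = GenotypeMatrix(np.ones((1, 500), dtype=np.int8), ["s"])
    assert diversity.detect_roh(vt, gm) == []


def test_detect_roh_fully_homozygous_chromosome():
    vt = _vt_grid(300, 10_000)  # 3 Mb, adequate density
    gm = GenotypeMatrix(np.zeros((1, 300), dtype=np.int8), ["s"])
    segs = diversity.detect_roh(vt, gm)
    assert len(segs) == 1
    assert segs[0].start == int(vt.pos[0] - 1) and segs[0].end == int(vt.pos[-1])
    assert segs[0].n_snps == 300


def test_detect_roh_recovers_implanted_tract():
    vt = _vt_grid(400, 10_000)  # 4 Mb at 1 SNP / 10 kb
    rng = np.random.default_rng(5)
    # heterozygote-rich background (HWE at p=0.5)
    vals = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(1, 400)).astype(np.int8)
    gm = GenotypeMatrix(vals, ["s"])
    tract = ("1", 1_000_000, 3_000_000)
    gm2 = implant_roh(vt, gm, {"s": [tract]}, sizes=ChromSizes({"1": 4_000_100}))
    segs = diversity.detect_roh(vt, gm2)
    assert len(segs) == 1
    span = 50 * 10_000  # one scanning window of 50 SNPs at this density
    assert abs(segs[0].start - tract[1]) <= span
    assert abs(segs[0].end - tract[2]) <= span


def test_detect_roh_sorted_nonoverlapping():
    vt = _vt_grid(600, 10_000)
    rng = np.random.default_rng(8)
    vals = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(2, 600)).astype(np.int8)
    gm = implant_roh(vt, GenotypeMatrix(vals, ["a", "b"]),
                     {"a": [("1", 500_000, 2_000_000), ("1", 3_500_000, 5_500_000)]},
                     sizes=ChromSizes({"1": 6_000_100}))
    segs = diversity.detect_roh(vt, gm)
    for s in segs:
        assert s.end > s.start
    by_sample = {}
    for s in segs:
        by_sample.setdefault(s.sample_id, []).append(s)
    for sample_segs in by_sample.values():
        for s1, s2 in zip(sample_segs, sample_segs[1:]):
            assert s1.end <= s2.start  # sorted and disjoint


def test_detect_roh_short_chromosome_skipped():
    vt = _vt_grid(10, 10_000)
    gm = GenotypeMatrix(np.zeros((1, 10), dtype=np.int8), ["s"])
    assert diversity.detect_roh(vt, gm) == []


def test_f_roh():
    sizes = ChromSizes({"1": 1_450_000_000, "2": 1_000_000_000, "X": 130_000_000})
    segs = [RohSegment("s", "1", 0, 24_500_000, 300),
            RohSegment("s", "X", 0, 50_000_000, 600)]
    fr = diversity.f_roh(segs, sizes, sample_ids=["s", "t"])
    assert fr["s"] == pytest.approx(24_500_000 / 2_450_000_000)  # X excluded
    assert fr["t"] == 0.0
    with pytest.raises(DataError):
        diversity.f_roh(segs, ChromSizes({"X": 130_000_000}))  # no autosomes


# --- heterozygote-excess Ne --------------------------------------------------

def test_ne_closed_form():
    assert _ne_from_d(0.1) == pytest.approx(1 / 0.2 + 1 / 2.2)
    assert _ne_from_d(0.0) == np.inf
    assert _ne_from_d(-0.3) == np.inf
    grid = np.linspace(0.01, 1.0, 50)
    ne = [_ne_from_d(d) for d in grid]
    assert np.all(np.diff(ne) < 0)  # larger excess -> smaller Ne


def test_ne_estimator_tracks_d(rng):
    """D-hat responds to the generated heterozygote excess.

    The per-locus ratio (H_obs - H_exp)/H_exp carries a known downward
    small-sample bias away from p = 0.5 (the noisy denominator is positively
    correlated with the numerator), so recovery at n = 50 is approximate:
    at true D = 0.05 over U(0.1, 0.9) frequencies E[D-hat] is ~0.035.
    """
    freqs = rng.uniform(0.1, 0.9, 2000)
    gm = sample_hwe_genotypes(freqs, 50, d_excess=0.05, seed=123)
    est = diversity.ne_het_excess(gm, maf_min=0.05)
    assert 0.02 < est.d_mean < 0.055
    gm0 = sample_hwe_genotypes(freqs, 50, d_excess=0.0, seed=123)
    est0 = diversity.ne_het_excess(gm0, maf_min=0.05)
    assert est0.d_mean < est.d_mean
    assert np.isfinite(est.ne) == (est.d_mean > 0)
    assert est.ci_low <= est.ne <= est.ci_high
    # loci at p = 0.5 are free of the ratio bias: tight recovery there
    gm5 = sample_hwe_genotypes(np.full(2000, 0.5), 50, d_excess=0.05, seed=7)
    est5 = diversity.ne_het_excess(gm5, maf_min=0.05)
    assert est5.d_mean == pytest.approx(0.05, abs=0.012)


def test_ne_invariant_to_order(rng):
    freqs = rng.uniform(0.2, 0.8, 300)
    gm = sample_hwe_genotypes(freqs, 40, d_excess=0.1, seed=5)
    est = diversity.ne_het_excess(gm)
    perm_v = rng.permutation(300)
    perm_s = rng.permutation(40)
    gm2 = GenotypeMatrix(gm.values[np.ix_(perm_s, perm_v)],
                         [gm.sample_ids[i] for i in perm_s])
    est2 = diversity.ne_het_excess(gm2)
    assert est.d_mean == pytest.approx(est2.d_mean, rel=1e-12)
    assert est.ne == pytest.approx(est2.ne, rel=1e-12)


def test_ne_needs_loci():
    gm = GenotypeMatrix(np.zeros((10, 3), dtype=np.int8), [f"s{i}" for i in range(10)])
    with pytest.raises(DataError):
        diversity.ne_het_excess(gm)  # all loci monomorphic


# --- LD decay ----------------------------------------------------------------

def test_ld_duplicated_column_r2_one(rng):
    H = rng.integers(0, 2, size=(40, 2)).astype(np.uint8)
    while H[:, 0].sum() in (0, 40):
        H = rng.integers(0, 2, size=(40, 2)).astype(np.uint8)
    H[:, 1] = H[:, 0]
    hp = HaplotypePanel(H, [1000, 31_000], phased=True)
    df = diversity.ld_r2_decay(hp, max_dist_bp=100_000, bin_width_bp=25_000)
    b = df[(df.dist_low <= 30_000) & (df.dist_high > 30_000)]
    assert b.mean_r2.iloc[0] == pytest.approx(1.0)


def test_ld_independent_columns_near_zero(rng):
    n_hap = 200
    H = rng.integers(0, 2, size=(n_hap, 40)).astype(np.uint8)
    hp = HaplotypePanel(H, np.arange(1, 41) * 1000, phased=True)
    df = diversity.ld_r2_decay(hp, max_dist_bp=50_000, bin_width_bp=50_000)
    observed = df.mean_r2.iloc[0]
    # permutation oracle: shuffling one column's haplotypes gives the null scale
    null = []
    for _ in range(20):
        Hp = H.copy()
        Hp[:, 0] = rng.permutation(Hp[:, 0])
        null.append(diversity.ld_r2_decay(
            HaplotypePanel(Hp, hp.positions, phased=True),
            max_dist_bp=50_000, bin_width_bp=50_000).mean_r2.iloc[0])
    assert observed < 5 * np.mean(null) + 0.05
    assert observed < 3 / n_hap  # ~1/n_hap scale
    assert 0 <= observed <= 1
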