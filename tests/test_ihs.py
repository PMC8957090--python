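import numpy as np
import pandas as pd
import pytest

from conftest import random_panel
from oracles import ehh_oracle, ihh_oracle, uihs_oracle
from selsig import ihs
from selsig.containers import HaplotypePanel, VariantTable
from selsig.errors import DataError
from selsig.ihs import ehh, ihh, ihs_scan, select_cores, standardize_ihs


def _vt_for(hp, chrom="1"):
    n = hp.n_variants
    return VariantTable(np.full(n, chrom, dtype=object), hp.positions,
                        np.full(n, "A", dtype=object), np.full(n, "G", dtype=object),
                        np.ones(n, dtype=bool))


def test_ehh_identical_carriers_stay_one():
    H = np.zeros((6, 5), dtype=np.uint8)
    H[:4, 2] = 1  # derived carriers all share the all-zero background
    hp = HaplotypePanel(H, [100, 200, 300, 400, 500])
    c = ehh(hp, core=2, allele="derived", direction="downstream")
    assert np.all(c.ehh == 1.0)
    assert c.truncated  # never fell below cutoff before the edge


def test_ehh_group_sizes_3_2_1():
    # 6 derived carriers split {3,2,1} at the next marker -> (3+1)/15
    H = np.zeros((8, 2), dtype=np.uint8)
    H[:6, 0] = 1
    H[0:3, 1] = 0
    H[3:5, 1] = 1
    H[5, 1] = 0
    # make row 5 differ from rows 0-2 at a third marker to split it off
    H = np.column_stack([H, np.zeros(8, dtype=np.uint8)])
    H[5, 2] = 1
    hp = HaplotypePanel(H, [100, 200, 300])
    c = ehh(hp, core=0, allele="derived", direction="downstream", cutoff=0.0)
    # after marker 2: groups {0,1,2},{3,4},{5} -> (C(3,2)+C(2,2))/C(6,2) = 4/15
    assert c.ehh[2] == pytest.approx(4 / 15)
    off, val, _ = ehh_oracle(hp.alleles, hp.positions, 0, 1, +1, 0.0, 10**9)
    np.testing.assert_allclose(c.ehh, val, atol=1e-12)


def test_ehh_two_carriers_diverge_to_zero():
    H = np.zeros((4, 2), dtype=np.uint8)
    H[:2, 0] = 1
    H[0, 1] = 1  # the two carriers differ at the next marker
    hp = HaplotypePanel(H, [100, 200])
    c = ehh(hp, core=0, allele="derived", direction="downstream")
    assert c.ehh[-1] == 0.0 and not c.truncated


def test_ehh_needs_two_carriers():
    H = np.zeros((4, 1), dtype=np.uint8)
    H[0, 0] = 1
    with pytest.raises(DataError, match="carriers"):
        ehh(HaplotypePanel(H, [100]), core=0, allele="derived")


def test_ihh_near_rectangle_matches_oracle():
    # EHH stays 1 out to ~+-L, splits {2,2} one marker out, then to singletons:
    # the integral is close to the 2L rectangle and must equal the literal
    # pair-enumeration oracle including the cutoff-crossing truncation.
    L = 10_000
    n_mark = 21
    pos = 1 + np.arange(n_mark, dtype=np.int64) * 1000  # core at distance L from ends
    H = np.zeros((6, n_mark), dtype=np.uint8)
    core = n_mark // 2
    H[:4, core] = 1
    H[2:4, [1, 19]] = 1   # split {0,1} vs {2,3} at distance 9 kb
    H[1, 0] = H[3, 0] = 1  # split to singletons at 10 kb
    H[1, 20] = H[3, 20] = 1
    hp = HaplotypePanel(H, pos)
    val, trunc = ihh(hp, core, "derived")
    o = 0.0
    for step in (-1, +1):
        off, v, t = ehh_oracle(hp.alleles, hp.positions, core, 1, step, 0.05, 200_000)
        o += ihh_oracle(off, v, 0.05, t)
    assert not trunc
    assert val == pytest.approx(o, rel=1e-12)
    assert 1.2 * L < val < 2 * L  # near-rectangular decay profile


def test_uihs_symmetric_panel_zero():
    # derived and ancestral carriers have mirror-image haplotype structure
    H = np.zeros((8, 3), dtype=np.uint8)
    H[:4, 1] = 1          # core: 4 derived, 4 ancestral
    H[[0, 1], 0] = 1      # derived split {2,2} upstream
    H[[4, 5], 0] = 1      # ancestral split {2,2} upstream
    H[[0, 1], 2] = 1
    H[[4, 5], 2] = 1
    hp = HaplotypePanel(H, [100, 200, 300])
    vt = _vt_for(hp)
    rec = ihs_scan(hp, vt, maf_min=0.0, keep_truncated=True)
    row = rec[rec.variant_index == 1]
    assert row.uihs.iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_uihs_antisymmetry_under_polarity_flip(rng):
    hp = random_panel(rng, 10, 14, span=20_000)
    vt = _vt_for(hp)
    rec1 = ihs_scan(hp, vt, maf_min=0.1, keep_truncated=True)
    flipped = HaplotypePanel(1 - hp.alleles, hp.positions, phased=True)
    rec2 = ihs_scan(flipped, vt, maf_min=0.1, keep_truncated=True)
    merged = rec1.merge(rec2, on="variant_index", suffixes=("_1", "_2"))
    assert len(merged) > 0
    np.testing.assert_allclose(merged.uihs_1, -merged.uihs_2, atol=1e-12)
    np.testing.assert_allclose(merged.ihh_d_1, merged.ihh_a_2, atol=1e-9)


def test_ehh_invariants_on_simulated_panel(rng):
    for _ in range(5):
        hp = random_panel(rng, 10, 15, span=30_000)
        for core in range(hp.n_variants):
            for allele in ("derived", "ancestral"):
                n_car = int((hp.alleles[:, core] == (allele == "derived")).sum())
                if n_car < 2:
                    continue
                for direction in ("upstream", "downstream"):
                    c = ehh(hp, core, allele, direction, cutoff=0.0)
                    assert c.ehh[0] == 1.0
                    assert np.all((c.ehh >= 0) & (c.ehh <= 1))
                    assert np.all(np.diff(c.ehh) <= 1e-12)  # monotone non-increasing


def test_brute_force_equivalence_small_panels(rng):
    checked = 0
    for _ in range(15):
        n = int(rng.choice([4, 6, 8, 10]))
        m = int(rng.integers(4, 16))
        hp = random_panel(rng, n, m, span=40_000)
        vt = _vt_for(hp)
        rec = ihs_scan(hp, vt, maf_min=0.0)
        for row in rec.itertuples():
            o = uihs_oracle(hp.alleles, hp.positions, row.variant_index)
            assert o is not None
            assert row.uihs == pytest.approx(o, abs=1e-9)
            checked += 1
    assert checked > 10


def test_standardize_ihs():
    rec = pd.DataFrame({"daf": [0.1, 0.12, 0.8, 0.82, 0.84],
                        "uihs": [-1.0, 1.0, 0.0, 1.0, 2.0]})
    out = standardize_ihs(rec, n_bins=10)
    for b, grp in out.groupby((out.daf * 10).astype(int)):
        np.testing.assert_allclose(grp.z.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(grp.z.std(ddof=0), 1.0, atol=1e-9)
    single = standardize_ihs(pd.DataFrame({"daf": [0.5, 0.55], "uihs": [-1.0, 1.0]}),
                             n_bins=1)
    assert sorted(single.z) == [-1.0, 1.0]
    # order invariance
    perm = out.sample(frac=1, random_state=1)
    out2 = standardize_ihs(perm, n_bins=10).sort_index()
    np.testing.assert_allclose(out2.z, out.z, atol=1e-12)


def test_standardize_merges_sparse_bins():
    rec = pd.DataFrame({"daf": [0.05, 0.5, 0.52, 0.54], "uihs": [5.0, 0.0, 1.0, 2.0]})
    out = standardize_ihs(rec, n_bins=10)  # lone record merges into the 0.5 bin
    assert len(out) == 4 and out.z.notna().all()


def test_select_cores_inclusive():
    rec = pd.DataFrame({"z": [3.0, -3.0, 2.999, 0.0]})
    out = select_cores(rec, z_thresh=3.0)
    assert list(out.selected) == [True, True, False, False]
    empty = select_cores(pd.DataFrame({"z": []}), 3.0)
    assert len(empty) == 0


def test_selected_fraction_standard_normal(rng):
    z = rng.standard_normal(100_000)
    out = select_cores(pd.DataFrame({"z": z}))
    frac = out.selected.mean()
    assert 0.0015 < frac < 0.004  # ~0.0027 two-sided tail mass at |z| >= 3


def test_ihs_scan_requires_phase():
    hp = HaplotypePanel(np.zeros((4, 2), dtype=np.uint8), [1, 2], phased=False)
    with pytest.raises(DataError, match="phased"):
        ihs_scan(hp, _vt_for(hp))
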