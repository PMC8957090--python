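"""Case/control allele-count Fisher's exact tests inside gene regions.

The test is allelic: each non-missing diploid contributes two alleles to a
2x2 table (group x allele).  The two-sided p-value is the classical
point-probability sum — all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's (with a
1e-7 relative guard against floating-point ties).  No multiple-testing
correction is applied to the primary p (the candidate-gene design reports
raw p-values), but a Bonferroni column is emitted alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, VariantTable
from .errors import DataError
from .regions import Region


def allele_table(gm: GenotypeMatrix, variant: int, case_ids: list[str],
                 control_ids: list[str]) -> np.ndarray:
    """2x2 allele counts [[case_alt, case_ref], [ctrl_alt, ctrl_ref]]."""
    if set(case_ids) & set(control_ids):
        raise DataError("allele_table: case and control groups overlap")
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    for s in list(case_ids) + list(control_ids):
        if s not in idx:
            raise DataError(f"allele_table: sample {s!r} not in genotype matrix")
    tab = np.zeros((2, 2), dtype=np.int64)
    for row, group in enumerate((case_ids, control_ids)):
        g = gm.values[[idx[s] for s in group], variant]
        g = g[g != MISSING]
        tab[row, 0] = g.sum()            # alt alleles
        tab[row, 1] = 2 * len(g) - g.sum()  # ref alleles
    return tab


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher p by hypergeometric point-probability summation."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("fisher_exact_two_sided: need a non-negative 2x2 table")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[0, 0] + t[1, 0]
    n = r1 + r2
    if c1 == 0 or c1 == n or r1 == 0 or r2 == 0:
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(k, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    take = pmf <= p_obs * (1.0 + 1e-7)
    if take.all():
        return 1.0  # observed table is (tied for) the most probable one
    return min(float(pmf[take].sum()), 1.0)


def assoc_scan(gm: GenotypeMatrix, vt: VariantTable, groups: dict[str, str],
               regions: list[Region] | None = None,
               case_label: str = "case", control_label: str = "control",
               alpha: float = 0.05) -> pd.DataFrame:
    """Fisher-test every SNP intersecting the given regions, ranked by p.

    ``groups`` maps sample id -> label; every sample in the matrix must be
    labelled.  With ``regions`` None all variants are tested.
    """
    missing = [s for s in gm.sample_ids if s not in groups]
    if missing:
        raise DataError(f"assoc_scan: no group label for sample(s) {missing[:3]}...")
    case_ids = [s for s in gm.sample_ids if groups[s] == case_label]
    control_ids = [s for s in gm.sample_ids if groups[s] == control_label]
    if not case_ids or not control_ids:
        raise DataError("assoc_scan: both groups must be non-empty")

    region_of = np.full(vt.n_variants, "", dtype=object)
    if regions is None:
        in_region = np.ones(vt.n_variants, dtype=bool)
    else:
        in_region = np.zeros(vt.n_variants, dtype=bool)
        pos0 = vt.pos - 1
        for r in regions:
            hit = (vt.chrom == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
            in_region |= hit
            label = ",".join(map(str, r.member_ids)) or r.source
            region_of[hit & (region_of == "")] = label
    which = np.flatnonzero(in_region)
    if which.size == 0:
        raise DataError("assoc_scan: no SNP inside the given regions")

    rows = []
    for j in which:
        tab = allele_table(gm, int(j), case_ids, control_ids)
        p = fisher_exact_two_sided(tab)
        maf_case = _group_maf(tab[0])
        maf_ctrl = _group_maf(tab[1])
        rows.append((str(vt.chrom[j]), int(vt.pos[j]), int(j),
                     tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1],
                     maf_case, maf_ctrl, p, region_of[j]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "variant_index",
                                     "case_alt", "case_ref", "ctrl_alt", "ctrl_ref",
                                     "maf_case", "maf_ctrl", "p", "in_region"])
    df["bonferroni_p"] = np.minimum(df["p"] * len(df), 1.0)
    df["significant"] = df["p"] < alpha
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def _group_maf(counts) -> float:
    n = counts.sum()
    if n == 0:
        return float("nan")
    f = counts[0] / n
    return float(min(f, 1.0 - f))
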