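"""Selected-region construction, extension/merging and gene capture.

Selected core SNPs within ``gap_bp`` of each other are clustered into one
region; regions are padded symmetrically (20 kb around iHS cores, 150 kb
around selected windows in the default analysis), clamped to chromosome
bounds, merged where they overlap, and intersected with gene annotation.
All intervals are 0-based half-open; gene capture requires >= 1 bp overlap
and ignores strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ChromSizes
from .errors import DataError


@dataclass
class Region:
    """Half-open genomic interval with provenance."""

    chrom: str
    start: int
    end: int
    source: str = ""  # "tajima" | "ihs"
    member_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"Region: end {self.end} <= start {self.start}")


@dataclass
class GeneInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"GeneInterval {self.gene_id}: end <= start")


def cluster_snps(positions_by_chrom: dict[str, np.ndarray], gap_bp: int = 50_000,
                 source: str = "ihs") -> list[Region]:
    """Cluster sorted selected-SNP positions (1-based bp) into regions.

    Consecutive SNPs at most ``gap_bp`` apart (inclusive) join one region;
    the region spans first to last member SNP, so an isolated SNP yields a
    1-bp region.
    """
    out: list[Region] = []
    for chrom, pos in positions_by_chrom.items():
        pos = np.asarray(pos, dtype=np.int64)
        if len(pos) == 0:
            continue
        if np.any(np.diff(pos) <= 0):
            raise DataError(f"cluster_snps: positions on {chrom} not sorted/unique")
        breaks = np.flatnonzero(np.diff(pos) > gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            members = pos[a:b + 1].tolist()
            out.append(Region(chrom, int(pos[a] - 1), int(pos[b]), source, members))
    return out


def extend_regions(regions: list[Region], pad_bp: int,
                   sizes: ChromSizes) -> list[Region]:
    """Pad regions by ``pad_bp`` both ways, clamp to [0, chrom length),
    and merge overlapping or touching results per chromosome."""
    padded: dict[str, list[Region]] = {}
    for r in regions:
        if r.chrom not in sizes:
            raise DataError(f"extend_regions: {r.chrom!r} missing from ChromSizes")
        start = max(0, r.start - pad_bp)
        end = min(sizes[r.chrom], r.end + pad_bp)
        padded.setdefault(r.chrom, []).append(
            Region(r.chrom, start, end, r.source, list(r.member_ids)))
    out: list[Region] = []
    for chrom in padded:
        rs = sorted(padded[chrom], key=lambda r: (r.start, r.end))
        cur = rs[0]
        for r in rs[1:]:
            if r.start <= cur.end:
                cur = Region(chrom, cur.start, max(cur.end, r.end), cur.source,
                             cur.member_ids + r.member_ids)
            else:
                out.append(cur)
                cur = r
        out.append(cur)
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def overlap_genes(regions: list[Region], genes: list[GeneInterval]):
    """Gene IDs captured by each region (>= 1 bp overlap) plus their union.

    Returns (list of per-region sets aligned with ``regions``, union set).
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.start)
    per_region: list[set[str]] = []
    for r in regions:
        gs = by_chrom.get(r.chrom, [])
        starts = np.array([g.start for g in gs], dtype=np.int64)
        ends = np.array([g.end for g in gs], dtype=np.int64)
        hit = (starts < r.end) & (ends > r.start)
        per_region.append({gs[i].gene_id for i in np.flatnonzero(hit)})
    union: set[str] = set()
    for s in per_region:
        union |= s
    return per_region, union


def intersect_gene_sets(a: set[str], b: set[str]) -> set[str]:
    """Genes flagged by both selection-scan methods."""
    return set(a) & set(b)


def regions_to_bed(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame([(r.chrom, r.start, r.end, r.source) for r in regions],
                        columns=["chrom", "start", "end", "name"])


def read_genes_bed(path) -> list[GeneInterval]:
    """Gene intervals from BED (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise DataError(f"{path}: gene BED needs >= 4 columns (name in column 4)")
    out = []
    for i, row in df.iterrows():
        strand = str(row[5]) if df.shape[1] > 5 else "."
        out.append(GeneInterval(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def read_genes_gff3(path) -> list[GeneInterval]:
    """Gene features from GFF3 (type == 'gene'; ID= or gene_id= attribute)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise DataError(f"{path}: line {ln}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or f"gene_line{ln}"
            # GFF3 is 1-based closed -> 0-based half-open
            out.append(GeneInterval(gid, parts[0], int(parts[3]) - 1, int(parts[4]),
                                    parts[6]))
    return out
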