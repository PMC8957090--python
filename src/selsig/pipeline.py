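"""End-to-end orchestration: simulate/ingest -> filter -> diversity ->
selection scans -> regions -> association, driven by one YAML config.

Stages communicate only through their declared on-disk formats (VCF, TSV,
BED), so any stage can be re-run in isolation.  A single config seed fans
out to per-stage seeds by a fixed hash derivation, so adding a stage never
perturbs the randomness of earlier ones.  Every run writes a manifest
recording the config, package version, input checksums and per-stage
parameters; reruns with identical config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, assoc, diversity, ihs, io, regions as regmod, simulate, tajima
from .containers import ChromSizes
from .errors import ConfigError, DataError, SelsigError

log = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "het", "roh", "ne", "ld", "tajima", "ihs",
          "regions", "assoc")

_KNOWN_KEYS = set(STAGES) | {"seed", "stages", "input"}

DEFAULTS: dict[str, dict] = {
    "simulate": {"n_diploids": 200, "chrom_length": 1_000_000, "mu": 2.5e-7,
                 "rec": 1e-7, "s": 0.0, "sweep_pos": None,
                 "burnin_generations": None, "post_sweep_freq_target": 0.8,
                 "sample_diploids": None},
    "filter": {"maf_min": 0.01, "miss_max": 0.2},
    "het": {},
    "roh": {"win_snp": 50, "win_het": 1, "win_miss": 5, "hit_threshold": 0.05,
            "min_length_kb": 1000.0, "min_density_kb_per_snp": 100.0,
            "max_gap_kb": 1000.0, "min_snp_per_roh": 50},
    "ne": {"maf_min": 0.05},
    "ld": {"max_dist_bp": 300_000, "bin_width_bp": 25_000},
    "tajima": {"window_bp": 50_000, "min_sites": 3, "tail": 0.01, "pad_bp": 150_000},
    "ihs": {"maf_min": 0.05, "cutoff": 0.05, "max_gap_bp": 200_000, "n_bins": 50,
            "z_thresh": 3.0, "cluster_gap_bp": 50_000, "pad_bp": 20_000},
    "assoc": {"alpha": 0.05, "case_label": "case", "control_label": "control"},
}


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31 - 1)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("config must set 'seed'")
    stages = cfg.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    for st in set(cfg) & set(STAGES):
        params = cfg[st] or {}
        unknown = set(params) - set(DEFAULTS[st])
        if unknown:
            raise ConfigError(f"unknown parameter(s) for stage {st!r}: {sorted(unknown)}")
    inp = cfg.get("input") or {}
    unknown = set(inp) - {"vcf", "chrom_sizes", "genes", "groups"}
    if unknown:
        raise ConfigError(f"unknown input key(s): {sorted(unknown)}")
    return cfg


def _params(cfg: dict, stage: str) -> dict:
    out = dict(DEFAULTS[stage])
    out.update(cfg.get(stage) or {})
    return out


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(stage: str, params: dict) -> str:
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# selsig {__version__} stage={stage} {kv}\n"


def _write_tsv(df, path: Path, stage: str, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, params))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_all(cfg: dict, outdir) -> Path:
    """Execute the configured stages in dependency order; returns outdir."""
    cfg = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg.get("stages", list(STAGES))
    inp = cfg.get("input") or {}
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}, "inputs": {}}
    state = {"stage": "setup"}

    def stage_on(name: str) -> bool:
        return name in stages

    try:
        # --- acquire inputs -------------------------------------------------
        state["stage"] = "simulate"
        if stage_on("simulate"):
            p = _params(cfg, "simulate")
            sample_n = p.pop("sample_diploids")
            sim_cfg = simulate.SimConfig(seed=derive_seed(seed, "simulate"), **p)
            vt, hp, truth = simulate.simulate_wright_fisher(sim_cfg)
            if sample_n:
                rng = np.random.default_rng(derive_seed(seed, "simulate.sample"))
                hp = simulate.sample_individuals(hp, sample_n, rng)
                keep = np.isin(vt.pos, hp.positions)
                vt = vt.take(keep)
            gm = hp.to_genotypes()
            sizes = ChromSizes({sim_cfg.chrom_name: sim_cfg.chrom_length})
            vcf_path = outdir / "simulated.vcf"
            io.write_vcf(vt, vcf_path, gm=gm, hp=hp, sizes=sizes)
            io.write_chrom_sizes(sizes, outdir / "chrom.sizes")
            with open(outdir / "truth.tsv", "w") as fh:
                fh.write(_header("simulate", {"seed": sim_cfg.seed}))
                fh.write(f"sweep_pos\t{truth.sweep_pos}\nsweep_freq\t{truth.sweep_freq}\n")
            manifest["stages"]["simulate"] = {"params": {**p, "sample_diploids": sample_n},
                                              "n_variants": vt.n_variants}
        else:
            if "vcf" not in inp:
                raise ConfigError("no 'simulate' stage and no input.vcf given")
            vcf_path = Path(inp["vcf"])
            if "chrom_sizes" in inp:
                sizes = io.read_chrom_sizes(inp["chrom_sizes"])
            else:
                sizes = None

        for key, pth in inp.items():
            try:
                manifest["inputs"][key] = {"path": str(pth), "sha256": _checksum(Path(pth))}
            except OSError as exc:
                raise ConfigError(f"input {key!r} not readable: {exc}") from exc
        if stage_on("simulate"):
            manifest["inputs"]["vcf"] = {"path": str(vcf_path),
                                         "sha256": _checksum(vcf_path)}

        vt, gm, hp = io.read_vcf(vcf_path)
        if not stage_on("simulate") and "chrom_sizes" in inp:
            sizes = io.read_chrom_sizes(inp["chrom_sizes"])

        # --- filter ---------------------------------------------------------
        state["stage"] = "filter"
        if stage_on("filter"):
            p = _params(cfg, "filter")
            keep = io.filter_variants(vt, gm, **p)
            vt, gm, hp = io.subset(vt, gm, hp, keep)
            filtered = outdir / "filtered.vcf"
            io.write_vcf(vt, filtered, gm=gm, hp=hp, sizes=sizes)
            manifest["stages"]["filter"] = {"params": p, "n_kept": int(keep.sum()),
                                            "n_total": int(len(keep))}
            vt, gm, hp = io.read_vcf(filtered)  # downstream consumes the file

        # --- diversity ------------------------------------------------------
        state["stage"] = "het"
        if stage_on("het"):
            import pandas as pd
            h = diversity.het_rate(gm)
            _write_tsv(pd.DataFrame({"sample": gm.sample_ids, "het_rate": h}),
                       outdir / "het.tsv", "het", {})
            manifest["stages"]["het"] = {"mean_het": float(np.nanmean(h))}

        state["stage"] = "roh"
        if stage_on("roh"):
            if sizes is None:
                raise ConfigError("roh stage requires chromosome sizes "
                                  "(input.chrom_sizes or the simulate stage)")
            import pandas as pd
            p = _params(cfg, "roh")
            segs = diversity.detect_roh(vt, gm, diversity.RohParams(**p))
            _write_tsv(diversity.roh_to_bed(segs), outdir / "roh.bed", "roh", p)
            fr = diversity.f_roh(segs, sizes, sample_ids=gm.sample_ids)
            _write_tsv(pd.DataFrame({"sample": list(fr), "f_roh": list(fr.values())}),
                       outdir / "froh.tsv", "roh", p)
            manifest["stages"]["roh"] = {"params": p, "n_segments": len(segs)}

        state["stage"] = "ne"
        if stage_on("ne"):
            import pandas as pd
            p = _params(cfg, "ne")
            est = diversity.ne_het_excess(gm, **p)
            _write_tsv(pd.DataFrame([{"d_mean": est.d_mean, "ne": est.ne,
                                      "ci_low": est.ci_low, "ci_high": est.ci_high,
                                      "n_loci_used": est.n_loci_used}]),
                       outdir / "ne.tsv", "ne", p)
            manifest["stages"]["ne"] = {"params": p, "ne": est.ne, "d": est.d_mean}

        state["stage"] = "ld"
        if stage_on("ld"):
            if hp is None:
                raise DataError("ld stage requires phased genotypes")
            p = _params(cfg, "ld")
            _write_tsv(diversity.ld_r2_decay(hp, **p), outdir / "ld.tsv", "ld", p)
            manifest["stages"]["ld"] = {"params": p}

        # --- selection scans ------------------------------------------------
        sel_windows = None
        tajima_regions: list = []
        state["stage"] = "tajima"
        if stage_on("tajima"):
            p = _params(cfg, "tajima")
            stats = tajima.window_stats(vt, gm=gm, sizes=sizes,
                                        window_bp=p["window_bp"],
                                        min_sites=p["min_sites"])
            _write_tsv(stats, outdir / "tajima_windows.tsv", "tajima", p)
            try:
                sel, lo, hi = tajima.select_windows(stats, tail=p["tail"])
            except DataError as exc:  # too few windows for the requested tail
                log.warning("tajima: selection skipped (%s)", exc)
                sel = np.zeros(len(stats), dtype=bool)
                lo = hi = float("nan")
            sel_windows = stats[sel]
            win_regions = [regmod.Region(str(r.chrom), int(r.start), int(r.end),
                                         "tajima", [int(r.window_index)])
                           for r in sel_windows.itertuples()]
            if sizes is not None and win_regions:
                tajima_regions = regmod.extend_regions(win_regions, p["pad_bp"], sizes)
            _write_tsv(regmod.regions_to_bed(win_regions),
                       outdir / "tajima_selected.bed", "tajima", p)
            _write_tsv(regmod.regions_to_bed(tajima_regions),
                       outdir / "tajima_regions.bed", "tajima", p)
            manifest["stages"]["tajima"] = {"params": p, "low": lo, "high": hi,
                                            "n_selected": int(sel.sum())}

        ihs_regions: list = []
        state["stage"] = "ihs"
        if stage_on("ihs"):
            if hp is None:
                raise DataError("ihs stage requires phased genotypes")
            p = _params(cfg, "ihs")
            rec = ihs.ihs_scan(hp, vt, maf_min=p["maf_min"], cutoff=p["cutoff"],
                               max_gap_bp=p["max_gap_bp"])
            rec = ihs.standardize_ihs(rec, n_bins=p["n_bins"])
            rec = ihs.select_cores(rec, z_thresh=p["z_thresh"])
            _write_tsv(rec, outdir / "ihs.tsv", "ihs", p)
            hits = rec[rec["selected"]]
            by_chrom = {c: np.sort(g["pos"].to_numpy())
                        for c, g in hits.groupby("chrom")} if len(hits) else {}
            core_regions = regmod.cluster_snps(by_chrom, gap_bp=p["cluster_gap_bp"])
            if sizes is not None and core_regions:
                ihs_regions = regmod.extend_regions(core_regions, p["pad_bp"], sizes)
            _write_tsv(regmod.regions_to_bed(ihs_regions),
                       outdir / "ihs_regions.bed", "ihs", p)
            manifest["stages"]["ihs"] = {"params": p, "n_cores": len(rec),
                                         "n_selected": int(rec["selected"].sum())}

        # --- gene capture ---------------------------------------------------
        state["stage"] = "regions"
        if stage_on("regions"):
            genes: list = []
            if "genes" in inp:
                gp = str(inp["genes"])
                genes = (regmod.read_genes_gff3(gp) if gp.endswith((".gff", ".gff3"))
                         else regmod.read_genes_bed(gp))
            _, genes_t = regmod.overlap_genes(tajima_regions, genes)
            _, genes_i = regmod.overlap_genes(ihs_regions, genes)
            common = regmod.intersect_gene_sets(genes_t, genes_i)
            for name, gs in (("genes_tajima.txt", genes_t), ("genes_ihs.txt", genes_i),
                             ("genes_common.txt", common)):
                with open(outdir / name, "w") as fh:
                    fh.writelines(f"{g}\n" for g in sorted(gs))
            manifest["stages"]["regions"] = {"n_genes_tajima": len(genes_t),
                                             "n_genes_ihs": len(genes_i),
                                             "n_common": len(common)}

        # --- association ----------------------------------------------------
        state["stage"] = "assoc"
        if stage_on("assoc"):
            if "groups" not in inp:
                raise ConfigError("assoc stage requires input.groups (sample\tgroup TSV)")
            p = _params(cfg, "assoc")
            groups = io.read_groups(inp["groups"])
            gene_regions = None
            if "genes" in inp:
                gp = str(inp["genes"])
                genes = (regmod.read_genes_gff3(gp) if gp.endswith((".gff", ".gff3"))
                         else regmod.read_genes_bed(gp))
                gene_regions = [regmod.Region(g.chrom, g.start, g.end, "gene", [g.gene_id])
                                for g in genes]
            res = assoc.assoc_scan(gm, vt, groups, regions=gene_regions,
                                   case_label=p["case_label"],
                                   control_label=p["control_label"], alpha=p["alpha"])
            _write_tsv(res, outdir / "assoc.tsv", "assoc", p)
            manifest["stages"]["assoc"] = {"params": p,
                                           "n_significant": int(res["significant"].sum())}
    except SelsigError as exc:
        raise type(exc)(f"stage {state['stage']!r} failed: {exc}") from exc

    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return outdir
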