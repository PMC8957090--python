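# selsig

Within-population selection-signature and genetic-diversity analysis for
diploid SNP data, aimed at livestock and other small resequencing panels
(tens of animals, whole-genome SNP calls). The package covers the standard
single-population workflow:

- **Variant handling** — biallelic-SNP ingest from VCF, the usual MAF ≥ 0.01
  / missingness ≤ 0.2 filters, Ts/Tv summary (`selsig.io`).
- **Diversity and inbreeding** — per-individual heterozygosity
  (N(NM) − O(HOM))/N(NM); PLINK-style scanning-window runs of homozygosity
  and the genomic inbreeding coefficient F_ROH = Σᵢ ROHᵢ / L_auto;
  heterozygote-excess effective size Ne = 1/(2D) + 1/(2(D+1)) with Selander's
  D = (H_obs − H_exp)/H_exp weighted across loci; binned LD (r²) decay
  (`selsig.diversity`).
- **Selection scans** — Tajima's D in non-overlapping 50-kb windows with
  empirical 1% tail selection, and the integrated haplotype score:
  uiHS = ln(iHH_A/iHH_D) from trapezoid-integrated EHH decay curves,
  standardized within derived-allele-frequency bins, selected at |Z| ≥ 3
  (`selsig.tajima`, `selsig.ihs`).
- **Regions and genes** — clustering of selected SNPs (≤ 50 kb joins),
  symmetric extension (±20 kb around iHS cores, ±150 kb around selected
  windows), interval merging, gene capture and two-method gene-set
  intersection (`selsig.regions`).
- **Association** — allelic two-sided Fisher's exact tests of case/control
  SNPs inside candidate-gene regions (`selsig.assoc`).
- **Synthetic data** — a forward-time diploid Wright–Fisher simulator with
  recombination, infinite-sites mutation and additive selective sweeps, plus
  targeted generators (heterozygote-excess genotypes, implanted ROH tracts,
  case/control panels), so the whole workflow is testable without any
  external download (`selsig.simulate`).

Everything is exposed both as a library and through the `selsig` command
line (`simulate`, `filter`, `het`, `roh`, `ne`, `ld`, `tajima`, `ihs`,
`regions`, `assoc`, `run-all`).

## Worked example

Simulate a 40-animal sample from a sheep-like population that just went
through a partial selective sweep, and scan it:

```python
import numpy as np
from selsig import diversity, ihs, tajima
from selsig.containers import ChromSizes
from selsig.simulate import SimConfig, sample_individuals, simulate_wright_fisher

vt, hp, truth = simulate_wright_fisher(
    SimConfig(seed=60, chrom_length=3_000_000, s=0.1,
              sweep_pos=1_525_000, post_sweep_freq_target=0.8))
panel = sample_individuals(hp, 40, np.random.default_rng(1))
svt = vt.take(np.isin(vt.pos, panel.positions))

print(f"{svt.n_variants} SNPs; sweep reached {truth.sweep_freq:.2f}")
het = diversity.het_rate(panel.to_genotypes())
print(f"mean heterozygosity {het.mean():.3f}")

win = tajima.window_stats(svt, hp=panel, sizes=ChromSizes({"1": 3_000_000}))
sweep_win = win[win.window_index == 1_525_000 // 50_000]
print(f"Tajima's D in the sweep window: {float(sweep_win.d.iloc[0]):.2f} "
      f"(genome-wide mean {np.nanmean(win.d):.2f})")

rec = ihs.select_cores(ihs.standardize_ihs(ihs.ihs_scan(panel, svt), n_bins=10))
near = rec[np.abs(rec.pos - 1_525_000) <= 50_000]
print(f"{len(rec)} iHS cores; min uiHS within 50 kb of the sweep: "
      f"{near.uihs.min():.2f}")
```

Output:

```
2768 SNPs; sweep reached 0.80
mean heterozygosity 0.198
Tajima's D in the sweep window: -2.03 (genome-wide mean -0.11)
1187 iHS cores; min uiHS within 50 kb of the sweep: -2.95
```

The sweep window's D sits well below the genome-wide mean (diversity was
dragged down by hitchhiking), and the most negative unstandardized iHS near
the swept site reflects the long shared haplotype of the derived allele.
At this deliberately small population size the contrast between swept and
neutral haplotypes is compressed; see `docs/methods.md` for what the
simulator's scale does and does not establish.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it simulates a neutral and a sweep chromosome, draws a 40-diploid sample,
and executes the full statistics stack (heterozygosity, Ne, windowed
Tajima's D, iHS). Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.
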