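# Methods

This note documents the models and numerical choices behind `selsig`: what
each statistic computes, which parameters matter, what the synthetic-data
generator emulates, and where the desk-scale setting limits what a green
test can establish.

## Coordinates and containers

Variant positions keep the VCF's 1-based convention; every derived interval
(analysis windows, ROH segments, selected regions, BED output) is 0-based
half-open. Genotypes are alt-allele dosages in {0,1,2} with −1 for missing;
haplotypes are binary with 1 = derived under the current polarity. Simulated
panels are exactly polarized because every polymorphism is a tracked
mutation; for real VCFs the default polarity is ref = ancestral, and an
ancestral-allele table can be supplied.

## Variant filtering

A variant is kept when it is a biallelic SNP with minor-allele frequency
≥ 0.01 (computed from non-missing allele counts, PLINK-style) and a missing
fraction ≤ 0.2. Multi-allelic records and indels are dropped at ingest.

## Heterozygosity, ROH and F_ROH

Per-sample heterozygosity is (N_nonmissing − N_homozygous)/N_nonmissing.

ROH detection follows the scanning-window scheme: windows of `win_snp = 50`
consecutive SNPs are homozygous when they contain ≤ 1 heterozygous and ≤ 5
missing calls; a SNP belongs to a run when ≥ 5% of the windows spanning it
are homozygous (`hit_threshold = 0.05`, the reading of the "0.05 missing
calls allowed per window" parameter as the PLINK window hit threshold, since
per-window missing calls are already governed by their own parameter).
Maximal flagged runs become segments subject to: length ≥ 1000 kb, ≥ 50 SNPs
(`min_snp_per_roh`, unstated upstream, configurable), inter-SNP gap ≤ 1000 kb
(`max_gap_kb`, likewise configurable), and density ≤ 100 kb/SNP. Boundary
accuracy is limited to about one scanning-window span (50 SNPs), which at
1 SNP/10 kb is ±500 kb; the recovery tests assert exactly that.

F_ROH is the summed autosomal segment length divided by the total autosome
length; X-chromosome segments are excluded by the autosome flags in the
chromosome-sizes table. Heterozygosity and Ne use all loaded chromosomes
(an all-female sample makes X diploid), F_ROH autosomes only.

## Heterozygote-excess Ne

Per locus j with N_j non-missing diploids: H_obs is the heterozygote
fraction and H_exp = 2p̂q̂·2N_j/(2N_j−1) (Levene's small-sample expectation;
a `levene=False` toggle gives plain 2p̂q̂). Selander's index
D_j = (H_obs − H_exp)/H_exp is combined across loci as the weighted mean
with w_j = N_j(n_j−1)/n_j (n_j = 2 alleles), and

    Ne = 1/(2D) + 1/(2(D+1)),   D ≤ 0 → Ne = +∞.

The 95% CI is a leave-one-locus-out jackknife on D mapped through the
monotone-decreasing Ne transform. Loci are screened at MAF ≥ 0.05.

**Known limitation.** D̂ is a mean of per-locus ratios whose noisy
denominator (p̂q̂) is positively correlated with the numerator; at n = 50
this biases D̂ downward away from p = 0.5 (Monte Carlo: E[D̂] ≈ 0.010, 0.036,
0.049 at p = 0.1, 0.3, 0.5 for a true D = 0.05). This is a property of the
method's own formula — a ratio-of-sums estimator would remove it but would
be a different method — so small-panel D̂ (and hence Ne) should be read as
biased toward zero excess, and the parameter-recovery acceptance check
fails honestly at n = 50 over broad frequency spectra.

## Windowed Tajima's D

Windows are non-overlapping, 50 kb wide and anchored at coordinate 0 of
each chromosome. Per segregating site, diversity is 2p̂q̂·n/(n−1) with n the
non-missing allele count at the site; summed over a window this equals the
mean pairwise Hamming distance exactly when no data are missing (an
invariant the tests assert at 1e-9). D uses the 1989 variance constants
with the fixed panel size n = 2 × samples even under missingness (recorded
in output metadata). Windows with S < 3 (`min_sites`) get an undefined D
and are excluded from quantile computation. Selected windows are those at
or beyond the empirical 1% quantiles (linear interpolation, ties included);
a degenerate all-equal distribution selects nothing and warns.

## EHH and iHS

For a core allele, EHH at marker distance x is Σ_g C(k_g,2)/C(n_c,2) over
extended-haplotype groups among the carriers. The walk stops when EHH drops
below `cutoff = 0.05`, at a chromosome edge, or at an inter-marker gap
> 200 kb; iHH is the trapezoid integral over physical distance (no genetic
map; constant-rate scaling cancels in the within-bin standardization), with
the final sub-cutoff segment cut at the linear-interpolated crossing. Cores
still above the cutoff at a boundary are "truncated" and excluded by
default (`keep_truncated` retains them). uiHS = ln(iHH_A/iHH_D) is computed
for cores with MAF ≥ 0.05 and ≥ 2 carriers of each allele, standardized
within 50 equal-width derived-allele-frequency bins (occupied bins with < 2
records merge into their nearest neighbour), and |Z| ≥ 3.0 (inclusive)
flags selection. Standardization is a genome-wide operation: on data
dominated by a single swept region it should be pooled with the rest of the
genome, otherwise the sweep normalizes itself away.

The inner EHH walk is compiled with numba; a literal pair-enumeration
oracle in the test suite pins its semantics at 1e-9.

## Selected regions, genes, association

Selected iHS cores within 50 kb of each other (inclusive) cluster into one
region spanning first to last member SNP; iHS regions are padded ±20 kb and
selected Tajima windows ±150 kb (giving 350-kb intervals from 50-kb
windows), clamped to chromosome bounds and merged. Gene capture requires
≥ 1 bp of overlap, ignoring strand; gene sets from the two scans are
intersected. The case/control test is allelic: each non-missing diploid
contributes two alleles to a 2×2 table whose two-sided Fisher p is the sum
of hypergeometric point probabilities ≤ the observed one (relative guard
1e-7 against floating-point ties). Raw p-values are reported (candidate-
gene design); a Bonferroni column is emitted alongside.

## The Wright–Fisher generator

Discrete generations, N diploids, random mating with selfing allowed.
Gametes recombine with Poisson(rec·L) crossovers at uniform positions and
mutate with Poisson(mu·L) new sites on the integer-bp grid (collisions
re-drawn — infinite sites, biallelic by construction). Selection is
additive (fitnesses 1, 1+s/2, 1+s). Sweep runs inject one copy after
burn-in, restart from the saved burn-in state on loss (conditioning on
establishment), and stop at the target frequency. Burn-in is 10N
generations from a monomorphic start, which approximates mutation–drift
equilibrium at this scale. All randomness flows from the single config
seed; the generation loop is a numba kernel seeded per call, and identical
configs reproduce bit-identical panels.

Default desk-scale world: N = 200, L = 1 Mb, mu = 2.5e-7 and rec = 1e-7
per bp per generation, i.e. θ = 2e-4/bp (about one segregating site per kb
in an 80-haplotype sample, a rescaling of sheep-like diversity) and
ρ = 8e-5/bp. Mutation is scaled harder than recombination so that haplotype
structure — the substrate of EHH — remains resolvable: with ρ = θ the
hitchhiking footprint of an Ns = 20 sweep barely exceeds one 50-kb window.
Analyses mimic the target study design by sampling 40 diploids from the
population.

**What the desk scale does not establish.** With N = 200 and s = 0.1
(Ns = 20), a sweep to frequency 0.7–0.9 takes ~150 generations while
neutral drift carries an allele to the same frequency in ~400–800; the
expected uiHS shift, ln(T_neutral/T_sweep) ≈ 1, is comparable to the
neutral uiHS spread, and an incomplete sweep leaves hitchhikers at
intermediate frequency, which raises π and keeps the sweep window's D out
of the extreme tail. Green calibration tests therefore establish neutral
behaviour (mean windowed D ≈ 0, normal-like standardized iHS tails) and
*qualitative* sweep signals (depressed D, negative uiHS at the site), not
high-power detection at genome-wide thresholds — real applications of
these statistics rely on Ns several orders of magnitude larger. The
acceptance suite states the strict joint-detection property anyway and
reports its measured rate.

## Pipeline

`run-all` executes the configured stages in dependency order, exchanging
data only through on-disk formats (VCF/TSV/BED), so every stage can be
re-run in isolation. The config seed fans out to per-stage seeds through a
fixed hash, so adding a stage never perturbs earlier randomness. The
manifest records the package version, full config, input checksums and
per-stage parameters; identical configs and inputs give byte-identical
outputs. Exit codes: 0 success, 2 configuration error, 3 data error.

## Test-suite scaling

Simulation-heavy checks are sized to run on one CPU in minutes: 50 neutral
1-Mb replicates for calibration, 20 sweep replicates on 3-Mb chromosomes
(the sweep site at a window centre, 1.4 Mb from each edge — beyond the EHH
truncation horizon), a shared neutral background for genome-wide pooling,
and brute-force oracles confined to panels small enough for literal
enumeration.
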