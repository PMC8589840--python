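# rtgloh

Analysis toolkit for **return-to-growth (RTG) recombination** in diploid
yeast hybrids.

Hybrids between diverged *Saccharomyces* lineages are often sterile: meiosis
fails through mutational defects, rearranged karyotypes or high sequence
divergence between the parental subgenomes. If meiosis is aborted after
Spo11-induced double-strand breaks (DSBs) but before the first division, the
cell repairs the breaks off the homolog, buds, and segregates its recombined
chromatids mitotically — producing a mother/daughter pair of diploids with
complementary **loss-of-heterozygosity (LOH)** blocks. Crossover (CO) repair
yields *terminal* LOH reaching a chromosome end; non-crossover conversion
(NCO) yields *interstitial* LOH. This para-meiosis lets sterile hybrids
recombine, and the resulting LOH genotypes support linkage mapping where a
cross is impossible.

The package is aimed at people analysing marker-level genotype data from
such experiments (or building methods for them). It provides:

- **`rtgloh.markers`** — genome layout, biallelic marker maps, genotype
  tracks (`HET`, `HOM_P1`, `HOM_P2`, `MISSING`), hotspot interval tracks,
  subtelomere masking, TSV/BED readers and writers (1-based inclusive
  internally; BED converted at the boundary).
- **`rtgloh.simulate`** — a mechanistic RTG generator with full ground
  truth: Poisson DSBs placed hotspot-weighted, per-mismatch heteroduplex
  rejection 1 − (1 − ρ)^m (the Msh2-dependent anti-recombination barrier,
  switched off by `msh2_null`), CO/NCO resolution, 2+2 mitotic-like
  chromatid segregation, mitotic-background T0 controls, and phenotypes
  with planted QTLs.
- **`rtgloh.loh`** — LOH segmentation exactly as defined for marker data:
  maximal same-parent homozygous runs (single-marker events included),
  first/last and midpoint start/end coordinates, terminal/interstitial
  classes, per-clone summaries, breakpoint regions and marker windows,
  mother/daughter reciprocity, rank-sum / Fligner–Killeen clone-set
  comparisons.
- **`rtgloh.association`** — permutation overlap test of breakpoint regions
  against recombination hotspots (per-chromosome length-preserving
  randomisation, empirical p with +1 correction, alternative "greater"),
  the local Z profile over shifts in a window W = 10·S_m with step S_m/2,
  and the relative-intensity comparison RI = H/max(H) at configurable
  paddings.
- **`rtgloh.rate_assay`** — URA3-loss LOH rates R_T = 100·CFU_5FOA/CFU_YPD,
  the LOH ratio R_T6/R_T0 and LOH difference R_T6 − R_T0, replicate
  aggregation and the progression–recombination Pearson correlation.
- **`rtgloh.qtl`** — D_r = log2(D) − log2(D_control) growth normalisation,
  growth/heterosis classification, marker filtering, single-marker LOD scans
  (LOD = (n/2)·log10(RSS₀/RSS₁), additive or factor coding), genome-wide
  permutation thresholds and LOD-drop support intervals.

A `rtgloh` command-line tool wraps the library
(`simulate`, `call-loh`, `associate`, `rate`, `qtl`).

## Worked example

Simulate two RTG pairs on the built-in yeast-like genome, call their LOH
landscape, and compute rate metrics from a CFU table:

```sh
rtgloh simulate --theta 0.0004 --n-pairs 2 --seed 3 --out-dir sim
rtgloh call-loh --genotypes sim/rtg000_mother.tsv --genotypes sim/rtg000_daughter.tsv \
    --markers sim/markers.tsv --layout sim/layout.tsv --out loh
head -2 loh/summaries.tsv
```

```
clone	n_interstitial	n_terminal	frac_markers	frac_p1	frac_p2	frac_genome
rtg000_mother	21	6	0.18649861140781884	0.13715018158513137	0.04934842982268746	0.1712799270980035
```

The mother clone carries 21 interstitial and 6 terminal LOH events covering
18.6% of its (non-masked) markers — 13.7% homozygous for parent 1 and 4.9%
for parent 2; the two parental fractions always add up to the total. With a
CFU table (`strain, timepoint, replicate, cfu_5foa, cfu_ypd`):

```sh
rtgloh rate --cfu cfu.tsv --out rate && cat rate/loh_metrics.tsv
```

```
strain	r_t0	r_t6	ratio	difference	ln_ratio	p_increase	test	negative_difference
s1	0.11666666666666667	2.147869674185464	18.410311493018263	2.0312030075187972	2.9129109148747037	0.014204202566054414	one-sided Welch t on log rates	False
```

Here 0.117% of T0 cells and 2.15% of T6 cells had lost the URA3 marker: an
18.4-fold LOH ratio and a 2.03 percentage-point LOH difference, with the
one-sided test confirming the RTG-induced increase (p ≈ 0.014).

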