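# Methods

## The RTG recombination model

The simulator emulates a single aborted meiosis in a diploid hybrid. After
meiotic S-phase every chromosome exists as four chromatids, two carrying
each parental haplotype; at every marker a chromatid holds either the
parent-1 or parent-2 allele. The generative steps are:

1. **DSB formation.** The cell draws a Poisson number of double-strand
   breaks (`dsb_rate`, default 160 — the scale of Spo11 activity in a
   meiotic budding-yeast cell). Each break lands inside a hotspot interval
   with probability `hotspot_weight` (default 0.8), choosing the hotspot
   proportionally to its hit count H and the position uniformly within it;
   otherwise it is uniform over the genome (chromosome chosen by length).
2. **Anti-recombination.** Repair proceeds through a heteroduplex spanning
   the repair tract (geometric length, `tract_mean` default 2 kb —
   literature-scale for yeast conversion tracts). Every marker in the
   tract is a mismatch; the event aborts with probability
   1 − (1 − ρ)^mismatches (`rho`, default 0.1 per mismatch). This is the
   simplest per-mismatch rejection model of Msh2-dependent heteroduplex
   rejection; `msh2_null=True` sets ρ = 0. It reproduces the qualitative
   behaviour that matters: recombination falls with local heterozygosity
   and recovers when mismatch repair is inactivated. No quantitative ρ is
   asserted — the real rejection curve is not a published constant.
3. **Resolution.** A surviving break becomes a crossover with probability
   `p_co` (default 0.05), exchanging everything distal to the break between
   one chromatid of each homolog; otherwise a one-way conversion copies the
   donor alleles over the tract onto the recipient chromatid. The default
   p_co reflects the strongly interstitial-biased event spectrum seen in
   RTG clones (roughly one terminal event per ten interstitial ones).
4. **Segregation.** The mother keeps one chromatid of each homolog per
   chromosome, chosen uniformly among the four valid mitotic-like splits;
   the daughter receives the complement. No further replication occurs.
   Genotypes follow directly from each cell's two chromatids.

**Centromere behaviour.** RTG clones keep their centromeres heterozygous
(pericentromeres are recombination-cold, and mitotic-like segregation keeps
one centromere per homolog). The simulator enforces this mechanistically:
DSBs are suppressed in a zone extending `cen_radius` (default 10 kb) from
the centromere *and always past the nearest marker on each side*, and both
crossover exchanges and conversion tracts grow distally, away from the
centromere. The extension past the flanking marker is this package's
choice: with sparse marker maps a radius alone would occasionally allow a
break between the centromere and its nearest marker, homozygosing a marker
that the data would call "centromere-flanking". With this construction
centromere-flanking heterozygosity is exact by design, which is what the
test suite asserts.

**Ground truth.** Each pair records its resolved events (kind, position,
chromatids, conversion tract) and two derived truths: (a) *truth
segments* — the maximal homozygous marker runs per cell computed directly
from the chromatid arrays, the deterministic projection of the events onto
the marker map (individual events can overlap on an arm, so events and
maximal runs are not 1:1); and (b) the marker indices whose four-chromatid
allele dosage deviates from 2:2. Crossovers conserve dosage exactly;
only net conversions break it, so (b) is precisely the set of
non-reciprocal markers a mother/daughter comparison should flag.

**Marker maps and hotspots.** Marker positions follow a Bernoulli(θ)
per-bp process (geometric gaps). The built-in layout is a yeast-like
16-chromosome genome (~12.1 Mb, approximate *S. cerevisiae* lengths and
centromere positions) with a configurable 20 kb subtelomeric mask per end —
the mask length is a configuration default, not a published constant. The
synthetic hotspot generator defaults to ~300 hotspots/Mb of ~500 bp with
exponential-tailed hit counts, the density scale of the genome-wide Spo11
DSB map. The default θ = 4.2 × 10⁻⁴ yields ≈ 5,000 markers, the panel size
used throughout the tests; real intra- and interspecies hybrids span
roughly θ ≈ 10⁻³–10⁻²/10⁻¹ and are exercised explicitly in the
anti-recombination checks.

**What the generator does not emulate.** No sequence-level reads, no
CNVs/aneuploidies or structural variants, no chromatid interference, no
meiotic completion, no selection on the recombinants. Passing tests
therefore demonstrate the internal consistency of caller, statistics and
simulator under this mechanism — not calling accuracy on read-level noise,
mapping artefacts or deletions masquerading as LOH (which require
read-depth evidence this package does not consume).

## LOH calling

Maximal runs of consecutive markers with the same homozygous genotype form
one segment. Conventions, where the underlying definitions are silent:

- MISSING calls are transparent — they neither break nor support a run; a
  run consisting only of MISSING markers is no event. An optional
  `max_gap` (bp, default unlimited) splits runs bridged by long gaps.
- A HOM_P1 run immediately followed by HOM_P2 splits into two segments
  whose shared breakpoint is the midpoint of the adjacent opposite-parent
  markers.
- *Terminal* means the run reaches the outermost non-masked informative
  marker of the chromosome (the callable arm end); otherwise the segment
  is *interstitial*. Masked subtelomeric markers never define the extent.
- Two coordinate systems per segment: `first`/`last` are the positions of
  the run's own terminal markers; `start`/`end` are midpoints to the
  nearest informative marker outside the run, clamped to `first`/`last`
  at an arm end.
- Whole-chromosome homozygosity (which would imply LOH across the
  centromere) is emitted as a single flagged segment, not silently split.

Breakpoint regions span from the outermost homozygous marker of a segment
to the nearest flanking marker outside it (two per interstitial segment,
one per terminal), and carry the ≤ k nearest heterozygous and ≤ k nearest
homozygous marker positions (k default 5) for local-heterozygosity
comparisons.

## Breakpoint–hotspot association

The overlap statistic counts query regions intersecting ≥ 1 reference
region (closed intervals, ≥ 1 bp). The null re-places each query region
uniformly at random on its own chromosome, preserving its length and never
crossing a chromosome end; regions may overlap each other. This is the
simplest length-preserving randomisation consistent with a permutation
framework and is stated explicitly for reproducibility. The empirical p
uses the +1 correction, so p ≥ 1/(ntimes+1) and is never 0; a degenerate
null (SD 0) yields Z = NaN with a flag and p from the same formula. The
local Z profile shifts the reference set rigidly over
[−5·S_m, +5·S_m] in steps of S_m/2 (S_m = mean reference-region length),
truncating at chromosome ends (circular wrapping behind a flag). The
relative-intensity report compares RI = H/max(H) between hotspots
overlapping and not overlapping padded breakpoint regions with a one-sided
rank-sum test — the comparison itself is standard; the choice of rank-sum
is this package's and is recorded in the report object.

Being a count statistic, the permutation test is slightly conservative for
small region sets (ties at the observed value inflate the corrected p).
Calibration near the nominal level needs enough regions for the null count
to be effectively continuous; the calibration checks use 300 regions
against a genome-wide-density hotspot track, where the type-I error sits
within the binomial band around 5%.

## Rate assay

R_T = 100·CFU_5FOA/CFU_YPD (percent of plated cells that lost URA3). The
LOH ratio R_T6/R_T0 and difference R_T6 − R_T0 are computed on replicate
means (matching how replicate averages are reported); per-replicate ratios
are additionally emitted in paired mode. Significance of the T6 increase:
one-sided Welch t on log-transformed rates (the log stabilises the
multiplicative replicate CV), paired or unpaired, with a one-sided
rank-sum fallback when any rate is 0; the test used is recorded in the
result. A negative mean difference is flagged rather than suppressed. The
progression correlation (Pearson, two-sided) excludes records with
non-positive LOH difference before correlating — they cannot be placed on
the log scale and would otherwise bias the fit — and correlates the
difference on the log scale and the ln-ratio directly.

## QTL mapping

Phenotypes are D_r = log2(D) − log2(D_control,local). Growth classes
relative to the ancestral hybrid use the fixed thresholds: highly inferior
D_r ≥ 1, inferior 0.25 ≤ D_r < 1, neutral |D_r| < 0.25, superior
−1 < D_r ≤ −0.25, highly superior D_r ≤ −1 — at |D_r| = 1 the more extreme
label wins, at |D_r| = 0.25 the non-neutral one. Heterosis calls use
one-sided Welch tests against each parent at α = 0.05 (worse-parent =
significantly slower than both; best-parent = significantly faster than
both; missing parent data → not evaluable).

Markers with no genotype in any clone, or homozygous in fewer than two
clones, are removed before scanning (a single homozygous sample cannot
support linkage; an all-heterozygous marker has no variance). The scan is
single-marker regression with LOD = (n/2)·log10(RSS₀/RSS₁), computed from
sufficient statistics per marker with per-marker missing-genotype masking;
clones with missing phenotypes are dropped, never imputed. Additive coding
(HET 0, HOM_P1 +1, HOM_P2 −1) is the default since an RTG LOH panel is not
a standard cross type; a 2-df genotype-factor coding is available and the
coding used is carried in the result. Genome-wide thresholds come from
permuting the phenotype rows (default 1,000 permutations) and taking the
95th-percentile order statistic of the per-permutation maximum LODs —
⌈q·n⌉-th of the sorted maxima, the 950th of 1,000 at the default.
Support intervals are LOD-drop intervals (default drop 1.5, a conventional
value; the drop is configurable) expanded to the flanking markers just
outside, flagged one-sided at a scan edge. No correction across
environments is applied by default (each environment gets its own
genome-wide permutation threshold); a Bonferroni option is a caller-side
multiplication away since per-environment p-levels are explicit.

## Problem sizes and determinism

The test-suite and acceptance-script workloads are: a 200-pair RTG panel at
≈ 5,000 markers for the round-trip/reciprocity/centromere checks; 200 null
datasets of 300 regions at 1,000 permutations each for type-I calibration;
a 20,000-draw Monte-Carlo null against exact enumeration on a 1 kb toy
genome; 500 clones per condition for the divergence/msh2 direction checks
(one 200 kb chromosome, DSB rate scaled to 20 for the single-chromosome
harness); 100 recovery replicates of a 125-clone LOH panel with a planted
1-SD additive QTL plus 200 null family-wise-error runs at 1,000
permutations. The QTL harness panels are generated with the mitotic-LOH
generator at an elevated event rate (≈ 28% of markers homozygous per
clone), emulating a recombination-selected RTG panel — linkage mapping
needs genotype variance, and the panels actually phenotyped in such
experiments are selected recombinants. All randomness flows from explicit
seeds; clone indices are mixed into the RNG stream so populations are
reproducible element-wise and independent of generation order.

## Known limitations

- LOH is inferred from genotypes alone; hemizygous deletions are
  indistinguishable from LOH without read-depth input (out of scope).
- The anti-recombination model treats mismatches as independent; real
  heteroduplex rejection likely saturates and depends on tract mechanics.
- The permutation randomisation is layout-uniform: it does not model
  GC content, replication timing or masked-region avoidance.
- The rank-sum continuity-corrected p-values are asymptotic; at very small
  clone counts exact tests would differ slightly.
- Interval mapping between markers (HMM genotype inference), epistasis
  scans and CNV-aware covariates are not implemented.
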