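# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `islandscape`, and what the synthetic-data
generator does and does not emulate.

## Coordinates and formats

All coordinates are 0-based, half-open, BED-style. ChIP tags are
single-end records of (5′ position, strand); every tag is extended
`fragment_length` bp 3′-ward for coverage. The default fragment length is
150 bp (a typical sonicated-chromatin fragment; exposed everywhere as a
parameter). Densities are fragment-bp per bp per anchor; per-million
scaling is optional and used only when comparing tracks of different
depth.

## CpG-island prediction

The caller implements the classical sliding-window lineage: a `window`
(200 bp) at `step` (1 bp) qualifies when GC ≥ `min_gc` (0.50) and CpG
observed/expected ≥ `min_oe` (0.60), where O/E = N_CpG·L/(N_C·N_G) over
non-N bases. Overlapping qualifying windows are merged; each merged run is
snapped to the outermost CpG it contains (window runs overshoot into
CpG-poor flanks by up to a window length; anchoring at CpGs removes that
slop, as genome browsers' island tracks do), then trimmed base by base —
preferring terminal A/T/N — until the reported interval itself satisfies
all three thresholds, or dropped if it falls below `min_length` (200 bp)
first. Windows with more than 50% N are skipped; the CpG snap is disabled
when `min_oe` is 0 so that degenerate thresholds remain usable.

Association classing: an island is TSS-associated if it overlaps any TSS
± 1 kb, else TES-associated by the same rule, else "other"; TSS takes
precedence. A strong/weak split (length × O/E score, cut at the set
median) is provided as an explicitly labelled stand-in — no canonical
definition exists.

## Peak calling and occupancy

Windows of 500 bp at 250-bp steps are scored by the Poisson upper-tail
probability of the IP tag count given λ = input count × (IP depth / input
depth), floored at the genome-wide expected IP count per window so that
input dropouts cannot manufacture enrichment. Benjamini-Hochberg q-values
are computed across all windows genome-wide; windows with q ≤ FDR (0.05)
and fold ≥ 2 are merged when overlapping, and the summit is the
maximum-coverage base of the merged span. There is deliberately no
input-free mode.

An island is "occupied" with ≥ 1 bp of peak overlap (`--min-overlap`).
Peaks touching no island are reported with the GC and O/E of their spans:
on simulations containing islands just below the prediction thresholds,
these non-island peaks sit above genome background on both statistics —
the signature of bona fide islands missed by the annotation.

The promoter-vs-body depletion test is a paired two-sided t-test on
per-gene (promoter − body) H3-normalised enrichment values (Welch's
unpaired test is available). H3 normalisation divides a modification's
percent-input by H3's percent-input per amplicon, controlling nucleosome
density. When all paired differences are exactly zero the t statistic is
reported as 0 with p = 1 (the limit scipy leaves as NaN).

The knockdown volcano uses the pooled-variance two-sample t-test per
transcript with log2(knockdown mean / control mean); transcripts with a
nonpositive condition mean are excluded and flagged. The
expression-vs-binding trend uses statsmodels lowess on a 100-point grid
plus Spearman's rho; a constant tag vector yields rho = 0 by convention
and a constant expression vector an undefined (flagged) correlation.

## Bisulfite analysis

Clones are compared ungapped and full-length against the unconverted
top-strand reference (amplicon-style clones need no gapped alignment;
bottom-strand clones are out of scope in v1). At each reference CpG C:
clone C → methylated, T → unmethylated, else missing. Conversion
efficiency is T/(T+C) at non-CpG reference cytosines; clones below 0.95
are rejected, as are clones mismatching more than 10% of non-C reference
positions. Clones are classified methylated at ≥ 80% methylated CpGs and
nonmethylated at ≤ 20% (exposed as flags; real imprinted alleles are
near-saturated so the split is insensitive between roughly 0.6/0.4 and
0.9/0.1); intermediate "partial" (mosaic) clones are always reported,
never dropped, and excluded from percent-methylated. Allele enrichment of
ChIP versus input clone sets is a two-sided Fisher exact test on the 2×2
nonmethylated/methylated count table.

## Binding model

A single-site (1:1 Langmuir) model throughout: the near-identical measured
affinities of one-CpG and six-CpG probes argue that the domain engages one
CpG at a time, so no avidity or cooperative (Hill) terms are included, and
mass-transport limitation is ignored. Kinetic fitting minimises squared
residuals jointly over all sensorgrams for shared (k_on, k_off, R_max) in
log-parameter space — enforcing positivity and making the jacobian-derived
standard errors directly relative — from a fixed 3×3 multistart grid
(k_on ∈ {1e4, 1e5, 1e6} M⁻¹s⁻¹, k_off ∈ {1e-3, 1e-2, 1e-1} s⁻¹) to dodge
local minima deterministically. Flat input raises an error rather than
returning a spurious fit. The steady-state route fits
R_eq = R_max·c/(c + K_D) by least squares and flags (without failing) data
whose concentrations do not bracket the half-max response. Concentrations
are molar internally; K_D is reported in µM.

## The synthetic world

The generator states a biological model and draws data from it:

- **Sequence.** A two-row dinucleotide Markov chain (one transition row
  after C, one elsewhere) whose rows are tuned by fixed-point iteration so
  the stationary composition hits the target GC and the after-C G
  probability hits the target CpG O/E; every emitted sequence is verified
  by direct counting and redrawn if outside ±0.05 of either target.
  Background defaults: GC 0.40, O/E 0.20 (a CpG-depleted methylated
  genome); island defaults: GC 0.65, O/E 0.85–1.0, length ≥ 200 bp,
  placed non-overlapping with a 2-kb gap and bounded retries (failure
  names the offending spec). TSS-associated islands get a gene whose TSS
  is the island midpoint; TES-associated ones a gene ending there; gene
  lengths are uniform 5–15 kb, plausible for compact mammalian genes.
- **Methylome.** Two alleles. Every background CpG is methylated on both
  (an optional per-site Bernoulli `mosaic_fraction`, default 0, models
  mosaically nonmethylated weak sites); nonmethylated islands are 0/0,
  imprinted islands maternal=1/paternal=0, "full" islands 1/1.
- **Tags.** Per-base sampling weights: input and H3 uniform; KDM2A
  = 1 + (fold − 1) × s where s is the local nonmethylated-CpG density in a
  200-bp window, saturating at 8 sites — so fully methylated islands sit
  exactly at background and enrichment plateaus at `island_fold`
  (default 20); H3K36me2 = 1 − (1 − depletion) × s (default depletion 1/3)
  further halved over expressed gene bodies, where H3K36me3 instead
  concentrates (baseline 0.1, body gain 10); H3K36me1 like me2 with a
  milder 0.6 depletion. The fold/depletion magnitudes are free parameters
  of the simulation — no measured values exist for them. Sampled bases are
  fragment midpoints; 5′ ends are midpoint ∓ half a fragment with 50/50
  strands, and exactly `n_tags` tags are emitted.
- **Bisulfite clones** sample an allele per clone by `allele_weights`,
  convert non-CpG Cs (and CpG Cs of unmethylated alleles) C→T at
  `conversion_rate` 0.99, and carry truth labels for testing.
- **Expression** is log-normal per gene (log2 mean 8, sd 2 — a typical
  microarray-intensity spread), independent of island status by
  construction; replicate noise is log-normal with sd 0.1 on log2 (no
  measured value exists; 0.1 matches well-behaved array replicates); a
  designated KDM2A transcript is scaled by (1 − knockdown_fraction),
  default 0.6 matching the achieved knockdown.

Identical config + seed reproduce byte-identical outputs; numba
accelerates the sequential chain scan with a pure-Python fallback that
draws the same variates.

What the generator does **not** emulate: read-level sequencing error,
mappability and repeat structure, paired-end fragments, diploid sequence
variation, PCR duplicates, qPCR efficiency, or array normalisation
artefacts. A green test therefore establishes that the analysis code
implements its stated statistics correctly on data from the stated model —
not that the pipeline is robust to every artefact of real libraries.

## Calibration scale-downs

Two stochastic calibration suites are scaled for test-suite runtime, with
acceptance bands widened only to the binomial width at the reduced n,
never beyond: the no-depletion promoter-vs-body null uses 400 tag
resamplings on a shared 300-kb genome (accepting a 2–9% rejection rate at
α = 0.05), and the noisy K_D recovery study uses 60 seeds (median |error|
< 10%, median signed error within ±2%).

## Known limitations

- The island caller's resolution is bounded by the window length; the CpG
  snap removes most but not all boundary slop.
- The Poisson window test ignores tag autocorrelation from fragment
  extension; its BH calibration is verified empirically on the null
  simulation rather than asserted analytically.
- Top-strand bisulfite only; clones must be full-length amplicons.
- The paired t-test on H3-normalised ratios is mildly anticonservative
  for heavily skewed enrichment distributions (visible as ~7% empirical
  rejection at nominal 5% in the null calibration at n = 9 genes).
- Strong/weak island classing is a stand-in definition.
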