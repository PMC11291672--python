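# Methods

## Marker panel and pair partition

The built-in routine-genotyping panel has 23 assays: one mitochondrial SNP,
eleven chromosome-5 SNPs (ten inside the introgression island plus the
background SNP `SB` outside it), and eleven unlinked ancestry-informative
SNPs pooled in a single multiplex reaction.  Island markers carry region
labels — four left-shoulder SNPs (SNP11–14), the core SNP15 adjacent to
the candidate CYP450 tandem repeat, and five right-shoulder SNPs (SNP16,
18–21) — chosen so the 45 = C(10,2) island pairs partition into 9
core–shoulder, 6 within-left, 10 within-right and 20 cross-shoulder pairs.
Positions honour the documented anchors (core at 877,292 bp; SNP15–16
≈ 22 kb apart; SNP12–13 ≈ 35 kb; SNP20–21 ≈ 74 kb; island spanning
~0.7–1.3 Mb); the remaining positions are interpolated.  A user panel TSV
is the single source of truth for ids, positions and region labels;
every downstream partition derives from it.

Coordinates are 1-based bp on the recipient-species reference naming used
by the panel file.  Markers are defined by their two diagnostic alleles,
so no strand handling is needed.

## Genotype calling from fluorescence

A well's VAFF is f₁/(f₁+f₂) with f₁ the donor-specific channel; it is
scale-invariant, so plate-to-plate intensity differences cancel.  Wells
with zero total signal are flagged failed, never silently dropped.

Cutoffs separating the three VAFF clusters are calibrated per (run,
assay) from the four positive-control wells: lower cutoff = midpoint of
the native-homozygote and heterozygote cluster means, upper = midpoint of
heterozygote and donor-homozygote.  Introgressed-control wells anchor the
heterozygote cluster only when their VAFF actually lies between the two
homozygote clusters (they are homozygous native outside their introgressed
tract); otherwise the heterozygote mean is synthesized as the homozygote
midpoint.  With either homozygote control missing the configured defaults
(0.33, 0.66) apply, with a logged warning.  Calls within a margin
(default 0.05 VAFF units) of a cutoff are flagged `near_cutoff`; they are
excluded from frequency computations by default but listed for QC, and a
per-(run, assay) override table can reproduce hand-curated cutoffs.

The hybrid index is the pooled multiplex VAFF.  Category thresholds
default to 0.125/0.875 so that an individual heterozygous at ≥3 of the 11
multiplex loci (pooled donor fraction ≥ 3/22 under balanced channels) is
called admixed — sensitive enough to flag first- and second-generation
backcrosses.  Species classification combines the nuclear category with
the mitochondrial call (effectively haploid: dosage 2 → donor mitotype,
0 → native); concordance is reported for non-admixed individuals, and
admixed individuals are always reported regardless of mitotype.

## Exact tests and conventions

All temporal tests are exact; conventions are stated because they change
p-values at the printed precision:

* 2×2 and r×c tables use the two-sided point-probability rule: p sums the
  hypergeometric probabilities of all tables with the observed margins
  whose probability is ≤ that of the observed table (relative tolerance
  1e-7 against round-off).  The r×c (Freeman–Halton) test enumerates
  tables completely; a guard (default 2·10⁶ tables) switches to a seeded
  Monte Carlo permutation estimate for large tables.  A zero margin gives
  p = 1 with a degenerate flag.
* The exact differentiation test is applied per population at the core
  SNP (allelic 2×2 and genotypic 2×3 tables), with Benjamini–Hochberg
  adjustment within each per-population family, and pooled over the whole
  dataset for every island SNP.  Because it is ambiguous whether pooled
  tests should use allele or genotype tables, both are always reported
  side by side.
* The Wilcoxon signed-rank test over populations (or pairs) as replicates
  discards zero differences (their count is reported) and uses the exact
  2ⁿ distribution when n ≤ 15 with tie-free |differences|, else the
  normal approximation with tie-corrected variance.
* The sign test is the exact binomial: two-sided p = 2·min(tail) capped
  at 1 — the convention under which 8 decreases of 9 pairs gives
  p = 20/512 ≈ 0.039 and 9 of 10 gives p = 22/1024 ≈ 0.0215.

## EM linkage disequilibrium

For each marker pair, the four haplotype frequencies are estimated from
the 3×3 joint dosage table by EM: all genotype classes except the double
heterozygote determine their gametes; the double heterozygote is split
between the two phase resolutions in the ratio p_AB·p_ab : p_Ab·p_aB
under the current estimate (ties split 50/50, the deterministic
resolution of the EM saddle — a table containing only double
heterozygotes stays at D = 0).  Iteration starts from linkage equilibrium
(p_AB⁰ = p_A·p_B) and stops when the largest frequency change is below
1e-8 (cap 1000 iterations); a debug flag asserts the observed-data
log-likelihood never decreases.  With no double heterozygotes the
estimate equals direct gamete counting exactly.  r² is undefined
(reported missing, excluded from means) when either locus is monomorphic
in the sample.

Populations enter the LD analysis per period only when the core
donor-allele frequency in that period exceeds 0.05; below that, diversity
is too low for r² to be informative.  Mean r² aggregates unweighted over
every defined (population, pair) value; the pair-then-population and
population-then-pair alternatives are also computable since the
aggregation choice is not standardised.  Pairs undefined in one
population drop only that population's contribution.  Note that r²
estimated from small samples at rare alleles is biased upward
(E[r²] ≈ 1/n under independence), so mean r² over many near-monomorphic
pairs has a noise floor; the per-class direction-of-change tests are the
more robust erosion readout.

## The forward simulator

One recipient-species population of N diploids carries haplotypes over
the chromosome-5 marker map.  Each generation: (1) a Binomial(2N, m) draw
of haplotypes is replaced by all-native immigrants, summarising gene flow
from unswept populations; (2) diploids form by random pairing;
(3) fitness is multiplicative, w = (1+s_core)^(core dosage) ·
(1−s_del)^(total shoulder dosage) — directional selection at the core
opposed by immigration realises the migration–selection balance, and an
optional overdominance mode (off by default) makes the core advantage
heterozygote-specific instead; (4) parents are drawn proportional to
fitness; (5) each gamete recombines with at most one crossover per
inter-marker interval, intervals independent (no interference — adequate
at 11-marker scale), with probability = bp distance × per-bp rate.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| N | 500 diploids | a marina-scale breeding population |
| s_core | 0.10 | strong local advantage of the core allele |
| s_del | 0.02 /copy | mildly deleterious hitchhikers in the native background |
| m | 0.05 /gen | immigration of non-introgressed natives |
| p0 | 0.30 | initial frequency of full-length donor tracts |
| burn_in, gap | 30, 20 gen | pre-sampling equilibration; cohorts ~20 generations apart |
| n_sample | 400 | individuals per sampled cohort |
| rec rate | 7e-7 /bp/gen | see below |
| signal high/low/het | 900/100/500 a.u. | VAFF clusters ≈ 0.1/0.5/0.9 |
| noise_sd | 40 a.u. | ≈11σ cluster separation, a clean KASP run |
| multiplex_gain | 11 | pooled reaction is 11× brighter at instrument-level read noise |

The recombination rate is fixed by a self-consistency argument, since no
genetic map is available for the island: a full-length donor tract has
net fitness (1+s_core)(1−s_del)⁹ ≈ 0.92 per haplotype, so the core allele
survives only if crossovers strip its shoulder load faster than the tract
declines (~0.13/generation including immigration).  With shoulders
~100–400 kb from the core this requires at least ~5e-7 per bp; within the
admissible range the default is calibrated to the regime that reproduces
the qualitative erosion signature — stable core, declining shoulders,
falling core–shoulder r² — while the nearest shoulder (22 kb) remains
partially linked over tens of generations.  The value is illustrative,
not inferred from data.

The fluorescence forward model renders each sampled cohort as one run of
plate records: homozygote/heterozygote channel means with Gaussian noise
truncated at zero, a native mitotype record, a pooled multiplex record
under balanced pooling, and the four positive-control wells (one donor,
one plain native, two introgressed natives heterozygous across the
island).  A single top-level seed drives everything; replicate streams
derive by fixed seed increments, so each replicate is independently
reproducible and identical configs give byte-identical outputs.

### What the generator does and does not emulate

It emulates: two species pools with diagnostic alleles, introgressed
tracts on the 11-SNP chromosome-5 map, a core allele at
migration–selection balance, shoulder erosion over ~20 generations
between two sampling periods, and three-cluster fluorescence with
Gaussian noise plus control wells.  It does **not** emulate: the
multi-population mosaic of a real contact zone (one focal deme only —
immigration summarises the metapopulation), F1 hybridization dynamics
(hybrids are injected as fixtures when the classifier needs them),
per-assay amplification-efficiency differences in the multiplex (balanced
pooling is assumed and surfaced in config), plate/instrument batch
effects, or tract-length observables.  Tests passing on simulator output
therefore validate the pipeline's statistical machinery, not field
sampling designs with population structure.

### Known limitations

With one deme of N = 500 and cohorts 20 generations apart, the core
allele's stochastic change between samples has standard deviation
≈ √(20·p(1−p)/2N) ≈ 0.05 at p ≈ 0.2 — genetic drift, since the
migration–selection restoring force is weak (~0.01/generation).  The mean
shoulder decline between samples is bounded by the shoulder frequency
remaining after burn-in (≈ p0·e^(−(m+s_del)·30) ≈ 0.04).  Consequently
the *magnitude* of the core change is smaller than the mean shoulder
decline only in a minority of replicates, even though the core has no
systematic trend while the shoulders do; with many populations (as in a
real spatial design) or larger N the comparison would favour the core.
The replicate-level readouts that are robust at this scale are the
majority-decline fractions for shoulder frequencies and core–shoulder r²,
and the disappearance of both when s_del = 0 and m = 0 (the mechanism
control: erosion requires purging or immigration).

Other numerical choices: genotype-table encodings are declarative (a
dialect block: allele symbols and missing tokens) because deposited
tables vary; unknown encodings become missing with a logged count.
Report TSVs are written with fixed column order and are byte-identical
for identical inputs.
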