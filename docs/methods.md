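# Methods

This note documents the models implemented in `gctevo`, the assumptions
behind them, the synthetic data they are validated on, and the numerical
choices made where the design was open.

## Genome model

All computations run on a scaled genome preserving GRCh38 proportions:
22 autosomes split into p/q arms at the centromere, chromosome X with
PAR1/PAR2 (two copies in males) flanking the hemizygous body, and
chromosome Y. The total autosomal length is a parameter: 3 Gb reproduces
the human scale; the test suite and acceptance script use 30 Mb so that
window-level simulation and per-variant bookkeeping run in seconds.
Coordinates are 0-based half-open in memory and 1-based inclusive in
emitted TSVs.

## Sex-chromosome dosage

The literal adjusted ratio R subtracts the normal-cell depth contribution
from tumor depths, numerator (chromosome of interest) and denominator
(autosomes, length-weighted mean). It is unbiased only when tumor and
normal per-copy coverages match. The default `per_copy` mode therefore
divides tumor depths by c_t = TD_auto/((1−ρ)·2 + ρ·ψ) and normal depths by
c_n = ND_auto/2 before the subtraction, which yields R = n_chr/ψ exactly
for noise-free data and makes the 0.5 baseline exact for WGD tumors
without sex-chromosome gain. Calls use a configurable tolerance around
0.5 (default ±0.05); no printed threshold exists for "amplified", so the
call boundary is a documented default, not a reproduced constant. In the
simulated normal male, the whole-chromosome X ratio sits slightly above
0.5 (≈0.509) because the pseudoautosomal regions carry two copies — the
same effect real male genomes show.

## Hemizygous X copy-number calling

Segmentation minimizes Σ residual² + γ·(#breakpoints) by an exact O(n²)
dynamic program; structural-variant breakpoints cut the signal into
independently segmented blocks. γ (default 10 in squared-LogR units at
10 kb windows) and the minimum segment length are configurable — no
published values exist for them. Calibration estimates one additive LogR
shift as the median of expected-minus-observed offsets over autosomal
regions of known state (diploid and gained classes pooled), then the
state model is inverted per segment:

n_eff = (N((1−ρ)ψ_n + ρψ_t)·2^L/ψ_n − (1−ρ)N)/ρ,  ψ_n = 2.

Hemizygosity enters only through the germline copy number N (1 on non-PAR
X/Y, 2 elsewhere), keeping a single formula for autosomes, PAR and
non-PAR. A segment is clonal when n_eff is within τ = 0.2 copies of an
integer (half the distance to the midpoint, symmetric); otherwise the
fractional part of n_eff is reported as the fraction of tumor cells
carrying the next-higher state. States are capped at 8 copies, the
maximum the method is asked to resolve. Below-zero n_eff beyond τ is
flagged as an artifact rather than clipped silently.

## WGD detection, timing, and pre-WGD divisions

Detection applies the strict major-copy-number thresholds (>50% of
autosomal bp at MCN ≥ 2 plus ≥ 11 majority-MCN ≥ 2 autosomes; >50% at
MCN ≥ 3 for multiple WGD) and is invariant to segment subdivision because
all fractions are bp-weighted.

The timing ratio compares per-bp densities of distinct clonal clock-like
mutation loci between MCN = 2 and MCN = 1 clonal segments (3 vs 2 when
multiple WGD is called). Under a constant clock, a segment duplicated at
time t_w out of a clonal lifetime t carries density ∝ 2t − t_w per copy
pair, an unduplicated one ∝ t, so the ratio runs from 2 (doubling at the
origin) to 1 (doubling at the end). Counting distinct loci (a duplicated
mutation once) rather than multiplicity classes makes these limits exact;
the multiplicity-class reading is available behind a flag. Subclonal
mutations post-date any clonal WGD and are excluded — including them
measurably inflates late-WGD ratios. The ratio is flagged undefined
rather than raised when a stratum has no length or the denominator no
mutations.

Pre-WGD divisions restrict to clonal balanced 2+2 segments — the only
states where multiplicity 2 unambiguously means "before the doubling"
without LOH confounding — count clonal substitutions of all contexts at
multiplicity 2, extrapolate to the full autosomal genome by the length
ratio, and convert with d = M/(2r): r is a per-haploid-genome rate, the
pre-WGD cell was diploid. r defaults to 0.6 with reported bounds at 0.5
and 0.7.

The multiplicity/CCF inversion (m_raw = VAF·((1−ρ)N + ρn_tot)/ρ, rounded
and clamped to [1, MCN], CCF capped at 1.25 then clipped to 1) and the
CCF ≥ 0.9 clonality threshold are provided and unit-tested, but
per-variant thresholding is intentionally not the default source of
clonality for the timing estimators: at 80× coverage, binomial read noise
alone misassigns a substantial fraction of truly clonal variants, a
problem production pipelines solve by clustering variants jointly —
functionality outside this package's scope. The timing and chronology
estimators therefore consume clonality/multiplicity annotations provided
on input (from the simulator, or from an upstream clustering tool in real
use), with the derived annotations available via configuration.
NRPCC = depth·ρ/(ρψ + 2(1−ρ)) is reported as the standard power metric
for subclone detection (adequate above 10).

## Chronology

The MRCA point estimate is the burden-share formula
t = age·B_cl/(B_cl + B_sub/η) with η = 1 (no clock acceleration, matching
the low mutational burden of these tumors). Burdens weight each clock
variant by 2/n_tot — converting per-genome counts to a diploid-equivalent
scale — and subclonal variants additionally by CCF, approximating the
average per-cell post-MRCA burden. This weighting is an approximation to
full subclonal deconvolution and is stated as such in output metadata.
Latency is defined as age − t_MRCA; the identity holds exactly by
construction.

Uncertainty uses conjugate Gamma posteriors for the latent clonal and
subclonal intensities (λ | B ~ Gamma(α₀ + B, β₀ + 1)) with a weak prior
(β₀ = 0.1 pseudo-observations) whose scale is pooled across the cohort
through a log-normal (geometric-mean) fit of per-sample burden rates.
Posterior draws of t = age·λ_cl/(λ_cl + λ_sub/η) give the 95% interval;
as the prior weight vanishes the posterior mean converges to the
closed-form point estimate (tested). B_cl = 0 yields the degenerate
t = 0 / latency = age result with a flag.

## i(12p) and arm events

The representative copy number of each chromosome-12 arm is the total CN
of the longest clonal segment, ties broken toward higher CN ("largest"
read as longest — the natural metric on segmented profiles). Lenient:
12p ≥ 12q + 1; stringent: 12p ≥ 12q + 2; stringent calls are a subset of
lenient ones for any input. Subclonal chr12 segments are ignored for the
representative state. Arm baselines are 2 (non-WGD) and 4 (WGD); arm
gain/loss requires >50% of covered bp at least one copy above/below
baseline, CN-LOH >50% with minor allele 0 at total ≥ baseline. Focal
queries report baseline-relative CN with +2/−2 thresholds for high-level
amplification and deep deletion and an optional minimum length (10 Mb for
large Y deletions). Arm boundaries come from a table input so the scaled
genome works unchanged.

## Scores and statistics

The replication-stress score z-scores each signature gene across samples
(population SD), sums weighted z-scores per sample, and z-normalizes the
sums across samples — so outputs have mean 0 and population SD 1 by
construction. Per-gene-across-samples is the default normalization axis;
the per-sample-across-genes alternative is a flag. The 17 published gene
weights are an input file (they belong to an external study); the bundled
synthetic weight table preserves only the structure and is labelled as
synthetic. Zero-variance genes get z = 0 with a warning.

Methylation probes are filtered on raw, unscaled MAD > 0.1 across samples
(no 1.4826 normal-consistency factor — the filter is a spread cutoff, not
a robust SD estimate), then per-sample median betas are reported for X
and autosomal probes separately.

Wilcoxon rank-sum tests use the exact null for tie-free groups up to
n = 25, else the tie-corrected normal approximation. Fisher's exact test
reports the conditional maximum-likelihood odds ratio (maximizing the
Fisher noncentral hypergeometric likelihood, the convention of standard
exact-test implementations) alongside the sample cross-product ratio.
Benjamini–Hochberg q-values follow the step-up construction and are
cross-checked against an enumeration oracle and statsmodels.

## Synthetic cohorts: what they emulate, and what they do not

Each sample draws age, purity, subtype, WGD status (91.7% positive, 6.35%
of those multiple), MRCA age (uniform fraction 0.5–1 of age), WGD time
(0–5% of age, reflecting the fetal origin of the doubling, clamped at the
MRCA), X copy number (1–8, mode 2–4), i(12p) (88%, half with ≥2 extra
copies), and pre-WGD division count (30–70). Clock mutations accrue at
μ/(2·L_auto) per bp per copy per year (μ = 3 clock mutations per diploid
genome per year by default); mutations predating a duplication appear at
multiplicity = copies of that allele. Pre-WGD divisions add substitutions
at r per haploid genome per division. Subclonal loci counts are scaled by
1/CCF so the CCF-weighted per-cell burden matches the clock expectation —
this is what makes the chronology weighting a genuine round trip. Samples
with positive latency always carry 1–2 subclones: with zero subclonal
variants the MRCA age is unidentifiable from data, so "no subclones"
corresponds to an MRCA at diagnosis. Read support is binomial around the
purity/CN-expected VAF at Poisson depth; window depths are Poisson in
read counts. MCN = 1 strata in WGD genomes are modelled as arms that lost
one copy of each allele immediately after doubling (their mutation
history is then exactly that of a never-duplicated arm); chromosome 12 is
exempt from random arm loss so the i(12p) truth flag stays meaningful.

Not emulated: read-level artifacts (mapping, GC bias — LogR inputs are
assumed GC-corrected), mutational spectra beyond the clock/non-clock
dichotomy, nested subclone phylogenies, germline variation, and kataegis
or other clustered processes. Passing recovery tests therefore
demonstrates estimator correctness under the stated generative
assumptions, not robustness to every artifact of real sequencing data.

## Problem sizes

The suite and the acceptance script run on the 30 Mb genome with 10 kb
windows; recovery experiments use 50 replicate tumors (timing, divisions)
or 100 (chronology), matching the precision the corresponding checks
require. At these sizes a typical sample carries a few hundred somatic
variants — the same order as a real low-burden germ cell tumor genome.

## Known limitations

- The chronology hierarchy is a deliberately simple conjugate model; its
  intervals are not calibrated against the full hierarchical regression
  used in pan-cancer chronology work.
- The clock-mutation set is a trinucleotide-context proxy (C>T at NpCpG);
  signature-attributed clock sets can be supplied via the `clock_flag`
  column instead.
- Per-variant clonality thresholding is noisy at realistic coverage (see
  above); real-data use should supply cluster-based clonality.
- Chromosome Y is handled at the dosage level only; segment-level Y
  calling is out of scope.
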