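# Methods

## The problem

Selective sweeps — the local loss of neutral diversity that a positively
selected allele drags along as it rises — are routinely scanned for, and
increasingly classified as *hard* (one origin haplotype) or *soft* (several,
e.g. from standing variation). Both tasks are usually done under panmictic
assumptions. This package implements a simulation study of what happens when
the population is actually subdivided: how fast adaptation crosses deme
boundaries, how the standard detection statistics behave through the stages
of a sweep under migration, and when hard sweeps get misclassified as soft
(and vice versa) because the classifier's training stage, or its demographic
null, does not match the data.

## Single-site simulator

`single_site` tracks one adaptive allele in 1–3 demes of `N_e` haploid
chromosomes each (default 10,000). Per generation, in this order:

1. **migration** — deterministic mixing of deme frequencies along the deme
   graph; each edge passes an expected `Nm` chromosomes per direction
   (`Nm ∈ {0.02, 0.2, 2, 20, 200}`);
2. **selection** — the haploid genic map `p' = p(1+s)/(1+ps)` with per-deme
   `s` (default 0.02);
3. **drift** — one binomial draw of the allele count per deme.

The allele arises as a single copy in its origin deme; runs that lose it
everywhere are discarded and restarted with fresh randomness, conditioning
on eventual global fixation without biasing within-run dynamics. The event
order and the deterministic treatment of migration/selection are our own
discretisation choices (any consistent order differs only at `O(s·m)`);
drift is the only stochastic step besides the restart rule. Three-deme
migration graphs: *connected* (all pairs), *forked* (d0–d1, d0–d2),
*stepping-stone* (d0–d1–d2), with rate `m` per edge per direction.

Timing summaries record per-deme first passages at 5% (`t5`), 99.5%
(`t995`, "completion" — the last half percent is drift-dominated), and at
frequency 1 (`tfix`), plus the selection phase `t995 − t5` and the waiting
period before the allele first appears outside its origin deme. The
headline medians (the time for the allele to take over the recipient deme
d2) are reported on the `tfix` scale; completion-threshold values are kept
alongside, and the ~80-generation gap between the two scales at
`N_e = 10,000` is exactly the drift tail the 99.5% convention exists to
cut off.

Closed forms used as oracles: the deterministic logistic travel time
`[logit(p1) − logit(p0)]/ln(1+s)` (≈ 412 generations for 5%→99.5% at
`s = 0.02` in the `1/s` approximation) and the `log(N_e)/s` sojourn law for
population-size scaling (25% reduction at `N_e = 1000`, 7.5% at 5,000, a
6.4% spread over the 11,000–20,000 range that the high-migration limit
spans).

## Genomic simulator

`genomic_sim` is a forward infinite-sites engine for a 600-kb region
(`L = 600,000` continuous bp coordinates) in one or two demes of 10,000
haploid chromosomes. Chromosomes are paired into transient diploids each
generation (monoecious random mating, selfing allowed — no persistent
pedigree is kept); fitness is co-dominant in the selected site (1, `1+s`,
`(1+s)²`). Each offspring chromosome picks a parent individual within its
deme ∝ fitness and receives one parental chromosome, recombined with
probability `c = 0.006` at a single uniform breakpoint (multiple crossovers
are negligible at this rate), then acquires `Poisson(μ = 0.006)` new
mutations at uniform fresh positions. "Per individual per generation" for
`μ` and `c` is interpreted per transmitted chromosome, which matches the
600 kb × 1e-8/bp arithmetic for human-like parameters. Migration moves
whole individuals with probability `m`, implemented as a balanced swap of
`Binomial(N/2, m)` individuals per direction so deme sizes stay exact
(expected `Nm` chromosomes per generation per direction; the balancing
halves the variance of the net flow, which no analysis here is sensitive
to). Columns fixed or lost population-wide are pruned each generation; the
selected column is exempt.

The neutral initial state comes from the coalescent (msprime: island model
with the same sizes and migration, infinite-sites mutations at continuous
positions), or from a forward neutral burn-in (≥ 20 N generations) kept as
a slow cross-check; the two agree on mean pairwise diversity within
Monte-Carlo error. The sweep inserts one mutant chromosome in deme d1 at
100 kb from the left region end; loss resets the population to the saved
initial state.

**Snapshots.** The standard schedule photographs the population per deme at
within-deme frequencies 20/40/60/80/99.5% and at 1,000–5,000 generations
after that deme's 99.5% crossing, plus once at global fixation: 21 in-run
snapshots for two demes, 11 panmictic; with the initial neutral state these
are the 22/12 analysis time points. The low-migration local-adaptation
scenario (m0.2L) instead snapshots every 100 generations up to 20,000 and
stops regardless of fixation. From each snapshot, 50 samples of 50
chromosomes per deme (or 50 pooled chromosomes for *mixed* samples) are
drawn without replacement; columns monomorphic within a sample are dropped
except the selected site.

**Rescaling.** `rescale(config, λ)` maps `N→N/λ`, `s,m,μ,c → ×λ`,
preserving `Ns`, `Nm`, `Nμ = θ/2`, `Nc`; times shrink by λ. It refuses
`s·λ ≥ 0.5` (leaving the weak-selection regime where the scaling is
exact to first order). The desk-scale default for tests and scaled studies
is λ = 10 (demes of 1,000, `s = 0.2`); population-scaled diversity
(θ_region = 240 panmictic) is unchanged, so sample statistics are directly
comparable. What λ = 10 does *not* preserve: `O(s²)` corrections to sweep
trajectories and the absolute number of segregating haplotypes during very
long post-fixation recoveries; the package's directional conclusions were
checked to be insensitive to this, but numeric power values at desk scale
are not claimed to equal full-scale ones.

**Training material.** Classifier training sets are panmictic
(`N_e = 20,000` before rescaling). Hard sweeps start from a new mutation at
100 kb; soft sweeps apply selection to a standing neutral variant whose
frequency is within 10% ± 2% — the eligible variant nearest 100 kb — and
re-draw the population if none exists. One sweep run is photographed at all
five training stages (60%, 80%, 99.5%, fixation, fixation + 1,000
generations), and several samples are drawn per run; stages therefore share
populations, which costs nothing for the directional cross-testing
phenomena and an order of magnitude in runtime. The "mix" set pools one
fifth of each stage per class.

## Summary statistics

All statistics run on 100-kb windows stepped by 10 kb (51 windows per
region). Per window: θπ, Watterson's θW (denominator `a_{n−1}`), Fay &
Wu's θH (`Σ 2k²/(n(n−1))` over derived counts), Tajima's D (standard
normalisation; missing below 3 segregating sites), Fay & Wu's H = θπ − θH
(raw, not Zeng-normalised — an open choice recorded here), the haplotype
spectrum (n_hap, H1, H12, H2/H1 over distinct row patterns within the
window), and the per-window *proportion of significant* iHS and nSL scores
(|z| > 2).

iHS/nSL use a pairwise formulation of EHH: for pivot p and carrier group g,
`EHH(p,q)` is the fraction of chromosome pairs in g identical at all sites
between p and q; iHH integrates EHH outward by trapezoid, evaluated at each
SNP, until it decays below 0.05 or the last SNP of the region (no
extrapolation past the outermost SNP), in bp for iHS and in segregating-site
units for nSL; the score is `ln(iHH_A/iHH_D)`. Pivots are SNPs with derived
sample frequency in [0.06, 0.94], the range over which frequency-binned
normalisation against the neutral background is defined (mean/SD per
derived-count bin; building a table fails loudly on a zero-spread bin). The
implementation computes, per chromosome pair, the nearest mismatch index on
each side of every site by running min/max scans, so EHH at any pivot is a
rank lookup; it is exact (tested against brute-force enumeration) and fast
enough to score thousands of ~1,000-SNP samples.

The composite-likelihood scans are deliberately *simplified
re-implementations* of the cited model families — their contract is neutral
calibration and directional behaviour, not parity with released binaries.
SF2-style CLR: background SFS = the sample's own full-region spectrum;
under a sweep of intensity α at a 10-kb grid point, a SNP at distance d
escapes with probability `1 − e^{−αd}`, otherwise draws from a swept
spectrum with all mass at counts n−1 and 1 (split by the background mean
derived frequency); the statistic is `2(max_α − background)` log-composite-
likelihood with the background included in the maximisation (hence ≥ 0).
XP-CLR-style scan: the other deme's frequency is the Gaussian-drift prior
for the focal deme's (`σ²` fitted by moments genome-wide); a sweep of
strength s at the grid point inflates the variance by `1 + s·e^{−d/50kb}`;
the statistic is `2(max_s − s=0)`. FST is the per-site Hudson plug-in
`1 − H_w/H_b` (within-deme heterozygosities averaged; between
= `p₁(1−p₂) + p₂(1−p₁)`) averaged over polymorphic sites in the first
200 kb, then over the 50 samples of a snapshot. Ancestral states are known
(simulation truth); no misidentification model is included.

## Detection and calibration

Thresholds are empirical and demography-specific. Each neutral-background
region is cut into three non-overlapping 200-kb blocks; the extreme value
(in the statistic's sweep direction: higher for θH, H1, H12, CLR, XP-CLR
and the iHS/nSL proportions, lower otherwise) over the 11 windows entirely
inside a block represents it, pooling 3 values per region (15,000 at the
full 5,000-region scale). The cutoff at nominal FPR α is the
`floor(α·n)`-th most extreme pooled value, and "detected" means *at or
beyond* the cutoff somewhere in the scanned span — the first 11 windows
(the 200 kb centred on the selected site, mimicking a genome-wide scan) or
all 51. This order-statistic convention makes the FPR on the calibration
set exactly nominal (ties, impossible for continuous statistics, would err
anti-conservative). Samples whose entire span is missing (e.g. D in
monomorphic windows) leave the denominator and are counted. Deliberately
mismatched calibration (panmictic thresholds on subdivided data) is an
explicit mode, reproducing its inflated false-positive behaviour.

## Classification

Features are the window tracks of the eleven in-house statistics over the
first 11 windows (200-kb mode, or a frame shifted by 100/200/400 kb for the
flank probes) or all 51 (600-kb mode); missing windows are imputed by the
neutral-background feature mean, and a sample with > 50% missing entries is
dropped with a warning. XP-CLR and CLR are excluded from the feature set
(single-population training context; CLR additionally for cost) — this is
configurable at the `score_sample` level. The backend is sklearn's
`GradientBoostingClassifier` with fixed recorded hyper-parameters (150
trees, depth 3, learning rate 0.1, subsample 0.8) and an explicit seed; the
published boosting tool's exact feature list and hyper-parameters are not
public, so parity with it is out of scope — the *protocol* is the contract.
Predictor 1 (neutral vs sweep, hard + soft pooled) is thresholded not at
its model default but at empirical quantiles of an *independent* neutral
set's scores (5/1/0.1% FPR); predictor 2 (soft vs hard) always uses 0.5 to
avoid an a-priori bias toward either sweep type. Classification: below the
stage-1 cutoff → neutral; else soft or hard by predictor 2.

For two-deme test data, classifier features are normalised with the
panmictic tables (train and test identically featurized); the scaled-down
directional comparisons (spatial softening) apply the same pairs and
thresholds to both scenarios being compared, so the demographic mismatch
cancels from the direction.

## Problem sizes

The package's scaled study conditions, used by the test suite and the
analysis scripts' defaults: single-site experiments at full size (1,000
conditioned replicates per rate — seconds); genomic campaigns at λ = 10
with 6–20 replicate populations, 5–10 samples per snapshot, 60–150
neutral-background units for calibration, and classifier training sets of
40–60 samples per class per stage with a 150-sample independent neutral
set for thresholding. At these sizes the binomial noise on a power estimate
is a few percent, which is why the genomic-scale conclusions are asserted
as directions and orderings rather than point values; the full-scale
protocol (100 replicates × 50 samples, 5,000 NB regions, 1,000 + 1,000
training samples per stage) is reachable by passing λ = 1 and the full-scale
counts to the same drivers.

## Known limitations

* The genomic engine keeps the whole population as a dense 0/1 matrix;
  at λ = 1 a two-deme run holds ~20,000 × 2,000 bytes and full-scale
  campaigns are multi-hour jobs (no tree-sequence recording).
* One crossover at most per transmission; no gene conversion, no
  recombination map, exactly two demes at the genomic level.
* The CLR/XP-CLR simplifications share calibration and direction with the
  originals but not their numeric scale.
* Soft sweeps are generated from standing variation only (no recurrent
  mutation route), with the 10% ± 2% eligibility band.
* Mixed-sample neutral nulls are built by pooled subsampling of two-deme
  coalescent regions, the exact analogue of how mixed test samples are
  drawn.
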