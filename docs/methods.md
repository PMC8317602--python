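# Methods

`poolsweep` scans two-population pooled sequencing (pool-seq) data for
selective sweeps. Three window statistics are computed on 25-kb
non-overlapping windows, their top 1% sets are intersected, and the
surviving windows are annotated with overlapping genes. A synthetic
generator with plantable sweeps provides ground truth for validation.

## Statistics

### Weir–Cockerham F_ST

For one biallelic site with haploid sample sizes `n1, n2` and sample
allele frequencies `p1, p2` (alt-read fractions per pool), the
two-population Weir–Cockerham estimator is built from

```
MSP = n1 n2 / (n1 + n2) * (p1 - p2)^2                       # between-pop mean square
MSG = [n1 p1 (1 - p1) + n2 p2 (1 - p2)] / (n1 + n2 - 2)     # within-pop mean square
nc  = 2 n1 n2 / (n1 + n2)
F   = (MSP - MSG) / (MSP + (nc - 1) MSG)
    = 1 - nc MSG / (MSP + (nc - 1) MSG)                     # equivalent form
```

Windows aggregate sites as a ratio of sums (default) or a mean of
per-site ratios (`mode="mean-of-ratios"`). Negative estimates are
legitimate (expected value `-1/(n-1)` for identical frequencies in equal
pools) and never clamped.

The haploid sample sizes default to twice the pool sizes (70 and 118 for
the 35/59-diploid study design). Pool-seq sample size is genuinely
ambiguous — reads resample the pool — so `sample_size="depth-capped"`
(per-site `min(2 * individuals, depth)`) is available as an alternative.
With ~30x depth the read-sampling noise is not corrected by either
choice, so windowed F_ST on synthetic data runs somewhat above the
drift parameter F that generated it; the estimator itself is verified
against an ANOVA oracle on explicit haploid samples.

### Pooled heterozygosity and −ZH_p

Per window and target pool, with `nMAJ`/`nMIN` the read counts of each
SNP's within-pool major/minor allele,

```
Hp   = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2
-ZHp = (mu_Hp - Hp) / sigma_Hp
```

`Hp` lies in [0, 0.5], reaching 0.5 only when the summed counts balance;
sweeps depress it. The Z-transform uses the mean and *population*
(divide-by-N) standard deviation over all retained windows; with tens of
thousands of windows the ddof choice is negligible, and the population
convention makes the standardization identities (mean 0, sd 1) exact.
The transform parameters are returned so the same transform can be
re-applied to new values — this is also how the package's arithmetic is
validated against an externally published table of (Hp, −ZHp) pairs.

### XP-CLR

The cross-population composite likelihood ratio contrasts, per window, a
neutral drift model of the object population's frequencies against a
sweep model:

* **Null.** Given the reference frequency `p1`, the object frequency is
  Gaussian with variance `omega * p1 (1 - p1)`, censored to [0, 1] with
  the overflow as point masses at the boundaries. The drift scale
  `omega` is a genome-wide moment estimate,
  `mean[(p2 - p1)^2 / (p1 (1 - p1))]`, floored at 1e-4 when degenerate.
* **Sweep.** A lineage at recombination distance `d` from the focal
  point escapes with probability `c = 1 - (2 N s)^(-r d / s)` (star-like
  hitchhiking); the neutral frequency is pushed through `q = (1-c) + c p`
  or `q = c p` (alt- or ref-linked beneficial background, mixed 50/50
  because the favored allele is unknown).
* **Emission.** Pool read counts are binomial in depth at the modeled
  frequency — pool-seq data enters directly, without genotype calls.

The site likelihood integrates the emission over the frequency density.
The window score is `2 * max_s [sum_sites ll(s) - ll(0)]` over an s-grid
`{0} ∪ geomspace(1e-4, 0.1, 10)` that contains the null, so raw scores
are non-negative with `score = 0` exactly when the null wins. Distances
run from the window center at a constant recombination rate (1e-8 per bp
per generation) unless supplied otherwise. Scores are Z-normalized
genome-wide (per-chromosome normalization is a flag).

Two deliberate departures from genotype-based XP-CLR formulations:
the emission consumes pooled read counts rather than genotypes, and
high-LD SNP down-weighting is omitted (simulated sites are exchangeable).
The package makes no attempt to reproduce any external XP-CLR
implementation's numeric output.

**Quadrature.** The frequency integral uses Gauss–Legendre nodes mapped
onto the ±8 standard-deviation window around each site's drift peak
(intersected with [0, 1]), plus the censored boundary atoms; 256 nodes
by default (minimum 64). Windowing the nodes keeps narrow peaks fully
resolved: the default grid agrees with a 10x-resolution oracle to ~1e-12
in the log. CDF-difference bin masses were rejected on numerical
grounds — differencing upper-tail CDF values near 1 loses the bin mass
to floating-point cancellation.

**Degenerate neutral scans.** On fully neutral synthetic data the sweep
model loses at every window (any grid `s` implies near-complete
hitchhiking close to the focal point) and every raw score is exactly 0.
`normalize_scores` then raises; the pipeline reports zeros for the
normalized column and ranks windows by raw score, where the deterministic
(chromosome, start) tie-break makes the selection reproducible. This is
an honest boundary property of a composite LR whose null sits on the
edge of the parameter space, not an error state.

## Filtering

A SNP is discarded when any of the following holds; each rule is tallied
separately and a record failing several rules counts once per rule and
once overall, so `retained + discarded = input` exactly:

| rule | default | boundary |
|------|---------|----------|
| pooled MAF (counts summed over both pools) | < 0.05 | exactly 0.05 retained |
| per-pool depth (both pools; `combined` by flag) | < 10 | exactly 10 retained |
| site quality | < 20 | exactly 20 retained |
| distance to nearest indel, same chromosome | ≤ 15 bp | 16 bp retained |

"Within 15 bp" is read inclusively (≤ 15 discarded) as the conservative
interpretation; the boundary is pinned by unit tests so the choice is
explicit. MAF is pooled across both populations because the variant set
is joint; per-pool depth is required so both pools inform every window
statistic. Indel records are excluded from the SNP output but retained
as exclusion anchors. Filtering is idempotent.

## Windows, selection, and genes

A 1-based position `p` maps to the window starting at
`floor((p-1)/25000) * 25000`; windows occupy `(start, end]` so
consecutive windows share a printed boundary. Windows with fewer than
10 SNPs are discarded before any statistic, and the top 1% is the
`ceil(0.01 * N)` most extreme retained windows per statistic
independently, with threshold = the least extreme selected value and
ties broken by (chromosome, start).

Candidates are the exact three-way intersection. A gene (1-based
inclusive) overlaps a window iff `gene.start <= window.end` and
`gene.end > window.start` — at least one shared base under the window's
half-open occupancy; nothing short of overlap counts (no nearest-gene
assignment). Adjacent candidate windows stay separate rows, so a gene
spanning two windows appears twice in the table but once in the
distinct-gene count (`merge_adjacent` exists but is off by default).
Genes without a symbol keep their stable id.

## Synthetic data

The generator emulates the two-breed pooled design the scan targets and
nothing more:

| parameter | default | meaning |
|-----------|---------|---------|
| genome | 4 × 5 Mb | 800 windows of 25 kb |
| SNP density | 0.003 /bp | ~60k sites |
| background F | 0.05 | Balding–Nichols differentiation |
| ancestral freq | U(0.05, 0.95) | lets the MAF filter bite |
| pools | 35 + 59 diploids | haploid n = 70 / 118 |
| depth | Poisson(30), ≥ 1 | zero-depth records never emitted |
| base error | 0.002 | symmetric flip |
| indel density | 1e-4 /bp | material for the proximity filter |
| transition fraction | 0.649 | Ts/Tv ≈ 1.85, typical of dog variant sets |
| sweep | s = 0.05, N = 10^4, r = 1e-8 | footprint half-width ≈ 500 kb |

Population frequencies are independent Beta draws around the ancestral
frequency with variance `F p (1-p)`; the analytic expectation of the
genome-wide WC estimate under this model is checked in the tests. A
sweep moves the target population's linked (alt) allele deterministically
through the same hitchhiking map the XP-CLR model uses, with truth
windows defined as those within the footprint half-width (the distance
at which the escape probability reaches 1/2, `s ln2 / (r ln 2Ns)`).
Pooled sequencing draws pool composition binomially from 2n chromosomes,
then reads binomially from the pool frequency.

What the generator does **not** emulate — and hence what passing
recovery tests cannot certify on real data: linkage disequilibrium
beyond the deterministic transform, mapping and reference biases,
duplicate reads, depth heterogeneity along the genome, demographic
structure beyond a single split, and allele-frequency spectra shaped by
real mutation processes.

## Validation scale

The recovery experiment plants three s = 0.05 sweeps on a 20 Mb genome
(~60k SNPs, ~800 windows) and runs 20 seeded replicates plus 10 neutral
replicates; a sweep counts as recovered when any candidate window falls
inside its footprint. These sizes keep a full validation run in the
minutes range on one core while leaving ~700 neutral windows per
replicate for the outlier thresholds to be meaningful.

## Known limitations

* Windowed F_ST inherits uncorrected read-sampling noise (see above);
  absolute values are comparable only within a depth design.
* The sync format carries no site quality, so sync input receives a
  sentinel quality of 255 and the quality filter is a no-op there; the
  VCF path preserves QUAL.
* `omega` absorbs reference-frequency noise and pool sampling along with
  genuine drift; it is a scale parameter, not an estimate of divergence
  time.
* Exactly-tied statistics at the top-1% boundary are resolved by genomic
  position, which is reproducible but arbitrary.
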