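# Methods

## Coordinate conventions and inputs

All genomic coordinates are 0-based with half-open intervals. Only
autosomes (`chr1`–`chr22`, with or without the `chr` prefix) are kept;
sex chromosomes, chrM and non-canonical contigs are dropped at load time,
since both scores are defined on autosomes. Nucleosome maps, read starts
and fragments are read from BED-like text or SAM/BAM (via pysam);
a record's nucleosome center is `floor((start + end)/2)`, so
single-position records pass through unchanged.

The "start" of a read defaults to its reference-leftmost aligned
coordinate regardless of strand. This is deterministic and symmetric
under the ±300 bp footprint window; the alternative convention (5′ end on
the read's own strand, so reverse reads contribute their rightmost
coordinate) is available behind `leftmost=False` for users whose upstream
pipeline defines starts that way. The mapping-quality threshold defaults
to 30 and is configurable; duplicate-flagged, secondary, supplementary
and unmapped alignments are always excluded, and every loader reports
retained + excluded = input.

## Footprint histogram

For each read start `s` the nearest nucleosome center `c` on the same
chromosome is found by binary search on the sorted center array; the
signed distance `s − c` is kept when |s − c| ≤ 300, giving 601 integer
bins. Exact ties between two centers are assigned to the
smaller-coordinate center — a deterministic rule whose only observable
effect is on the handful of reads exactly halfway between centers; the
mirror-symmetry property test quantifies that it introduces no
directional artifact. The search is contract-tested against an all-pairs
brute-force scan.

## Mixture model and the nucleosome score

Class profiles are estimated by pooling counts over the training samples
of each class with a Dirichlet pseudocount α = 1 per bin:
θ_k,i = (Σ_j y_ji + α)/(n_k + 601α). Pooling is the maximum-likelihood
estimate under the joint multinomial model of the training data;
smoothing keeps every bin strictly positive so the mixture likelihood is
finite at λ = 0 and 1. A depth-equalizing variant (each sample weighted
1/n_j) is available for cohorts with very uneven sequencing depth but is
off by default.

The per-sample posterior is p(λ | y) ∝ Π_i θ_mixt,i^{y_i} on λ ∈ [0, 1]
(flat prior, no reparameterization). Because it is one-dimensional, the
default estimator evaluates the log posterior on a uniform grid
(100,001 points), exponentiates after subtracting the maximum, normalizes
by the trapezoid rule, and reads the 2.5/50/97.5% quantiles off the CDF
with linear interpolation. Grid error is far below the posterior spread
at any realistic depth; the grid size is configurable (minimum 1,001).

The MCMC path mirrors the original estimation setting: four parallel
chains, 300 kept iterations after 300 warm-up iterations, pooled draws,
posterior median. The sampler is a random-walk Metropolis on [0, 1] with
reflecting boundaries; the proposal scale is initialized from a Laplace
approximation at the MAP (2.4 × curvature scale) and adapted toward ~40%
acceptance during warm-up only. Chain c uses seed `seed + c`, and an
explicit seed is required. Convergence is assessed with the classic
split-R̂ (chains halved, R̂ = sqrt(((n−1)/n·W + B/n)/W)); identical
constant chains define R̂ = 1. Results with R̂ above the threshold
(default 1.05) are flagged, never silently accepted. The sampler is
validated against quadrature (|median difference| ≤ 0.005 on random
fixtures) rather than trusted on its own.

Degenerate cases: an empty histogram is an error; identical class
profiles make λ unidentifiable — the posterior is flat, the score is
reported as 0.5 with a full-width interval and the result is flagged.

## Genome-wide z-score

Bins are 1 Mbp, tiling autosomes; short terminal bins and bins with
mappability < 0.8 (configurable) are unusable. Correction is
counts-per-million of the usable total, divided by a lowess trend of CPM
against GC (span 0.3, fitted on usable bins; the trend collapses to the
mean when GC is constant), divided by mappability. Counts-per-million
first makes the result invariant to library size by construction.

Windows are 50 consecutive usable bins, step 1 bin, never crossing a
chromosome boundary; chromosomes with fewer than 50 usable bins simply
contribute no windows. The reference panel (≥3 healthy samples, identical
grids) stores per-window mean and standard deviation (sd floored at 1e−8
to survive degenerate simulated panels) and a leave-one-out
sum-of-squares distribution: each member is z-scored against the panel
without itself, so its own noise does not deflate its reference. A
sample's genome-wide z-score is (Σ z_w² − mean_LOO_SS)/sd_LOO_SS.

## L-WPS

At position p with window W = [p − 60, p + 60): the number of fragments
covering all of W minus the number of fragments with a start or last
base inside W, each fragment counted at most once on each side of the
subtraction. The sweep builds difference arrays of the per-fragment
contribution intervals (merging the two end intervals when the fragment
is shorter than the window) and is tested for exact equality with the
position-by-position definition. An optional fragment-length filter
(e.g. 120–180 bp mononucleosomal fragments, as in the literature this
score comes from) is off by default. Only the 120 bp "large" window
variant is implemented.

## Evaluation

AUC is the Mann–Whitney estimator with midranks (ties count 1/2);
confidence intervals use DeLong's structural components. Score
combination fits a logistic regression with intercept on the average
ranks of both scores; perfect separation or a rank-deficient design
(e.g. a constant score column) falls back to a lightly ridge-penalized
fit (L2 on the slopes only), flagged on the result. Optimism correction
follows Harrell: refit the whole procedure on each bootstrap resample,
take (AUC on the resample − AUC of that model applied to the original
cohort), average over 500 seeded resamples, subtract from the apparent
AUC. Resamples that lose a class are redrawn-by-skipping (they contribute
nothing), which keeps the estimate defined for small cohorts. New samples
are scored by interpolating their raw scores against the training
score→rank mapping, which also makes the combination invariant to
monotone transforms of either input. The Mann–Whitney test uses the
tie-corrected normal approximation with continuity correction, switching
to exact enumeration of label assignments (valid under ties) when the
smaller group has ≤ 8 observations; the two-sided exact p-value is
P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|). Spearman's ρ is the Pearson
correlation of average ranks; constant vectors are rejected.

## Synthetic data

The generator exists to give every module a ground truth, not to imitate
real chromatin.

- **M-profiles.** healthy f(d) ∝ 1 − a·exp(−d²/2σ_c²) +
  e·[exp(−(d−μ)²/2σ_e²) + exp(−(d+μ)²/2σ_e²)] with μ = 85 bp,
  σ_e = 25 bp, σ_c = 40 bp, a = 0.5, e = 0.6 — edge peaks near ±85 bp
  and a central dip, matching the qualitative shape of empirical cfDNA
  footprints. The tumor-like profile is (1−s)·f + s·uniform with s = 0.7:
  a flattening toward uniform, the direction of the deviation seen in
  HGSOC plasma. Histograms are single multinomial draws from
  λ·θ_tumor + (1−λ)·θ_healthy.
- **Reads and maps.** Centers at i·spacing (+ optional jitter), read
  starts = center + offset drawn from a profile. With spacing ≫ 600 bp
  the footprint recovers the profile exactly; at nucleosomal spacing
  (190 bp) neighbor attribution folds the tails, which the tests
  quantify rather than hide.
- **Fragments.** Midpoints on phased centers; lengths follow the cfDNA
  size ladder — dominant 167 bp mode with sub-peaks every 10 bp (the
  helical pitch of DNA on the nucleosome) and 3 bp within-peak jitter.
- **Binned coverage.** Expected count = depth × (1 + gc_slope·(GC −
  0.45)) × mappability × (1 + tf·(CN/2 − 1)), observed Poisson (negative
  binomial under an optional overdispersion parameter, for stress-testing
  z-score calibration). The synthetic genome is 4 chromosomes × 550 bins
  = 2,200 usable 1 Mbp bins, the same order as the ~2,700 autosomal bins
  of a human reference.
- **Cohorts.** Benign-like samples have λ = 0 and tumor fraction 0;
  invasive-like samples draw λ from [0.4, 0.8] and tumor fraction from
  [0.05, 0.2], with one gained segment (copy 3) covering 20% of bins.
  The default 200,000 histogram counts per sample corresponds to the
  fraction of a ~10⁷-read LC-WGS run that lands within ±300 bp of a
  mapped nucleosome center at desk scale; at that depth the
  mixture-weight posterior is narrow enough that group separation is
  essentially determined by the generating λ ranges.

What passing these tests shows: the estimators recover the quantities
the generative model defines, at the stated depths, with calibrated
nulls. What they do not show: performance on real plasma, where class
profiles differ far more subtly than the synthetic flattening, GC bias
is not linear, coverage is not Poisson, and the nucleosome map itself is
imperfect. Clinical-cohort AUCs cannot be reproduced here because the
underlying data are controlled-access.

## Pipeline determinism

`run_pipeline` derives all stage randomness from one global seed through
a single `numpy` generator consumed in a fixed order, rounds scores to
six decimals before writing, and records a SHA-256 per output file in a
manifest keyed by a hash of the configuration (excluding the output
location). Reruns with the same configuration and seed are
byte-identical; the manifest contains no timestamps.

## Known limitations

- Class profiles are pooled-count estimates; no hierarchical per-sample
  θ inference, no more than two classes, no region-restricted scores.
- The quadrature/MCMC equivalence is verified on fixtures with
  well-separated profiles and n ≥ 5×10⁴; at very low counts the
  posterior median from 1,200 MCMC draws carries Monte-Carlo error of
  the same order as the posterior spread.
- The genome-wide z-score pipeline performs no segmentation and no
  absolute copy-number or tumor-fraction estimation.
- S-WPS (short-fragment window protection) is not implemented.
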