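# Methods

This note records the models, parameter choices, and numerical conventions
behind `pulsa-screen`, and what the synthetic benchmarks do and do not show
about real screens.

## Generative model of the screen

A screen is a population of cells, each carrying exactly one sgRNA (the
low-MOI assumption: the bench protocol titers virus to ~30% survival
precisely so multiplets can be ignored). For a cell with guide g targeting
gene G:

- knockout success is Bernoulli(ε_g), where the per-guide efficacy ε_g is
  drawn once per guide (default Beta(8, 2), mean 0.8 — typical editing
  rates for a well-designed library). Selection latency (the 14 days of
  puromycin culture before sorting) is collapsed into ε_g; there are no
  time dynamics.
- inclusion formation is Bernoulli with
  `logit P = base_logit + effect_G · [knockout succeeded]`.
  The additive-logit link is the simplest generative model consistent with
  a screen that only observes population fractions. `base_logit` is a free
  parameter (the baseline fraction of reporter-positive cells with
  inclusions is not pinned down by the protocol); the package default is
  −2.2 (≈10% baseline aggregation), which matches the regime in which a 5%
  sorted tail can be nearly pure.
- reporter expression F is log-normal (σ = 0.5 by default) around a mean of
  1000 arbitrary units; guide abundance before sorting is log-normal per
  guide (σ = 0.3) to emulate library skew — no distribution is specified by
  the protocol, and the fold-change statistic cancels overall abundance.
- aggregated cells draw a latent `punctate_fraction` f ∈ [0.3, 0.95]
  (Beta(5, 2) rescaled): the fraction of F concentrated in the inclusion.
  The bounds are a synthetic choice giving clearly bimodal pulse shapes;
  they parameterize the diffuse-vs-punctate dichotomy that the reporter
  images show, not a measured quantity. Non-aggregated cells have f = 0,
  so `f > 0 ⇔ aggregated` is an invariant.

Not modeled: cell cycle, growth/fitness dropout (the screen sorts a single
timepoint), transfection mosaicism beyond the expression distribution, and
multi-guide integration.

## Pulse optics

The cytometer is modeled explicitly rather than as a black box. A cell
transits a Gaussian beam (σ_beam, default 2 µm) at `scan_speed`; the
diffuse reporter occupies the cell with spatial σ_cell =
`cell_sigma_factor × diameter` (0.25 × N(15, 1.5) µm ≈ diameter/4), the
inclusion is nearly a point source (σ_punctum = 0.5 µm). Convolution of
Gaussians gives the noiseless pulse as a two-component Gaussian in time
with component sigmas `sqrt(σ_beam² + σ_comp²)/v` and weights (1−f)·F and
f·F. Then:

- **height** = peak of the mixture (+ Gaussian detector noise, σ = 0.5
  signal units, floored at 0);
- **width** = time the noiseless signal exceeds an absolute
  `trigger_threshold` (2.0 signal units). An absolute threshold — not
  FWHM — is deliberate: FWHM is invariant to F and would erase the
  height-vs-width discrimination at the gate boundary. Pulses that never
  cross the trigger get width 0 and are excluded from gating (counted in
  QC), as on a real instrument;
- **area** = time-integral = F exactly (zero-mean noise integrates away),
  which makes area the total-expression analog and gives the exact
  linearity the tests assert.

The closed-form peak (component amplitude ∝ 1/σ) is verified against
numeric quadrature of the beam×distribution convolution to 1e-6; the width
crossing is found by 64 vectorized bisection steps bracketed by the
envelope Gaussian, giving ~1e-15 relative accuracy.

With the default geometry a punctate cell is ~1.7× taller and measurably
narrower than a diffuse cell of equal F. `beam_sigma = 2 µm` was chosen so
that, after the default 10–90% expression gate, the 5% aggregate tail is
>90% pure at 10% baseline aggregation — a regression-tested property of the
defaults, not an instrument spec.

## Gating

The sort protocol is: (1) an expression gate keeping pulse areas inside the
closed quantile band [q_lo, q_hi] (default 0.1–0.9; the bench protocol
sorts "a narrow range of expression"), where the q-th bound is the
ceil(q·n)-th smallest area — this order-statistic convention is normative
and tested; (2) aggregate/diffuse gates as the top/bottom
`target_fraction` (default 5%) tails of r = height/width. The real sorter
draws a 2-D polygon in H×W; its geometry is not published, so a 1-D ratio
quantile is used as a stated substitute that reproduces "≈5% per tail"
deterministically. Thresholds are order statistics capturing
round(target·n) records; boundary records belong to the gate (closed
interval, documented tie-break).

## Sequencing and counting

Each sorted pool is split into technical replicates (the protocol divides
each collected pool before gDNA extraction; default 2). Reads are
`left_flank + spacer + right_flank` with the lentiCRISPR-style constant
flanks as defaults (the true primer coordinates are not published; flanks
are config values), per-base substitution errors, and constant quality.
Counting anchors on the first exact occurrence of the left flank, takes
`spacer_length` bases, optionally verifies the right flank, and matches
against the library by hash — exact, or rescued at Hamming distance 1 when
the hit is unique; equidistant multi-hits are dropped as ambiguous, never
split. This replaces aligner-based mapping with a deterministic equivalent:
the mapping step of this assay only ever counts fixed-length spacers. QC
categories (`assigned / flank_fail / no_match / ambiguous`) partition the
reads by construction.

The pipeline's `tally` sequencing mode skips read synthesis and draws each
sample's counts multinomially from the sorted-cell tallies at the same
depth — statistically the error-free limit of the read path — and is the
default for large simulations; `reads` mode runs the full FASTQ round trip.

## Scoring

Per sample: `normalized = count / mean(count) × 10⁶ + 1`. "Sample mean" is
read literally as the mean count per guide (not the total); the choice only
rescales samples identically and cancels in the fold change. The
pseudocount is added **after** scaling, following the sentence order of the
protocol description, so ratios use (scaled + 1) values. Normalization is
exactly scale-invariant.

Per guide: LFC = log₂(norm⁺/norm⁻) (base 2 because hits are thresholded at
"LFC > 1" and configurable). Guides are ranked by mean normalized
abundance across the two pools, ties broken by guide id; each guide's LFC
is standardized against the mean and sample SD (ddof = 1) of the LFCs in a
window of `window` (default 2000) guides centered on it in rank space.
Edge windows shift inward so every window has exactly `window` members
(never shrunk — keeps the Z variance comparable across ranks; edge
behavior is not specified by the protocol). The focal guide is included in
its own window (simplest literal reading; excluding it changes Z by
O(1/window) and is exposed as a config flag). A zero-SD window yields
Z = 0. The vectorized implementation is required to match a naive
O(n·window) double loop to 1e-10; both live in the package and the oracle
is used in tests only.

Per gene: **phenotype** = mean signed Z of the two guides with largest |Z|
(ties by guide order; single-guide genes pass through flagged). **p** =
two-sided permutation tail of the gene's mean guide Z: for each gene size
s, `n_perm` draws of s values without replacement from the pooled
targeting-guide Zs, p = (1 + #{|null| ≥ |obs|})/(n_perm + 1). One shared
null per size class (statistically identical to per-gene nulls under label
exchange, ~100× cheaper); draws are seeded per size class so results are
independent of gene iteration order. An exhaustive mode enumerates all
C(n, s) subsets when that count is below a cap and returns the exact tail
fraction without smoothing. Two-sidedness matches a screen that reports
hits in both directions; sidedness, pool membership and smoothing are
visible in config.

Replicates are aggregated as unweighted per-guide means of LFC and local Z
(the protocol says only that replicates were "aggregated"; count pooling
and Stouffer weighting are alternatives deliberately not defaulted).
A consequence worth noting: because Z is standardized within replicate and
then averaged, the null Z of a guide has SD ≈ 1/√2, and a guide's combined
Z is approximately its mean LFC divided by the **per-replicate** window SD.
The permutation null is built from the same combined Zs, so p-values stay
calibrated regardless.

NTCs take part in the abundance ranking and window statistics (they are
real sequencing observations at matched abundances) but are excluded from
the permutation pool by default — both choices are unspecified in the
protocol and configurable. Grouped into consecutive pseudo-genes of 4,
NTCs give an independent null: on a null screen their p-values are
KS-uniform.

Hits: p < 0.005 and |phenotype| > 1, with the sign reported separately so
both hit directions can be listed. No FDR correction is applied by
default (the screen thresholds raw p-values); Benjamini–Hochberg is
available as an opt-in.

## Benchmark fixtures

Problem sizes are scaled to a single desk CPU while keeping the screen's
design ratios: 2,000 genes × 4 guides + 1,000 NTCs, 2,000-guide windows,
5% tails, 2 technical replicates, 100 reads/guide/sample, and 20,000
permutations (the full screen default is 100,000).

- **Null calibration**: no planted effects, 1,000 cells/guide. Measures the
  fraction of genes at p < 0.05, KS uniformity, and the hit count at the
  p < 0.005 reporting threshold.
- **Separable recovery**: 25 promoters (uniform 3–4 logits) + 25
  suppressors (uniform 1.6–1.9 logits), knockout efficacy 1, 2,000
  cells/guide (~80 cells/guide per sorted pool — an order of magnitude
  below the real sort's coverage but enough that 5-fold-depleted guides
  stay clear of the pseudocount floor). Magnitudes are direction-specific
  because the logit → fold-change map saturates on the depletion side:
  equal logits would pile strongly depleted guides onto the pseudocount
  floor at the bottom of the abundance ranking, where they inflate each
  other's window SD. With these choices every planted effect shifts its
  guides' LFC by ≥3 per-replicate window-SDs (median ≈ 4).
- **Noisy recovery**: per-cell efficacy 0.5, effect magnitudes solved from
  a purity-corrected enrichment model (sort-tail purities 0.99/1.0,
  regression-measured properties of the default optics) so the predicted
  guide shift is 1.5 window-SDs.
- **Micro-oracles**: hand-computed normalization/LFC/local-Z/phenotype
  values; exhaustive-vs-sampled permutation p on a 12-guide pool; √5
  height ratio vs quadrature; error-free 100,000-read counting round trip;
  a reduced 200-gene end-to-end screen whose planted gene must rank first
  and whose rerun must be byte-identical.

What passing these shows: the statistic is calibrated under its own
generative assumptions and recovers effects of the designed size. What it
does not show: robustness to real-screen pathologies outside the model —
fitness-coupled guide dropout, copy-number artifacts, sort impurity drift,
PCR jackpots, or guide off-target effects.

## Reproducibility

Every stage draws from `default_rng([seed, crc32(stage_name)])`, so stages
can be rerun independently; identical config + seed yields byte-identical
artifacts (manifest includes a hash of the scientific config, excluding
output paths). Floats are written with `%.10g`.

## Known limitations

- The optics are invented physics calibrated to behave like the assay, not
  a fitted instrument model; no FCS file I/O, compensation, or doublet
  discrimination.
- One guide per cell; no MOI > 1 handling.
- No indel tolerance or quality-aware matching in counting; no UMIs.
- Single-timepoint sorting only; no enrichment-over-time designs.
- The 2-D sorter gate is approximated by a 1-D ratio quantile.
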