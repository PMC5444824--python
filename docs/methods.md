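# Methods

## The statistical procedure

`enrichfit` treats enrichment detection as a single global modeling problem.
Given paired alignments from a feature-enriched library and an unenriched
control, the per-position enrichment score is the depth ratio rescaled by
the ratio of library-wide totals, `E_i = (D1_i/D2_i)·(ΣD2/ΣD1)`, computed
over every position with at least one mapped read in either library. The
score is scale-free: multiplying either library's counts by a constant
leaves every score unchanged, so no prior library-size normalization is
needed.

The null hypothesis is that, absent enrichment, scores are normal after a
Box-Cox power transform. The enriched minority skews the raw distribution
right; the transform absorbs the bulk shape, and enriched positions surface
in the upper tail of the fitted normal. Calling is one-sided by
construction — depletion is never tested — and, because the transform is
strictly increasing, thresholding transformed scores at `μ + σ·z₁₋α` is
exactly equivalent to thresholding raw scores at the inverse image of that
value (a property the test suite asserts as an identity).

Assumptions worth stating plainly: (1) the vast majority of analyzed
positions are unenriched, so the sample mean and SD of transformed scores
estimate the null parameters with negligible contamination; (2) one global
transform fits the whole genome — transcript-abundance variation inflates
the score variance rather than invalidating the model, which is why the fit
is gated on Q-Q linearity; (3) p-values are marginal and uncorrected
(per-position multiplicity is left to the user; a Benjamini-Hochberg
q-value column is emitted for convenience but never used for calling).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `count_mode` | `start` | which read coordinate carries the count: 5′-most aligned base (`start`), 3′-most (`end`), or every aligned base (`all`). 5′-end protocols use `start`; internal modifications use `all`. |
| `pseudo_count` | on | unit count added to both libraries at every analyzed position; guarantees a defined ratio. May be disabled only with per-library minimum depths ≥ 1. |
| `min_depth_enriched/control/sum` | 0 | raw-depth inclusion filters. Filtering discards sparse but genuine signal, so the default is fully inclusive. |
| `alpha` | 0.05 | one-sided upper-tail error rate of the fitted normal. |
| `r2_cutoff` | 0.90 | Q-Q R² gate below which the normal-model path is refused. |
| `percentile` | 95 | rank cutoff of the fallback path (top 5% called, ties included). |
| `min_mapq` | 0 | mapping-quality filter; unmapped/secondary/supplementary records are always skipped, duplicates always kept (reads sharing a 5′ start are the signal at enriched sites). |
| `window` (recall) | 5 nt | same-strand distance within which a call counts as detecting a known site. |

## Numerical choices

- **λ estimation.** Profile log-likelihood (via `scipy.stats.boxcox_llf`)
  maximized with a bounded scalar optimizer on λ ∈ [−5, 5], absolute
  tolerance 1e−5. At least 10 distinct positive scores are required;
  constant input is a degenerate-data error.
- **Q-Q construction.** Plotting positions (i − 0.5)/n (Hazen); R² is the
  squared Pearson correlation over the full point set, no trimming. R² is
  affine-invariant in the data, so the gate does not depend on μ, σ.
- **Pseudo-counts and totals.** The pseudo-count is added only at selected
  positions (those covered in at least one library), and the normalizing
  totals ΣD1, ΣD2 are taken after that addition over the same set, keeping
  the score equation self-consistent on exactly the analyzed positions.
- **Percentile fallback ties.** The called set is the ⌈n(100 − P)/100⌉
  largest scores expanded to include all ties at the cutoff value; an
  all-tied (zero-variance) input calls everything with a warning. The
  count uses the integer-friendly form `n(100 − P)/100` to avoid
  floating-point artifacts of `1 − P/100`.
- **Inverse transform at the boundary.** For λ < 0 the transform is bounded
  above by −1/λ; a critical value beyond it maps to +∞ (nothing callable on
  the raw scale). For λ > 0, arguments below the lower bound map to 0.
- **Fisher combination.** Computed directly as the χ²₂ₖ upper tail of
  −2Σln p (vectorized over positions); exact zeros are clamped to the
  smallest positive float with a warning. Positions missing a p-value in
  any replicate get no combined p and are excluded from Fisher calling but
  remain eligible for the consensus rule among the replicates where they
  are observed.
- **Coordinates.** Internally pysam's 0-based half-open; everything
  reported (tables, GFF3) is 1-based inclusive. Soft-clipped bases have no
  reference coordinate and never count; the read start is the first aligned
  base after clipping.

## The synthetic-data generator

`simulate` emulates the paired-library design: read 5′ starts are drawn
from one multinomial per library over all transcribed positions of both
strands (all positions where a full-length read fits), with the enriched
library's weight multiplied by the enrichment factor at planted sites.
Optional gamma-distributed position weights (shared between libraries)
inject the transcript-abundance heterogeneity a global model must absorb;
the default is homogeneous. Reads are error-free, full length (50 nt), and
written directly as coordinate-sorted SAM — alignment is deliberately
bypassed so tests isolate the statistical method from aligner behavior.
`simulate_depth_tables` exposes the identical sampling model one step
before SAM emission, as the fast path for purely statistical studies.

Standard study conditions used by the tests and the acceptance script,
chosen once as representative of a bacterial 5′-end experiment scaled to
desk size:

- **Strong-signal fixture:** 5,049 nt genome (10,000 transcribed
  position keys), 20 planted sites at factor 50, background depth 20
  (200,000 reads per library), two replicates sharing sites with
  independent sampling.
- **No-signal calibration:** 25,049 nt genome (50,000 keys), depth 20, no
  planted sites.
- **Weak-signal fixture:** factor 1.7 with 40 planted sites. At background
  depth 20 the null score SD is ≈ √(2/20) ≈ 0.32, putting the α = 0.05
  critical value near 1.5–1.7, so a 1.7× site straddles the threshold and
  single-replicate recall lands near 50% — the regime where combining
  replicates visibly adds power.
- **λ-recovery sampler:** transformed scores are stratified
  (quantile-jittered, then shuffled) normal draws whose inverse transform
  spans roughly 0.1–30, the range narrowed geometrically until the
  transform's support boundary −1/λ sits ≥ 5 SD from the mean (binding
  mainly at λ = 1). Stratification is variance reduction: recovery checks
  then measure estimator consistency, not Monte-Carlo noise, which matters
  because λ is weakly identified near 1 at moderate coefficients of
  variation.

What the generator does **not** emulate: sequencing errors and quality
variation, multi-mapping and alignment ambiguity, paired-end structure,
protocol-specific biases (ligation, PCR), and correlated replicate noise
(replicates share planted sites but are sampled independently, while real
replicates often share a control library). Passing tests therefore certify
the statistical machinery under its own model — calibration, power,
invariances — not robustness to upstream artifacts, which the mapping-
quality and depth filters only partially address on real data.

## Design choices where the design was open

- Depth counts **reads** per position in start/end mode and **aligned
  bases** (equivalently covering reads) in all mode.
- Both strands pool into one global score set and one fitted distribution;
  there is one experiment-wide critical value.
- When the normality gate fails the model path is refused outright and the
  percentile path reported, rather than silently emitting p-values from a
  bad fit; users may lower the gate explicitly.
- Recall denominators exclude known sites with no enrichment record within
  the window (nothing was observable there); both counts are always
  reported. Matching is same-strand only, since 5′ ends are strand-specific.
- Gene distances are nonnegative magnitudes with an explicit
  upstream/downstream relation; on the − strand the gene's end coordinate
  is its 5′ boundary and the conventions mirror accordingly.
- GFF3 output uses feature type `enriched_site` with the score in the
  score column and p-value/depths in attributes; gene lookup reads feature
  type `gene` by default (configurable).

## Known limitations

- The global model is conservative for weakly enriched sites in any single
  experiment; replicate combination is the intended remedy.
- Very discrete score distributions (low depth, few distinct ratio values)
  can fail the Q-Q gate; the percentile path then calls a fixed fraction
  regardless of signal.
- Memory scales with the number of covered positions (hash map of
  per-position counts); whole-mammalian-transcriptome `all`-mode analyses
  are the stress case.
- No spike-in-based false-discovery calibration and no clustering of
  adjacent calls; both are downstream steps outside this package's scope.
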