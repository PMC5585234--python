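# Methods

## Overview

The pipeline turns occurrence records of zooxanthellate reef corals into
per-cell proportional assemblages, calibrates two transfer-function
families against modern sea-surface temperature (SST) summaries, applies
them to fossil assemblages, and evaluates the reconstructed latitudinal
anomaly profiles. Every stage is exercised against a synthetic world in
which the answer is known.

## Data model and filters

Occurrence records carry taxon, genus, rank, coordinates, depth (m), an
epoch label and a zooxanthellate flag. Filters:

- **Depth ≤ 60 m, boundary inclusive.** Records with missing depth are
  retained with a logged warning (depth fields in occurrence databases are
  sparse; dropping them would gut real data); a switch drops them instead.
- **Zooxanthellate only** (optional switch).
- **Gridding**: 1° cells with floor semantics; a coordinate on the lower or
  left boundary belongs to that cell; longitudes wrapped to [−180, 180).
- **Proportions are count-based** — each record counts once, so p[c,t] =
  n(t in c) / n(c) — rather than presence/absence, which is available as a
  robustness switch. Duplicate records are deliberately not deduplicated.
- **Single-genus cells are excluded** (min_genera = 2) from *both* modern
  and fossil matrices and for *both* methods. The motivation for the rule —
  cells dominated by a taxonomic sampling focus carry no compositional
  signal — applies symmetrically, so we do not restrict it to the
  factor-analysis fossil branch.
- **Harmonization** restricts modern and fossil matrices to their shared
  taxon pool (identical column order), renormalizes rows and re-applies the
  cell filter, mirroring a calibration on extant taxa that also have a
  fossil record.

SST summaries per cell come from a 12-month climatology: `mean_sst` is the
arithmetic mean of the climatological months and `stv` (seasonal
temperature variability) the warmest-minus-coldest month range. STV is
computed on the multi-year climatological monthly means, not as the mean of
per-year ranges (the latter is available behind a flag). Cells with any
missing climatological month are treated as missing and dropped at the
assemblage–SST pairing step.

## The synthetic world

The generator produces the study conditions used throughout testing:

- **Field**: 1° cells spanning 32°S–33°N at 2 longitudes (130 ocean
  cells), mean SST = 28 − 0.25·|lat| °C, sinusoidal monthly curve with
  amplitude 1 + |lat|/6 °C and a 6-month phase flip in the southern
  hemisphere. Sampling the sinusoid at month indices aligned with its peak
  makes the annual range equal the prescribed amplitude exactly, which
  keeps ground truth closed-form.
- **Species pool**: 30 species in 10 genera; optima evenly spaced over
  19.5–28.5 °C (so the pool tiles the thermal gradient deterministically);
  tolerances uniform 1.5–3.5 °C; peak occupancies uniform 0.3–0.9; 20% of
  species get a monotonically increasing logistic response, reflecting the
  minority of taxa whose occupancy rises with temperature.
- **Sampling**: per cell and species, detections ~ Binomial(effort, p)
  with p the niche occupancy at the cell's mean SST; modern effort 50.
  Depths are drawn uniform (0, 60] m so the depth filter is exercised but
  passes; contamination (deep or azooxanthellate records) is injectable to
  test the filters.
- **Fossil scenario**: the field is shifted by a piecewise-linear latitude
  function — −1 °C for |lat| ≤ 15°, +2 °C for |lat| ≥ 25°, linear in
  between — with a −1 °C northern-hemisphere seasonal-range offset, then
  sampled at lower effort (15) on half the cells, mimicking the sparsity
  contrast of real fossil compilations.

What the world does **not** emulate: coastline geometry and land cells (the
toy ocean is a full band, with land approximated only in tests via missing
cells), dispersal limitation, habitat factors other than temperature,
taxonomic noise (synonyms, misidentifications), spatially autocorrelated
sampling effort, and time averaging within the fossil epoch. Passing tests
therefore demonstrate that the *method* recovers an imposed climate signal
from niche-driven composition under sampling noise — not that real coral
data carry such a clean signal.

## Imbrie–Kipp factor analysis

1. Rows scaled to unit Euclidean length (classic Q-mode; a no-scaling mode
   exists for linear-algebra tests).
2. Truncated SVD of the scaled matrix, retaining k factors (k must not
   exceed the effective rank; fewer than k+2 samples leaves the regression
   saturated and only warns, since pure reconstruction uses are legitimate).
3. Raw varimax rotation of the sample loadings via the SVD-based iteration;
   the rotation is orthogonal, so row communalities are preserved exactly.
   For two factors the criterion is a single sinusoid in the rotation
   angle, so the iteration's stationary point is the global optimum.
4. Least-squares regression of the environment on the rotated loadings
   (quadratic/cross terms optional, off by default).
5. Prediction by projection onto the (orthonormal) rotated taxon scores;
   communality below 0.5 flags no-analog fossil cells (flagged, not
   dropped). Missing calibration taxa in fossil cells are structural zeros.

Reproducibility conventions: each factor's sign is chosen so its
largest-magnitude taxon score is positive; factors are ordered by explained
variance. k defaults to 5 in the API; the validation analyses use k = 4,
chosen by cross-validated RMSE on the standard world. Calibration fits are
invariant to the rotation (the regression absorbs any orthogonal rotation),
which is verified numerically in the tests.

## ANN ensemble

A single-hidden-layer network: logistic hidden units, linear output,
squared-error loss, trained by L-BFGS-B with analytic gradients from
uniform(−0.5, 0.5) initial weights. "Hidden size 5" means five hidden
*units* in one hidden layer; the published weight caps (1000 weights for
187 species inputs, 400 for 66 genera) match the single-hidden-layer weight
count (946 and 341) and the reference implementation supports exactly one
hidden layer, so a deep reading is untenable. Inputs and target are
standardized from the calibration set (constants stored in the ensemble).

The transfer function is the per-cell **median** over seeded replicates
that differ only in weight initialization (bootstrap resampling of the
calibration set is available but off by default); the interquartile range
is reported as a stability diagnostic. Replicates are deterministic in
(base_seed, replicate_index). Replicates whose optimizer terminates
abnormally are dropped with a logged count (> 20% failures aborts the
run); reaching the iteration cap is a normal stop, part of the training
protocol, not a failure.

Numerical choices: weight decay defaults to 0; gradient tolerance 1e-6 and
ftol 1e-15 for full-precision fits. Desk-scale validation runs cap
training at 200 iterations with gradient tolerance 1e-5 — on the standard
world this leaves a standardized residual of ~0.02 (≈ 0.04 °C), an order
of magnitude below the sampling-induced error, at a tenth of the cost.
Validation ensembles use 100 replicates (20 inside multi-seed loops, 10 in
the sensitivity grid); full-scale runs with 1000 replicates are supported
by the same code path.

## Evaluation

- **Anomalies** are reconstructed minus modern at the fossil cell, with the
  *observed* modern climatology as the baseline — the less circular choice;
  comparing against the coral-modeled modern value is possible but is a
  different analysis.
- **LOESS**: tricube-weighted local polynomial regression; the span is the
  fraction of points in each local window; degree 2 by default; windows too
  small for the degree are widened to the minimum viable size. Evaluated at
  1° steps.
- **Band means**: 5° latitudinal tiles anchored at 0°, labelled by their
  centers; empty bands reported missing. Summary statistics are restricted
  to 32°S–33°N, the reef band (configurable).
- **Spearman matrices** use pairwise complete cases (≥ 4 shared bands) and
  an exact permutation null for n ≤ 8 tie-free samples (enumeration via the
  rank-difference formula), falling back to the t-approximation otherwise.
  Wilcoxon signed-rank tests go through scipy (exact for small tie-free
  samples); all-zero difference vectors return p = 1. Matrices report raw
  p-values; no multiple-testing correction is applied (noted here rather
  than silently).
- **ANOVA** is one-way across sources with 5° band means as the unit of
  replication — the same unit as the correlation matrix, chosen because
  sparse proxy series are only comparable after banding.
- **Cross-validation**: resubstitution (apparent error, the default
  internal check) and leave-one-out; in each LOO fold, taxa absent from
  the training fold are dropped and rows renormalized.
- **Sensitivity**: species pools and calibration cells are subsampled
  without replacement at given fractions (seeded); both methods are refit
  (reduced-replicate ANN) and internal RMSE plus the mean absolute shift of
  the fossil anomaly profile against the full-data run are reported. The
  subsampled pool is never allowed below 2 species; a single-species
  "assemblage" is compositionally empty (every row identically 1) and the
  factor model refuses it.

## Problem sizes

The standard validation world uses 130 calibration cells × 30 species,
65 fossil cells, effort 50/15. Multi-seed checks use 20 seeds (10 in the
acceptance script) with 20-replicate ensembles; leave-one-out validation
uses 100-replicate ensembles. These sizes make the full suite a
desk-scale computation while keeping binomial sampling error well below
the imposed anomaly amplitudes.

## Known limitations

- The taxon-niche world is driven by mean SST only; STV predictions ride
  entirely on the covariance of seasonality with mean temperature along the
  latitude gradient, so an imposed STV anomaly that is decoupled from the
  mean-SST anomaly is not recoverable by construction — a real limitation
  of assemblage STV transfer functions that the synthetic world reproduces.
- Fossil communality diagnostics flag, but do not correct, no-analog
  compositions.
- The LOESS implementation targets profile curves (hundreds of points);
  it is a direct per-grid-point fit with no interpolation speedups.
- Exact Spearman p-values are limited to n ≤ 8 (n! enumeration).
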