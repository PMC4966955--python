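# Methods

## Data model

A space-time field is a `P × N` matrix: `P` pixels unraveled row-major
from the north-west corner, `N` uniformly spaced time steps (daily or
8-day composites; the delay embedding assumes equal spacing). Missing
data is an explicit boolean mask, not NaN alone, so the gap-filling
iteration can distinguish "originally missing" from "numerically
invalid". Units are W/m² throughout.

## EOF analysis and delay embedding

The decomposition is an SVD of the mean-removed matrix. Two choices are
deliberate:

- **Row means.** The mean removed before SVD is the per-row (per pixel,
  or per pixel-lag row) mean, restored on reconstruction. This keeps each
  pixel's climatology out of the mode competition and makes the empty
  reconstruction return the climatology.
- **Vertical stacking.** Delay embedding builds one `W × (N−W+1)` Hankel
  block per pixel and stacks the blocks vertically, giving a
  `(P·W) × (N−W+1)` matrix — the multichannel-SSA convention. The
  alternative (horizontal concatenation) would cap the rank at `W` and
  could not hold a dozen secondary components at `W = 4`.

De-embedding averages the Hankel anti-diagonals per pixel (1 to `W`
entries per time step). It is the exact inverse on consistent Hankel
matrices; after truncation, where anti-diagonals disagree, the averaging
is the least-squares projection back to a valid series and incidentally
suppresses mode-truncation noise.

Mode signs are arbitrary in any SVD; each mode is normalised so its
largest-magnitude spatial loading is positive, which makes results
deterministic. Ties between equal singular values keep the
factorisation's order and are unstable under permutation — accepted, as
exact ties do not occur in continuous data.

`select_components` returns the smallest k whose cumulative variance
fraction reaches the threshold, with a 1e-12 slack so a threshold of 1.0
is not defeated by rounding.

## Gap filling

DINEOF-style: initialise missing entries at the per-pixel observed mean
(zero after mean subtraction), then alternate a k-mode truncated-SVD
reconstruction with an update of the missing entries. The subtracted mean
is recomputed each iteration from the current completed matrix. The
stopping rule — RMS change on the missing set ≤ 0.01 W/m² (two orders
below typical retrieval noise), capped at 500 iterations — is this
package's choice; on the benchmark fields convergence takes 10–20
iterations. Filling happens on the plain `P × N` matrix before any
embedding: embedding a gappy series would propagate each gap into `W`
columns. A non-monotone convergence trace warns rather than fails.
`choose_k_crossval` hides a fraction of the observed entries and picks
the k minimising their reconstruction error; it exists because the right
k is data-dependent, though the fusion pipeline by default derives its
gap-fill k from the primary variance threshold instead.

## Fusion

The component mixing operates in reconstructed (embedded) field space:
the primary product's truncated reconstruction plus the secondary's
selected components with the secondary's mean excluded. Splicing PC
coefficient matrices across the two decompositions would be meaningless —
the bases differ. "Positions after k_a" is read literally: the secondary
contributes modes k_a+1, k_a+2, … until their variance share reaches
`tau_secondary`, capped at `k_secondary_cap = 12`. On the synthetic
benchmark the cap binds (the secondary's trailing spectrum is flat), so
twelve secondary modes enter — the same count the reference configuration
uses. The 80/20 split is expressed as variance thresholds, not fixed
counts; the counts emerge from the data. If the primary's threshold
already consumes its full rank, the fusion degrades to the primary's
truncated reconstruction with a warning.

Negative-value replacement happens after de-embedding, in field space,
where "negative LE cell" has physical meaning; the fallback is the
secondary's main-pattern reconstruction (its own `tau_primary`
truncation), and a doubly negative cell is clamped to zero and counted.

The simple-average baseline fills one-sided gaps with the available
product rather than propagating them; only cells missing in both
products stay missing.

## Synthetic study conditions

The generator emulates one year of 8-day composites (46 steps) on a
40 × 40 grid at 1 km:

- **Truth**: rank 3, separable — smooth spatial patterns (a meridional
  gradient with a moist hot-spot, plus Gaussian-filtered random surfaces,
  orthonormalised) times seasonal harmonics at 1, 2, 3 cycles/year with
  random phases; mode RMS amplitudes 26/16/13 W/m² over a 70 W/m² base,
  shifted so the minimum is ≥ 2 W/m² (keeps tower fluxes strictly
  positive). The amplitudes put the leading mode just over half the
  variance so an 80% cut retains the seasonal modes.
- **Product A** (primary, PT-JPL-like): gain 1, bias +5 W/m², white noise
  sd 10 W/m², no gaps — continuous but noisy, with robust dominant
  patterns.
- **Product B** (secondary, MOD16-like): gain 1, bias +2 W/m²,
  mode-aligned noise sd 9 W/m² (white noise projected onto the orthogonal
  complement of the truth's spatial modes — structured error that cannot
  be confused with signal), 10% random gaps. Both products are biased
  high with the secondary less so, and their total errors are comparable
  with the secondary slightly better, mirroring the reported behaviour of
  the two real product families.
- **Towers**: at chosen pixels, `LE_ori = (1 − d)·LE_true` with closure
  deficit d = 0.2, `H_ori = β·LE_ori` with Bowen ratio β = 0.5, and
  available energy `Rn − G = LE_true(1 + β)` (G fixed at 10% of Rn), so
  the closure correction recovers the truth exactly by construction.

What the generator does **not** emulate: spatially varying or seasonal
bias, spatially correlated gap patterns (cloud masks), non-Gaussian
retrieval error, scale mismatch between tower footprint and pixel, and
weather-scale temporal variability beyond noise. Passing tests therefore
demonstrate the algebra and the fusion mechanism under known low-rank
truth, not performance on real product pairs.

## Problem sizes and numerics

The standard benchmark (40 × 40 × 46, twenty replicates) keeps every
decomposition economy-sized (embedded matrix 6400 × 43, SVD cost is
driven by the 43 columns), so the full 20-replicate fusion study runs in
seconds; tiles keep larger grids at this per-tile size. Relative
tolerances of 1e-8 are used for SVD identities, 1e-12 for the closure
algebra (pure arithmetic). R² is the squared Pearson correlation, not
1 − SSE/SST: the fused fields are not regression fits, and the two
definitions diverge under bias — the choice is documented so reported
values are interpretable. 8-day composites anchor at the series start by
default; a MODIS-calendar flag anchors at day-of-year 1, 9, … for
comparisons against real composite products.

## Known limitations

- No cross-tile information sharing: each tile's decomposition is
  independent, and seams are unblended (measured at ≲ 0.1% relative RMS
  on homogeneous fields, but potentially visible on heterogeneous ones).
- The fused field inherits the primary product's mean bias by
  construction; the method corrects patterns, not calibration.
- Only two-product fusion is supported; no Bayesian model averaging.
- The forward LE retrieval models themselves (Penman–Monteith,
  Priestley–Taylor) are out of scope: their outputs are this package's
  inputs.
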