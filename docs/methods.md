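# Methods

This note records the model behind `rpcross`, the defaults and the
reasoning behind them, the numerical conventions, what the synthetic
fixtures do and do not emulate, and known limitations.

## Input model and increments

The unit of analysis is a univariate, equally time-spaced series. For
interaction counts N(t) saved every `dt` (e.g. 0.1 ns between saved MD
states, 1000 points for a 100 ns run), the analysis consumes the
increment series ΔN/Δt, computed as the forward difference
(N(i+1) − N(i))/dt (length L − 1). The stencil is a free choice — the
pipeline is invariant to the 1/dt scaling and to any affine transform
of the series, because the recurrence threshold is set by targeting a
recurrence rate (see below) — so the simplest consistent one is used.
Missing or non-numeric values are rejected, never imputed: the delay
embedding requires a gapless series. Whether an input is a count or
already an increment is declared by the caller (`is_increment` /
`inputs_are_increments`); auto-detection is refused because silent
misinterpretation would corrupt every downstream quantity.

## Delay embedding

A series is compressed into sub-series
y⃗ᵢ(d, τ) = (xᵢ, xᵢ₊τ, …, xᵢ₊dτ), i = 1…L − dτ. **Convention
warning:** a sub-series has d + 1 coordinates, so this `dim = d` is
one less than the "embedding dimension m" (number of coordinates) of
the delay-reconstruction literature. The public API stores the order
d; documentation indices are 1-based but the storage contract is
purely order-based.

**Delay τ** — smallest lag h ≥ 1 whose sample autocorrelation lies
inside the large-sample white-noise band ±z₁₋α⁄₂/√L (α = 0.05 by
default, exposed in the config). "First non-significant
autocorrelation" admits several readings; the standard significance
band is the one implemented. If every lag up to L/2 is significant,
L/2 is returned with a warning.

**Dimension** — Cao's method. E(m) is the mean over i of the ratio of
the maximum-norm distance between the i-th m+1-coordinate delay vector
and its nearest neighbour (self and exactly coincident points
excluded) to the same distance with m coordinates; E1(m) =
E(m+1)/E(m). `cao_dimension` returns the smallest m with
|E1(m) − 1| ≤ tol and |E1(m+1) − 1| ≤ tol (tol = 0.05, max_dim = 10;
the cap shrinks automatically when the series is too short to
evaluate it). The returned value is the conventional number of
coordinates m; the model layer converts to the sub-series order as
`dim = m − 1`, so a signal living on a closed curve (m = 2, e.g. a
sine) maps to two-point sub-series, d = 1. If E1 never saturates the
series is noise-dominated: max_dim is returned with a noise flag, and
E2(m) = E*(m+1)/E*(m) is reported alongside (E2 ≈ 1 at every m is the
stochastic signature). Neighbour distances use the maximum norm,
Cao's original choice.

**Majority voting.** When several series are analysed jointly, the
modal τ and modal d are used for all of them (ties break to the
smaller value, biasing toward less compression). Voting pools all
series given to one model; grouping by interaction type first is the
caller's choice of inputs.

## Recurrence matrix and rate targeting

m_{i,i′}(λ) = 0 if ‖y⃗ᵢ − y⃗ᵢ′‖ ≤ λ, 1 otherwise. The convention is
inverted relative to most recurrence-plot software: 0 = recurrent,
rendered white; 1 = black. A rendering-only `invert` flag exists;
analysis never uses it. The norm is Euclidean by default with the
maximum norm available by config — on two-point sub-series the choice
is rarely decisive, and Euclidean is the common default in
recurrence-plot software.

The recurrence rate is the fraction of zeros over all side² entries,
**main diagonal included**. `lambda_for_rate` returns the smallest
distance value q such that the fraction of entries ≤ q reaches the
target — the empirical quantile of the full entry multiset, diagonal
included for consistency with the rate definition. The achieved rate
(≥ target, equal whenever attainable on the discrete multiset) is
reported alongside; targets below the attainable minimum (side/side²,
from the always-zero diagonal) are clamped with a warning. Because
quantiles scale with |a| and shifts cancel in row differences, the
binary matrix at a targeted rate is identical under x → a·x + b
(a ≠ 0) — a tested pipeline invariant.

## Diagonal-line entropy and the rate scan

Along every diagonal parallel to the main diagonal — excluding the
line of identity — maximal runs of zeros are histogrammed by length.
Both triangles are counted (the matrix is symmetric, so off-diagonal
runs appear twice) and length-1 runs are kept (no minimum line
length). S = −Σⱼ pⱼ ln pⱼ in nats. An empty histogram raises an
undefined-entropy error, deliberately distinct from S = 0 (a single
occupied class). Worked anchor values: the 5-point example vector
gives S = 0 at λ = 0.1 (runs {1: 2}) and S = ln 2 ≈ 0.693 at λ = 0.9
(runs {1: 2, 2: 2}).

**Direction of the rate–entropy relation.** Under this run-length
convention, S *rises* with the recurrence rate: more recurrences mean
longer and more varied zero-runs, up to the all-zero matrix at rate 1
whose off-main diagonals contribute two runs of every length
1…side − 1 — a near-uniform histogram with S = ln(side − 1), the
maximum. The scans on the chaotic-map and MD-like fixtures show this
as Spearman ρ ≈ +1. Readers accustomed to entropy *decreasing* with
the rate are usually looking at the complementary statistic (runs of
non-recurrent points), which this package does not compute: the
worked-example values above pin the recurrent-run definition.

**Working-rate selection.** Per series, S is scanned over a default
grid of 30 logarithmically spaced target rates in [0.01, 1]
(duplicate achieved rates on the discrete multiset are dropped).
On (log rate, log S), every continuous two-segment piecewise-linear
model with its breakpoint at an interior grid point is fitted by least
squares (hinge basis); the breakpoint minimising the SSE is the
series' candidate rate, ties breaking to the smaller rate, and a scan
whose best broken fit is no better than a single line is flagged "no
edge". The working rate is the modal candidate across series. This is
the simplest model that realises "the edge between the linear and
non-linear regime"; a single-line multi-curve fit is a possible
alternative and is out of scope. Non-positive or undefined S values
are excluded from the logs with a warning. A caller who prefers a
fixed rate (e.g. the 9 % used throughout the recurrence plots here)
can override selection with `working_rate`.

## Cross detection

Steps, for polarity *dark* (full-width bands of black pixels crossing
the diagonal; *white* mirrors them on the complemented weights):

1. column weights wᵢ = Σ_{i′} m_{i,i′} (ones per column; white: zeros);
2. simple moving average of width k — centred, truncated to the
   available points near the edges so the output keeps the input
   length (even k spans k points biased one step right);
3. standardisation to z-scores with the population (divisor n)
   standard deviation — the choice of divisor is a monotone rescaling
   and cannot change the argmax below, only marginal threshold
   crossings;
4. k = argmax over the grid of the maximum standardised smoothed
   weight (ties → smallest k); the grid default is 1…⌊side/4⌋ — the
   objective states no range, and capping at a quarter of the plot
   keeps one average from spanning unrelated regions;
5. k is recorded as the estimated cross width;
6. cross centres are the strict local maxima of the standardised
   smoothed vector exceeding the threshold standard score (default
   2.5 σ; 2 σ and 3 σ are reasonable alternatives). Plateaus
   contribute their midpoint; boundary points count when they exceed
   their single inner neighbour; candidates are thinned greedily in
   descending score order so surviving centres are at least k apart.

Centre indices are reported 1-based in sub-series numbering, with
scores on the dark-weight scale (dark centres above +threshold, white
centres below −threshold), so dark detection on a matrix coincides
exactly with white detection on its complement — a tested invariant.

**Null calibration (measured, design-dependent).** The centre score is
the maximum of ~L weakly dependent z-scores; for L ≈ 1000 the expected
maximum of the null field is ≈ 3.2 σ, so on stationary pure-noise
increment series at least one ≥ 2.5 σ cross is reported in essentially
every run (measured ≈ 100 % over 100 seeded 1000-point fixtures). The
threshold is therefore a *localiser and ranking device* — it selects
where the most anomalous window is and how wide — not a family-wise
false-positive control. Detected crosses should be read comparatively
(position, width, score) and, where a hard guarantee is needed,
re-assessed against a user-chosen null, e.g. a permutation baseline.
Against 4 σ mean-shift windows spanning 10 % of a 1000-point series
the detector attains 100 % recovery over 100 seeds with localisation
error within the reported width k.

## Synthetic fixtures

The generator (`rpcross.synthetic`) exists so every stage is testable
without MD trajectories; all randomness flows through NumPy's seeded
PCG64 generator, making every fixture bit-reproducible from its spec.
Kinds: the 5-point worked-example vector; iid Gaussian and AR(1)
increment noise; the logistic map and a sine for embedding-parameter
tests; `regime_change` (one window of mean-shifted/variance-inflated
increments — the dark-cross mechanism; effect sizes are parameterised
in units of the background σ, keeping fixtures scale-free like the
pipeline); `oscillation_window` (a low-variance periodic segment —
the white-region mechanism of locally stabilised increments); and
`md_like_counts` — non-negative integer counts rising with a
saturating exponential to a plateau (fast early aggregation, then
equilibrium; default timescale L/10) with AR(1) fluctuations (memory
0.7) on top, at three preset regimes matching the magnitudes of the
motivating systems (≈115 ± 10 polysaccharide–polysaccharide hydrogen
bonds, ≈9000 ± 80 polysaccharide–water hydrogen bonds, ≈67 ± 8
hydrophobic–polar contacts, saved every 0.1 ns). Post-plateau
increments pass a rank-correlation stationarity check at the 5 %
level.

What the fixtures do **not** emulate: real aggregation physics —
temperature dependence, slow drifts, long-memory kinetics, or
cross-correlation between interaction types. Passing tests therefore
demonstrate that the pipeline recovers the *statistical signatures* it
is designed for (planted regime changes, oscillation windows, chaotic
vs stochastic embeddings), not that any particular molecular
conclusion follows for real trajectories.

## Numerical choices and degenerate inputs

- Thresholding uses ≤ λ (closed ball); λ = 0 is legal and recovers
  exact recurrences only.
- Quantile thresholds come from the sorted entry multiset, so achieved
  rates are exact on ties; ceil arithmetic carries a 1e-9 slack
  against float round-off.
- Zero-variance series: the ACF delay and Cao dimension raise a
  degenerate-series error; cross detection on a constant weight
  vector returns an empty result flagged `no_structure` rather than
  erroring.
- Exactly coincident embedded points are excluded from Cao
  nearest-neighbour searches; an all-coincident series errors.
- Entropy of an empty run histogram is an error, never 0.
- The resonant-sampling pitfall: a perfectly periodic signal sampled
  at a commensurate period produces exactly duplicate delay vectors
  and degrades Cao's statistics; fixtures use non-commensurate
  periods, and real increment series are never exactly periodic.

## Run configuration

`rpcross run --config run.yaml` accepts: `inputs` (each either
`{path, column}` or `{synthetic: {kind, length, seed, ...}}`),
`inputs_are_increments`, `alpha`, `max_dim`, `e1_saturation`, `norm`,
`rate_grid`, `working_rate`, `threshold_sigma`, `polarities`,
`k_grid`, `tau`, `dim`, `upscale`, `output_dir`, `seed`. A run is
reproducible from its config alone; every estimated parameter (τ, d,
λ, RR, k, threshold) is logged at INFO level, and per-series entropies
are computed at the single voted rate so series are comparable.

## Problem sizes in the test suite

The suite runs on series of 100–1000 points and recurrence matrices up
to side 60 for the brute-force oracle comparisons; the
anomaly-recovery and null-calibration studies use 100 seeds of
1000-point series each. These sizes make every statistic stable while
keeping the default `pytest` run around ten seconds.

## Known limitations

- Only diagonal-line entropy is computed; other recurrence
  quantification measures (determinism, laminarity, trapping time) are
  out of scope.
- White *squares* are handled only through their cross generalisation
  and the oscillation-window fixture; no dedicated block-geometry
  detector exists.
- The breakpoint selector assumes one knee; scans with several regime
  changes return the single best two-segment fit.
- The 2.5 σ threshold does not control the family-wise error rate on
  long series (see the null calibration above).
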