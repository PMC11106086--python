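# Methods

`ringanchor` implements a hybrid dendrochronology / single-year
radiocarbon dating workflow: ring-width series are cross-dated into a
floating chronology, single-ring Δ¹⁴C measurements from selected samples
are matched against an annually resolved atmospheric reference by a
chi-square placement scan, an abrupt cosmogenic ¹⁴C excursion (a Miyake
event) pins the match to a single calendar year, and that anchor dates
every cross-dated timber. A re-implementation of conventional Bayesian
wiggle-matching is included so the annual-anchoring approach can be
contrasted with calibration against a block-resolution curve.

## Calendar and unit conventions

All arithmetic runs on the astronomical year axis (0 = 1 BC, −1 = 2 BC);
the historical BC/AD labels, which skip year 0, exist only at the I/O
boundary. cal BP = 1950 − astronomical year.

Radiocarbon quantities interconvert as

    age BP = −8033 · ln F¹⁴C                      (Libby mean life)
    Δ¹⁴C   = (F¹⁴C · e^{(1950−t)/8267} − 1)·1000   (true mean life, ‰)

with first-order (delta-method) error propagation throughout. Monte-Carlo
propagation is deliberately not offered: the inputs this package targets
carry σ ≈ 1.5–3 ‰, for which the linearisation error is negligible.
Round-trip conversions are exact to better than 1e−9 relative, which the
test suite enforces.

A constant ¹⁴C-age bias (e.g. from a bad standard batch) is removed in
age space with quadrature error combination. Its equivalent Δ¹⁴C shift
depends on the ambient Δ¹⁴C level, which is therefore an explicit
parameter of `delta14c_shift_for_age_offset` rather than a constant: a
+30.9 yr bias corresponds to about +4.2 ‰ when the ambient level is near
+90 ‰, the typical mid-6th-millennium BC value.

## Cross-dating statistics

Ring widths are stored in integer 0.01 mm units (measuring-table
precision), making Tucson/RWL round trips lossless. For correlation
statistics, series are standardised to the log-index

    I_t = ln(100 · w_t / MA_k(w)_t),   k = 5 by default,

a centred moving-average high-pass (Baillie–Pilcher standardisation);
the window shrinks symmetrically at the ends. Two t statistics are
offered — Baillie–Pilcher (Pearson r of log-indices) and Hollstein
(Pearson r of year-to-year log growth ratios) — both mapped through
t = r·√((n−2)/(1−r²)), with an infinite sentinel at |r| = 1. GLK scores
sign agreement of year-to-year changes (ties involving exactly one zero
change score ½; two zero changes score 1).

Numerical caveat, verified by simulation: the moving-average filter
leaves short-lag autocorrelation in the indices, so the Baillie–Pilcher
t is mildly anti-conservative under the null (≈1.2% exceedance of |t|=3
at n=100 instead of the ≈0.3% of an exact t distribution). Screening
decisions are user-level; `crossdate_scan` reports every admissible lag
(minimum overlap 10 years by default) rather than thresholding.

Chronologies are plain means of the member log-indices with per-year
replication; a master for cross-dating may be a width series or a
chronology (whose index is mapped back to a dimensionless width scale
via exp).

## Annual reference curve

Per-year compilation of multi-lab single-ring Δ¹⁴C records uses the
inverse-variance weighted mean, with the per-year uncertainty set to the
larger of the internal error 1/√Σwᵢ and the external error (weighted SD
of the mean) — standard practice for multi-laboratory radiocarbon
compilations where scatter can exceed the quoted errors. A plain mean is
available behind `weighted=False`; per-archive integer year offsets
(e.g. a master-chronology dating correction) are applied before
averaging. Single-record years carry that record's σ.

Block-resolution calibration curves (IntCal 5-column `.14c` text) are
interpolated linearly in both mean and σ; this matches the behaviour of
common calibration software closely enough for the contrasts drawn here
and is exactly reproducible. Extrapolation is refused.

`splice_plus` replaces base-curve knots inside a window (default total
width 82 years, centred on the event year) with annual knots converted
from the Δ¹⁴C reference. The operation is local (the base curve is
bit-identical outside the window) and idempotent.

## Chi-square placement

With measurements Rᵢ ± δRᵢ at ring offsets rᵢ from the waney edge
(r = 0 is the final ring) and a reference C ± δC, the placement statistic
at candidate end year x is

    χ²(x) = Σᵢ (Rᵢ − C(x−rᵢ))² / (δRᵢ² + δC(x−rᵢ)²).

The scan is global by default — every integer x for which all x − rᵢ lie
in the reference coverage — so the placement is an honest search, with an
optional window for speed. All global minimisers are reported; downstream
consensus checking fails loudly on ties or on any nonzero residual
between a sample's best placement and its dendro-implied position.

The screening level uses df = n − 1 at α = 0.05 (configurable), the
convention under which 5 and 9 measurements give critical values 9.49
and 15.51. Note that at the true placement on a discrete year grid no
continuous parameter is fitted away, so the expected minimum χ² under
correctly specified Gaussian noise is n rather than n − 1 (the property
suite verifies the mean to within 3 standard errors over 500
simulations); the df = n − 1 screening convention is therefore slightly
conservative.

Excursion detection flags year y when C(y) − C(y−k) ≥ 10 ‰ for any
k ≤ 2 (the "≥1% within 2 years" event criterion); consecutive flags
merge into one event reported at the year of the largest single-year
rise in the flagged run.

Anchoring arithmetic: a chronology of length L whose event-bearing ring
is relative year m, with the event at calendar year E, ends in calendar
year E + (L − m).

## Wiggle-matching

The D_Sequence-style posterior over the end year x of an annually spaced
age sequence is

    P(x) ∝ Πᵢ N(mᵢ; μ(x−rᵢ), σᵢ² + σ_curve(x−rᵢ)²)

on the annual grid, under a uniform prior over the scanned span (the
default for an unconstrained sequence). Log-likelihoods are max-shifted
before exponentiation; a posterior whose best placement still underflows
raises an explicit total-mismatch error. Agreement indices are not
reproduced — the annual-versus-block contrast needs only posteriors and
HPD intervals.

HPD intervals are minimal sets on the year grid: years are added in
descending probability until the level is reached, ties broken
deterministically by year order so the set is mass-minimal for its size
(a uniform posterior over 100 years yields exactly 95 years at the 95%
level). `include_ties=True` instead admits every boundary-tied year,
making coverage ≥ level at the cost of minimality. Because the grid is
discrete the interval mass generally overshoots the level slightly, so
simulated coverage sits marginally above the nominal rate.

## Felling phases

A waney edge makes the felling year exact (felling in the dormant season
after the final ring; no sub-annual resolution is attempted). Partial
sapwood with s observed rings bounds the felling year in
[end, end + (max_sapwood − s)] with a genus-configurable allowance
defaulting to 20–30 rings for oak; heartwood alone yields a terminus
post quem. Phases are single-linkage groups of exact years with gap ≤ 2
years by default; range-only elements are attached to phases their range
overlaps, as "consistent with", never as members. The activity span is
the difference between the latest and earliest exact felling years.

## Synthetic data

The generators emulate the four input kinds with the statistical
structure the analysis assumes, and always return their ground truth.

* **Ring widths**: log-width = ln 100 + a·e^{−age/τ} (age trend,
  a = 0.6, τ = 30 yr) + common AR(1) signal (φ = 0.7, innovation
  SD 0.2) + per-tree noise (SD 0.2); 20 trees, mean segment 66 years on
  a 303-year chronology. Missing and false rings are optional
  deletions/duplications recorded in the truth table (rates < 5%).
* **Reference**: baseline random walk (SD 1 ‰/yr) around +90 ‰ plus a
  one-year spike of 15.8 ‰ relaxing exponentially with a 40-year time
  constant — the minimal shape consistent with a rise completed within
  two years followed by slow decay; the true post-event profile is a free
  parameter. Each lab reports truth + constant offset + N(0, 1.5 ‰).
* **Samples**: Δ¹⁴C (or exactly converted age BP) read off the truth
  curve at end_year − rᵢ plus lab noise; the two-stage dissection preset
  measures every 4th ring, then 20 consecutive rings around the event.
* **Site**: elements drawn from configured felling-phase years (default:
  the seven phases spanning 188 years) with waney-edge presence
  probability and sapwood counts; elements without a waney edge lose a
  random number of outer rings.

What the generators do **not** emulate: climate signals with spatial
structure, heteroscedastic or drifting lab errors, juvenile-wood ¹⁴C
effects, or regionally varying atmospheric offsets. Passing
parameter-recovery tests therefore demonstrates correctness of the
algorithms under the stated noise model, not robustness to every
property of real archives.

## Problem sizes and determinism

Simulation-backed checks use 200 replicates for placement-recovery and
curve-contrast rates and 500 for posterior-coverage and χ²-calibration
means — sizes at which the binomial/standard-error tolerances quoted in
the tests are meaningful while the whole suite runs in well under a
minute. All randomness flows from a single integer seed through named
per-generator substreams (`SimulationConfig.rng`), so identical configs
reproduce bit-identical data.

## Known limitations

* Inter-series correlation depends on the standardisation chosen; rbar
  values from other software (different detrending families) are not
  directly comparable.
* The calibration-curve model is a point-interpolated mean ± σ, not an
  errors-in-variables posterior; marine/hemispheric offsets and outlier
  models are out of scope.
* Missing/false rings are simulated but never auto-corrected; resolving
  them is a replication-based, manual step in practice.
* The χ² scan assumes the reference and measurements share the same
  Δ¹⁴C scale; systematic inter-lab offsets should be removed (e.g. via
  `apply_age_offset`) before scanning.
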