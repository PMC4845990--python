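# Methods

## Model

The terminal end bud is treated as eight fixed-size compartments in a
moving frame: basal regions 1–4 (cap → myoepithelium) and luminal regions
5–8 (body → mature luminal layer), paired across layers by maturity
(tip, neck, subtending duct, mature duct). Each region i holds N_i cells
with time-invariant per-cell proliferation and death rates r_i, d_i
(h⁻¹). Because region sizes do not change, the stationarity condition

    0 = influx − outflux + (r_i − d_i) N_i

propagates every region's net production downstream; summing along a
layer gives the flux of cells deposited into the mature duct,
Φ_bas = Σ₁₋₃ (r−d)N and Φ_lum = Σ₅₋₇ (r−d)N. A 2-D longitudinal section
of a duct of length L shows N = 2L/l monolayer cells of axial length l,
so each layer elongates at λ = (l/2)Φ. Internal units are µm and hours;
rates are reported in mm/day (×0.024).

Four nested variants:

1. **Base model** — the equations above (X = δ = 0, T = 1).
2. **Cap-cell flux** — a fraction X of newborn basal cells in the donor
   regions (default {1, 2}; {1, 2, 3} selectable) migrates into the
   maturity-paired body region: φ_bas→lum = X·Σ_donors r_i N_i is
   subtracted from the basal flux and added to the luminal flux. The leak
   is removed from the basal chain region-wise in proportion to each
   donor's own production; only the total is constrained by the layer
   balance, the per-region split is a package choice.
3. **Apoptotic correction** — measured luminal apoptotic indices
   under-report body-cell clearance; death rates in regions 5–7 become
   d(1+δ). On indices the correction is therefore multiplicative, so the
   minimal δ consistent with a corrected index c and a measured index m is
   δ = c/m − 1.
4. **Tortuosity** — both λ are divided by the total path tortuosity T to
   give straight-line displacement rates.

**Matching condition.** Adhering layers must elongate together. With δ
fixed, both rates are affine in X, giving the closed form

    X = (l_bas Φ_bas − l_lum Φ_lum^δ) / ((l_bas + l_lum) Σ_donors r_i N_i).

T cancels. Solutions outside [0, 1] are clipped and flagged rather than
raised — the fit analysis deliberately explores wide admissible ranges.

**Experimentally grounded X\*.** Cap (SMA+) cells found resident in body
regions are dying rather than cycling; at steady state their replacement
flux is (standing count)/(residence time), and X\* is that flux divided by
newborn-cap production. The residence time defaults to the apoptosis
marker's 8 h visibility window — the one quantity in this estimate that is
not directly measured.

**Uncertainty.** The printed ± method for rate estimates is a choice:
every uncertain input (N, r, d with a standard error) is drawn
independently from a normal truncated at zero and the model re-run per
draw; the half-width is the SD of the resulting rates. Monte Carlo
subsumes the delta method (the suite checks agreement on a linear case to
5% at 2·10⁴ draws) and handles the truncation honestly. Whether a
reported ± is an SD or an SEM of inputs is up to the caller's standard
errors; the package does not reinterpret them.

## Kinetics estimators

The dual-pulse design marks S-phase cells with EdU at t = 0 and with BrdU
during the 2 h before each harvest. Estimators, in order of appearance:

- **S phase**: first chase time at which the EdU/BrdU double-positive
  fraction reaches its minimum, minus the 2 h offset. The minimum is
  located on the raw fractions, taking the earliest sample within two
  binomial standard errors of the smallest value. A moving average is
  deliberately *not* used here: when G1 is long the dip's floor is a flat
  near-zero tail, and averaging drags the falling shoulder into the
  minimum, biasing the estimate late by up to one sampling interval.
- **Total cycle**: chase time of the first post-minimum maximum of the
  double-positive fraction, located on a 3-point moving average (the
  re-entry peak is broad, so smoothing helps rather than hurts); ties go
  to the earliest time. If the post-minimum maximum never exceeds 2× the
  minimum fraction the region is flagged non-cycling instead.
- **G2/M**: the EdU+pHH3+ fraction rises to a plateau spanning
  t ∈ [G2/M, S]; the duration is the plateau onset, estimated as the
  earliest time within two binomial standard errors of the maximum.
- **Fraction → rate**: at steady state a pulse of length p labels the
  cells that traverse S during T_S + p hours, so LI = r(T_S + p) and
  r = LI/(T_S + p). The conversion is a plain function and can be swapped.
  Death rates use the apoptosis marker window: d = AI/w with w = 8 h, the
  midpoint of the observed 6–10 h post-labeling visibility peak.
- **Indices**: pooled positives/total over harvests with Wilson 95%
  intervals (statsmodels).

**Identifiability.** The dip only exists when the labeled cohort's
re-entry does not overtake its exit: cycle ≥ 2·T_S + pulse. Inside that
regime the recovery study (S ∈ {4,6,8} h × cycle ∈ {12,16,24} h, 2000
cells, 10 seeds each) recovers both durations within one 2 h sampling
interval in ≥ 90% of runs; outside it no estimator could succeed and the
suite excludes those design points.

## Tortuosity

T is composed multiplicatively from a bifurcation factor 1/cos θ̄ (a
segment deflected by θ̄ projects onto the prior axis shortened by cos θ̄)
and a turning factor 1/(1−ū) (straight-line measurements between
bifurcations under-report path by the fraction ū). This composition
reproduces the whole-mount summary values 1.23, 1.06, T = 1.31 and the
19%/24% displacement underestimates simultaneously, which an additive
(1+u) composition does not. θ̄ is the arithmetic mean of per-bifurcation
deflections. Rounding to reporting precision (2 decimals, integer
percents) happens only at output.

## Synthetic-data generators

All generators are seeded (`numpy.random.default_rng`) and
bit-reproducible.

- **Dual pulse**: each of n cells carries a cycle clock with per-cell
  lognormal jitter (one factor scaling all phases; log-SD 0.05) at a
  uniform random position; defaults are the reference kinetics G1/S/G2M =
  8/6/2 h, 2000 cells, EdU pulse 0.25 h, BrdU window 2 h, harvests every
  2 h to 24 h. Deaths form a stationary Poisson stream per cell slot
  (started one CC3 window before t = 0, since exponential lifetimes make
  the renewal process memoryless) with dead cells replaced, matching the
  fixed-size-region assumption. Not emulated: label dilution, staining
  noise, per-region cell-number variation between sections — so passing
  recovery tests demonstrates estimator correctness under the model's own
  assumptions, not robustness to histology artefacts.
- **Forward compartment simulation**: per step of 0.1–0.5 h each cell
  divides w.p. r·Δt or dies w.p. d·Δt (mutually exclusive; Δt capped so
  probabilities stay < 0.1); newborn donor-region cells migrate w.p. X;
  surplus is evicted downstream (the evicted cell is an anonymous count —
  the model claims no age structure), holding every N_i exactly constant;
  evictions from regions 3 and 7 are mature-duct depositions. The
  empirical deposition rate ± its Monte-Carlo SE is the oracle against
  which the analytic fluxes are checked (3σ over randomized parameter
  sets).
- **Duct path**: straight runs of N(1141, 99) µm in 10 µm steps with
  Brownian heading noise, deflected by N(35.5°, 1.9°) with random sign at
  each bifurcation; a single branch is tracked. The per-step heading SD
  is calibrated from the target underestimate u via the stationary-walk
  identity E|Σe^{iθ}|² = Σ ρ^{|j−k|}, ρ = e^{−σ²/2} (RMS ratio = 1−u);
  for u = 6.1% this gives σ ≈ 0.083 rad.
- **Gland course**: linear growth from 10 mm at the first age plus
  i.i.d. normal noise per gland × age.

## Problem sizes and numerics

Simulation sizes used by the tests and the acceptance script — 2000–5000
cells per pulse experiment, 300–400 h forward-simulation horizons, 8–23
path branches, 10 seeds per recovery study — are chosen so Monte-Carlo
errors sit well below the tolerances being checked while the whole suite
runs in seconds. Counts are kept exact (rational arithmetic in the
monolayer tiling) and rounded half-up only at reporting. Degenerate
inputs raise typed errors (`tebmodel.errors`); shrinking layers (negative
net flux) and out-of-range matching solutions are flagged, not raised.

## Design choices where the ground is open

- Half-annulus cap counting uses the mid-layer arc radius — unbiased
  between the inner and outer arcs, neither of which is privileged.
- Monolayer vs multilayer tiling: basal regions and the mature luminal
  lining (region 8) count along perimeters; body regions 5–7 tile by
  area with one cell footprint per cell.
- Replicate glands at the same age are averaged before interval rates;
  the OLS trend instead uses raw per-gland points. Both summaries (mean
  interval rate and regression slope) are reported, since they answer
  slightly different questions when growth is uneven across intervals.
- The reconstructed parameter set packaged for demonstration marks every
  slot that is not a direct measurement; it exists so the pipeline runs
  end to end out of the box, not as a substitute for a measured table.

## Limitations

2-D geometry only; no spatial resolution inside regions; no hormone
dynamics, branching-pattern prediction, or label-dilution modelling; the
fraction→rate conversion assumes steady-state age structure; tortuosity
is planar and ignores branch-order effects.
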