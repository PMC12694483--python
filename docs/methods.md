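# Methods

## The accounting model

`nbudget` treats one growing season of one treatment plot as a nitrogen
ledger over three compartments — soil (0–60 cm inorganic pool), plant
(above-ground biomass) and atmosphere (N₂O):

    N_input   = fertilizer rate + pre-season soil inorganic N
    N_output  = end-of-season soil inorganic N + plant N accumulation
                + seasonal N₂O emission
    N_balance = N_input − N_output
    ANLR      = N_balance / rate × 100 %     (undefined at rate 0)

All terms are kg N·ha⁻¹. The balance is *apparent*: biological N
fixation (substantial in legume stands), leaching and NH₃ volatilization
are deliberately outside the ledger, so negative balances in
unfertilized plots partly reflect unmeasured inputs rather than true
soil mining, and the loss rate reads as "applied N not recovered in the
measured pools". Budgets are computed per year independently, each with
its own measured pre-season reserve — no carryover chaining — because
end-of-season residues and next spring's reserves are both measured
quantities that need not agree. Components enter the ledger as
replicate means.

Classification uses configurable thresholds, default ±20 kg·ha⁻¹:
below −20 is a deficit, above +20 a surplus, between them
near-equilibrium. The published tables this package reproduces are
qualitative on this point; ±20 kg·ha⁻¹ is roughly the spread of the
near-balanced treatments and about 10 % of a typical seasonal input.

## Component computations

**Soil stocks.** Layer stock = γ·h·N/10; the divisor is the exact unit
conversion, not an empirical constant. Layers must be contiguous and
non-overlapping; the conventional profile is three 20 cm layers over
0–60 cm. Bulk density may vary per layer, defaulting to the site value
1.45 g·cm⁻³ when omitted. Sampling position (furrow center on ridged
plots) is recorded but does not enter the arithmetic.

**Plant accumulation.** Organ accumulation = content (%) × dry matter;
contents are stored as percent throughout and divided by 100 only inside
the computation. Season totals sum organs and cuts; hay yield is total
leaf + stem dry matter. Quadrat-to-hectare scaling is assumed done
upstream.

**Chamber flux.** The headspace slope is an OLS fit over all points
(r² defined as 1 for two points, NaN for zero concentration variance).
The printed flux formula's product — ρ = 1.25 kg·m⁻³, height in m, slope
in µL·L⁻¹·min⁻¹, ×60 — is dimensionally mg·m⁻²·h⁻¹; the package
converts it to a canonical µg·m⁻²·h⁻¹, which makes the 24·10⁻⁵ constant
of the seasonal trapezoid exact (µg·m⁻²·h⁻¹ × days → kg·ha⁻¹). Because
ρ is 28 g per 22.4 L, fluxes are on an N₂O-N mass basis, and the
emission term passes into the ledger unchanged — the reproduced budget
arithmetic confirms that pass-through is what the reference table used.
Negative slopes (chamber uptake) are retained. Chambers with ≥3 points
and r² < 0.90 are flagged, never dropped: no standard QC rule exists
for these deployments, and flagging preserves the record while exposing
quality. Ridge and furrow chambers combine as w·F_ridge + (1−w)·F_furrow
with w = 0.5 by default — ridge and furrow surfaces are taken as equal
areas absent surveyed geometry — and w is configurable.

**Seasonal totals.** The trapezoid runs over actual date gaps in whole
days, with no extrapolation before the first or after the last
campaign. It is exact for piecewise-linear flux and, for the smooth
seasonal curves the generator produces (Gaussian peak, σ = 25 d,
15-day sampling), agrees with dense quadrature to well under 1 %.

## Statistics

Crossed fixed-effects ANOVA fit by OLS (year is a fixed crossed
factor). Balanced designs use the sequential decomposition, which is
then orthogonal and exact to machine precision; unbalanced data fall
back to Type II sums of squares with a warning (the designs this
package targets are balanced, so that path is secondary). Factor
columns are renamed internally before formula construction so user
column names can never collide with formula-language builtins.
Significance tags: `**` p < 0.01, `*` p < 0.05, `ns` otherwise.
Shapiro–Wilk (on cell-centered residuals) and Levene (median-centered)
prechecks are advisory and never block the ANOVA; untestably small
data is marked rather than failed.

LSD = t(1−α/2, df_error)·√(2·MSE/n). The post hoc is *protected*: when
an omnibus p-value is supplied and non-significant, all levels share one
letter. With means sorted descending, non-significance under a single
LSD threshold is an interval relation, so the maximal mutually
non-different sets are contiguous runs; letters are assigned per maximal
run, which guarantees the defining property exactly: two levels share a
letter iff their difference is within the LSD.

## The synthetic trial

The generator emulates the structure of a two-year, 3-pattern ×
4-rate × 3-replicate ridge–furrow alfalfa experiment, with every
parameter in `SyntheticDesign`:

* pattern effects multiplicative (FP 1.00, JM 1.08, PM 1.15), applied
  to soil N, plant N and N₂O alike;
* plant dose–response `1 + 0.45·(2u − u²) + 0.05·u`, u = rate/160:
  peaks at the 160 kg·ha⁻¹ grid point, with the small tilt placing
  240 above 80 as field dose–responses do;
* soil N and N₂O monotone in rate (slopes 0.0030 and 0.00085 per
  kg·ha⁻¹ — the latter puts the 240-rate emission ≈20 % above
  unfertilized, matching observed spans);
* second-year multipliers 1.60 (soil), 1.15 (plant), 1.20 (N₂O) for a
  wetter retention year;
* seasonal flux 18 + 50·exp(−(doy−200)²/2·25²) µg·m⁻²·h⁻¹ before
  multipliers, campaigns every 15 days mid-April to mid-October; the
  implied seasonal totals span ≈1.5–2.5 kg·ha⁻¹ across treatments,
  inside the 1.2–3.0 kg·ha⁻¹ range seasonal field totals occupy;
* soil concentrations decay exponentially with depth (0.015 cm⁻¹) from
  surface values of 12 (NO₃⁻-N) and 5 (NH₄⁺-N) mg·kg⁻¹; profiles are
  sampled pre-season (April) and post-season (September), the residue
  10 % above the same year's initial level;
* three cuts (early June, mid July, late August) with tissue N
  declining 1.00/0.85/0.75 across cuts (the dilution effect of faster
  summer regrowth).

Noise is multiplicative lognormal with unit mean (CV default 0.08) for
concentrations, dry matter and fluxes — strictly positive measurements
get strictly positive noise — and optional additive Gaussian for
temperature. Within-treatment variance magnitudes are not published for
trials of this kind, so the CV is a conventional field-measurement
choice, not a fitted one. Chamber series are emitted as exact linear
30-minute headspace rises (0/10/20/30 min) whose slope inverts the flux
formula at the plot's noisy flux: slope estimation then recovers each
chamber's flux exactly, placing all sampling error at the flux level
where it is interpretable. Every generated observation has a noise-free
twin in the truth table, and generation is deterministic given the
seed.

What the generator does *not* emulate: process-based mineralization or
nitrification kinetics, weather beyond the fixed seasonal curve,
spatial correlation between plots, leaching or fixation fluxes, or
realistic replicate-variance structure. Passing recovery tests
therefore demonstrate that the pipeline arithmetic is faithful and that
designed effects of realistic size survive realistic multiplicative
noise — not that the statistical layer is calibrated against real field
variability.

## Numerical choices and edge cases

* Report rounding is half-away-from-zero (via `decimal`) to 2 places,
  matching agronomic table conventions; internal computation never
  rounds. The zero-rate loss rate renders as "—".
* Zero-variance concentration series return slope 0 with r² = NaN
  (flagged undefined) rather than dividing 0/0.
* Duplicate cuts, duplicate flux dates, profile gaps/overlaps and
  mismatched ridge/furrow pairs are hard `DataError`s; negative
  components, out-of-range percents and invalid geometry are
  `ValidationError`s; degenerate ANOVA designs are `DesignError`s. The
  CLI maps these to exit codes 2/3/4.
* Ledger identity `N_input − N_output − N_balance = 0` holds exactly
  (same-magnitude additions); the ANLR inversion
  `ANLR·rate/100 = balance` holds to floating-point round-off.

## Problem sizes

The default simulated trial is 72 plots × (6 soil rows + 3 cuts + 13
campaigns × up to 2 chambers × 4 samples), about 8,600 rows total;
truth-integration oracles use 20,001-point grids. The full pipeline
runs in about a second, and the complete test suite in well under a
minute.
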