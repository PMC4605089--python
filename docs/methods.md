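# Methods

This note documents the models, conventions and assumptions behind
`htltea`, in the order a dataset flows through the package.

## Experiment records and the CSV schema

The experiment table stores **raw masses (g) plus the dry feed mass**, one
row per run. Percent yields, closure, ratios and recoveries are always
recomputed downstream; no derived value is ever persisted. This makes the
accounting layer the single source of truth: a stored yield cannot drift
from the masses that imply it.

Two blocks are nullable per row. Gas mass/composition is absent for runs in
vented reactors (the 2-chamber design cannot retain gases), and the aqueous
co-phase (ACP) block is absent when that phase was not analysed. Crude
oxygen is *not* a column: the reader reconstructs it as
`100 − C − H − N − ash`. Published oxygen columns labelled "by difference"
are not always reproducible this way (see *Known discrepancies*), so records
built in memory may instead carry a measured/printed oxygen with
`oxygen_is_by_difference=False`, and `oxygen_difference_report` surfaces the
gap rather than overwriting either number.

Validation is strict with one deliberate exception: the proximate closure
(moisture + volatiles + fixed carbon + ash ≈ 100 ± 2 %) is recorded as a
note on the record instead of raised, because the bundled reference
feedstock sums to 104.0 at face value and the right behaviour is to carry
the published numbers with the discrepancy visible.

## Product accounting

- Yield basis is the **dry, ash-inclusive feed mass** (moisture 3.54 % is
  part of the feed unless the caller passes a dry-corrected mass). This
  convention reproduces the published energy-recovery values.
- Mass closure is the sum of the four component yields; the lost share is
  its complement to 100. Catalyst mass never enters the slate.
- Energy recovery `ER = yield_frac × HHV_crude / HHV_feed × 100` may exceed
  100 % when co-solvent mass is incorporated into products (isopropyl
  esters); the validator allows yield fractions up to 1.05 for the same
  reason.
- Atomic ratios use standard atomic masses (C 12.011, H 1.008, N 14.007,
  O 15.999) by default; any masses can be passed explicitly (printed tables
  are typically computed with integer masses — both agree at the two
  decimals such tables carry).
- `anova_one_way` is classical one-way ANOVA (delegated to
  `scipy.stats.f_oneway` behind validation: ≥2 groups, ≥2 replicates each).
  The test suite checks it against an independent from-scratch
  sum-of-squares decomposition.
- Comparisons against published two-decimal inputs use an absolute
  tolerance of 0.1 percentage points to absorb input rounding.

## Process energetics

Slurry heating duty uses a **constant-property model**:
`Q = ρ[(1−f)·c_w + f·c_s]·ΔT / 1000` MJ m⁻³, defaults c_w = 4.18 and
c_s = 2.0 kJ kg⁻¹ K⁻¹, ρ = 1000 kg m⁻³, ambient 25 °C. For a 10 wt% slurry
this gives 1287.7 / 1089.6 / 891.5 MJ m⁻³ at 350 / 300 / 250 °C, matching
the ~1290 / ~1100 / ~890 rule-of-thumb figures within 1 %.
Saturated-liquid enthalpy differences from steam tables overshoot these
figures by >10 % because real c_p of water rises steeply toward the critical
point; the constant-c_p model is therefore kept as the stated convention,
with all four constants overridable.

Binary-solvent critical points are a **two-anchor lookup**, exact at pure
water (374.1 °C, 22.1 MPa) and at the tabulated 1:1 isopropanol–water
mixture (311.3 °C, 10.2 MPa), linear in alcohol mass fraction elsewhere and
flagged `interpolated`. This is bookkeeping, not a thermodynamic mixing
model; fractions above 0.5 extrapolate on the same line and should be
treated with caution.

Chemical-energy tables multiply stream mass by HHV; the natural basis is
100 kg dry feed, so feed chemical energy is exactly 100 × HHV_feed
(2488 MJ for the bundled yeast).

## Biorefinery mass flow

Upgrading uses fixed coefficients per kg biocrude: 75 % fuel, 14 % coke,
10 % process gas, 0.035 kg H₂ consumed, 0.004 kg catalyst. These
coefficients are stated independently and **do not close**: the residual
`m + m_H2 − (fuel + coke + gas)` (4.5 % of biocrude at defaults) is reported
on every result and never renormalized away. Solid char routes to a
process-heat sink. ACP nutrient recycle converts Kjeldahl-N and total-P
concentrations (mg L⁻¹) times the recovered ACP volume (L) into kg streams;
the recovered volume has **no default** — it is a genuinely unreported
quantity and must be supplied by the caller. All flows are homogeneous of
degree one in the feed mass.

## Techno-economic analysis

The DCF uses end-of-year discounting at the target IRR. With build phases
(f₁…f_B) capital is spent at the ends of years 1…B and production occupies
the following `plant_life_years` years; with an empty phase tuple the full
capital is an undiscounted year-0 outlay — the analytic limit in which the
MFSP closed form `(CRF·capex + opex)/gallons`,
`CRF = r(1+r)ⁿ/((1+r)ⁿ−1)`, holds exactly and anchors the solver tests.
Defaults: IRR 10 %, income tax 35 %, plant life 30 years, phases
8/60/32 %, 72 × 10⁶ L fuel per year (3.78541 L gal⁻¹).

Depreciation is straight-line over a configurable `depreciation_years`
(default 10) on the full capital — the simplest auditable schedule; an
accelerated schedule would be a config extension. Tax is
`rate × max(0, revenue − opex − depreciation)`. Labor and working capital
are excluded by default (operating totals are used on an excluding-labor
basis); working capital is opt-in as a fraction of capex, injected at the
first production year and recovered in the last. Dollars are a single
nominal basis; no cost-year indexing is attempted.

The MFSP solver brackets `[0, 100]` $/gal, expands the bracket tenfold on
demand, and runs Brent's method to an xtol of 1e-12 so the NPV at the
solved price is within $1 of zero even for very large plants. Headline
literature fuel prices for this pathway (≈$5/gal) depend on equipment-level
cost tables that are not part of this package; the engine is therefore
validated by the closed-form, fixed-point and monotonicity properties, not
by reproducing a headline number. One-at-a-time sensitivity perturbs one
named economic input at a time (biocrude yield scales fuel output
proportionally; a catalyst cost line moves inside the opex total) and
returns a tornado-ordered table; a perturbation that produces invalid
assumptions becomes a per-row error without aborting the run.

## Synthetic campaign generator

The generator emulates the reference study design: four treatment
conditions, duplicate runs, per-fraction yields drawn independently from
Gaussians truncated at zero and converted to masses on a 40 g dry-feed
basis. Defaults are the reference condition means with biocrude-yield SDs
0.4 / 0.2 / 0.1 / 0.2 percentage points — the two non-catalytic values are
reported replicate spreads; 0.2 (their midpoint) is assumed for the
catalytic conditions and for the solids/gas/NVR fractions, whose spreads are
unreported. Crude compositions and HHVs default to SD 0 (single reported
values). The feed HHV spread is 0.53 MJ kg⁻¹. The reported ± values are
treated as SDs across runs (whether they are SDs or SEs is not stated in the
source material). A whole draw is rejected and redrawn if its product-mass
closure exceeds 105 % of feed, so generated tables always pass record
validation. Gas blocks attach only to closed-reactor ("2-L") conditions,
with a representative CO₂-dominant composition (0.95/0.03/0.015/0.005 for
CO₂/CO/CH₄/C₂H₆).

What the generator does *not* emulate: covariance between fractions (no
joint spread information exists), temperature/heating-rate response,
compositional drift between replicates, or measurement error on elemental
analyses. Passing tests therefore demonstrate correct statistical
bookkeeping of the assumed noise model, not fidelity to HTL chemistry.

`recover_parameters` returns per-condition sample means/SDs recomputed from
masses, making it an end-to-end check: at n = 10 000 replicates the
configured biocrude means and SDs are recovered within 1 % relative, and the
default duplicate design yields a significant one-way ANOVA (α = 0.05)
across treatments in ≥95 % of seeded runs. A single integer seed drives one
`numpy` generator; runs are bit-reproducible for a fixed seed.

## Known discrepancies (surfaced, not repaired)

- Feedstock proximate block sums to 104.0 %; kept, with a validation note.
- Feedstock oxygen: printed 33.85 vs by-difference 33.95 (0.10 gap).
- Biocrude oxygen: printed "by difference" values (e.g. 12.73 %) differ from
  `100 − C − H − N − ash` (8.93 %) under every convention tried; the
  printed values are stored and the gap is reported per record.
- C–H recovery of the non-catalytic 300 °C run computes to 68.7 % against a
  published lower bound of 68.2 %; the arithmetic is kept.
- The upgrading coefficients leave a ~4.5 % closure residual by design.
- The published opex process shares (52/1/41/8 %) sum to 102 %; strict
  allocation rejects them unless `renormalize=True` is passed.

## Problem sizes

Default test problem sizes: 100 examples per property test, 50 random
instances per arithmetic-oracle loop, 1000 seeded campaigns for the ANOVA
significance rate, 100 randomized plants for the NPV fixed-point check and
n = 10 000 replicates for parameter recovery. These sizes give comfortable
statistical resolution for every assertion while keeping the whole suite
fast enough to run on every commit.
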