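# Methods

## Physical model

The chip channel is a shallow rectangle, width w = 0.1 cm, height
h = 0.015 cm, length 1.2 cm, perfused with culture medium treated as an
incompressible Newtonian fluid of constant density ρ = 1 g/cm³ and dynamic
viscosity µ = 9.3×10⁻⁸ N·s/cm² (= 9.3×10⁻³ dyn·s/cm² = 0.93 cP, a
plausible value for DMEM + 10% FBS at 37 °C; adopted verbatim, not
corrected). All internal arithmetic is CGS; µL/hr, µm and N·s/cm² are
converted exactly once at the API boundary (`gutchip.units`), because the
literature's mix of N and dyn units is the classic source of 10⁵-fold
errors.

At the relevant pump rates the channel Reynolds number is
Re = ρ(Q/wh)h/µ ≈ 9×10⁻³, so the flow is creeping: inertia is negligible,
the fields are linear in Q, and flow is reversible. The package's default
regime is therefore Stokes flow; a Navier–Stokes (Oseen–Picard) option
exists purely to confirm that inertia changes nothing at these conditions
(it agrees with Stokes to <0.1% at Q = 29 µL/hr).

**Wall shear.** For w ≫ h the parallel-plate result τw = 6µQ/(wh²) holds
on the wide walls. This is the package-wide *reference* stress — it is the
quantity perfusion protocols are specified in — even though the fabricated
aspect ratio of 6.7 is finite. The exact rectangular-duct series correction
(`duct_shear_correction`, mid-floor value ≈ 1.10 at aspect 6.7) is exposed
as a diagnostic, not the default, because the flow-chamber convention
defines the reference.

**Cell shear.** Cells on the floor are modelled as rigid 2D obstacles in
the longitudinal x–z plane, the plane of the parallel-plate model; the
spanwise direction is treated as uniform. This is a deliberate idealization
of a confluent monolayer (spanwise neighbours suppress lateral bypass); for
an isolated cell in 3D, flow around the sides would lower the amplification
somewhat, so single-cell amplification ratios here are upper-ish estimates.
Three reference morphologies track polarization, heights fixed by the
measured monolayer heights and widths being declared assumptions (the
source imagery is not dimensioned); all are config-overridable:

| label  | height | width | shape                           |
|--------|--------|-------|---------------------------------|
| small  | 13 µm  | 26 µm | hemispherical bulge (half-circle: chord = 2×height) |
| medium | 27 µm  | 18 µm | rounded column (semicircular cap) |
| tall   | 34 µm  | 12 µm | rounded column (semicircular cap) |

Arrangements are a single cell or a streamwise array (default n = 5,
gap = width/2, centred with ≥ max(5 widths, h) of clear channel on both
sides so the imposed fully developed inlet/outlet profiles are honest —
channel-flow disturbances decay over a height-scale distance). The first
cell met by the flow is `outer`; downstream cells are `inner`
(sheltered). By Stokes reversibility the trailing cell mirrors the leading
one, so its peak equals the outer value; interior cells are genuinely
sheltered.

## Flow solver

Staggered (MAC) finite differences: u on vertical faces, w on horizontal
faces, p at cell centres; the Stokes saddle-point system (momentum +
continuity, one pressure dof pinned and re-gauged so the outlet mean is 0)
is assembled sparse and solved with a direct LU factorization — no
iteration, no randomness, bit-identical reruns.

Boundary conditions: parabolic inflow rescaled so the *discrete* flux
equals Q exactly; identical profile at the outflow plane; no-slip,
non-permeable floor, top wall and cell surfaces. Obstacles are rasterized
by cell-centre sampling, but the no-slip wall is **not** imposed at the
staircase: every grid link cut by the analytic cell surface uses a
Shortley–Weller (cut-link) stencil with the true wall distance, and flat
walls half a spacing off the node line (floor, ceiling) use the equivalent
quadratic ghost. This restores second-order geometric fidelity: the
empty-channel refinement study (h/10, h/20, h/40) shows L2 velocity and
floor-shear errors of 0.50%, 0.125%, 0.031% — a clean 4× drop per halving —
and obstacle peak stresses move <2% between the default and half grid
spacing.

Default grid spacing is 1 µm (12 elements across the narrowest default
cell), automatically refined so every geometric feature (cell width, gap,
clearance) spans ≥ 8 elements; the solver refuses coarser setups.
Continuity is enforced to a relative residual ≤ 10⁻⁸ and the realized flow
rate must match the request to 0.1% (both checked on every solve).

## Shear extraction

Raw face-by-face stresses on a rasterized boundary spike at staircase
corners, so apical shear is evaluated on the *analytic* profile curve: at
each surface point (arclength spacing ≈ one grid cell) the tangential
velocity is interpolated at two fixed normal offsets (1.5 and 3 µm,
floored at 1.25 grid spacings) and differenced through the no-slip wall
with a one-sided quadratic — exact for locally parabolic profiles, and
independent of grid refinement by construction. Per cell we report the
arclength-weighted mean and the peak; the peak excludes the two samples
nearest each floor contact line (corner singularity) and passes a
3-sample moving average (residual grid-scale ripple). Amplification
ratios divide by the *analytic* τw for the same Q (the reporting
convention); using the numerical empty-floor shear instead moves ratios by
<2% at the default grid.

The headline τc per morphology follows the culture timeline: a **single**
cell for `small` (early culture is subconfluent, the regime the bulge
model describes) and the **outer array cell** for `medium`/`tall` (the
monolayer is confluent by the time it has polarized). All
arrangement/role combinations are always reported alongside
(`summary_table`). The reported figure is the peak, not the mean, because
the bulge model's 3× is a peak amplification and peak exposure is the
quantity a protocol should bound.

Computed values at Q = 29 µL/hr (τw = 0.02 dyn/cm²): small single
τc = 0.054 (2.7×), medium array outer 0.069 (3.5×), tall array outer
0.0866 (4.3×); linearity gives 0.0537 for the tall monolayer at 18 µL/hr.
These numbers are recomputed, not stored, by the test suite and examples.

## Flow scheduling

Stokes linearity makes the shear sensitivity k = τc/Q a property of the
geometry alone; `shear_sensitivity` measures it with one solve (and
verifies linearity with a second at 2Q, falling back to per-interval
solves only if a Navier–Stokes configuration breaks 1% linearity). A
morphology timeline (half-open day intervals; a transition takes effect at
the start of its stated day) then yields Q = τc_target/k per interval,
reported both exactly and rounded to the 1 µL/hr granularity of a pump
setting. Schedules are stepwise-constant — discrete pump settings, no
ramps.

The default target (`early_stage_target`) is the small-cell peak τc at the
polarization-initiating condition τw = 0.02 dyn/cm² (0.054 dyn/cm² with
the defaults). With the default timeline (small from day 2, tall from day
5) the schedule is 29 µL/hr then 18.1 → 18 µL/hr, i.e. holding the
early-stage cell shear reproduces the decreased-flow protocol.
`standard_protocols` returns the three benchmark conditions: C (constant
29 µL/hr, days 2–8), D (29 then 18 from day 5), S (static).

## Synthetic monolayer heights

The generator emulates confocal height morphometry: per condition,
projection means are drawn Normal(condition mean, between-projection SD)
and measurements Normal(projection mean, within-projection SD), both
truncated below 1 µm (physical positivity; a sub-percent effect on the
means). Defaults: 820 measurements over 103 projections per condition
(309 projections split over the three day-8 groups; per-condition counts
are configurable). Condition means are the measured 13 µm (S8, static
day 8), 27 µm (C5, constant flow day 5), 34 µm (C8 and D8, both day-8
flow groups). The spreads are *assumptions* — only means and counts were
measured — set to 4 µm between / 3 µm within projections so the day-8
group SEMs (~0.17 µm) are small against the 6–21 µm group differences,
and doubled for C5, whose mid-polarization monolayers are reported as
much more variable. Sampling is vectorized truncated-normal with an
explicit seed; the condition label is folded into the RNG stream so
equal-parameter conditions (C8, D8) are independent samples; no global
random state.

What passing tests show — and don't: the generator reproduces its own
two-level model (grand means within 2 SEM, seed-ensemble SD matching the
analytic √(σ_b²/J + σ_w²/n), ≥95% correct morphology classification over
200 seeds). It does not model segmentation bias, spatial correlation along
a projection, or unequal projection sizes, so it validates the pipeline's
statistics, not confocal image analysis.

Classification back to a morphology uses midpoint thresholds between the
reference heights (20 µm and 30.5 µm), ties toward the shorter class —
deliberately simple, since the heights sit far from the thresholds.

## Numerical and design choices, in brief

- Direct sparse LU (not iterative): problem sizes (≤ ~6×10⁵ unknowns at
  the finest default grids) factor in seconds to ~1 min and determinism is
  free. Default problem sizes in the test suite and examples (1 µm grids,
  0.75 µm for tall arrays; half-grid checks at 0.5 µm) were chosen so a
  full run stays in the minutes range on one CPU.
- Pressure is defined up to a constant under all-Dirichlet velocity
  boundaries; one dof is pinned and the field re-gauged to outlet mean 0.
- Zero-flow requests return the identically zero field (with the schedule
  generator warning on a zero shear target).
- Degenerate geometry (cell taller than the channel, overlapping cells,
  under-resolved features) fails loudly at construction or solve time, not
  silently.
- The `width ≥ height` channel assumption warns rather than errors; the
  formula degrades gracefully and narrow test channels are legitimate.

## Limitations

2D slice (no lateral bypass or spanwise packing), rigid non-growing cells,
steady flow (no start-up transients or pulsatility), Newtonian
constant-temperature medium, no fluid–structure interaction, no permeable
membranes. Amplification ratios for isolated cells should be read as
monolayer-slice idealizations rather than free-standing 3D single-cell
predictions.
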