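# Methods

`hemoshear` is a desk-scale reimplementation of the standard hemodynamic
work-up used in intracranial-aneurysm rupture-risk studies: simulate
pulsatile flow over an aneurysm geometry, cycle-average the wall shear
stress (WSS), reduce it to a small metric suite, and compare metric
distributions between ruptured and unruptured groups.  Patient angiograms
are replaced by parametric planar geometries and by calibrated synthetic
cohorts; everything else follows the clinical pipeline.

## Geometric model

Aneurysms are modelled as planar sidewall sacs on a straight parent
channel: the lumen occupies `y ∈ [0, H]` with `H` the parent caliber (mm),
and the sac boundary is a polyline attached to the `y = H` wall.  Two
families span the clinically reported aspect-ratio range (≈0.5–3.1):

* **hemispherical bump** — a half-disc of radius `r`; neck `= 2r`, height
  `= r`, hence aspect ratio (AR) exactly 0.5.  The canonical wide-necked
  sac.
* **circular sac with constricted neck** — a circle of radius `r` lifted
  `d` above the wall, joined to a neck of width `w < 2r` by the outer
  tangent lines.  Height `= d + r`, so AR `= (d + r)/w` reaches deep
  narrow-necked shapes.  Feasibility requires `sqrt((w/2)² + d²) > r`.

Morphometry uses the clinical 2-D definitions: height is the maximum
distance from the neck centre to the dome (measured on the polyline, not
perpendicular to the neck plane — the alternative reading; for symmetric
sacs with the tip above the neck midpoint the two coincide); neck width is
measured along the parent wall; AR = height/neck.  "Dome area" in the
planar model is the sac boundary arc length — every metric that normalizes
by dome area is a measure ratio, so the reduction preserves its meaning.
A sac is **narrow-necked** iff AR ≥ 1.4 *and* neck < 4 mm; a neck of 4 mm
or more forces **wide** regardless of AR (the 4-mm clause is read as an
override, matching the clinical wide-neck convention).  The classification
is isolated in one function (`classify_neck`).

## Discretization

The domain is meshed on a uniform Cartesian grid with square cells (side
`cell_size`, at least 8 cells across the caliber; `build_mesh` snaps the
cell size to an integer divisor of the caliber so the parent walls are
grid-aligned and parent wall shear carries no staircase error).  The sac
is the staircase of cells whose centres fall inside the sac polygon.
Wall elements are (fluid cell, outward face) pairs.  Sac faces receive
arc-length weights by projecting the true sac polyline length onto the
nearest faces, so the summed sac weight converges to the exact boundary
length under refinement (a raw Manhattan staircase length would
overestimate a semicircle by ~27%).  The parent reference ("probe")
segment is tagged on the sac-bearing wall, centred 10 mm from the nearer
neck endpoint — upstream by default, 2 mm extent; both are configurable
because the location is standard but the extent and side are conventions.

## Flow model

Blood is incompressible and Newtonian (ρ = 1050 kg/m³, μ = 3.5·10⁻³ Pa·s).
The 2-D incompressible Navier–Stokes equations are discretized finite-
volume on a staggered (MAC) grid and solved with SIMPLE pressure–velocity
coupling: first-order upwind convection, central diffusion with half-cell
no-slip ghosts at walls, implicit Euler in time.  Momentum systems are
relaxed (α_u = 0.7) and swept with a few Jacobi iterations inside the
SIMPLE outer loop; the pressure-correction Poisson system is solved by a
direct sparse factorization, refreshed every few outer iterations.  The
outer loop at each time level runs until the cell mass residual falls
below 10⁻⁵ of the inflow flux (10⁻⁶ for steady solves) *and* the velocity
update stagnates, and fails loudly with its residual history otherwise.

Boundary conditions: no-slip rigid walls; a flat inlet profile scaled to
the instantaneous flow rate; outflow by zero-gradient velocity rescaled so
outflow equals inflow exactly (global mass balance is exact by
construction), with the pressure level pinned to zero mean on the outlet
column.  The inflow is the single-harmonic waveform
`Q(t) = Q_mean + (Q_max − Q_mean)·sin(2πt/T)` — the minimal waveform
reproducing the three measured quantities (mean 185 ml/min, max
301 ml/min, 64 bpm).  Three cycles are integrated from rest and the last
is returned; the flow-rate constraint suppresses the slowest transient
mode, so cycle-to-cycle differences at the defaults are far below 1%.

**Dimensional matching.**  The planar channel is tied to the physiological
regime through a reference vessel diameter `D`: the channel carries the
cross-section mean velocity of a circular vessel of diameter `D` at the
prescribed flow, so the channel Reynolds number `ρUH/μ` (with `H = D`)
equals the tube value.  By default `D` is derived from the physiological
mean Reynolds number 364 (`D = 4ρQ/(μπ·Re)` ≈ 3.236 mm), which reproduces
the physiological Womersley number `α = (D/2)√(ωρ/μ)` ≈ 2.29; deriving
`D` from α = 2.32 instead gives Re ≈ 360.  The two printed numbers are
mutually consistent only to ~1%, so the package exposes both derivations
(`diameter_for_reynolds` / `diameter_for_womersley`) and reports both
numbers.

**Validation oracles.**  `analytic_channel_solution` provides the exact
developed-channel velocity under the single-harmonic forcing: plane
Poiseuille for the mean plus the oscillatory (Womersley-type) profile with
complex wavenumber `k = sqrt(iωρ/μ)`, normalized so the analytic flow rate
matches the forcing exactly; its zero-frequency limit is the steady
parabola.  The suite checks the solver against `6μq/h²` wall shear
(steady, three grid levels with monotone error decay, <5% at 32 cells)
and against the oscillatory series at α ≈ 2.3 (<5%, measured ~1%,
relative L2 over the last cycle).  Pulsatile validation runs at a reduced
flow rate (channel Re ≈ 40 at the physiological α) so the flow develops
within a short channel; α, not Re, controls the oscillatory profile being
validated.

## WSS metrics

Instantaneous WSS at a wall element is `μ|u_t|/(Δ/2)` — the tangential
velocity at the adjacent cell centre differenced one-sided against the
no-slip wall half a cell away.  The cycle average per element is the
trapezoidal time integral of |WSS| over the last cycle divided by the
period.  From the averaged field:

* **MWSS** — arc-length-weighted mean over sac elements (Pa);
* **HWSS** — highest sac value; of the *time-averaged* field by default,
  optionally the peak over elements and instants (`hwss_mode="peak"`) since
  "highest WSS" is ambiguous between the two;
* **PWSS** — weighted mean over the parent probe, computed from the
  cycle-averaged field (instantaneous-then-average and average-then-mean
  commute for this linear reduction);
* **LSAR** — fraction of sac arc length with averaged WSS *strictly* below
  0.1·PWSS ("below 10%" is read as strict; boundary elements at exactly
  the threshold are not low-shear);
* **M-P, H-P ratios** — MWSS/PWSS and HWSS/PWSS.

Invariants enforced and property-tested: LSAR ∈ [0, 1], HWSS ≥ MWSS,
scale equivariance (the threshold tracks PWSS, so ratios and LSAR are
invariant under uniform scaling), permutation invariance, LSAR monotone in
the threshold fraction.

## Synthetic cohorts

The default cohort reproduces the reference composition: 72 aneurysms,
41 ruptured / 31 unruptured, stratified narrow/wide.  Group sizes per
stratum are not published, so each label defaults to a 50% narrow split
(rounded); only the totals are calibrated quantities.

**Metric mode** draws the four per-group metric sets (MWSS, HWSS, PWSS,
LSAR) directly from group-calibrated distributions: a normal truncated at
zero for metrics summarized as mean ± SD (LSAR additionally truncated at
1), and a log-normal matched to the published median and quartile figure
for skew-summarized metrics.  The published tables print a single
"quartiles" number per entry whose meaning (IQR vs Q3) is not stated; the
calibration accepts either via `quartile_kind` and defaults to IQR.  HWSS
is drawn conditionally truncated below the record's MWSS so the invariant
holds; the M-P and H-P ratios are *derived* from the sampled values, never
sampled independently.  The default calibration encodes the narrow-stratum
group summaries (e.g. ruptured MWSS 1.96 ± 1.30 Pa vs unruptured
3.33 ± 1.45 Pa) and the wide-stratum ones.

**Geometry mode** draws sac parameters per stratum (deep flasks for
narrow, bumps for wide) and rejects shapes whose measured classification
misses the intended stratum (a stratum rejecting >90% of draws is a
configuration error).  `run_cohort_cfd` meshes and simulates each
geometry independently; per-record failures are isolated and reported,
not fatal.

A single seed fans out to per-record substreams via
`SeedSequence.spawn`, so cohorts are reproducible regardless of execution
order.

What the generator does *not* emulate: angiographic segmentation noise,
3-D sac shape variety, within-patient clustering of multiple aneurysms
(records are independent, as in the source analysis), and any
morphology–hemodynamics coupling in metric mode (metrics and morphology
are conditionally independent given the group).  Passing tests therefore
demonstrate the correctness of the pipeline machinery and the qualitative
physics, not clinical reproduction.

## Statistics

Per variable and per group, normality is tested with a one-sample
Kolmogorov–Smirnov test against a normal with estimated moments using
Lilliefors-corrected critical values (plain KS with estimated parameters
is anti-conservative; which exact KS variant the original SPSS analysis
used is unknowable, so this choice is documented rather than asserted).
Both groups must pass (p ≥ 0.05) for the equal-variance independent t
test (Welch via `equal_var=False`); otherwise the Mann–Whitney U test —
exact enumeration when min(n₁,n₂) ≤ 8 without ties, tie-corrected normal
approximation with continuity correction otherwise.  Descriptives follow
the test: mean ± SD or median with Q1/Q3 (both quartiles are reported
since a single "quartiles" figure is ambiguous).  Spearman correlations
use tie-corrected mid-ranks.  The univariate screen admits metrics at
two-sided p < 0.05; backward stepwise logistic regression then removes
the least-significant predictor while its Wald p exceeds 0.10 (a common
removal default; the screen threshold is the stated 0.05), recording a
full removal trace that replays to the final model bit-for-bit.  Complete
separation is flagged on the result, not raised.  No multiple-testing
correction is applied across metrics, matching the source procedure.
The adaptive gate + test pipeline holds its nominal type-I error (checked
at n = 30/30 over 2000 null replicates against the 95% binomial band).

## Problem sizes and numerical defaults

Defaults: Δt = period/200 (implicit Euler), α_u = 0.7, α_p = 0.3, mass
tolerances 10⁻⁵ (pulsatile) / 10⁻⁶ (steady), 4 Jacobi momentum sweeps,
pressure refactorization every 8 outer iterations.  The validation suite
runs the steady refinement study at 8/16/32 cells across the caliber and
the pulsatile validation at 16 cells, 200 steps/cycle, 3 cycles.  The
end-to-end cohort demonstration uses 8 aneurysms at 16 cells across the
caliber and 50 steps/cycle: at 8 cells the sac shear layer is
under-resolved and LSAR saturates at 1.0 in both strata, while from 16
cells on the wide stratum desaturates (≈0.9) and the expected contrast
(narrow: lower MWSS, higher LSAR) appears — resolution, not calibration,
controls this behaviour.

## Known limitations

* The 2-D reduction makes sacs shear-driven cavities: sac-to-parent WSS
  ratios (M-P ≈ 0.01–0.05) are an order of magnitude below 3-D values,
  which reflect inflow jets in curved vessels.  Directions of contrasts
  are preserved; magnitudes are not.
* Rigid walls and Newtonian rheology, as in the source setting.
* First-order upwind convection and staircase sac walls limit sac-side
  accuracy at coarse grids; parent-side WSS is clean because those walls
  are grid-aligned.
* Metric-mode cohorts carry no hemodynamics–morphology correlation within
  groups, so Spearman analyses on them only reflect between-group
  structure.
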