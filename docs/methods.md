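# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Transport model

Particles follow the Itô advection–diffusion model

    dx = u(x, t) dt + sqrt(2 K) dW,

integrated by operator splitting: an explicit-midpoint (second-order
Runge–Kutta) advection step followed by an additive Gaussian random-walk
displacement with per-axis standard deviation `sqrt(2 K dt)` metres. The
splitting is the standard random-walk treatment of constant Fickian
diffusivity; with K constant there is no drift correction term. Positions are
kept in geographic degrees; every displacement is computed in local metres and
converted with the spherical-Earth factors `dlat = dy / R * 180/pi`,
`dlon = dx / (R cos(lat)) * 180/pi` at the latitude where the displacement
applies, which keeps the midpoint scheme genuinely second order on the
lon/lat ODE (verified by the convergence test: return-to-start error on a
circular orbit falls by a factor 3.5–4.5 when the step halves).

Defaults (all configurable in `TrackerConfig`):

| parameter | default | units | rationale |
|---|---|---|---|
| internal step `dt` | 1800 | s | resolves mesoscale advection; at ≤ 2 m/s a particle moves ≤ 3.6 km per step |
| diffusivity `K` | 933 | m²/s | sub-grid variability scale of a ~1/12°, daily-mean current product |
| Earth radius | 6 371 000 | m | spherical Earth; consistent with the degree/metre conversions throughout |
| `max_age_days` (PLD) | 10 | d | conservative pelagic larval duration for *Acropora*-type broadcast spawners |

Velocity sampling is bilinear in space and linear in time between daily
snapshots. Near the coast, land nodes contribute zero velocity and the
bilinear weights are renormalised over the ocean nodes of the cell; this
avoids the spurious onshore pull that leaks in when masked values are treated
as zeros with full weight, while remaining deterministic and continuous up to
the cell boundary.

**Status machine.** ACTIVE and STRANDED interconvert; INACTIVE (age ≥ PLD)
and LEFT_DOMAIN (outside the grid hull) are absorbing. A stranded particle is
held at its last ocean position, keeps ageing (the developmental clock does
not pause ashore), and resumes drifting if the tentative step returns to
ocean. Particle count is conserved: particles are re-flagged, never removed.
The ocean/land decision is a nearest-node landmask test, adequate because the
synthetic coastline is grid-resolved; polygon-accurate coastline interaction
is out of scope.

**Randomness.** One counter-based Philox stream per release batch, spawned
from the master seed via `SeedSequence`. Within a batch the draws are
vectorised over particles in fixed order, so results are bitwise reproducible
and independent of how batches are iterated. Draws are consumed for every
particle at every step (including frozen ones) to keep streams aligned as
statuses change.

## Biology

`BiologyConfig`: PLD 10 d, precompetency 4 d, hence a 6-day settlement
window. A connectivity event is the first record of a competent (4 d ≤ age ≤
10 d), ACTIVE larva inside a reef polygon; one event per (larva, destination)
pair — the matrices count distinct larvae, so re-entries add nothing, while a
larva may still connect to several different reefs. Self-recruitment (a larva
inside its natal polygon at its first competent record) is a legitimate event
and forms the matrix diagonal. Two open choices and how they were decided:

- Stranded records are not containment-tested by default (reefs are subtidal;
  a beached larva is not settling), switchable with `test_stranded=True`.
- Containment is tested at discrete 30-minute records, not along segments. At
  ≥ 1.5 m/s a particle moves ~2.7 km per step, comparable to reef diameters,
  so fast-transit connectivity is undercounted; this is accepted as a known
  bias of record-based detection and documented rather than hidden. (The
  scenario contrasts below hold despite it.)

Travel-time statistics use the population (ddof = 0) standard deviation: the
simulated larvae are the entire population of interest, not a sample. Cells
are blank exactly where the count matrix is zero. Temporal supply tables to a
destination complex omit intra-complex events by construction, so they show
external supply only.

The release schedule anchors at Feb 1 00:00 and steps 48 h while the date
stays in Feb–Mar: 30 releases in any year (a leap year shifts the last one to
Mar 30). Seeding is 200 larvae/km² above 1 km² of plan area (nearest-integer,
half away from zero — the protocol implies approximate counts, not an exact
integer contract) and a floor of 200 below it.

## Synthetic flow fields

Currents are defined by a scalar streamfunction and differentiated with
central differences, so the discrete divergence of every generated field is
identically zero — particles cannot pile up for numerical reasons, and psi
itself is a conservation oracle for the tracker (K = 0 tracking in a steady
Rankine field conserves psi to ~1e-6 of the core scale in the solid-body
core, where bilinear interpolation is exact).

One fixed equirectangular metric (cos at the domain-centre latitude) is used
for both streamfunction evaluation and differentiation. A per-latitude-row
metric was considered and rejected: with mismatched stencil metrics the
discrete divergence picks up O(1e-3) residuals, defeating the purpose of the
streamfunction construction. The cost is a ≤ ~2% speed distortion at the
domain edges of an 8° domain, irrelevant to the regime contrasts.

Components: uniform drift (psi = v·x − u·y); Rankine vortex (solid-body core,
1/r exterior; rotation +1 = counterclockwise = southern-hemisphere
anticyclone); Gaussian jet along a waypoint polyline (erf cross-path profile;
the end segments are extended far beyond the domain so the sign seam of the
cross-track coordinate cannot enter it). Each component carries an optional
piecewise-linear amplitude modulation in time — the cheapest way to represent
intermittent streams and eddy arrival/decay without solving dynamics.

**Domain.** 32–36°E, 28–20°S at 1/24°, 20 daily snapshots — finer than the
1/12° product it emulates so that eddies and jets are resolved at desk scale
with minutes-long runtimes. The coastline is meridional (land west) with a
Gaussian concave bight (centre 25.4°S, half-width 0.8°, indentation 0.6°).
Four reef bands mirror the along-shore complex ordering, north to south:
BA −21.6°, INHM −23.2°, INHC −25.6° (inside the bight), MRC −26.85°. Reefs
are small rotated squares, 0.5–3 km² of plan area, 5–20 km offshore,
placed disjointly with seeded randomness.

**Scenarios.** The constants were designed from transit-time algebra — the
distance between bands divided by the stream speed must fall inside or
outside the 4–10-day competency window — and then verified by simulation:

- **A** (slow alongshore stream): coastal jet 25 km offshore, width 40 km,
  peak 0.3 m/s. INHC→MRC (~140 km) transits in ~6–7 d (connects); BA→MRC
  (~580 km) would need ~22 d (cannot connect within the PLD). The 0.3 m/s
  peak is a modelling choice — no observed value exists for the weak bight
  stream — and is configurable.
- **B** (bypassing stream + lee cyclone): straight jet at ~33.55°E past the
  bight mouth, bending back to the coast south of it, peak 1.0 m/s; clockwise
  (cyclonic) Rankine eddy inside the bight (32.70°E 25.35°S, core 40 km, peak
  0.45 m/s; solid-body loop period ~6.5 d). Bight larvae recirculate in the
  lee eddy before diffusing into the jet, so their travel times to MRC
  lengthen by ~1 d on average relative to A, and far fewer arrive.
- **C** (boundary-current regime): coastal jet 30 km offshore, width 45 km,
  peak 1.6 m/s, fed by an offshore counterclockwise (anticyclonic) eddy
  (34.8°E 21.3°S, core 80 km, peak 0.4 m/s). BA→MRC transits in ~4.5–6 d,
  inside the settlement window. The eddy is kept compact: the 1/r far field
  of a larger vortex sweeps the jet offshore at the bight latitudes and
  destroys the coastal corridor.

**What the generator does not emulate:** data-assimilative dynamics, tides,
bathymetry beyond the binary landmask, vertical structure, realistic eddy
life cycles, or the true reef geography (polygons are synthetic stand-ins
for digitised reef charts). Tests passing on these fields demonstrate the
correctness of the tracking, settlement and aggregation machinery and the
qualitative flow-regime mechanisms — not quantitative predictions for any
real coastline.

## Numerical details and edge cases

- Grid and time axes must be strictly increasing and uniform; a descending
  latitude axis in an input file is flipped on read, and missing-value fills
  become the landmask when no mask variable is present.
- Plan areas use a Lambert azimuthal equal-area projection about the polygon
  centroid (shoelace on projected vertices); agreement with a spherical-excess
  oracle is within 0.5% for polygons < 10 km across. Sub-m² rings are
  rejected as degenerate.
- Overlapping reef polygons resolve containment to the first reef in
  north→south order (deterministic tie-break, warned on construction).
- A release whose 10-day horizon extends past the field's time span is
  truncated with a warning; its trailing records repeat the frozen state.
- Age is compared with `>=` at the PLD boundary: a larva at exactly 10 days
  is inactive (the stricter reading of "tracked for 10 days").
- `seed_count` rounds half away from zero; `numpy.round`'s banker's rounding
  would silently bias counts at .5 boundaries.
- The demo problem sizes (1/24° grid, 20 daily steps, 4 reefs per complex,
  3 release dates in the regime tests) keep the full suite to a few minutes
  on one CPU; all sizes scale through configuration.

## Known limitations

- Record-based settlement detection undercounts fast transits (above).
- The nearest-node coastline makes stranding resolution grid-limited.
- Gaussian-jet waypoint kinks produce curvature discontinuities in the flow
  (the streamfunction itself stays continuous and non-divergent).
- No larval mortality, competency decay, swimming or post-settlement
  survival: connectivity counts are potential, not realised, recruitment.
- The fixed-metric projection is appropriate for single-digit-degree domains;
  basin-scale domains would need a proper spherical streamfunction curl.
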