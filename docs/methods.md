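# Methods

This note documents the models, numerics, and design choices behind
`tissellate`, in the spirit of a simulator's model documentation: what is
assumed, what is tunable, and what passing tests do and do not show.

## Colliding-front model

**Assumptions.** A freely expanding epithelial monolayer advances with an
outward normal speed *v*<sub>n</sub> that is uniform along its perimeter
and independent of tissue geometry and density (default 29.5 μm/h, the
measured MDCK edge speed).  When two fronts meet, the boundary pins at the
point of contact and never moves *as a front* again; post-collision drift
is a separate, mechanical effect handled by the mechanics layer.  The model
is a continuum front description with no cell-scale resolution: features
below ~100 μm (e.g. the escape streams seen at some tri-tissue
collisions, an emergent three-body effect) are outside its validity
domain, and uniformity of *v*<sub>n</sub> degrades in high-curvature
zones; no curvature correction is applied.

**Numerics.**  The engine tracks, per tissue, a per-pixel continuous
travel distance *f* from the initial footprint boundary (seed pixels carry
the negative signed inside-distance so growth starts at the footprint
edge, not at pixel centers).  Each step of length d*t*, a free pixel's
tentative distance is relaxed over a Euclidean chord window of radius 5
pixels — `min(f(y) + |x−y|)` over claimed pixels *y* in the window,
computed as one grey-scale erosion with a conical structuring function —
and the pixel is claimed once its tentative distance drops below the
cumulative advance *v*<sub>n</sub>·*t*.  Distances accumulate real chord
lengths, so:

- long-run edge speed is exact regardless of d*t* (a CFL condition
  *v*·d*t* ≤ spacing is enforced; the default 10 μm / 20 min pair
  satisfies it at 29.5 μm/h);
- fronts are isotropic to a fraction of a percent.  Repeated single-pixel
  dilation was rejected because its limit shape is a diamond (~20% speed
  deficit along diagonals); chord relaxation measures a calibrated
  29.6 μm/h effective radial speed for a nominal 29.5 (the residual
  +0.4% is the chord-metric direction quantization).

Chords are at most 5 pixels (50 μm at default resolution), shorter than
any tissue, so fronts cannot tunnel across a competitor.  Contested pixels
go to the tissue with the smaller continuous arrival estimate
(*f*/*v*<sub>k</sub>); exact ties go to the lower tissue id, which keeps
mirror-symmetric scenes symmetric to one pixel and makes every run
bit-deterministic.  `step_fronts` therefore carries state (the distance
fields) between calls; the one-shot functional signature returns that
state explicitly, and `simulate` manages it internally.

**Oracle.**  For convex seeds and equal speeds the final tessellation has
the closed form "assign each point to the seed with the smallest
d(x, seed)/v" (a weighted-distance partition).  `arrival_partition`
implements it with exact Euclidean distance transforms and is used as an
independent cross-check: on random convex scenes the stepped simulation
and the oracle disagree on <0.1% of pixels (tolerance 0.5%), all within a
pixel of a boundary.  With unequal speeds the oracle ignores the need for
fronts to travel *around* slower tissues; it remains a good bound for
engulfment geometries (the fast front is faster both ways around) but is
documented as approximate there, and it warns on non-convex seeds.

## Boundary metrics

Boundary curves are extracted by marching squares on one tissue's
indicator at level 0.5, keeping the longest contour run whose vertices lie
against the other tissue (within 0.9 px of it); vertices are sub-pixel by
linear interpolation.  **Roughness** is the RMS transverse deviation from
the mean boundary line along the collision axis, computed after resampling
the curve at uniform 10-μm arc-length intervals.  The resampler picks the
*nearest original vertex* rather than interpolating: interpolation
synthesizes smoother points and damps vertex-scale fluctuations by
√(2/3) ≈ 0.82, biasing the RMS low.  Nearest-vertex sampling preserves a
white-noise amplitude while still weighting vertices evenly by arc length;
the cost is that roughness is linear in amplitude only to a few percent
for steep boundaries (arc length itself grows with amplitude).  RMS
deviation is a stand-in definition — it is the standard interface metric
and supports smoothness *comparisons*, but absolute experimental roughness
values are not reproduced here.  **Prediction error** is the symmetrized
mean nearest-vertex distance between two curves.  **Tri-junctions** are
8-connected clusters of 2×2 pixel blocks containing ≥3 distinct nonzero
labels, reported at the cluster centroid; this is deterministic and robust
to resolution.

## Collision mechanics

Post-collision boundary motion is modeled as pressure-driven flow against
cell–substrate friction: −∇P = ξ**v** with P = P(ρ) increasing, so
**v** = −(P′(ρ)/ξ)∇ρ.  Active traction is neglected at the boundary
because polarized traction decays within ~50 μm of the outer edges, which
are ~1 mm away.  Friction ξ is a user parameter (default 100 Pa·s/μm²,
the literature value) and is assumed density-independent; a
density-dependent ξ would change speeds but not the direction of motion.
The logarithmic equation of state P = K ln(ρ/ρ<sub>e</sub>) gives
P′ = K/ρ, hence K = ρ·P′(ρ).  With the fitted P′ ≈ 0.5 Pa·mm² and a mean
density of 3.4×10³ mm⁻² this chain yields K ≈ 1.7 kPa ~ 2 kPa, between
the stiffness of suspended monolayers under stretch (20 kPa) and the
spreading-derived tensile value Γ/h = 2.4 mN/m / 5 μm = 0.48 kPa.

Measurement conventions (defaults follow the standard assay):

- velocity and density fields live on 88-μm square windows (the final PIV
  window size); velocities are stored in μm/h and the ξ relations convert
  internally (3600 s/h);
- kymographs average over the strip direction ignoring 1 mm at the top
  and bottom, with a centered 3-timepoint moving average; empty bins stay
  NaN, never zero; replicate kymographs are averaged after aligning on the
  initial configuration, cropped to the median extent;
- the center of expansion is the midpoint of the largest contiguous run of
  bins with |v_x| < 3 μm/h;
- the boundary trace comes from label adjacency; fusion is the first frame
  at which the two labels touch (the natural operational definition of the
  fusion point);
- boundary velocity is the least-squares slope of the trace over a
  configurable window, default 20–36 h (after collision, before the
  boundary stalls);
- the density gradient is (ρ_R − ρ_L)/300 μm over 300-μm boxes either
  side of the boundary (exact for linear profiles);
- the P′ fit is through *assay-average* points, with the Pearson r
  reported over individual pairs; both behaviors are exposed, and an
  optional through-origin fit is provided because it is ambiguous whether
  the canonical fit is constrained (the default is unconstrained).

## Synthetic data generator

The generator emulates two-rectangle collision assays in one dimension
(uniform along the strip).  Pre-collision, edges advance at
*v*<sub>n</sub> with an edge-localized velocity profile decaying over
300 μm into the bulk; density is advected conservatively (first-order
upwind finite volume, CFL-substepped) by that same field and grows
logistically (default rate 0.04 h⁻¹ ≈ 18-h doubling, carrying capacity
6000 mm⁻²), so edges dilute as they spread and older/bigger regions end up
denser, as in experiments.  Post-fusion, the boundary moves with
v_b = −(P′/ξ)∂ρ/∂x (gradient measured by the generator's own 300-μm box
bookkeeping, independent of the analysis code — only the
`pressure_velocity` formula is shared, and it is unit-tested separately),
while the velocity field is the simplest shape consistent with the
observed kymographs: piecewise linear through (outer edge, −v_n),
(center of expansion, 0), (boundary, v_b), (outer edge, +v_n).  The
center of expansion relaxes exponentially from the denser tissue's
centroid to the fused-tissue centroid with a configurable timescale
(default 10 h) — the relaxation rate is exposed rather than asserted
because it is not otherwise constrained.  Gaussian noise (1 μm/h on
velocity windows, 5% on density windows) is added last; nuclei are an
inhomogeneous Poisson pattern with per-window intensity ρ·area.  All
randomness flows through one `numpy.random.default_rng(seed)` (PCG64);
fixed seeds give bit-identical output.

Because density is advected by the same velocity field that moves the
boundary, the generated fields satisfy the 1-D continuity equation in
zero-growth mode (total mass is conserved to round-off; the central
difference residual shrinks as the discretization is refined), and the
instantaneous v_b/∂ρ relation holds exactly at every step — so pipeline
recovery of P′ tests the *analysis*, not a tautology of shared code.

**What the generator does not emulate:** PIV correlation noise structure
(noise is iid Gaussian per window), cell-scale granularity, curvature of
real boundaries along the strip, heterotypic mechanics, and the escape
dynamics of tri-tissue collisions.  Passing the recovery tests shows the
analysis chain is unbiased under the model's assumptions at realistic
noise; it does not validate the pressure–density model against real
tissue.

## Problem sizes and tolerances

Test simulations use 1.6–3.4 mm worlds at 10–20 μm spacing and 20–30 min
steps — large enough that boundaries span hundreds of pixels, small enough
that the full suite runs in well under a minute per heavy fixture.
Geometric assertions use 1–1.5 pixel tolerances (discretization), speed
calibration ±0.3 μm/h, Monte-Carlo assertions the analytic ±2–3σ bands at
fixed seeds, and parameter recovery ±20% at default noise.  Degenerate
inputs (zero speeds, empty scenes, non-adjacent labels, all-NaN bins,
degenerate fits) return documented values or raise with the offending
quantity named.

## Known limitations

- The boundary-drift mechanics and the shape engine are deliberately not
  coupled: tessellation shapes are geometry-only, and density-driven
  drift is analyzed separately.  Feeding drift back into shapes is
  possible future work.
- The arrival-partition oracle is exact only for convex seeds at equal
  speeds without wrap-around.
- The dye-segmentation histogram normalization (matched 1st–99th
  percentile rescaling, ties to the first channel) is one reasonable
  choice among several; the underlying procedure is not uniquely
  standardized.
- No statistical machinery for comparing roughness distributions across
  conditions is included.
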