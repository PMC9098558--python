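# Methods

This note documents the models, algorithms and numerical choices behind
`tmsmap`, what the synthetic-data generator does and does not emulate, and
the known limitations of the approach.

## Problem setting

Multi-muscle nTMS motor mapping asks how strongly the cortical
representations of simultaneously recorded muscles overlap, and how that
overlap depends on stimulation intensity. The measured primitive is the
motor evoked potential (MEP): the peak-to-peak EMG amplitude a single TMS
pulse evokes in each muscle, paired with the coil position that evoked it.
A *motor map* is the spatial distribution of MEP amplitude over stimulation
sites for one muscle at one intensity; overlap is quantified on
co-registered maps.

## EMG processing

* **Peak-to-peak extraction.** Amplitude = max − min of the trace within
  10–60 ms after the pulse; latency = time of the window's absolute
  extremum. Latency is carried through but not used by any downstream
  metric.
* **Trial rejection.** A trial is rejected iff any sample within 300 ms
  before the pulse exceeds ±20 µV. This is the only automated rejection
  rule: it is the single objective criterion in the protocol this package
  implements (the original workflow also allowed visual rejection, which is
  not reproducible in software). Traces are assumed hardware band-passed;
  no further filtering is applied.
* **Aggregation.** The accepted trials at one site reduce to their median.
  A site whose trials are all rejected is dropped from map construction
  with a warning rather than imputed; with three pulses per site and
  realistic artifact rates this is rare.
* **rMT.** The resting motor threshold is the lowest tested stimulator
  intensity (% MSO) at which ≥ 5 of 10 amplitudes exceed 100 µV, on a
  pre-collected intensity series; adaptive staircases are not modelled. A
  boundary flag marks series whose lowest tested intensity already
  qualifies.

## Map construction

* **Merging.** Sites within 3 mm (single-linkage, i.e. connected
  components of the ≤ radius graph) are replaced by their mean coordinate
  and median amplitude. The protocol's walk keeps sites ≥ ~11 mm apart, so
  merging matters mainly for repeated or re-visited coil positions in real
  logs.
* **Plane projection.** Coil coordinates are projected orthogonally onto
  the least-squares plane of the site cloud (SVD); the 2-D axes are the
  in-plane principal directions with a deterministic sign convention.
  In-plane millimetre distances are preserved; curvature of the real
  cortical surface is deliberately ignored (see Limitations).
* **Interpolation.** Amplitude is interpolated on the Delaunay
  triangulation of the merged sites, piecewise-linearly in **log**
  amplitude, with values at or below a 10 µV response floor treated as
  floor. The log-domain choice is deliberate: MEP amplitude decays roughly
  exponentially with distance from a representation's core, and at the
  protocol's ~14.5 mm site spacing amplitude-space chords overestimate the
  suprathreshold extent of a representation by tens of percent, whereas
  log-space chords track it to a few percent (measured against analytic
  fields; a C¹ cubic interpolant showed no improvement). The interpolant
  is exact at the sites, cannot overshoot the node range, and has no free
  smoothing parameter. Outside the convex hull of the sites the boundary
  amplitude is tapered linearly to zero within one median site spacing;
  beyond that the map is identically zero. Because no-overshoot
  interpolants cannot exceed their node values, a peak that falls between
  sites is reconstructed slightly low — an irreducible property of
  interpolation from sparse grids.
* **Grid.** Default 1 mm cell size, extent = sites + 10 mm margin, or an
  explicit shared extent so that the maps of different muscles (and
  intensities) of one subject are cellwise comparable. Maps are stored as
  ESRI-style ASCII grids with a JSON sidecar for muscle/intensity labels.

## Map and overlap metrics

* **Area / volume / centroid** at threshold *t* (default 50 µV, the
  absolute response criterion; a relative criterion is available through
  `contour_fractions`): cell count × Δ², amplitude sum × Δ², and the
  amplitude-weighted mean cell centre (an unweighted variant is an option).
* **Intersections.** The overlap of two amplitude maps is their cellwise
  minimum, the unique choice for which X₁₂ ≤ min(X₁, X₂) holds and the
  union (cellwise maximum) satisfies inclusion–exclusion exactly for both
  area and volume, for two and three maps. Overlap degrees follow the
  intersection-over-union formulas on these X's; values are graded on the
  five-step category scale with the first band closed ([0, 20] →
  negligible) and subsequent bands half-open, the natural continuous
  reading of integer band edges.
* **EMD.** Both maps' suprathreshold amplitude distributions are
  normalised to unit mass (topography should be compared independently of
  size, which the other parameters already measure) and the exact optimal
  transport cost is computed with Euclidean mm ground distance by solving
  the transportation linear program (HiGHS, sparse constraints). For
  cohort-scale maps the grids are first aggregated into ~4 mm blocks
  (mass-preserving, positions at block centres), which changes pairwise
  EMDs by well under the grid resolution while keeping each LP small.
  Triple ("ALL") records carry no EMD — optimal transport between three
  distributions has no canonical scalar — but do carry the centroid
  distance between the target map and the triple-overlap map.

## The synthetic-data generator

The generator stands in for subject recordings that are not publicly
available. It emulates the study design end to end:

* **Excitability fields.** Each muscle's representation is an isotropic
  2-D Gaussian amplitude field: peak-to-peak amplitude `P·g·exp(−r²/2σ²)`,
  with gain g = 1 at 110 % rMT and `intensity_gain` per +10 % rMT step.
  Defaults: three overlapping fields (FCR σ 9 mm / 420 µV, FPB σ 8 mm /
  460 µV, ADM σ 8.5 mm / 380 µV) whose centres sit 9–12 mm apart, giving
  50 µV map areas of ~9–14 cm² and medium-to-high true pairwise overlap —
  the regime the emulated protocol reports and, importantly, a field scale
  the 20-site grid can actually resolve: substantially narrower fields
  make a design with ~14.5 mm site spacing unable to recover overlap
  changes of a few percentage points, which the real study demonstrably
  could. `intensity_gain` defaults to 2.0 (amplitude doubling per +10 %
  rMT, ~+30 % map area), standard recruitment behaviour between 110 % and
  120 % rMT. Per-subject variability jitters centres (SD 1.5 mm), spreads
  (±10 %) and peaks (±20 %).
* **Grids.** A pseudo-random walk from the hotspot: step length
  N(14.5, 3.6) mm, uniform direction, candidates resampled when closer
  than `spacing_mean − spacing_sd` (≈ 10.9 mm) to an existing site or
  farther than 34 mm from the hotspot (a disc with the area of the
  conventional 6 × 6 cm coverage region, which is also the area 20 sites
  at 14.5 mm spacing tile). Realised nearest-neighbour spacing is
  ~12.3 ± 1.2 mm, inside the protocol's printed band; a plain
  minimum-separation of a few mm lets the walk cluster at half the printed
  spacing, so the separation rule is part of the design emulation.
* **Trials.** Each pulse yields one trace per muscle: Gaussian baseline
  noise (default 3 µV RMS — a quiet resting baseline; the ±20 µV rule then
  rejects essentially only injected artifacts) plus a one-cycle biphasic
  sine at 20 ms latency, 15 ms duration, scaled so its *sampled*
  peak-to-peak equals the field amplitude exactly; field values below
  10 µV emit no deflection (absent responses at the fringe). With
  probability `artifact_rate` (default 0.005, matching the reported
  rejection tally of a few trials per cohort) a 50 µV pre-activation burst
  is injected 150 ms before the pulse, which forces rejection.
* **Design counts.** 12 subjects × 2 intensities × 20 sites × 3 pulses,
  one shared grid per subject reused at both intensities, three muscle
  traces per pulse. The per-target-muscle session dimension of real
  protocols is collapsed: all three fields are sampled by one grid centred
  on the composite hotspot. Coordinates are generated in the map plane
  with a dummy third coordinate; plane projection is exercised (and tested
  on tilted planes) separately.
* **Ground truth.** Because the fields are analytic, the true
  suprathreshold regions are discs, and the true pairwise/triple area ODs
  are computed on a 0.1 mm grid (the pair case is verified against the
  closed-form circle-lens intersection in the tests). These are the
  recovery targets for the whole pipeline.

What the generator does **not** emulate: EMG crosstalk between muscles,
electric-field physics and coil orientation effects, anisotropic or
multi-peaked representations, amplitude trial-to-trial variability beyond
additive baseline noise (real MEPs fluctuate ~20–40 % between identical
pulses), and cortical surface curvature. Passing recovery tests therefore
shows the *analysis chain* is correct and well-conditioned under the
protocol's sampling design — not that real maps are Gaussian.

## Measured behaviour under the emulated design

With the defaults above (problem sizes: 12-subject cohorts, 20 sites,
1 mm map resolution, 0.1 mm ground-truth grids), the pipeline recovers
each subject's true pairwise area OD with a median absolute error of
~3 percentage points, shows the higher-intensity increase of median area
OD for every muscle pair in every seeded cohort tested, and moves median
EMD and centroid distance by well under 1 mm between intensities — size
grows, topography stays. The acceptance script recomputes all of these at
an arbitrary seed.

## Numerical choices and degenerate inputs

* Thresholding is strict (`> t`); ties at exactly t count as below.
* Empty suprathreshold sets yield area 0, undefined centroid (`None`),
  NaN overlap degree (0/0), NaN EMD and NaN centroid distance — undefined
  results are values, not exceptions, so cohort tables keep their shape.
* Degenerate geometry (collinear site clouds, < 3 sites, mismatched map
  grids) raises `ValueError`; map intersection deliberately refuses to
  resample silently.
* Determinism: every stochastic step flows from one `numpy` Generator
  seeded from the run seed; identical seeds give byte-identical artifacts.
* Within-subject normalisation divides by the subject × parameter maximum;
  all-zero groups are left at zero with a warning. Cohort SDs use the
  sample (n − 1) estimator and are flagged undefined for single-subject
  cells.

## Limitations

* Maps live on the best-fit plane of the site cloud; reported areas are
  planar, not geodesic. For the ~6 cm extent of a mapping grid on the
  scalp the distortion is small but systematic.
* The interpolant is a declared design, not a reconstruction of any
  proprietary mapping software's algorithm; absolute areas from different
  map-construction tools are not interchangeable, although overlap
  *degrees* (ratios) are far less sensitive to the choice.
* EMD on coarsened grids is exact transport on the coarsened
  distributions; for sub-millimetre EMD questions use `coarsen=1`.
* The statistical modelling of cohort effects (mixed models, ANOVA,
  multiple-comparison correction) is intentionally out of scope; the
  summary tables are the tidy input such tools consume.
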