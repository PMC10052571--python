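# Methods

This note records the model, its assumptions, the parameter choices and the
numerical design of `phytocanopy`, including the places where the design was
genuinely open and the package had to commit to a choice.

## Plant and canopy geometry

A maize shoot is a stack of 19 phytomers; each phytomer's leaf is fully
determined by scalar descriptors (cm): midrib length `LL`, collar height
`HLBase`, highest-point and tip heights (`HLTop`, `HLTip`, equivalently the
differences `HDBTop = HLTop − HLBase ≥ 0` and `HDBTip`, which may be
negative for drooping tips), horizontal projections `Ltop ≤ Ltip`, leaf
azimuth, and maximum blade width.

**Midrib curve family.** The midrib is planar in the leaf's vertical
azimuth plane and is composed of two quadratic Bézier segments,
collar → highest point and highest point → tip, whose middle control points
sit at the highest point's height. This guarantees by construction that the
curve's maximum height is exactly `HDBTop`, attained at horizontal distance
`Ltop`, and that the tip lands at (`Ltip`, `HDBTip`). The remaining
constraint — arc length = `LL` — is met by a single shared "bulge"
parameter solved with Brent's method (both segments are straight chords at
bulge 0; arc length grows monotonically with bulge). Feasibility requires
`chord(collar→top) + chord(top→tip) ≤ LL`, which is stronger than the raw
descriptor inequality `chord(collar→tip) ≤ LL`; when descriptors are
raw-feasible but family-infeasible, the projections `Ltop`, `Ltip` are
shrunk by the smallest common factor that restores feasibility and `LL` is
kept exact (arc length and heights take priority over projections). Midribs
are sampled uniformly in arc length; descriptor extraction from a sampled
polyline (`measure_midrib`) refines the flat-topped height maximum with
sub-sample parabolic interpolation.

**Blade surface.** The blade is a flat ruled strip around the midrib. Its
width runs horizontally, perpendicular to the leaf plane, and follows a
beta-shaped profile `w(s) ∝ s^1.9 (1−s)^3.1` peaking at 0.3 of the midrib
length — a typical maize blade outline; no profile was available to copy,
so this is a package choice. The profile is floored at 1.5 % of the maximum
width so collar and tip facets keep strictly positive area. Tessellation
yields exactly `2 · n_segments · n_width_strips` triangles per leaf
(defaults 8 × 2).

**Stand layout.** Plants are replicated on a 10 × 15 grid: rows 0.6 m
apart, within-row spacing `1/(PD · 0.6)` m at plant density PD = 6 m⁻².
Leaf planes alternate ±90° off the row direction with ±15° seeded uniform
jitter (maize distichy; the recorded field azimuth distributions were not
available, so distichous alternation is assumed). The focal block is the
central 3 × 3 plants; all canopy-level quantities are normalised by its
ground area `M/PD = 1.5 m²`. An opaque *virtual wall* encloses the grid
footprint up to 60 % of plant height, emulating the optical closure of the
surrounding field; above wall height the sides are open. Stems and ears are
not rendered by default — the radiation bookkeeping concerns leaves.

## Radiation

Leaves are optically black: each photon is intercepted at its first hit, no
scattering, no spectral resolution, no penumbra. For each hour (local solar
time, integer hours from ⌈sunrise⌉ to ⌊sunset⌋):

* **Solar geometry** uses Spencer's declination series with standard
  hour-angle trigonometry, on local solar time (no equation-of-time or
  longitude correction is needed on that time base). Accuracy against an
  independent implementation is well under 0.5°.
* **Direct beam.** A facet receives the beam iff it *faces* it (angle
  between outward normal and propagation direction > 90°) and its centroid
  ray toward the sun is unoccluded by any leaf facet or wall. The flux on a
  sunlit facet is `I_dir / cos(zenith) · |cos(normal, beam)| · area`, i.e.
  beam-normal irradiance times projected area. The orientation-only
  classification (no occlusion test) is available as an option
  (`with_occlusion=False`) because the sunlit-area definition in the
  literature is sometimes purely orientational; occlusion-aware is the
  default since an orientation-only rule would count beam-shaded facets as
  sunlit.
* **Occlusion algorithm.** Exact ray casting, not a rasterised depth
  buffer: with a shared ray direction, the Möller–Trumbore test reduces to
  a 2D point-in-triangle test in the beam-perpendicular plane plus a depth
  comparison, which vectorises over ray-chunks × triangles with projected
  bounding-box culling. Exactness matters because the test suite demands
  flag-identical agreement with an independently written brute-force
  per-ray oracle; a 1 cm depth buffer could not guarantee that on arbitrary
  scenes. Rays ignore hits closer than 10⁻⁴ cm (the origin facet and
  seam-coincident neighbours).
* **Diffuse sky.** The hemisphere is discretised into rings of ~4–5
  azimuthal sectors each (46 sectors ⇒ 10 rings), each sector a directional
  source at the ring's flux-weighted zenith carrying its share of the
  horizontal diffuse flux; weights sum to one, so an unobstructed
  horizontal receiver recovers the incident diffuse flux exactly. Zenith
  resolution is prioritised over azimuth because interception by a canopy
  varies far more with source elevation; a classic 6-ring 46-sector layout
  left ~11 % discretisation error against a 145-sector sky, the adopted
  layout ~3–5 %. Radiance is isotropic ("uniform") by default with a
  standard-overcast option; the true sky distribution behind the reference
  data is unknown.
* **Direct/diffuse split** of incident PAR: fixed diffuse fraction
  (default 0.25, a clear summer day) or a Spitters-type clearness-index
  partition from the ratio of actual to extraterrestrial PAR.

Records per (focal plant, rank, hour): `LA` (cm²), `IPP` (µmol leaf⁻¹ h⁻¹,
3600 × the facet flux sum) and sunlit leaf area.

**Energy bound.** The suite asserts, for every daylight hour of a
multi-day run, that total intercepted direct power does not exceed the beam
power flowing through the scene: beam-normal irradiance × the area of the
scene bounding box projected along the beam. At zenith 0 this equals the
horizontal-footprint bound; at oblique sun the horizontal-footprint version
is *not* a valid bound, because light legitimately enters the scene's sides
above the virtual wall, so the beam-cross-section form is used.

## Leaf photosynthesis

Ye's light-response model and its closed-form maximum are given in the
README. Fitting is multistart (8 starts seeded from the data: Rd from the
dark point, α from the low-light slope) trust-region least squares with
bounds α ∈ (0, 0.15], β ∈ [0, 10⁻²], γ ∈ (10⁻⁵, 0.1], Rd ∈ [0, 10]
(physiologically plausible maize ranges). Because β is weakly identified at
chamber PPFD ≤ 2000 µmol m⁻² s⁻¹ and inflates the variance of α̂ when the
data do not support it, `fit()` also fits the β = 0 restriction and keeps
the lower-AICc model (small-sample corrected; `select="full"` disables
this). Standard errors come from the Gauss–Newton covariance at the
optimum.

**Layer mapping.** Measured parameter sets exist for three canopy layers —
upper, ear ("middle") and lower. The ear layer covers the ear leaf ± 1
rank; ranks above are upper, below are lower, with no within-layer
heterogeneity. In trait-swap scenarios the *host structure's* ear rank
anchors the mapping, so a parameter set transplanted onto a different
architecture follows that architecture's layering.

## Canopy integration

The chain is plain bookkeeping (README formulas): leaf-average PPFD per
hour, Ye-model leaf rates area-weighted over the focal plants, hourly →
daily integration (× 3600), biomass via 44 g mol⁻¹ CO₂ (with the explicit
10⁻⁶ µmol→mol factor — dimensional consistency forces it) and a CO₂→dry
mass conversion efficiency Cr = 0.41 for maize; interception energy via
4.55 µmol photons per joule of PAR and 10⁻⁶ J→MJ. Yield is the 60-day
post-silking accumulated biomass (Mg ha⁻¹ = g m⁻² × 10⁻²); RUE is
ADM/AIPAR. A non-60-day window must be requested explicitly. The canopy is
held static over the window (a silking-stage snapshot); no leaf senescence
or stay-green dynamics are modelled, so late-season declines in both area
and photosynthesis are outside the model's scope.

**Leaf-average vs facet-level integration.** Feeding the *leaf-average*
PPFD to the concave light response overestimates canopy assimilation
relative to the exact facet-level integral (Jensen's inequality over the
bimodal sunlit/shaded flux distribution). Measured on the reduced test
stand: ≈ 23 % overestimate under beam-dominated light (25 % diffuse),
< 10 % under diffuse-dominated light. The leaf-level formulation is kept —
it is the method under study — and the discrepancy is quantified in the
test suite rather than hidden.

## Heterosis decomposition

Seven scenarios (pure JNK728/J2416/JMC01; A1/A2 = parent structure + hybrid
physiology; B1/B2 = hybrid structure + parent physiology) and four
contribution percentages per metric. The arithmetic is exact-rational on
short-decimal inputs so printed tables reproduce without float drift;
percentages are reported at one decimal and integer-rounded (half away from
zero) for comparison with published integers. Structure and physiology
contributions are *not* forced to sum to 100 %; the residual
`100 − Cc − Cp` is reported as an interaction term (a package extension).
Scenario runs share the geometry seed through the structure source, so a
physiology swap leaves interception bitwise unchanged and a self-swap is
bitwise identical to the pure run.

## Synthetic-data generator

The generator replaces the study's 3D-digitiser, gas-exchange and weather
inputs:

* **Architecture.** Descriptor-vs-rank curves are scaled beta functions
  anchored at the published peak values and peak ranks (e.g. the hybrid's
  `HDBTop` peaks at rank 14 with 67.68 cm). Multiplicative rank noise
  (CV 2 %) is re-anchored so the stated peak value stays at the stated rank.
  `HDBTip = 0.8 · HDBTop` (mild droop), `Ltop ≤ 0.92 · Ltip`, and
  `LL = 1.06 ×` the two-chord length, which guarantees every generated
  spec is feasible downstream without repair. Collar heights follow a
  power-1.6 internode stack topping out just below plant height, which
  also places the ear (rank 13/13/12) near the observed ear heights. Blade
  widths are proportional to midrib length with the constant back-solved so
  total plant leaf area hits the cultivar targets (0.72 / 0.46 / 0.58 m²);
  widths are unreported in the source data, so area is the calibrated
  quantity. Plant-height jitter is 3 cm SD — between-canopy variation small
  enough that the cultivar ordering (JNK728 > JMC01 > J2416 in height and
  area) is preserved across seeds.
* **Physiology.** From published (α, Amax, Rd) triples per layer, β is
  fixed at 10⁻⁴ and γ solved from the Amax closed form. With β = 10⁻⁴ the
  photoinhibition optimum (~2280 µmol m⁻² s⁻¹) lies inside the measured
  PPFD range, as mild midday photoinhibition in maize does, and Amax is
  identified by the data rather than extrapolated (at β = 10⁻⁵ the fitted
  Amax was an asymptote estimate, biased ≈ +4 µmol at σ = 0.3). A-Q
  observations are Ye-model evaluations at the standard 12 PPFD levels
  (2000 … 50, 0) plus Gaussian noise; replicates model the three field
  plots.
* **Weather.** Sinusoidal clear-day PAR truncated at sunrise/sunset
  (default peak 2000 µmol m⁻² s⁻¹ at the study latitude, 39.93° N), an
  optional lognormal day-to-day cloudiness multiplier, and the configured
  direct/diffuse split.

What the generator does *not* emulate: organ growth between sampling dates
(a single static snapshot stands in for the 2-day digitisation cadence),
leaf senescence, measured 2021/2022 weather, within-layer physiological
gradients, and real azimuth distributions. Passing tests therefore certify
the computational pipeline and its internal consistency on realistic
synthetic canopies — not agreement with any particular field season.

## Problem sizes and numerical tolerances in the test suite

Tests run reduced configurations chosen as the smallest stands that still
exhibit mutual shading and border effects: 3 × 5 or 3 × 3 plant grids,
coarse tessellation (8 facets/leaf), 10-day windows for scenario
identities, 3 days for the hourly energy audit, 16–46 sky sectors; the
occlusion oracle runs 50 random ≤ 500-facet scenes with exact flag
equality. Fit-quality checks use 200 replicate fits at σ = 0.5 with 3
measurement replicates per level (median α error < 5 %, median R² > 0.99).
Geometry round-trips hold LL and heights to 0.5 % and projections to 2 %;
aggregation identities (layer additivity, IPAR scaling) to 10⁻¹² relative;
the diffuse-sky discretisation to 5 % between 46 and 145 sectors. The
full-scale 150-plant, 60-day configuration is supported and exposed through
the CLI config but is not exercised by the default suite.

## Known limitations

* Black-leaf optics: no transmitted/scattered PAR, so deep-canopy PPFD is
  underestimated relative to radiosity-style engines.
* Centroid-sampled occlusion: a facet is wholly sunlit or wholly shaded;
  partial overlaps resolve only with finer tessellation.
* Static canopy and constant physiology over the 60-day window; yield
  equals accumulated biomass with no partitioning or grain-filling
  dynamics.
* The leaf-average PPFD formulation overestimates assimilation under
  strong direct light (quantified above).
* Local solar time only; comparisons with clock-time weather records need
  an external longitude/equation-of-time correction.
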