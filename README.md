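# phytocanopy

Phytomer-based 3D maize canopy photosynthesis: parametric canopy
reconstruction, hourly PAR interception on triangulated stands, leaf-to-canopy
photosynthesis integration, and a trait-swap decomposition that attributes
hybrid–parent differences in yield and radiation use efficiency to canopy
*structure* versus leaf *photosynthetic capacity*.

## The problem

Maize hybrids out-yield their parental inbreds through two entangled routes:
a larger, better-arranged canopy that intercepts more light, and leaves that
fix more carbon per photon intercepted. Field measurements alone cannot
separate the two, because every plant carries its own structure *and* its own
physiology. A 3D canopy photosynthesis model can: build the hybrid's canopy
with a parent's leaf physiology (and vice versa), simulate both, and read off
how much of the yield gap each trait class explains.

The package targets crop modellers and breeders working with
functional–structural plant models. It ships with profiles for the hybrid
JNK728 and its parents J2416 (male) and JMC01 (female).

## The model

**Plant geometry.** A plant is an ordered stack of phytomers. Each leaf is
described by field-measurable descriptors — midrib length `LL`, collar height
`HLBase`, heights of the midrib's highest point and tip (`HLTop`, `HLTip`),
horizontal projections collar→highest point (`Ltop`) and collar→tip (`Ltip`),
azimuth and maximum blade width. A two-segment quadratic Bézier midrib
satisfies the heights and projections exactly and the arc length `LL` by a
one-parameter bulge search; a ruled blade with a beta-shaped width profile is
triangulated around it. Plants are replicated onto a 10 × 15 grid (0.6 m
rows, 6 plants m⁻²) surrounded by an opaque "virtual wall" at 60 % of plant
height that mimics the optical closure of a larger field.

**Radiation.** Direct-beam and diffuse-sky PAR are intercepted facet by
facet at an hourly step, with exact ray-cast occlusion (leaves are black:
single interception, no scattering). A facet is *sunlit* when it faces the
beam and is unoccluded. The diffuse sky is a ring-structured set of
directional sectors (46 by default). Output records per plant, leaf rank and
hour: leaf area `LA` (cm²), intercepted photons `IPP` (µmol leaf⁻¹ h⁻¹) and
sunlit leaf area.

**Leaf photosynthesis** (Ye's model):

    A(Q) = α (1 − βQ) / (1 + γQ) · Q − Rd
    Amax = α ((√(β+γ) − √β) / γ)² − Rd

with initial slope α, photoinhibition β, saturation γ and dark respiration
Rd. `LightResponseModel(ppfd, a).fit()` returns a results object with
estimates, standard errors, R² and a `summary()` table.

**Canopy integration.** Per leaf and hour, `PPFD = IPP/3600/(LA·10⁻⁴)`;
leaf rates are area-weighted to the instantaneous canopy rate over the focal
ground area (9 central plants / plant density), summed over daylight to the
daily canopy assimilation, converted to biomass with 44 g mol⁻¹ CO₂ and a
CO₂→dry-mass efficiency of 0.41, and to intercepted energy with
4.55 µmol photons J⁻¹. Accumulating over a fixed 60-day post-silking window
gives yield (ADM, Mg ha⁻¹), accumulated interception (AIPAR, MJ m⁻²) and
RUE = ADM/AIPAR (g MJ⁻¹).

**Heterosis decomposition.** Seven scenarios — the three pure cultivars plus
A1/A2 (parent structure, hybrid physiology) and B1/B2 (hybrid structure,
parent physiology) — yield contribution percentages, e.g.

    Cc,J2416 = (Y_JNK728 − Y_A1) / (Y_JNK728 − Y_J2416) × 100

for canopy structure vs the male parent, and analogously for photosynthetic
capacity (B-scenarios) and the female parent.

## Worked example

The bundled reference scenario table carries post-silking yield (Mg ha⁻¹)
and RUE (g MJ⁻¹) for all seven scenarios. Running the decomposition:

```bash
phytocanopy scenarios contributions
```

prints

```
Heterosis decomposition (yield)
            structure  photosynth.  interaction
  vs J2416      69.9%        35.9%        -5.8%
  vs JMC01      41.8%        74.2%       -16.0%
  hybrid advantage vs J2416: 35.1%
  hybrid advantage vs JMC01: 27.2%
Heterosis decomposition (rue)
            structure  photosynth.  interaction
  vs J2416      21.3%        87.2%        -8.5%
  vs JMC01       5.2%       115.5%       -20.7%
  hybrid advantage vs J2416: 13.1%
  hybrid advantage vs JMC01: 16.6%
```

Reading: against the male parent the hybrid's yield advantage is mostly
structural (70 % vs 36 %), against the female parent mostly physiological
(42 % vs 74 %); the RUE advantage is dominated by leaf physiology against
both parents. The two shares need not sum to 100 % — the residual is the
structure × physiology interaction.

The same decomposition accepts your own simulated values
(`--yields my_scenarios.csv`), and `phytocanopy scenarios run --config
examples/config_reduced.yaml` produces such a table from a full 3D
simulation of synthetic canopies. `phytocanopy synth all --out <dir> --seed N`
writes the synthetic phytomer, A-Q and weather CSV families.

In Python:

```python
from phytocanopy.datasets import EXAMPLE_YIELDS
from phytocanopy.heterosis import contributions
print(contributions(EXAMPLE_YIELDS, metric="yield").summary())
```

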