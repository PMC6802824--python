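# Methods

This note documents the models implemented in `sslforward`, the
conventions and defaults they use, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Scattering models

All models return the backscattering cross-section σ_bs (m²) on a
frequency grid in kHz; target strength is TS = 10·log10(σ_bs). Zero
backscatter is an explicit sentinel value (−999 dB) that maps to exactly 0
in linear scale, so aggregation never manipulates −∞.

### Fluid-like bodies (DWBA)

Weak scatterers (density contrast g and sound-speed contrast h near 1) are
modelled with the distorted-wave Born approximation for a deformed finite
cylinder:

```
f_bs = (k₁/4) ∫ Γ a(s) · J₁(2k₂a(s)cosβ)/cosβ · exp(2i k₂ d̂·r(s)) ds
Γ    = (1 − gh²)/(gh²) − (g − 1)/g,     k₂ = k₁/h
```

integrated along the body axis r(s), where β is the angle between the
incident direction d̂ and the cross-sectional plane at s. Two shapes are
supported: a straight prolate spheroid (elliptical taper, used for
copepods) and a uniformly bent cylinder on an arc of radius ρ_c = 3L with
a taper profile a(s) = a₀√(1 − (2s/L)¹⁰) (shrimp-like bodies, bladderless
fish). Both ρ_c/L and the taper order are configurable; the defaults are
the values commonly used for euphausiid-like shapes in the DWBA
literature.

Orientation is the body tilt above the horizontal for a vertically looking
echosounder. σ_bs is averaged in linear scale over N(mean, SD) tilt using
Gauss–Legendre quadrature with 61 nodes on mean ± 3 SD, weighted by the
normal density — deterministic and reproducible, with no Monte-Carlo
noise. A zero SD collapses exactly to the single-angle evaluation.

Numerics: the axis integral uses composite Simpson with an odd node count
scaled to the maximum interior phase (≥ 10 nodes per radian of k₂L,
minimum 129); the J₁(x)/x singularity at end-on incidence is handled by
its analytic limit 1/2. The implementation agrees with an independently
coded adaptive-quadrature evaluation to better than 0.1 dB across the
tested parameter range, and reproduces the Rayleigh f⁴ law at ka ≤ 0.01
to a slope error below 2 %.

### Elastic shells (high-pass dense-fluid sphere)

Hard aragonite-shelled pteropods use the high-pass interpolation

```
σ_bs = a²(ka)⁴α² / (1 + 4(ka)⁴α²/R²)
```

with equivalent radius a from the silhouette-disc convention, empirical
reflection coefficient R (default 0.5) controlling the geometric plateau
σ_bs → a²R²/4, and the dense-fluid Rayleigh coefficient
α = (1 − gh²)/(3gh²) + (1 − g)/(1 + 2g) evaluated at aragonite-like shell
contrasts (defaults g = 2.62, h = 2.32; the acceptance-relevant behaviour
— the plateau and the (ka)⁴ rise — depends only on R). σ_bs is monotone
non-decreasing in frequency by construction.

### Gas-bearing organisms (damped resonant prolate spheroid)

The gas inclusion (pneumatophore or swimbladder) is a prolate spheroid
with semi-axes b = L/2 and a = b/(L/2a). The model combines three
ingredients:

1. **Minnaert resonance with tissue tension.** For the equal-volume
   sphere of radius r = (a²b)^{1/3},

   ```
   ω₀² = [3γ(P + 2τ/r) − 2τ/r] / (ρ r²)
   ```

   with ambient hydrostatic pressure P(z) = 101325·(1 + z/10) Pa, air
   (γ = 1.4) inside the inclusion, and surface tension τ representing the
   tissue interface. For sub-millimetre inclusions with τ of tens of
   N·m⁻¹ the tension term rivals the ambient pressure and raises the
   resonance substantially.

2. **Shape correction.** A pulsating non-spherical bubble of the same
   volume resonates at ω₀·√(C/r), with C the electrostatic capacitance of
   the shape (prolate spheroid: C = 2be/ln((1+e)/(1−e)), eccentricity
   e = √(1 − a²/b²)). The factor is 1 at aspect ratio 1 and ≈ 1.03 at
   L/2a = 2.35, so elongation shifts the peak only slightly.

3. **Damping.** The cross-section is the classical damped-resonance form

   ```
   σ_bs(f) = r² / [((f_R/f)² − 1)² + δ(f)²]
   δ(f) = k·r + 4η/(ρωr²) + (f_R/f)²·Im(Φ)/Re(Φ)
   ```

   radiation, tissue-viscosity and thermal terms respectively; Φ(f) is
   the Devin-style complex polytropic factor of heat conduction in the
   gas (isothermal limit 3 at low f, adiabatic 3γ at high f), evaluated
   with the ideal-gas density at the inside pressure and a default water
   temperature of 283.15 K. δ is floored at 10⁻¹² so a fully undamped
   scatterer at exact resonance stays finite.

The model is a Rayleigh-regime approximation valid for k·b < 0.1;
frequencies beyond that are still computed (the forward model uses
full-band predictions) but flagged in the spectrum's validity mask. The
printed validity condition "ka < kb < 0.1" is redundant in its first
inequality (a < b always), so k·b < 0.1 is the binding constraint.

At aspect ratio 1 the implementation collapses onto an independently coded
damped Minnaert sphere within 0.2 dB across 18–420 kHz, which bounds any
transcription ambiguity in the spheroid equations.

**Medium defaults.** c = 1500 m/s, ρ = 1026 kg/m³ (no hydrographic
profiles are bundled); both are configurable. The gas thermodynamic
constants (air: specific gas constant 287 J/(kg·K), k = 0.025 W/(m·K),
c_p = 1005 J/(kg·K)) are needed only by the small thermal-damping term.

## Forward model

Records are binned into 0.1 mm length classes (lower-edge inclusive) on an
absolute grid; density mass is conserved exactly. Each occupied bin is
evaluated at its midpoint length. The taxon spectrum and layer total
follow the natural-scale sums given in the README; per-taxon components
are retained so the contribution of each taxon can be attributed (the
linear fractions sum to 1 at every frequency).

Morphometric conventions:

* silhouette → radius: rectangle for cylinders (a = A/2L), ellipse for
  spheroids (a = 2A/πL), disc for shells (a = √(A/π)); an implied radius
  exceeding L/2 is returned but flagged with a warning;
* elastic-shell record lengths are shell diameters (equivalent radius
  L/2);
* gas-bearing record lengths are measured gas-inclusion lengths by
  default; records flagged as body lengths are converted by the
  swimbladder rule: body = prolate spheroid with minor axis L/6,
  swimbladder = 2.5 % of body volume with a species length-to-width ratio
  (C. linearis 1.63, C. acus 2.75, other fish 1.5).

The gas-model depth for a layer is the midpoint of the layer's sampled
depth range (surface 10–24 m → 17 m, deep 70–96 m → 83 m); the data do
not constrain the within-layer depth of individual scatterers any better.
Taxa flagged "excluded" (jellyfish, comb jellies, swimming crabs, and the
single surface swimbladdered fish) are carried through I/O but never enter
the sums. A configuration switch re-runs bladderless *Argentina
sphyranea* juveniles as gas-bearing with generic fish parameters, since
the timing of their swimbladder development is uncertain.

## Uncertainty analysis

Priors (normal or log-normal, per the published table) are sampled by
Latin-Hypercube: n equal probability strata per parameter, exactly one
uniform draw per stratum, strata paired across parameters by independent
seeded permutations. Quantiles of the priors are analytic (exact standard
normal quantile). Lengths are measured and never sampled; the fluid-like
orientation distribution already carries its spread inside the model and
is likewise not sampled.

Per length class, n = 1000 model evaluations produce pointwise 5/50/95 %
quantiles computed in the **linear** σ domain and then converted to dB —
the linear domain preserves the additivity of the aggregation sums, so
per-class envelope components can be combined. Community-level bands can
be formed either per class or after density-weighted aggregation of the
quantile curves; the two are not identical and outputs are labelled
accordingly.

## Echogram analysis

Cell spectra are standardized by the dB value of the mean over transducers
of the natural-scale band means (offset-invariant: a uniform dB shift
leaves the standardized spectrum unchanged; a spectrum constant across
bands maps to 0 dB). The 240–260 kHz noise interval is excluded from
analysis and the 280–420 kHz band, though kept in spectra, is excluded
from the clustering feature space because of its limited range.

Segmentation uses a Gaussian mixture with diagonal covariances over the
standardized feature spectra — at 2 kHz resolution the feature dimension
is large relative to typical cell counts, so full covariances are not
identifiable (an option retains them). Initialization is deterministic:
component means are the linear-scale mean spectra of k equal horizontal
depth bands (remainder bins join the deepest band), reflecting the
horizontally stratified structure of scattering layers; with no random
restarts, a fit is fully reproducible. Convergence: relative log-likelihood
tolerance 10⁻⁶, at most 500 iterations. A component left empty is
re-seeded at the cell farthest from its assigned centre and the fit is
repeated (logged).

The cluster count is chosen by minimizing BIC over a candidate range —
the quantitative proxy for "as few clusters as distinguishable spectrum
shapes". Cluster median spectra and their 25/75 % bands are computed per
frequency in the dB domain from the **raw** spectra (standardization is
used only for the feature space); a linear-domain option exists behind a
flag.

Measured layer spectra along a net track are the per-frequency medians
over the two echo-integration cells below the net headline at each track
point — the two depth bins whose tops lie at or below the headline depth,
with bins half-open [top, bottom). Comparisons report the per-frequency
difference, mean differences over named intervals, and
narrowband-equivalent points (18, 38, 70, 120, 200, 333 kHz, nearest grid
frequency).

## Synthetic data

The generator emulates the survey situation: vertically stratified layers
whose cells carry a forward-modelled community spectrum plus independent
normal noise in the dB domain, and community tables with the published
taxon/length/density structure (shipped verbatim as the surface and deep
presets, excluded taxa included but flagged). Lengths are drawn from
N(mean, SD) truncated at 0.05 mm; per-record densities partition the taxon
total exactly. Everything is reproducible bit-for-bit from a seed.

The default noise SD of 2 dB is a fixture choice giving quantile bands of
realistic width; it is **not** an estimate of instrument noise. The
generator does not emulate: spatial covariance of noise, within-layer
vertical gradients, avoidance or catchability bias of the nets, beam
geometry, or multiple scattering. Passing closed-loop tests therefore
demonstrates the internal consistency of the pipeline (model → echogram →
extraction → comparison), not the fidelity of any model to real organisms.

## Problem sizes used in tests

Closed-loop tests run 2- and 3-layer grids of 25 ping blocks with 40
records per taxon on a reduced frequency grid (the two CW channels plus
6–10 kHz steps across the FM bands); this keeps the deterministic DWBA
evaluations cheap while preserving every band's contribution to the
feature space. The acceptance script evaluates the gas model on the full
2-kHz grid (202 frequencies), which is instantaneous.

## Known limitations

* The gas model is used (flagged) outside its Rayleigh validity at high
  frequency; a gaseous-cylinder formulation would be more appropriate when
  gas-bearing scatterers dominate the whole spectrum.
* Exact modal-series solutions for spheres/spheroids, shell-elasticity
  models for pteropods, multiple scattering, near-field effects and
  beam-pattern weighting are out of scope.
* Biological sampling error (catchability, avoidance, destruction of
  fragile organisms) is not propagated; the uncertainty analysis covers
  model parameters only.
* Tissue viscosity and surface tension for pneumatophores are not
  measurable quantities in the literature; the defaults are interpolations
  between water and fish flesh and the priors around them are wide.
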