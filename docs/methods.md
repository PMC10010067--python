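# Methods

## Membrane model

The membrane is the mammalian Fohlmeister-type RGC description at 37.1 °C:
fast sodium (m³h), delayed-rectifier potassium (n⁴), calcium (c³),
calcium-activated potassium, and passive leak. The voltage-gated rate
constants are used exactly as printed in the source parameter set (they are
already temperature-adjusted; no further Q10 scaling is applied), with the
removable singularities of α_m (−35 mV), α_n (−37 mV) and α_c (−13 mV)
evaluated by their analytic limits. Nernst potentials are fixed at
E_Na = 61.02 mV, E_K = −102.3 mV, E_pas = −65.02 mV; E_Ca is recomputed
each step from the submembrane calcium pool via RT/2F · ln([Ca]_e/[Ca]_i).
The pool is 0.1 µm deep, pumped toward 10⁻⁷ M with a 1.5 ms time constant,
and fed by −3 I_Ca/(2Fr). The leading factor 3 is implemented exactly as
printed even though some earlier formulations of the same pump use a
different prefactor; a unit test pins the unit conversion (1 mA cm⁻² ↦
−1.5545×10⁻³ M ms⁻¹) against a hand calculation.

Extracellular calcium is not part of the published parameter set; the
default is 1.8 mM, a standard literature value, exposed in the config.

**The model is a pacemaker.** With the printed conductances the total ionic
current is inward at every subthreshold voltage (the leak reverses at
−65.02 mV and the sodium window current dominates above it), so an
unstimulated cell has no stable resting point: after initialization it
fires a spontaneous spike within ~5–15 ms, recovers, and eventually settles
into maintained firing. Maintained discharge is a documented property of
this RGC model family and of real ganglion cells. Consequently "rest" is
defined by protocol, not by a fixed point: the cell is initialized at
−65 mV with steady-state gating and calcium at the pump target, settled for
50 ms, and — because spontaneous spike timing depends on morphology — the
state is then advanced in 5 ms increments until the following 10 ms window
is free of spontaneous spikes. All stimuli are applied from that cached
quiescent state. The equilibrated voltage drifts by a few mV over a 10 ms
stimulus window (the slow pacemaker ramp); thresholds are reproducible
because the protocol is fixed.

## Geometry

Compartments are cylinders (frusta where tapered) in a rooted tree. The
axial path runs soma (20 µm long × 20 µm diameter, modeled as one
cylindrical section whose lateral area equals the equivalent sphere's) →
hillock (40 × 3 µm) → sodium channel band (40 µm, linear 3→0.8 µm taper) →
narrow segment (75 × 0.8 µm) → axon (3000 × 1 µm). The retinal surface is
z = 0 with tissue below; the axon ascends from the soma along a
quarter-ellipse with a vertical tangent at the soma vertex and a horizontal
tangent at the nerve-fiber-layer vertex (NFL depth 15 µm by default),
continuing horizontally in +x once the curve is exhausted. Regions are laid
out by arc length starting at the top of the soma; the soma itself extends
vertically below the ellipse vertex. In diameter sweeps the band's taper
connects the hillock and narrow-segment diameters so the regions always
join smoothly.

Dendrites attach at the deep end of the soma in one of three
representations: none; an equivalent cylinder (10 × 4 µm vertical stub plus
two 810 × 2 µm horizontal branches, matching the 11 560 µm² somatodendritic
area of the traced arbor it replaces); or a branched tree read from an SWC
file. When no tracing is supplied, a synthetic generator stands in: a
random planar binary-branching tree constrained to a 168 × 183 µm dendritic
field, carrying ~3 mm of total dendritic length at micron-scale tapering
diameters, rescaled so its lateral area matches the 10 304 µm² dendritic
target exactly. The length/diameter balance matters — the passive load an
arbor puts on the soma is set by its input conductance, not its area alone
— so the generator emulates a mid-peripheral parasol cell's length scale
rather than hitting the area with short fat cable. The generator does not
reproduce the asymmetry, stratification depth, or branch-order statistics
of real tracings; results that depend on fine dendritic structure (e.g.
map asymmetries near the arbor) should be read accordingly.

Discretization splits each section into equal compartments no longer than
its region's target length. Defaults are the optimized per-region values
(soma 4 µm; hillock/band/narrow/axon 5 µm; dendrites 10 µm), which
reproduce 1 µm-resolution thresholds to within the 0.1 µA bisection
tolerance; the operation is idempotent and preserves arc length, taper, and
surface area.

## Fields and stimuli

All sources are quasi-static: a unit-current potential vector is computed
once per electrode position and scaled by the instantaneous pulse current.
The analytic sources are the equipotential-disc solution on a semi-infinite
homogeneous medium (default 200 µm diameter, σ = 1 S m⁻¹, 50 µm above the
surface) and a point source (method of images); both place the return
electrode at infinity. Tabulated per-compartment potentials (one value per
line, with the source current declared in the header) can be substituted
for fields computed externally. The stimulus is a charge-balanced biphasic
pulse, cathodic phase first, 0.45 ms per phase, onset 1 ms, zero interphase
gap by default.

A homogeneous half-space is a deliberate simplification: layered retinal
conductivities (vitreous ≫ retina, anisotropic nerve-fiber layer) smooth
the potential along the NFL and steepen it with depth. See "Known
differences" below for what this changes.

## Cable solver

Axial conductances combine half-compartment resistances in series
(ρ = 136.6 Ω cm); membrane capacitance is 1 µF cm⁻² of lateral area.
The extracellular drive enters the axial current as g_jk(V_e,k − V_e,j),
mathematically equivalent to pinning a zero-impedance extracellular node to
the applied potential — a spatially uniform V_e provokes no response, which
a test asserts.

Time stepping is the staggered second-order implicit scheme of the classic
compartmental simulators: gating states advance by exponential
(Rush–Larsen) updates with rates frozen at the step-start voltage, living
on the half-step grid (the first step advances them dt/2); the voltage then
advances by a Crank–Nicolson step solved with one Hines tree-elimination
per step (O(N), numba-compiled). Calcium uses the exact exponential
solution of the pump equation with the influx frozen over the step. The
stimulus enters as its exact average over each step, so pulse edges carry
no charge bias at any dt. With the default dt = 5 µs, bisection thresholds
are identical to dt = 1 µs, and a single-compartment trace stays within
~0.5 mV of a stiff adaptive-solver reference under a robust suprathreshold
current step. Trace accuracy degrades near-threshold where spike latency is
intrinsically hypersensitive to any perturbation; threshold values are
unaffected (they are bisection brackets, not latencies).

Spikes are upward 0 mV crossings, linearly interpolated, merged within a
1 ms refractory window. Propagation is classified from soma, band, and
distal-axon recordings: `echo_spike` (band fires ≥2 with the later spike
reaching the distal axon) is tested before `soma_failure` (distal spike
without somatic invasion); `bidirectional` requires both soma and distal
axon to follow; anything without a distal spike is `no_spike`.

## Threshold search and studies

Activation threshold is the smallest amplitude eliciting a distal-axon
spike (somatic invasion can fail at small diameters without abolishing the
propagating response; the criterion compartment is configurable), found by
bisection to a 0.1 µA bracket, initial bracket 0–100 µA with doubling to
1600 µA. Electrode grids default to 1 × 1 mm at 50 µm steps (441 nodes);
the desk scale used in tests is 5 × 5 nodes over 500 × 500 µm, chosen so
the grid still resolves structure at the scale of the 200 µm disc.

The scripted studies compare dendrite representations (threshold maps),
sweep elliptical trajectory steepness across soma depths 35/55/75 µm
(reach = 1–8× the soma-to-NFL rise by default; the published ellipse
extents are not recoverable, so the sweep bounds are config), classify
propagation regimes across hillock (2–4 µm) and narrow-segment
(0.6–1.0 µm) diameters, verify discretization invariance, and evaluate the
AF/weighted-AF predictors over a soma-position grid with exponential
threshold–distance fits. The diameter study classifies the response at
1.25× threshold: at exactly threshold the initiating spike is the marginal
event by construction, so a small suprathreshold margin probes the
propagation regime rather than the bisection bracket. Compartment weights
for the weighted AF are the steady-state band depolarization per 1 nA
injected into each compartment of the passive cell; by reciprocity of the
symmetric passive system this is a single linear solve with injection at
the band. The weight readout is steady-state (the readout time is not part
of the published recipe); the band's central compartment anchors the
computation.

## Known differences from layered-field models

With the analytic half-space field, absolute thresholds are roughly 2–3×
higher than published values computed with a layered finite-element retina,
and — more importantly — the spatial structure differs: the homogeneous
field has strong gradients along the superficial axon, so at threshold the
spike initiates at the narrow-segment→axon junction for electrodes more
than ~50 µm from the soma, whereas layered/anisotropic NFL conductivities
suppress axonal activating-function peaks and make the sodium channel band
the universal initiation site. Consequences observed here and verified by
the test suite: the threshold-map minimum sits where the disc footprint
covers both the band and the junction (interpreting "above the band" as
disc-footprint coverage); the hillock-diameter endpoints (4 µm →
bidirectional, 2 µm → failure of somatic invasion) reproduce, but the
knife-edge echo regime at 3 µm appears at other diameter/amplitude
combinations instead; and a 0.6 µm narrow segment does not block
bidirectional propagation under this field, so the published
conductance-compensation effect has no substrate to act on. These are
field-model differences, not solver properties; importing a layered-field
potential table reinstates the published conditions to the extent the
table does.

## Numerical and design choices

- Units: mV, ms, µm, mS cm⁻², µF cm⁻², µA cm⁻² internally (µS/nA/nF for
  absolute quantities); predictor currents are reported in mA cm⁻².
- Bisection reports the upper (spiking) end of the final bracket; values
  quantize to ~0.098 µA steps from the 0–100 µA starting bracket.
- AF endpoints use one-sided three-point differences and are excluded from
  peak finding.
- Degenerate exponential fits (near-constant data) return R² ≈ 0 rather
  than raising.
- SWC import accepts the standard 7-column dialect, requires ≥2 samples and
  exactly one root, and treats the root sample as the attachment anchor;
  type codes are not otherwise interpreted.
- Every random choice (synthetic dendrites) flows from a single integer
  seed through `numpy.random.default_rng`; identical seeds give identical
  trees, files, and downstream results.

## Limitations

Epiretinal, direct activation only: no bipolar/amacrine network, no
electrode impedance or double-layer dynamics, no degeneration-induced
remodeling, no myelination, no non-planar axon trajectories, and no
finite-element tissue solver (fields are analytic or imported). Absolute
thresholds should be compared across conditions within this package, not
against devices.
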