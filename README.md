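# rgcstim

Multi-compartment cable modeling of extracellular retinal ganglion cell
(RGC) stimulation.

Epiretinal prostheses drive the surviving output neurons of a degenerated
retina — the retinal ganglion cells — with current pulses from disc
electrodes on the inner retinal surface. `rgcstim` is a library and
command-line tool for simulating that interaction: it builds mammalian RGC
geometries compartment by compartment (soma, axon hillock, sodium channel
band, narrow axon segment, distal axon, and optional dendritic arbors),
couples them to extracellular potential fields under the quasi-static
assumption, integrates Fohlmeister-type membrane dynamics with an implicit
staggered cable solver, finds activation thresholds by bisection, and
evaluates activating-function threshold predictors against the full cable
solution. It is aimed at neural-engineering researchers who want a
transparent, scriptable alternative to monolithic simulator setups for
studying how cell morphology and electrode placement shape activation.

## The model

Each compartment obeys the membrane equation

    C_m dV/dt + g_Na m^3 h (V - E_Na) + (g_K n^4 + g_KCa)(V - E_K)
        + g_Ca c^3 (V - E_Ca) + g_pas (V - E_pas) = I_axial

with Hodgkin–Huxley-style gating kinetics `dx/dt = -(α_x + β_x) x + α_x`
for x ∈ {m, h, n, c}, a ligand-gated Ca-activated K conductance
`g_KCa = ḡ (Ca/1µM)² / (1 + (Ca/1µM)²)`, a submembrane calcium pool driven
by `d[Ca]/dt = -3 I_Ca / (2 F r) - ([Ca] - 10⁻⁷ M)/1.5 ms`, and a dynamic
calcium Nernst potential. Channel densities vary by cell region; the sodium
channel band (SOCB) carries 3–5× the Na⁺ density of its neighbors and is
the natural spike-initiation site. Compartments are coupled through axial
conductances (ρ = 136.6 Ω cm, C_m = 1 µF cm⁻²), and an extracellular
stimulus enters through the axial terms as differences of the applied
potential `V_e` between neighboring compartments. For a disc electrode on a
homogeneous half-space the unit-current potential is the closed-form
equipotential-disc solution
`φ = I/(4σa) · (2/π) · arcsin(2a / (√((r−a)²+z²) + √((r+a)²+z²)))`;
tabulated fields from an external solver can be imported instead.

The activating function `AF = ∂²V_e/∂x²` along the fiber arc, a passive
one-time-step transmembrane-current proxy, and a weighted AF (AF values
scaled by each compartment's passive influence on the SOCB, summed over the
top-n compartments) are provided as reduced threshold predictors.

## Worked example

```python
import numpy as np
from rgcstim import (DiscElectrode, PulseWaveform, assemble, build_rgc,
                     equilibrate, find_threshold, simulate, classify_propagation)

cell = build_rgc(dendrite_mode="equivalent-cylinder")   # 799 compartments
system = assemble(cell)
equilibrate(system)

# 200 um disc electrode, 50 um above the retina, over the sodium channel band
result = find_threshold(system, DiscElectrode(), (50.0, 0.0, 50.0),
                        locate_initiation=True)
print(f"threshold {result.threshold:.2f} uA, "
      f"initiates in {result.initiation_region}")

ve = DiscElectrode(center=(50.0, 0.0, 50.0)).unit_potentials(cell.centers)
response = simulate(system, ve, PulseWaveform(result.threshold))
print(classify_propagation(response, cell, system))
```

prints

```
threshold 43.55 uA, initiates in narrow
bidirectional
```

i.e. a biphasic, cathodic-first, 0.45 ms/phase pulse of 43.55 µA elicits a
spike that starts in the narrow axon segment adjoining the sodium channel
band and propagates both back into the soma and down the axon. (Absolute
thresholds and the precise initiation site depend on the field model; a
layered finite-element tissue field gives lower thresholds and shifts
initiation into the sodium channel band itself — see `docs/methods.md`.)

The same operations are available from the shell:

```
rgcstim threshold --electrode 50,0,50 --dendrites equivalent-cylinder
rgcstim map --step 125 --extent 500 --out out/
rgcstim experiment trajectory --scale desk --out out/
rgcstim fixtures dendrite --area 10304 --seed 7 --out dendrite.swc
```

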