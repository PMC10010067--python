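# rgcstim default configuration (version 1)
# All physical defaults live here so every constant is overridable without
# code changes.  Units: um, ms, uA, mS/cm^2, S/m, M.

config_version = 1

[sections.soma]
length = 20.0
diameter = 20.0

[sections.hillock]
length = 40.0
diameter = 3.0

[sections.socb]
length = 40.0
proximal_diameter = 3.0   # tapers to the narrow-region diameter
distal_diameter = 0.8

[sections.narrow]
length = 75.0
diameter = 0.8

[sections.axon]
length = 3000.0
diameter = 1.0

[trajectory]
soma_depth = 35.0
nfl_depth = 15.0
horizontal_reach = 150.0

# per-region maximum conductances (mS/cm^2): gbar_na, gbar_k, gbar_ca, gbar_kca, gbar_pas
[channels.dendrite]
gbar_na = 60.0
gbar_k = 35.0
gbar_ca = 1.0
gbar_kca = 0.17
gbar_pas = 0.1

[channels.soma]
gbar_na = 60.0
gbar_k = 35.0
gbar_ca = 0.75
gbar_kca = 0.17
gbar_pas = 0.1

[channels.hillock]
gbar_na = 150.0
gbar_k = 90.0
gbar_ca = 0.75
gbar_kca = 0.17
gbar_pas = 0.1

[channels.socb]
gbar_na = 420.0
gbar_k = 250.0
gbar_ca = 0.75
gbar_kca = 0.11
gbar_pas = 0.1

[channels.narrow]
gbar_na = 150.0
gbar_k = 90.0
gbar_ca = 0.75
gbar_kca = 0.2
gbar_pas = 0.1

[channels.axon]
gbar_na = 100.0
gbar_k = 50.0
gbar_ca = 0.75
gbar_kca = 0.2
gbar_pas = 0.1

[membrane]
ca_e = 1.8e-3            # extracellular calcium (M); assumption, not printed

[discretization]
dendrite = 10.0          # optimized per-region section lengths (um)
soma = 4.0
hillock = 5.0
socb = 5.0
narrow = 5.0
axon = 5.0

[pulse]
phase_width = 0.45       # ms per phase, cathodic first
interphase_gap = 0.0
onset = 1.0

[electrode]
diameter = 200.0         # um disc
height = 50.0            # um above the retinal surface
sigma = 1.0              # S/m half-space conductivity

[solver]
dt = 0.005               # ms
duration = 10.0
equilibration = 50.0

[threshold]
tolerance = 0.1          # uA bisection convergence

[grid]
step = 50.0
extent_x = 1000.0
extent_y = 1000.0
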