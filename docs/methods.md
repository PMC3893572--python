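# Methods

## Model and assumptions

`lfpsim` predicts extracellular potentials around single neurons and
populations in two decoupled steps.

**Cable step.** The neuron is a branched passive cable discretized into N
compartments. Within a compartment the membrane potential is spatially
uniform; adjacent compartments exchange intracellular ohmic currents through
axial conductances g = 1/(R½(n) + R½(parent)), R½ = (Ra·Δs/2)/(πd²/4).
Membrane currents are a passive leak g_pas·(V − e_pas) plus optional
single-exponential conductance synapses g(t)·(V − e_rev) with
g(t) = w·Σ_spikes exp(−(t − t_s)/τ). Intracellular electrode currents
(step and sinusoidal clamps) enter the node equation but are *not*
transmembrane currents: they are recorded separately (I_inj) and excluded
from the forward-model source term, which makes electrode injection a
monopole configuration by construction.

The extracellular potential is assumed constant (zero) while solving the
cable equations, while the forward step assumes a finite-conductivity
medium; this standard inconsistency is what makes the scheme fast, and it is
accurate because the computed potentials (µV scale) are far too small to
perturb the membrane dynamics. Externally *imposed* potentials are
supported explicitly: `insert_v_ext` adds a per-compartment extracellular
potential so axial currents are driven by gradients of V + v_ext.

**Forward step.** The medium is an infinite, homogeneous, isotropic, ohmic
volume conductor with scalar conductivity σ (default 0.3 S/m, cortical gray
matter), under the quasistatic approximation; potentials reference zero at
infinity. Sources are compartment currents treated as point sources at
chord midpoints, line sources along chords (closed-form integral), or the
mixed soma-sphere method. The mixed method *requires* a single-compartment
root soma and raises otherwise, rather than silently misassigning the
sphere source. Flat circular contacts average the point field over m
uniform disc samples; the samples are drawn once per contact from a
dedicated seeded RNG stream (time-invariant contact geometry — the
alternative of redrawing per time step would only add Monte-Carlo noise).

## Numerical scheme

Time stepping is implicit on the branched tree: backward Euler by default
(first order, unconditionally stable, no ringing) or Crank–Nicolson
(second order) when accuracy of oscillatory responses matters. Each step
solves a symmetric positive-definite tree-structured system; chain
topologies use a banded Cholesky solve (O(N)), general trees a sparse LU
that is refactorized only when the diagonal (synaptic conductance) changes.
Default dt = 0.0625 ms (a power of two, exactly representable); default
v_init = −65 mV equals the default leak reversal, so an unstimulated cell
is exactly at rest. A negative `tstart` runs warm-up steps whose samples
are discarded; recordings always cover [0, tstop].

The recorded transmembrane current uses the discrete identity
I_mem = (axial inflow) + I_inj evaluated at the solved step. This is the
continuous-time Kirchhoff identity evaluated on the computed trajectory, so
it is accurate at the scheme's order and conserves current *exactly*: the
axial terms cancel pairwise, leaving Σ I_mem − Σ I_inj = 0 to float
rounding. Synaptic currents, when recorded, use the post-step voltage
(consistent with the same identity).

The three-case line-source evaluation (field point projecting before,
alongside, or beyond the segment) rewrites the single log expression with
conjugate factors so every branch subtracts only same-sign quantities;
perpendicular distance is clamped to the compartment radius per evaluation
point, including each disc sample of a surface average independently.
Zero-length segments (the spherical soma) fall back to point/sphere sources
with the distance clamped at the equivalent-sphere radius √(area/4π).

## Morphology and discretization

SWC is the single supported format (7 columns; radii doubled to diameters;
parents must precede children; exactly one root). Sections are maximal
unbranched same-type runs named by SWC type code (soma, axon, dend, apic,
with bracketed suffixes when repeated). A `.rot` sidecar (lines `x = <rad>`
…) supplies a default orientation applied about the soma center *before*
any user rotation; rotations are right-handed about the fixed x, then y,
then z axes.

Each section is split into nseg equal-arc-length compartments, nseg odd
from the d_lambda rule (spacing ≤ 0.1·λ_f at f = 100 Hz) unless overridden.
Chord endpoints interpolate the 3D path at arc-length breakpoints, so chord
length ≤ arc length for curved sections (refinement recovers the arc
monotonically). Electrical quantities preserve the cable: membrane area is
the frustum integral of the piecewise-linear diameter profile over the arc
span, axial resistance uses the arc length, and the compartment radius used
for clamping and line-source geometry is the arc-weighted mean diameter
over the span divided by two (the averaging within a compartment is not
uniquely determined by the reconstruction; the arc-weighted mean is the
simplest choice consistent with area preservation). A single-point soma
becomes one spherical compartment of area πd²; its nominal axial half
resistance is that of an L = d cylinder.

Global compartment indices follow a counter in a nested loop over sections
in declaration order, then within-section position, so the first
compartment of the first section is index 0 — the root-soma precondition of
the mixed method checks exactly this.

## Populations and input correlation

All cells share one pool of independent homogeneous Poisson trains
(rate r events/s over the simulation window) generated from a single pool
seed. Each cell selects n_select trains uniformly without replacement using
a per-cell stream `SeedSequence(master_seed, spawn_key=(cell_index,))`; the
same stream seeds area-weighted synapse placement on the configured
sections. "Input correlation" is operationalized as the Pearson correlation
between two cells' pooled spike counts in 5 ms bins (bin width
configurable); for shared Poisson inputs its expectation is
n_select/n_trains, so 100 of 1000 gives 0.1. The paperless constant here is
the bin width: 5 ms is of the order of the synaptic time constant and the
estimate is insensitive to it for homogeneous Poisson inputs.

Cells are simulated independently (no synaptic coupling — a stated
non-goal), each through the coefficient-matrix runtime path, and per-cell
potentials are summed in fixed cell-index order. Parallelism is a pure
execution detail via a process pool; results are bit-identical to the
serial path because every cell's computation is deterministic given the
master seed.

## The validation oracle and benchmark

`lfpsim.validation` solves the frequency-domain passive cable equation for
a finite stick with sealed ends under end-point sinusoidal current
injection: V(x) = (I₀ r_i/γ)·cosh(γ(L−x))/sinh(γL) with
γ = √(1 + iωτ_m)/λ. Sealed ends match a cable with no leak path at its
tips. The transmembrane current density (1 + iωτ_m)g_m V(x) integrates to
exactly I₀ (checked in the suite), and the extracellular amplitude is that
density integrated against the 1/(4πσr) kernel by composite Gauss–Legendre
quadrature with panel doubling until successive estimates change by
< 1e-9 mV. The module imports only numpy and the geometry constants of its
own spec — no cable/forward code — which a test enforces by inspecting its
import list.

The benchmark drives a 1000 μm × 2 μm stick (Ra = 150 Ω·cm, c_m = 1 μF/cm²,
g_pas = 1/30000 S/cm², hence τ_m = 30 ms and λ_DC = 1000 μm) with a 1 nA,
100 Hz sinusoid at one end, using Crank–Nicolson at dt = 1/64 ms with
nseg = 501, a 300 ms warm-up (10 τ_m) and a 50-cycle analysis window, and
extracts amplitudes by Fourier projection over the integer-cycle window
(exact for the discrete steady state). Discretization sizes come from an a
priori error budget: temporal (ω dt)²/12 ≈ 1e-5; spatial (Δx/λ_AC)²/12 with
λ_AC ≈ 230 μm at 100 Hz ≈ 4e-5; and the dominant term, the injection-site
offset — the clamp attaches to the compartment node Δx/2 = 1 μm from the
end while the oracle injects exactly at x = 0 — worth ~2e-4 at the nearest
(50 μm) evaluation point. The observed agreement is ~5 matching significant
digits across lateral points 50–500 μm from the stick, comfortably beyond
the 3-digit level the benchmark asserts.

## What the synthetic generators do and do not emulate

The built-in stick and ball-and-stick fixtures, the Poisson pool and the
disc placement helper reproduce the *structure* of the standard study
conditions (passive membranes, uncorrelated-source pools with controlled
overlap, laminar electrode geometries). They do not emulate reconstructed
dendritic branching, active conductances, synaptic bombardment statistics
beyond homogeneous Poisson, or tissue heterogeneity — so passing tests
demonstrate the correctness of the forward-modeling machinery, not the
realism of any particular predicted waveform. Reconstructed morphologies
can be supplied as SWC files and run through the identical pipeline.

## Known limitations

- Passive membranes only: no Hodgkin–Huxley-type channels, so extracellular
  *spike* waveforms of active models are out of scope.
- Scalar homogeneous σ: no anisotropy, layered media, slice/electrode
  interfaces (method of images), frequency-dependent conductivity, or FEM.
- No ephaptic feedback: computed fields do not act back on the membrane
  (imposed fields require `insert_v_ext` with user-supplied values).
- Single-exponential synapses only; double-exponential kinetics and
  event-driven network connectivity are not provided.
- The `tstart`/`tstop`/`dt` grid must be commensurate; recordings share the
  solver grid (no separate recording decimation).
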