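# lfpsim

Biophysical forward modeling of extracellular potentials around
morphologically detailed neurons.

Extracellular recordings — spikes and local field potentials (LFPs) — are
generated by transmembrane currents of nearby neurons. `lfpsim` implements
the standard two-step scheme for predicting these signals from first
principles:

1. **Cable step.** A morphology (SWC file or built-in synthetic fixture) is
   discretized into N compartments; each compartment n obeys Kirchhoff's
   current law for the membrane potential V_n,

       C_n dV_n/dt + Σ_j I_nj(V_n, t) = g_{n−1,n}(V_{n−1} − V_n) + g_{n,n+1}(V_{n+1} − V_n) + I_inj,n(t),

   with passive leak and conductance-based exponential synapses as membrane
   currents, solved implicitly (backward Euler or Crank–Nicolson) on the
   branched tree. The net transmembrane current I_n(t) of every compartment
   (outward positive, electrode injections excluded) is the source term of
   step two. Σ_n I_n(t) = 0 holds to machine precision unless an
   intracellular electrode injects current, in which case the imbalance is
   exactly the injected (monopole) current.

2. **Forward step.** The tissue is an infinite, homogeneous, isotropic,
   ohmic volume conductor with scalar conductivity σ. A current I at
   distance r contributes φ = I/(4πσr); summing over compartments gives the
   *point-source* approximation, integrating along each compartment's axis
   in closed form gives the *line-source* approximation,

       φ(r, t) = 1/(4πσ) Σ_n I_n(t)/Δs_n · log| (√(h_n² + ρ_n²) − h_n) / (√(l_n² + ρ_n²) − l_n) |,

   and a *mixed* method treats a single-compartment root soma as a sphere
   source with line sources elsewhere. Distances are clamped at the
   compartment radius, so potentials are finite everywhere. Finite
   electrode contacts are modeled by averaging over m random points on a
   flat disc. Because the map from currents to potentials is linear, a
   coefficient matrix **C** (n_contacts × N) is precomputed once and
   Φ(tᵢ) = C·I(tᵢ) is evaluated at runtime — no need to store the full
   current matrix (1000 compartments × 1 s × 20 kHz × 8 bytes = 160 MB).

Populations of independent cells share a pool of presynaptic Poisson spike
trains; each cell selects n_select of n_trains trains without replacement,
which sets the pairwise input correlation to n_select/n_trains (100 of 1000
→ 0.1). Contributions add linearly, and serial and process-parallel
execution are bit-identical under the same master seed.

Units: μm, ms, mV, nA, μS, nF; Ra in Ω·cm, c_m in μF/cm², g_pas in S/cm²,
σ in S/m. In this closure φ[mV] = I[nA]/(4π σ[S/m] r[μm]) with no
conversion factor.

## Worked example

A passive ball-and-stick cell receives one excitatory synapse near the
distal end of its 700 μm dendrite, firing once at t = 20 ms; two contacts
record at (−130, 0, 0) μm (near the soma) and (−220, 0, 700) μm (near the
synapse):

```yaml
# example.yaml
mode: single
morphology:
  fixture: ball_and_stick
  params: {soma_diameter: 20, stick_length: 700, stick_diameter: 2, n_points: 15}
stimuli:
  - {kind: synapse, section: dend, relpos: 0.9, weight: 0.005, spike_times: [20.0]}
sim: {tstop: 100, dt: 0.0625}
electrode:
  sigma: 0.3
  method: line_source
  contacts: [[-130, 0, 0], [-220, 0, 700]]
output: {path: out.h5, format: h5}
```

```text
$ lfpsim simulate example.yaml
lfpsim: single run: N=24, n_contacts=2, dt=0.0625, method=line_source, seed=0
mode: single
n_compartments: 24
n_contacts: 2
n_samples: 1601
output: out.h5
```

`out.h5` holds datasets `t` (ms) and `phi` (2 × 1601, mV). The trace near
the synapse dips negative (the synaptic sink pulls current out of the
extracellular space) while the trace near the soma goes positive (the
distributed return currents), the classic sink–source dipole pattern; for
this configuration the extrema are about −5.0·10⁻⁵ mV and +5.9·10⁻⁵ mV.

The same library surface is available from Python
(`lfpsim.simulate`, `lfpsim.lfp_line_source`,
`lfpsim.compute_coefficient_matrix`, `lfpsim.run_population`, …), and other
CLI subcommands cover populations (`lfpsim population`), coefficient-matrix
precomputation (`lfpsim coeffs`), fixture generation (`lfpsim fixture`), the
built-in validation benchmark (`lfpsim validate`) and storage bookkeeping
(`lfpsim estimate-storage`).

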