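# Methods

`wormsim` is a desk-scale neuromechanical simulation of *Caenorhabditis
elegans*: a particle-based soft-body physics engine drives a worm body with
95 body-wall muscles, a connectome-based neural layer supplies the muscle
commands, and a behavioral-validation layer quantifies the resulting
locomotion and decides whether two populations of tracks are statistically
distinguishable. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not establish.

## Fluid and soft-body physics

The engine is predictive–corrective incompressible SPH (PCISPH). Particle
quantities are interpolated with compact-support kernels of radius `h`:
poly6 for density, the spiky gradient for pressure forces, and the standard
viscosity Laplacian, each with dimension-specific normalization so the
density kernel integrates to one in 2D and 3D. The default configuration is
2D (a top-down view of a crawling worm); every operator is
dimension-generic.

Density is the usual summation over neighbors, including the particle's own
contribution and frozen BOUNDARY particles, so fluid resting against a wall
sees a filled neighborhood. Non-pressure forces are gravity, a
pairwise-antisymmetric viscosity term

    F_ij = mu * m_i * m_j * (v_j - v_i) * lapW(r_ij) / (rho_i * rho_j),

linear-strain springs `F = k (L - r0) / r0` (stiffness `k` in newtons at
100% strain; no damping term — viscosity provides dissipation), and a
cohesion-style surface tension `F_i = -kappa * sum_j m_j W(r_ij) (x_i - x_j)`
between liquid pairs. Every internal pairwise force is constructed
antisymmetrically, so internal momentum is conserved to rounding — the test
suite verifies net internal force below 1e-8 relative and momentum drift
below 1e-8 over 100 steps.

Incompressibility is enforced iteratively: positions are predicted from the
accumulated forces, densities re-estimated, and pressures incremented by
`delta * (rho_pred - rho0)` with the stiffness `delta` precomputed once
from a prototype particle with a filled regular-lattice neighborhood. The
increment is under-relaxed by 0.5: on deficient neighborhoods (free
surfaces, walls) the prototype stiffness overshoots, which otherwise
sustains a pressure oscillation that pumps energy into splashes. The loop
runs at least 3 and at most 7 iterations and stops when the maximum
relative compression falls below `eta = 0.01`; rarefaction at free surfaces
is not counted as error, as is conventional. Negative pressures are clamped
to zero. Boundary handling combines three mechanisms: frozen BOUNDARY
particles contribute to density and receive mirrored pressures, analytic
box walls project penetrating particles back and remove their normal
velocity (inelastic contact), and the worm's membrane is additionally
protected by segment-crossing detection (below).

Integration is semi-implicit (symplectic) Euler with a CFL-style advisory
cap `dt <= 0.25 h / v_max`; exceeding it raises a warning, NaN state is
fatal and names the first offending particle. Two further explicit-scheme
limits matter in practice and drove the default parameters: the viscous
diffusion limit `dt < s^2 rho / (4 mu)` (s = particle spacing) and the
spring frequency limit `omega dt < ~0.3`. Neighbor search is a uniform grid
with cell size `h`, vectorized via sorted linearized cell keys; an O(N^2)
brute-force oracle is kept in the test suite and must return identical
neighbor sets.

The dam-break fixture used to stress the pressure solver is a centimeter
scale column (spacing 2 mm) in the laminar regime (mu = 0.5 Pa s, Reynolds
~ 10): a millimeter-scale gravity collapse of a low-viscosity fluid is not
resolvable at a desk-scale explicit timestep, and the incompressibility
property being tested is independent of the Reynolds number.

## The worm body

The body is a hydrostatic skeleton: a closed capsule-shaped loop of ELASTIC
shell particles (default 1 mm long, 10:1 aspect ratio, 20 um spacing)
enclosing a lattice of LIQUID particles whose mass is raised 5% above the
ambient rest mass, so the interior is pressurized and keeps the shell
inflated. Shell springs come in three families: structural springs along
the outline, cross "ribs" pairing opposite dorsal/ventral particles, and
diagonals for shear stiffness. Particle spacing must not exceed a quarter
of the body width, or construction is refused — a coarser shell would be
impermeable in name only.

The 95 body-wall muscles follow the anatomical arrangement: four
longitudinal rows with 24 (dorsal left), 24 (dorsal right), 23 (ventral
left) and 24 (ventral right) muscles, anterior to posterior. In 2D the two
dorsal rows act on the dorsal edge springs and the two ventral rows on the
ventral edge; each edge spring is therefore co-owned by one left-row and
one right-row muscle and the rest-length factors multiply. Activation
`a` in [0, 1] contracts a muscle by scaling its spring rest lengths to
`r0 (1 - c_max a)` with `c_max = 0.3`; scaling always starts from the
original rest lengths, so re-applying the same activation vector is
idempotent.

The midline (49 points, head first, the worm-tracker convention) is the
arc-length resampling of the dorsal/ventral midpoint chain plus the head
and tail tip particles; positive bend angles are dorsal. A self-intersecting
shell makes the midline undefined and raises. Interior particles are kept
inside by a per-step segment-crossing test against the membrane: a particle
whose step crossed a membrane segment is reflected across it and loses its
normal velocity.

## Neural dynamics

The connectome is a directed multigraph of named neurons with typed
synapses, loadable from a CSV edge list (`pre,post,kind,weight,polarity`,
duplicates aggregated by summing weight) or a restricted NeuroML subset
(populations plus `projection` / `continuousProjection` /
`electricalProjection` connection lists; unsupported elements are skipped
and counted). Electrical synapses are stored once per unordered pair and
applied symmetrically. Neurons and synapses are canonically sorted by name,
which makes simulated trajectories exactly invariant to the ordering of the
wiring data.

Two membrane models can be swapped with a single config switch:

* **LI** — leaky integrator, `tau dV/dt = -(V - V_rest) + R (I_ext +
  I_syn)`, advanced by the exact exponential update (defaults tau = 10 ms,
  R = 0.1 GOhm, V_rest = -65 mV; units mV/ms/nS/pA so conductance times
  voltage is directly a current).
* **HH** — classic single-compartment Hodgkin–Huxley with squid-axon
  conductances, integrated with RK4 at dt <= 0.05 ms (stiffness cap);
  network currents in pA are converted to densities through a configurable
  membrane area (default 5e-6 cm^2). The suite checks RK4 at dt = 0.01 ms
  against an adaptive high-accuracy integration of the same equations
  (RMS < 0.5 mV over a 100 ms step-current protocol).

Chemical synapses are graded — transmitter release varies continuously with
presynaptic voltage, the dominant mode in *C. elegans*: `ds/dt =
(s_inf(V_pre) - s) / tau_s` with sigmoid `s_inf` (half-activation -35 mV,
slope 5 mV, tau_s = 10 ms), current `w g_syn s (E_rev - V_post)` with
E_rev = 0 mV (excitatory) or -70 mV (inhibitory). Wiring data rarely
records polarity, so the default is excitatory with an override table. Gap
junctions are ohmic and antisymmetric, so their summed current is exactly
zero network-wide. The network update is synchronous with synaptic currents
lagged one step: deterministic and independent of neuron order.

## Neuro-muscular coupling

The physics clock is the master (its timestep is the stability bottleneck).
Every `exchange_every` physics steps the neural model is sub-stepped to
fill the exchange window, motor-neuron voltages are mapped to muscle
activations by a clipped linear ramp between `v_lo = -50 mV` and
`v_hi = -20 mV` (muscles with no mapped motor neuron stay at zero), and the
activations are held constant until the next exchange. A scripted
central-pattern-generator surrogate (rectified traveling sine, dorsal and
ventral rows in antiphase, default 2 Hz — the swim frequency of the real
animal — and wavelength 0.8 body lengths) can replace the connectome for
physics-only studies.

The default environment is a resistive medium, the standard abstraction of
a crawling/swimming substrate in undulatory-locomotion models: shell
particles feel anisotropic drag with the normal coefficient five times the
tangential one (8e-5 vs 1.6e-5 N s/m per particle), which is what converts
undulation into thrust. The drag is applied as an exact exponential decay
of the tangential/normal velocity components each step — unconditionally
stable, so realistic substrate coefficients do not constrain the timestep.
A full SPH liquid bath remains possible by adding LIQUID blocks to the
scene, at a corresponding particle-count cost. With the defaults, the 5 s
reference run (50,000 physics steps, 298 particles) produces a traveling
wave at the driver frequency and a net displacement of several percent of a
body length; it completes in roughly two minutes on one CPU.

Runs are bitwise reproducible: identical config and seed give identical
HDF5 payload hashes (dataset contents are hashed, not container bytes).

## Behavioral validation and the imitation game

Features per track: centroid speed (mean, SD), signed bend angles between
successive midline segments (mean absolute, SD), reversal rate (sign flips
of the centroid velocity projected on the head–tail axis, with a hysteresis
of 2% body length per second and a 0.5 s minimum hold), omega-turn rate
(head-to-tail distance below 0.25 of the arc length for at least 3 frames,
events merged within 1 s), and the dominant undulation wavelength (peak of
the time-averaged spatial power spectrum of the bend profile, Hann-windowed
and zero-padded for peak localization, reported as a fraction of body
length). All features are invariant to global rotation and translation.
The thresholds are configurable defaults: the behavioral literature names
these features but no universal definitions.

The imitation game asks whether an "expert" can reliably tell simulated
tracks from real ones using objective measurables. The expert surrogate is
deliberately simple: features are z-scored on the pooled data and a
nearest-centroid linear rule is scored by leave-one-out accuracy;
significance comes from shuffling group labels (default 500 permutations)
with `p = (1 + #{null >= observed}) / (1 + n_perm)`. Groups below 10 tracks
are refused as underpowered. Because LOO accuracy is discrete, permutations
tie frequently and the raw p-value is conservative (measured null rejection
0.017–0.03 at alpha = 0.05); ties are therefore ordered by the classifier's
mean margin, scaled well below one accuracy increment so distinct
accuracies are never reordered. With the tiebreak, the measured null
rejection rate is ~0.05 and the null p-value distribution is uniform to KS
< 0.06. Any scoring rule with the same signature can replace the default
discriminator. The verdict is DISTINGUISHABLE exactly when p < alpha
(default 0.05 — a chosen operating point, not a claim about what "reliably
distinguish" must mean).

## Synthetic data: what it does and does not show

The fixtures module generates every input the tests need: toy layered
connectomes with muscle-target metadata, analytic traveling-wave midline
tracks (with the per-frame mean of the transverse coordinate removed so the
centroid moves exactly at the nominal speed), constructed reversal and
curl (omega) tracks, wave populations with animal-to-animal parameter
spread, fluid scenes, and the CPG driver. Each generator draws from a
counter-based stream namespaced by fixture kind, so outputs are
reproducible bytes and adding fixtures never perturbs existing ones.

These fixtures establish that the estimators recover known kinematics and
that the statistical machinery is calibrated under a known null. They do
not emulate real behavioral-database statistics: real tracks have
tracker noise correlated in time and space, posture distributions far
richer than a single traveling mode, and behavioral state switching.
Passing these tests therefore validates the machinery, not any claim that
the simulated worm is behaviorally indistinguishable from a real one.

## Known limitations

* 2D default: the four muscle rows collapse pairwise onto two edges;
  three-dimensional postures (rolls, deep omega turns) are out of reach.
* The membrane is impermeable to interior particles but the shell can, at
  extreme distortion, self-intersect; midline extraction then refuses.
* Explicit viscosity bounds the usable `mu` at a given timestep; strongly
  viscous regimes need smaller steps rather than implicit coupling.
* No neuromodulation, no learning, no sensory transduction models: inputs
  are injected currents.
* The real 302-neuron wiring file is an optional external input; shipped
  tests run on generated fixtures only.
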