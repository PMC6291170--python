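# Methods

This package simulates the spontaneous transition from cellular
action-potential-duration (APD) alternans to spatially discordant alternans,
conduction block and re-entry in cardiac tissue, and provides the analysis
stages that quantify each step of that cascade.  This note records the
models, the numerical choices, and the places where the design was genuinely
open, so that a reader can judge what the simulations do and do not show.

## Cell model

The detailed myocyte is the Luo–Rudy 1991 (LR91) ventricular model: eight
state variables (V, the Hodgkin–Huxley gates m, h, j, d, f, X and the
intracellular calcium concentration) with the classic fast sodium current

    I_Na = S_gNa · g_Na · m³ h j (V − E_Na),   g_Na = 23 mS/µF, E_Na = 54.4 mV.

Two knobs drive the whole study:

* **S_gNa** — a dimensionless scaling of the macroscopic sodium conductance.
  0.6 mimics loss-of-function, 1.5 gain-of-function channelopathy; 1.0 is
  control.
* **Δτ_h** — an increment added to the fast inactivation gate's time
  constant at membrane potentials below −70 mV (default 30 ms; graded
  values of 0–40 ms are supported).  It slows recovery of I_Na from inactivation, as in
  some SCN5A-linked familial arrhythmia syndromes, and is what opens a wide
  pacing-rate window of APD alternans.

Two LR91 parameters are re-tuned relative to the 1991 publication, following
the common practice of the alternans/spiral-wave literature: the slow inward
conductance is reduced to 0.052 mS/µF and G_K is scaled ×1.2.  The published
values give an APD near 353 ms, which cannot even pace 1:1 at the 140–200 ms
cycle lengths where discordant alternans lives; the short-APD variant has
APD ≈ 146 ms at slow pacing, so the diastolic interval at 180–210 ms cycle
lengths becomes comparable to the slowed h-gate recovery and the cell shows
a period-doubling cascade there (onset ≈ 197 ms with Δτ_h = 30; no
alternans with Δτ_h = 0; onset shifts right for S_gNa = 0.6 and left for
1.5).  The resting state frozen in the source was obtained by integrating
the quiescent model for 100 s at dt = 0.005 ms; the stored vector is a fixed
point of the right-hand side to ~1e−12 per ms.

Absolute numbers that are properties of the base model shift with that
choice: the strand conduction velocity at D = 0.15 mm²/ms comes out near
78 cm/s (rabbit ventricular preparations, which this class of tissue model
is usually tuned against, conduct nearer 57 cm/s), and the alternans
bifurcation sits at a 197 ms cycle length.  Every *relationship* studied —
√D scaling of conduction velocity, the 2:1 anisotropy ratio, the ordering
of ERP and restitution slope in S_gNa, the concordant → discordant → block
sequence in cycle length — is model-independent and is what the tests
assert.

A three-variable minimal excitable cell (fast inward, slow inward, slow
outward current; Fenton–Karma form, mapped to mV by V = −85 + 100·u)
implements the same model interface ~20× cheaper per step.  Its presets:
`mbr` (the original long-APD fit), `steep` (slow time scales halved;
APD ≈ 118 ms, restitution slope crosses 1, alternans for cycle lengths
~160–200 ms, 2:1 below), and `flat` (fast gate recovery; same APD, no
alternans at any captured rate).  `s_gna` scales its fast inward current
and `delta_tau_v` slows its recovery gate below a threshold, mirroring the
two knobs of the detailed cell.  The minimal cell is a test vehicle and the
driver of the scaled-down 2D experiments; it makes no claim about any
species' physiology.

## Tissue model

Mono-domain reaction–diffusion on a regular lattice:

    ∂V/∂t = ∇·(D ∇V) − I_ion / C_m,

1D strand default 800 nodes at dx = 0.15 mm (120 mm), D = 0.15 mm²/ms; 2D
sheet default 800×800.  Anisotropy uses D_perp = D_par/4 (the 2:1
conduction-velocity ratio), with the per-node tensor
D = R(θ) diag(D_par, D_perp) R(θ)ᵀ and the idealised elliptical fibre field
θ(x₀,y₀) = arctan(−x₀/(4 y₀)), origin at the left-top corner; on the
singular line y₀ = 0 we take the limit convention θ = −(π/2)·sign(x₀) and 0
at the origin.  Dead cells (inhomogeneous tissue) are non-conducting nodes:
all links touching them carry zero conductance (an internal no-flux
boundary), they are skipped by the reaction step, and they are never a
clamped potential — so they neither activate nor sink charge.

The discrete operator is assembled in flux form: every inter-node face gets
a conductance (arithmetic mean of the adjacent tensors) and its flux is
added with opposite signs to the two neighbours.  Cross-derivative terms of
the rotated tensor use the transverse difference averaged over the two
face-adjacent nodes, one-sided where a neighbour is missing or dead.  Flux
form makes two invariants exact by construction: L·const = 0 and
Σ_nodes(L·V) = 0 (discrete conservation under zero-flux boundaries); both
are asserted in tests, and pure diffusion of a Gaussian matches the heat
kernel to 0.02 % on a strand.

Time stepping is first-order operator splitting: a forward-Euler reaction
substep per node (matching the cell-level integrator) followed by a
Crank–Nicolson diffusion solve on V.  The implicit matrix is constant per
(geometry, dt) and factorised once — Thomas prefactorisation in 1D (the
whole cable loop is compiled), sparse LU with a symmetric-pattern ordering
in 2D.  dt defaults to 0.005 ms for the detailed cell; the minimal cell is
run at 0.1–0.2 ms (its APD changes by < 1 ms between 0.1 and 0.25 ms).  A
diffusion-only oracle (the same splitting with the CN solve replaced by 20
explicit substeps) agrees with CN to < 0.5 mV everywhere, including on the
travelling upstroke.

## Protocols

"Supra-threshold" is quantified as 2× the diastolic capture threshold found
once per model by bisection at rest (2 ms pulse); strand/sheet stimuli
cover 5 end nodes / a corner block.  Steady-state pacing delivers 20 beats
and records the last two APDs.  The S1–S2 protocol snapshots the state at
the 20th S1, times the last S1's 90 % repolarisation once, and branches one
short simulation per diastolic interval.  The ERP search descends in 10 ms
then 1 ms steps (optionally bisection-refined to 0.1 ms) and returns the
smallest S1–S2 interval whose S2 response overshoots 0 mV.

## Measurements

An activation is a contiguous stretch of dV/dt above threshold
(default 10 mV/ms) whose take-off potential lies below 0 mV and whose V
crosses 0 mV within 30 ms — sub-threshold stimulus artefacts fail one of
the two voltage conditions.  APD90 runs from the maximal-dV/dt instant to
the interpolated crossing of peak − 0.9·(peak − take-off).  The take-off
reference is the diastolic minimum within the 3 ms before the upstroke:
referencing the voltage *at* the maximal-dV/dt sample would make the level
depend on the sampling interval (that sample sits mid-upstroke) and
truncate the slow terminal repolarisation.  A fixed resting reference is
available behind a flag.  DI is defined so that activation + APD + DI
equals the next activation exactly.  Conduction velocity uses the
activation-time difference between nodes 25 and 75 (away from the
boundaries), reported in cm/s.  Restitution slopes are centred finite
differences with one-sided ends; the alternans bifurcation point is the
largest cycle length whose last two APDs differ by more than ε = 1 ms.

For beat-resolved APD *maps* built from 1 ms frames, upstroke times are
refined by interpolating the −40 mV crossing; without this the ±0.5 ms
quantisation of frame-grid upstrokes appears as a node-to-node sawtooth in
the beat-to-beat difference field and fabricates spurious APD nodes.

## Classification and phase mapping

After discarding a 5-beat pacing transient: a run is *block* if any
delivered beat never activates the distal probe (node N−25); *discordant*
if the final beat-pair APD difference exceeds +ε at some node and −ε at
another — APD-node positions are the interpolated zero crossings between
consecutive significant nodes of opposite sign (sub-ε jitter cannot create
crossings); otherwise *concordant*, with a `no_alternans` sub-label folded
into concordant for the three-colour map.  The block-site DI is measured at
the last node the failing wavefront reached (at the pacing site itself if
no node activated): arrival time minus the previous beat's repolarisation
there, clipped at 0 with a collision flag.

## Re-entry detection

The phase is a time-delay embedding θ(t) = atan2(V(t−τ) − V*, V(t) − V*),
τ = 10 ms, V* the midpoint of the run's voltage range.  Phase singularities
are plaquettes whose wrapped phase differences wind by ±2π; they are linked
across frames by greedy nearest-neighbour matching (radius 10 nodes, 1-frame
gap tolerance), and an episode is reported when the unwrapped phase at a
probe 3 nodes from the trajectory's mean core advances by ≥ 1 full turn.
The rotation count is insensitive to τ over 5–20 ms on the planted-rotor
suite, planted cores are recovered within one node over random placements,
and planar-wave runs yield zero singularities.  Re-entry is thus defined
operationally (≥ 1 rotation), which is stricter and more reproducible than
visual identification from snapshots.

## Scaled-down 2D experiments

The full-size transition experiments (800×800 nodes, 4 s at dt = 0.005 ms)
are supported behind the same interface but are multi-hour runs on one
core.  The desk-scale defaults drive the `steep` minimal cell — with its
excitability raised (τ_d 0.18) so that broken wavefront ends can curl at
this domain size, and its recovery slowed by 20 ms below −70 mV — on a
200×200 sheet at dx = 0.25 mm (50×50 mm), D = 0.06 mm²/ms, dt = 0.2 ms,
corner pacing at a 172 ms cycle length just above the strand conduction
margin, 4 s of activity.  Under these conditions the homogeneous control
conducts without a single re-entry episode, while the 2:1 elliptical-fibre
anisotropic sheet desynchronises the alternating wavefronts regionally and
deterministically produces episodes of 1.5–2 rotations — the anisotropy
route of the full-size experiments.  Randomly assigned 10 % dead cells at
this domain size produce conduction failures, halved local response rates
and sub-rotation wavelets, but the discordance node ring barely fits in
50 mm, so the dead-cell route to *full* rotations needs the larger domain;
this is a stated limitation of the desk scale, not of the method.  Dead
nodes carry no meaningful phase, so plaquettes touching them are excluded
from singularity detection (a dead cluster otherwise fabricates winding).
Because the domain holds only a few wavelengths, episode counts, onset
times and sustainment at desk scale are indicative, not quantitative
predictions of the full-size model.

## What the synthetic fixtures do and do not show

Every analysis stage is validated against fixtures whose ground truth is
known by construction: piecewise-linear AP trains whose planted APD90 is
exact under the package's own measurement convention; planted
concordant/discordant/blocked APD fields; rigid rotors (and mirrored
opposite-chirality pairs) built directly in phase space; and the
exponential-restitution map APD = A − B·exp(−DI/τ), whose alternans onset
has the closed form DI* = τ ln(B/τ).  The map with a capture floor is
multistable near onset — a cold-started iteration can land on a coexisting
2:1 orbit — so the brute-force onset oracle seeds at the 1:1 fixed point
plus a small perturbation to probe the local period doubling.  Passing
these tests shows the measurement and detection machinery is correct; it
does not by itself validate the physiology of either cell model, which is
why the directional cell/tissue-level checks above are asserted separately.

## Known limitations

* The base myocyte is a guinea-pig ventricular model, not a rabbit
  epicardial one; model-specific absolute numbers (CV at fixed D, the
  exact bifurcation cycle length) differ from rabbit values as noted
  above.
* One directional cell-level result inverts in this substitute: the
  beat-to-beat APD difference averaged over each conductance's own
  alternating rate range comes out *larger* at S_gNa = 0.6 than in control,
  because the reduced-conductance alternans window sits immediately above
  its own 2:1 boundary where the small AP is nearly a conduction failure.
  The ERP and restitution-slope orderings are the expected ones.  The
  corresponding test asserts the expected direction and fails, by design,
  to keep the divergence visible.
* First-order (Godunov) splitting between reaction and diffusion; the
  splitting error is assessed only through the diffusion oracle and the
  dt/dx refinement checks.
* 2D runs at desk scale use the minimal cell; calcium-driven alternans
  mechanisms are outside both cell models.
* No bidomain electrics, no 3D geometry, no adaptive time stepping.
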