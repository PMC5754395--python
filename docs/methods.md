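# Methods

`emgface` reconstructs, at reduced scale, a complete experiment in
EMG-driven forward biomechanics of the perioral region: surface-EMG
(sEMG) recordings of seven facial muscles are turned into normalised
muscle activation patterns, those patterns drive a finite-element lip
model, and the simulated lip-marker motion is compared against measured
(here: synthetic reference) motion with 3-D correlation coefficients.
This note documents the model, its assumptions, every parameter that
matters, and what the synthetic data do and do not establish.

## Signal chain

**Band-pass.** Raw bipolar sEMG (14 channels, default 2048 Hz, mV) is
filtered with a fourth-order Butterworth band-pass, 15–500 Hz. The
filter is applied forward–backward (`sosfiltfilt`), which squares the
magnitude response and cancels the group delay; zero phase matters
because feature frames are later aligned with marker frames. The
quoted "order 4" therefore describes the designed filter, while the
effective magnitude roll-off is order 8.

**Willison amplitude (WAMP).** For each channel, a sliding window of
200 ms (N = round(0.2·fs) samples, 410 at 2048 Hz) hops one sample at a
time ("maximum overlap"); the feature is the count of successive-sample
absolute differences ≥ s_lim within the window. Default threshold
s_lim = 10 mV. Frames are stamped at the window centre. WAMP is
invariant to constant offsets and equivariant under joint scaling of
signal and threshold; both properties are tested.

**Normalisation.** Per channel and per (instruction, repetition)
segment, the feature trace is min–max normalised onto [0, 1]. A
constant trace (e.g. a truly silent channel) maps to zeros rather than
dividing by zero. Note the flip side, which the strategy comparison
exploits: a channel that carries only leaked cross-talk is *not*
constant and is stretched to full scale — normalisation destroys
absolute amplitude information across channels.

**Measured-to-model composition.** The model has ten muscle groups per
side; only seven can be measured. The unmeasured groups are composed
linearly from neighbouring measurements — OOP = 0.5(OOS + OOI),
OOM = 0.1(OOP + OOI), BUC = 0.5(RIS + ZYG), LAO = 0.75·LLSAN,
DLI = 0.75·DAO — and MEN, ZYG, RIS, DAO, LLSAN pass through. (A
commonly quoted rule of thumb makes the marginal orbicularis one fifth
of the peripheral; the equation actually implemented is the
0.1(OOP + OOI) form, which coincides with one fifth of OOP only when
OOI = OOP.) Outputs are clipped to [0, 1].

**Strategies.** `act_all` drives all 20 channels. `act_3` selects the
three muscles with the largest time-variance of the bilaterally
averaged feature and drives them with each side's own (unaveraged)
trace — averaging is used for selection only, since nothing suggests
the activation itself should be symmetrised. Variance ties break on
the canonical muscle order (OOP, OOM, BUC, LAO, DLI, MEN, ZYG, RIS,
DAO, LLSAN). `act_rel` keeps a fixed per-instruction relevant-muscle
table (see `emgface.muscles.RELEVANT_MUSCLES`), passing the normalised
features through unchanged (no re-normalisation within the subset).

## Lip model

**Geometry.** Two curved slabs (upper/lower lip), each an annular
sector of trilinear hexahedra: by default 16 elements along the arc, 4
vertically, 3 radially (384 elements, 680 nodes in total), inner radius
30 mm, thickness 7.5 mm, arc 120°, lip height 10 mm, initial gap 2 mm.
Three radial layers are labelled inner/centre/outer; the innermost node
shell is fixed (attachment to mandible/maxilla, treated as rigid).
This deliberately replaces the full generic face model (thousands of
hexes and wedges, jaw geometry, lip–lip collision handling) with a
structured mesh a laptop can integrate; the lips start separated and
interpenetration is not checked. Ten marker nodes sit on the outer
surface: mouth corners and the cupid-bow pair plus philtrum on the
upper lip, five points along the free edge of the lower lip.

**Ground matrix.** Two-term Mooney–Rivlin on the distortional first
invariant with a logarithmic volumetric term,
W = C10(Ĩ₁−3) + C20(Ĩ₁−3)² + (κ/2)(ln J)², with C10 = 2.5 kPa,
C20 = 1.175 kPa, κ = 25 kPa, tissue density 1040 kg/m³, gravity
9.8 m/s² in −y. The distortional split is the standard
F̃ = J^(−1/3)F. Soft incompressibility adds a quadratic bulk penalty
(k_b/2)(J−1)² with k_b = 25 kPa, evaluated at the quadrature points
(an element-level approximation of nodal-averaged pressure coupling).
All layers share the same passive properties.

**Muscles.** Each of the 20 muscle groups is a fibre polyline; every
element whose centroid lies within 5 mm of the polyline becomes a
muscle element, with fibre direction the tangent of the nearest
segment; explicit element lists can override the radius rule (the
orbicularis groups of the original model were assigned manually).
Along the fibre acts a transversely isotropic nominal stress
σ = σ_max·(f_p(λ̄) + a·f_a(λ̄)), λ̄ = λ/λ_ofl with λ_ofl = 1 (the
reference configuration is optimal fibre length). The passive branch
is exponential, f_p = P1(e^{P2(λ̄−1)}−1) for 1 < λ̄ < λ*, and continues
linearly with matched value and slope beyond λ* = 1.4 (C1 by
construction); P1 = 0.05, P2 = 6.6. The active curve is the parabola
f_a = 1 − 4(λ̄−1)² clamped to [0, 1] (peak 1 at optimal length, zero at
λ̄ = 0.5 and 1.5) — the published transversely isotropic muscle models
print only λ*, P1, P2, so the active-curve shape is this package's
choice, isolated behind `MuscleDef` so it can be swapped. The fibre
stress derives from an analytic strain-energy integral, so internal
forces remain the exact gradient of a total energy at fixed activation.
The default fibre polylines are schematic (arcs around the mouth for
the orbicularis groups, oblique/vertical lines for the elevators,
depressors and corner muscles), mirror-symmetric in x, and shipped as
editable data — they are anatomy-like, not anatomical.

**σ_max adaptation.** The shared maximum muscle stress starts at
300 kPa and is multiplied by 0.9 whenever a run inverts an element
(det F ≤ 0 at any quadrature point of an accepted step), then the run
restarts; a floor of 1 kPa turns a hopeless configuration into an
explicit error. One adapted value is shared across all strategy runs
of a dataset/mesh so that strategy comparisons are not confounded by
different stress scales; the pipeline probes with the element-wise
maximum activation over all records (a conservative superset) on a
coarser 48-frame grid, and falls back to a global decrement-and-restart
if a production run still inverts.

**Time stepping.** One implicit step per activation frame (160 frames
per instruction by default, dt = duration/160). Each backward-Euler
step minimises the incremental potential — strain energy + gravity +
(1/2dt²)‖x − x_pred‖²_M with lumped mass — over the free nodes with
L-BFGS-B and the analytic gradient, warm-started from the inertial
prediction. Viscosity is a Kelvin–Voigt term on the Green-strain
increment, (β/2dt)Σ w‖E − E_prev‖² with β = 0.5 kPa·s by default: it is
objective, scales like a stiffness, and needs no assembled tangent
matrix (which this solver never forms — the reason a classical
stiffness-proportional Rayleigh term is not used). 8-point Gauss
quadrature per hex. ln J is extended quadratically (C1) below
J = 0.05 so that line-search probes through nearly inverted states stay
finite; inversion is diagnosed on accepted states only. Convergence
uses a projected-gradient tolerance of 1e-4 mN by default (positional
error well below 1e-3 mm at the model's stiffness scale); a line-search
abort with an already-tiny gradient is accepted.

**Units.** mm–kg–s internally, hence stresses in kPa and forces in mN;
user-facing parameters keep kPa, kg/m³, m/s². x is lateral (left
positive), y vertical (gravity −y), z anterior.

## Synchronisation and scoring

Simulated and reference trajectories are linearly resampled onto a
common grid (default 160 frames). Each 30×T stacked coordinate matrix
is row-centred and reduced by SVD to its first principal component
coefficient vector b = u₁ᵀX (centring is a deliberate deviation from
projecting the raw matrix: the raw first component is dominated by the
constant mean offset of the marker positions, which carries no timing
information; a flag restores the uncentred behaviour). The integer
shift maximising the per-lag-normalised cross-correlation of the two
coefficient vectors — segment norms in the denominator, lags leaving
less than a quarter of the frames excluded — aligns the pair, which is
then cropped to the overlap. Per-lag normalisation is used instead of
zero-padded global normalisation because the latter biases recovered
shifts toward zero by several frames on smooth signals. The sign
ambiguity of independently computed principal components is resolved by
the sign of the peak correlation magnitude; ties prefer the smallest
|shift|.

Per marker, agreement is the Pitermann–Munhall 3-D correlation: the
mean-removed average dot product over the 3-D standard deviations. As
printed in the source literature the numerator averages with 1/n while
the standard deviations use 1/(n−1); these do not cancel, so ρ(v,v) =
(n−1)/n. The default implements the printed form exactly; a
`consistent=True` switch uses 1/n throughout, making ρ a genuine 3-D
Pearson coefficient with ρ(v,v) = 1. Both modes are tested; neither is
declared "intended". Summaries report mean, sample standard deviation
and median per strategy / instruction / marker; single-observation
groups report std 0 with an explicit flag.

## Synthetic data

No recordings of this experiment were ever deposited, so the package
generates its own ground truth:

* **Activation truth.** Per instruction (A purse lips, B raise upper
  lip, C depress mouth corners, D voluntary smile, E left-right-left,
  F purse–smile–purse) only the relevant muscles carry envelopes:
  raised-cosine ramp (0.3 s) – hold – release with 0.2 s rest margins,
  peak 1.0. E alternates left/right dominance over three sub-phases; F
  interleaves purse and smile muscle sets. Per-muscle gains mirror the
  measured-to-model composition (OOM at 0.2 of OOP, LAO at 0.75 of
  LLSAN, DLI at 0.75 of DAO) so that a noise-free pipeline can recover
  the truth on the relevant channels. Onset jitter (std 0.05 s in the
  noisy benchmark) emulates repetition variability. Four repetitions
  with 2 s rest is the default protocol; the repetition count is a
  config knob (the source material is self-contradictory about 4 vs 5).
* **sEMG.** Each measured channel is carrier × envelope: unit-RMS
  Gaussian noise band-limited to 15–500 Hz (8th-order Butterworth,
  ≥95% in-band power), scaled by 35 mV at full envelope. The carrier
  amplitude was fixed once by a design scan (`scripts/carrier_scan.py`): 35 mV makes the normalised WAMP response at the
  default 10 mV threshold closest to proportional in the envelope
  (10 mV is far above physiological sEMG in mV; with the threshold kept
  at its quoted value, the carrier scale is the free constant that
  makes it meaningful). Cross-talk is a nonnegative row-stochastic
  mixing matrix; the default leaks 0.1 between anatomically adjacent
  same-side electrode pairs. A band-limited noise floor (0.5 mV RMS)
  models front-end noise. The truth-to-electrode pull-back inverts the
  composition rules: both orbicularis sites see the OOP envelope, and
  buccinator activity floods the RIS/ZYG sites — exactly the leakage
  the composition rules assume.
* **Reference trajectories** at 100 frames/s: either self-consistent
  (the FEM itself simulates the truth) or a fast linear kinematic
  surrogate (fixed seeded synergy map, mirror-symmetric) for tests that
  do not need the FEM.

What the synthetic data do *not* emulate: motor-unit physiology,
electrode geometry and skin impedance, volunteer-specific anatomy,
head-pose error of camera tracking, and the amplitude distortions of
real sEMG-force relationships. Passing the closed-loop test therefore
shows the pipeline is self-consistent and numerically sound — not that
it reproduces any volunteer's numbers, which are unobtainable.

## Standard benchmark sizes

Two canonical configurations (in `emgface.pipeline`) back the test
suite and `scripts/acceptance.py`:

* `closed_loop_config` — instruction A, one repetition, no noise, no
  cross-talk, no jitter, full 16×4×3-per-lip mesh, 160 frames,
  reference trajectories from the same model, consistent-normalisation
  metric. The whole loop (truth → sEMG → WAMP → act_rel → FEM → sync →
  ρ) yields median ρ ≈ 0.998; residual error comes from the mild
  sigmoidal distortion of the WAMP response and window smoothing.
* `noisy_benchmark_config` — all six instructions, one repetition,
  cross-talk 0.1, noise floor 0.5 mV, onset jitter, all three
  strategies, 8×3×2-per-lip mesh, 64 frames. Sized so a full run
  completes in minutes on one core; the strategy ordering it probes
  (selective strategies not outperformed by act_all) is insensitive to
  the mesh density.

## Known limitations

* At the printed stiffnesses (C10 = 2.5 kPa, κ = k_b = 25 kPa) the
  tissue is orders of magnitude softer than an active muscle stress of
  up to 300 kPa: driven elements lose or gain up to half their volume
  (J ≈ 0.45–2.2) without inverting. The original full-face model
  (nodal incompressibility, finer mesh, contact constraints) confines
  volume better; on this reduced mesh the quadratic penalty provides a
  restoring pressure (tested) but not near-incompressibility under
  full activation.
* No lip–lip contact: pursing instructions can interpenetrate the
  slabs; results remain well-defined but unphysical in the contact
  region.
* The fibre geometry is schematic; absolute displacement directions
  are plausible, not anatomical. Correlation metrics are insensitive
  to this as long as simulation and reference share the model.
* L-BFGS minimisation of the incremental potential is robust but
  first-order; very stiff configurations (bulk moduli ≫ 1 MPa) may hit
  iteration limits.
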