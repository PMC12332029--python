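# Methods

## Physical model and conventions

The package treats each nucleus as an isolated spin-½ in the rotating
frame of its carrier. A shaped pulse is *n* rectangular elements of equal
duration `dt = total_duration / n`, fixed amplitude ν₁ (the calibrated
peak B1 field) and free phases φ_j. Element *j* at offset Δ propagates the
spin by

    V_j = exp[-i·2π·dt·(Δ σz/2 + ν₁ (cos φ_j σx + sin φ_j σy)/2)],

a rotation about the tilted effective field (ν₁cos φ_j, ν₁sin φ_j, Δ) by
2π·ν_eff·dt, ν_eff = √(ν₁²+Δ²). Sign convention: `exp(-iH·2π·dt)` with
positive gyromagnetic ratio, so a phase-0 90° pulse maps Z→−Y. Nuclei
with negative γ (¹⁵N) are treated with the same effective convention; the
design problem is invariant under this choice up to a reflection of the
phase axis. Offsets follow one global orientation: higher ppm → higher
(positive) offset, offset = (ppm − carrier) × Larmor(MHz) in Hz.
Internal units are Hz/seconds/radians; user-facing quantities are
kHz/μs/ppm/degrees, converted at the model boundary.

Relaxation during the pulse, couplings between spins, and amplifier
response functions are outside the model. The only hardware-transient
concession is a validation warning when elements are shorter than 1 μs
(at typical maximal amplitudes of ~25 kHz a 1 μs element rotates by 9°,
below the ~10° guideline where transient effects stay negligible).

## Scaled-unitary arithmetic

Every matrix in the computation — element propagators, partial products,
phase-derivative kernels — is quaternion-form `[[a, −b̄], [b, ā]]` and
stored as the pair (a, b). This set is closed under multiplication; a
product costs 4 complex multiplications instead of 8, and the trace of a
product of two such matrices is automatically real and costs exactly 4
real multiplications: Tr(PQ) = 2Re(p_a q_a) − 2Re(p̄_b q_b). The phase
derivative has the closed form dV/dφ = −(i/2)(σz V − V σz), i.e. the pair
(0, i·b) — exact at any element duration (no small-dt approximation) and
validated against central finite differences.

## Objective and gradients

With partial products X_j = V_j X_{j−1} (X₀ = 1) and kernels
C_j = X_j† (dV_j/dφ_j) X_{j−1}, the derivative of the total propagator is
dV/dφ_j = V·C_j, so each restraint's gradient is a trace against C_j:

* **universal/identity** — F = Re Tr(V U†)/2, I = 1 − F,
  dI/dφ_j = Re Tr(B C_j) with B = −(U†/2)·V. Note the order: the trace
  kernel is W·V, not V·W; the two differ for non-commuting factors and
  only the former reproduces finite differences. The fidelity is
  phase-sensitive (distinguishes U from −U); a phase-insensitive variant
  (Tr(V U†)/2)² is available behind an option since the 2π-rotation sign
  is physically irrelevant.
* **state-to-state** — F = (1 + n_final·n_finish)/2 with
  n_final = R(V)·n_start; B = −2·ρ_s V† ρ_f V.
* **XYcite** — I = z_final² for a spin starting on +Z;
  B = 2 z_final·σz V† σz V. Squaring (rather than |z|) keeps the
  objective smooth at the optimum.
* **suppression** — I = 1 − (1/n) Σ_k F_k over the Z→Z fidelities of all
  prefixes X_k, with B_k = −(2/n)·ρ_z X_k† ρ_z X_k and
  dI/dφ_j = Σ_{k≥j} Re Tr(B_k C_j). Because the trace is linear, the
  double sum collapses via suffix accumulation of B_k into a single O(n)
  pass (the brute-force O(n²/2) prefix evaluation is retained as the test
  oracle). A `stride` option subsamples checkpoints for very long pulses.

Normalizations are fixed so that I = 0 exactly at perfection and I ≤ 1
for the state restraints; all four gradients are verified against central
finite differences (relative error < 10⁻⁶) as the master correctness
oracle, for single conditions and for the full mixed-band aggregate.

The aggregate objective averages infidelities over every (band frequency,
B1 scale) condition: I_total = Σ_e w_e Σ_bands Σ_freqs I / N_freqs with
N_freqs the total count across bands. Bands are deliberately *not*
renormalized per band — raising a band's frequency count raises its
priority. Frequencies are distributed evenly and endpoint-inclusively
(n = 1 → band centre), so stated band edges are always optimized.
Averaging infidelities rather than fidelities matters only for the
nonlinear XYcite cost; infidelity averaging was chosen for consistency
across restraints. Conditions are independent, so the evaluation is
embarrassingly parallel; here it is vectorized across all conditions in
one numpy scan (per cost evaluation: one sequential loop over elements of
short vector operations), which makes a 250-element, 180-condition
gradient evaluation take a few milliseconds on one core.

## Optimization

Phases start uniform on [0, 2π) from a seeded `numpy` Generator and are
unconstrained during minimization (wrapped to [0, 2π) only at export).
The minimizer is SciPy's full-memory BFGS with Wolfe line search, driven
by the analytic gradients. Defaults: max 2000 iterations, gradient-norm
tolerance 10⁻¹⁰, and a relative-change stop when the best-so-far
infidelity improves by less than 10⁻⁹ (relative) over a 10-iteration
window. The recorded trace is the best-so-far infidelity, hence
non-increasing by construction; the returned pulse is the best point ever
evaluated.

**Horserace mode** runs `n_seeds` independent optimizations (seeds
seed, seed+1, …) for `checkpoint_iterations` each and carries only the
lowest-infidelity trajectory to completion (ties → lowest seed; defaults
50 seeds / 100 iterations). Because BFGS accumulates curvature, a
restarted continuation would not reproduce an uninterrupted run; the
winner is therefore re-run from its seed with the full budget, which
reproduces the checkpoint trajectory exactly and then continues it — and
makes the n_seeds = 1 case bitwise identical to a plain run.

## Simulation and reports

Excitation profiles evaluate the total propagator over offset × B1-scale
grids and apply it to magnetisation starting on X, Y and Z. The default
profile grid is 4× denser than the optimization grid and offset by half a
step so the evaluation points interleave the optimization points —
between-grid misbehaviour is always visible. Reports serialize the full
numeric payload (waveform, infidelity trace, profiles, per-point
restraint fidelity) as JSON, round-tripping bit-exactly; plots and CSV
tables are derived artifacts. The per-point fidelity uses the same
formulas as the optimizer, so profile values at optimization-grid points
reproduce the reported objective exactly. For multi-band ¹³C pulses an
interface-width convention of fidelity < 0.99 around a band boundary is
suggested for reading profiles; it is a convention, not a calibrated
quantity.

Rectangular references: on-resonance t90 = 1/(4ν₁); null-placed
t90 = √15/(4ν) and t180 = √3/(2ν) put the first excitation null at ±ν Hz
(used by classical triple-resonance sequences to decouple CO from Cα).

## Fixtures and file formats

The built-in catalogue mirrors published design problems: ¹⁵N universal
90x (250 μs, 6.85 kHz, 106–133 ppm, 60 frequencies, carrier 119.5 ppm);
¹H universal 90x (0–12 ppm, 96 frequencies, 23 kHz, 100 μs); broadband
¹⁹F excitation (300 ppm, 300 frequencies, 20.2 kHz, 2000 μs); three-band
¹³C transforms at 17.6 kHz with CO 158–198 / Cα 40–78 / Cβ 8–40 ppm and
96/96/20 frequencies, carriers 58 or 176 ppm; and a ¹H water-suppression
pulse (9.76 kHz) with universal rotations on the aliphatic/amide bands
and the prefix-hold on 4.65–4.85 ppm. Catalogue values not printed with
the published problems were fixed once as realistic: a 600 MHz (¹H) field
(so ¹⁵N Larmor 60.8 MHz, ¹³C 150.9, ¹⁹F 564.6), element counts at the
1–2 μs guideline, and a 2000 μs duration for the water-suppression entry
(long low-amplitude pulses are the norm for that task).

Shape files are plain text in two dialects: Bruker JCAMP-DX
(`##`-headers, amplitude 0–100%, phase in degrees, 6 decimals) and
Varian/Agilent `.RF` (phase / amplitude-0–1023 / duration-count columns).
Phase-only pulses export at constant maximal amplitude. Round-trips
recover phases to <10⁻⁴ degrees. Batch design is driven by a YAML config
(pulses, optimizer options, output options); unknown keys are rejected,
YAML syntax errors carry line numbers, semantic errors are anchored by
pulse name/index.

## What the synthetic problems do and do not show

All tests run on synthetic design problems and exact Bloch simulation.
They establish mathematical correctness (oracle-verified propagators and
gradients, duality and invariance properties) and optimizer behaviour
(convergence to analytic optima, low final infidelities, small
seed-to-seed spread). They do not model spectrometer non-idealities —
amplifier droop and transients, probe detuning, relaxation during long
pulses, radiation damping — so simulated fidelities are upper bounds on
spectrometer performance. The element-duration warning and the B1
ensemble are the two deliberate concessions to hardware reality.

## Problem sizes in the test suite

The shared expensive computation is the ¹⁵N universal-90x design run to
convergence from 10 seeds (~1–2 minutes total); all other tests use
problems of 1–64 elements and a handful of conditions, chosen so each
oracle comparison is exhaustive at small n rather than sampled at large n.
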