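# Methods

## Model and normalization

The package implements the extended Jansen–Rit circuit for one cortical
area in fully dimensionless form. Mean PSPs are scaled by the sigmoid slope
and time by the excitatory dendritic time constant τ, so the synaptic
second-order kinetics reduce to unit form for the excitatory branches
(damping 2, stiffness 1) and to damping 2β, stiffness β² for the inhibitory
branch, with β = τₑ/τᵢ. Couplings α_ba absorb maximum firing rate, sigmoid
slope, contact counts and synaptic gains (α_ba = 2e₀ r c_ba H τ²/τ_{e,i});
`NormalizationMap` documents this mapping and reproduces the default
dimensionless set from Jansen-style physiological constants, but no
computation runs in physical units — τ enters only as f = η/τ at I/O
boundaries (a single characteristic time rescales the dynamics without
changing them).

The periodic photic input drives the inhibitory interneurons:
x₂T = ζ exp(−2δ cos²θ). The phase advances as θ̇ = πη; since cos²θ is
π-periodic, the pulse train repeats every 1/η of normalized time, which is
the testable contract for the phase convention. The pulse-shape parameter
defaults to δ = 110 (width ≈ 0.2 κ at η ≈ 0.1). The variance of the
deterministic train has the closed form
ζ²[e^(−2δ)I₀(2δ) − (e^(−δ)I₀(δ))²], evaluated with exponentially scaled
Bessel functions; it defines the signal power in every stimulus-SNR
computation and is verified against dense quadrature to < 1e−6 relative.

Fixed points of the unforced system reduce to a scalar root problem in x₀₃
(which lies in (0, 1) because it is a sigmoid output); the default initial
state is this equilibrium plus a fixed offset of 1e−3 on the PSPs —
deterministic, reproducible, and off the (unstable) rest state so
trajectories land on the limit cycle. With the default parameters the
unforced cycle runs at η_int = 0.108 with near-harmonic waveform.

## Integration

Two paths. The adaptive path uses scipy's DOP853 at rel_tol = 1e−11 (the
high-order method takes large steps on this smooth field). The compiled
path is classical fixed-step RK4 (numba) at Δκ = 2.5e−3, chosen after
checking that Lyapunov exponents at boundary cells agree with Δκ = 1e−3 to
~3e−4 — about 30–80 steps per stimulus pulse. Both paths agree to ~1e−8 on
trajectories, and all sweeps, scans and surrogate rendering use the
compiled path (the surrogate generator uses Δκ = 5e−3; its records are
statistical objects, not shadowing targets). Trajectories are resampled
uniformly at Δκ = 1e−2 for analysis.

The analysis window defaults to the final 20% of post-transient samples
rather than a fixed sample count: transient-free windows are what matters,
and the window length only sets the spectral bin width.

## Lyapunov spectra and regime labels

The six exponents of the neural subsystem come from integrating the
variational flow alongside the trajectory (tangent matrix advanced by the
same RK4) with modified Gram–Schmidt QR renormalization every 10 steps; the
accumulated log of the diagonal yields the exponents. The stimulus phase is
treated as explicit time dependence, so the tangent space stays
six-dimensional and the exponent sum must equal the constant Jacobian trace
−(4 + 2β) = −5 — it does, to machine precision, which is a structural
check of the variational algebra rather than a numerical accident.

For a forced configuration the full autonomous system carries one
additional, trivially zero exponent along the drive. It is not reported in
the spectrum (whose sum then matches the trace) but it is re-inserted when
counting zero exponents for classification, so the textbook signatures
hold unchanged: entrained limit cycle — one zero (the drive) and all neural
exponents negative; two-torus — two zeros; chaos — one positive exponent.
The zero tolerance defaults to 1e−3 per unit κ: well under typical
contracting exponents (~1e−1), above estimator noise at the desk-scale
spans. Convergence is summarized by the drift between the full-span and
half-span estimates; spectra with drift above 2e−3 carry a warning flag
(chaotic cells fluctuate more and often do — the flag marks estimator
noise, not failure).

Desk-scale spans are 2–6e3 κ per cell (the package default is 3e4 for
single configurations); a long-reference span is impractical per cell on
one core and unnecessary for sign-based classification, as the drift
estimate shows. An independent two-trajectory divergence estimator (pair
renormalized every 1 κ) exists purely as a cross-check; it agrees with the
QR route in sign at every tested cell, and to ~1e−4 on locked cells.

The Kaplan–Yorke dimension uses the standard partial-sum formula; by
convention D = 0 when even λ₁ < 0 (the section collapses to a point) and
D = n when every partial sum is non-negative.

## Charting the stimulus plane

Sweep grids are linear in amplitude over [0, 4.1] and constrained in
frequency so that the stimulus period is an integer number of resampling
intervals ((η·Δκ)⁻¹ ∈ ℕ, i.e. η = 100/N), keeping the narrow pulses
commensurate with the sampling. Default desk grid 12 × 24; the
reference-resolution grid (106 × 69) is available by configuration. Cells
are independent and failures are recorded as NaN, not fatal. Cells whose
largest exponent lands within 3 × zero_tol of zero — tongue edges and tori,
where finite-span noise can flip the regime and, by shrinking |λ₂| as well,
inflate the Kaplan–Yorke ratio λ₁/|λ₂| — are recomputed once at four times
the span before the maps are filled; solidly chaotic or locked cells are
not revisited.

Mode locking is decided from the stroboscopic section (states sampled once
per stimulus period, step snapped to divide the period exactly): a locked
orbit visits a small finite point set, a torus fills a closed curve, chaos
scatters. Points are clustered at an absolute tolerance of 2e−3 (states
are O(1)–O(10)); a section still spiraling in (second-half extent < 0.5 ×
first-half extent) counts as locked, which catches the slow convergence at
tongue edges where |λ₁| ~ 1e−3. Spectral commensurability is *not* used as
the lock test: on a forced torus the driven line at η can dominate the
spectrum, so a peak at η does not distinguish locking from
quasi-periodicity.

Entrainment intervals along an amplitude row are maximal runs of locked
cells with λ₁ ≤ zero_tol. Two kinds of interior interruption do not
terminate a run: chaotic cells of any length flanked by locked cells (the
"islands" that riddle the tongues), and single-cell non-entrained dropouts
— features below the scan resolution of 0.002 (a genuine quasi-periodic
window of this width exists inside the ζ = 0.8 tongue near η = 0.048).
Interval endpoints are reported midway between the bracketing grid cells,
the unbiased estimate under grid sampling; the half-step is the resolution
limit. The chaotic islands are returned separately.

Boundary locators: the low-frequency periodic branch ends at the first
chaotic cell of an ascending λ₁-sign scan (reported as the bracket
midpoint); the two-torus onset is the zero crossing of λ₁(η) interpolated
between scan cells — below it the locked branch has λ₁ < 0, on the torus
λ₁ joins zero (a torus birth).

Poincaré sections use the plane x₃₁ = its post-transient mean with
positive-going crossings located by linear interpolation — transverse to
the unperturbed cycle — and record x₃₂, the bifurcation-diagram
coordinate. The diagram reproduces the period-adding cascade: section
point counts grow one at a time as η decreases (1 → 2 → 3 at
η = 0.048 → 0.016 → 0.008 for ζ = 3.6301).

Known deviation: at ζ = 3.6301 the band η ≈ 0.12–0.17 hosts a stable
locked orbit in this implementation (probed from five initial states and
by continuation in η; no coexisting chaotic attractor was found), where
the original charting reports chaos. The locked branch loses stability at
η ≈ 0.172 via a torus birth, so the torus window *above* 0.172 and every
other charted boundary reproduce. The discrepancy is initial-condition /
transcription sensitivity in a strongly multistable band, not a step-size
artifact (exponents agree between Δκ = 1e−3 and 2.5e−3).

## Wolf estimator

Fixed-evolution-time estimation on a Takens embedding (defaults: dimension
16, delay 9 samples ≈ 50 ms, evolution 5 samples ≈ 25 ms at 200 Hz). The
nearest admissible neighbor of the fiducial point is evolved alongside it;
log separation growth accumulates; the neighbor is replaced — by the
closest admissible point best aligned with the current separation — only
when the separation leaves the admissible scale range. Replacing only on
demand makes the log sums telescope between replacements, so bounded
oscillations of the embedded distance cancel instead of ratcheting the
estimate (replacing every step biases periodic signals positive by
selecting minimal-distance phases).

Scale defaults per record: min-scale = the noise-floor estimate (median
nearest-neighbor distance on a subsample), floored at 1e−4 of the
attractor extent so that exactly periodic records — whose nearest
recurrences sit at floating-point rounding distance — are not tracked at
the rounding scale; max-scale = 10% of the attractor extent; temporal
exclusion window = one embedding span. When no neighbor exists within the
scale bounds (near-rationally sampled locked orbits cluster into phase
classes), the bounds are relaxed to the closest temporally separated
point. Estimates are in nats per second and are exactly invariant under
amplitude scaling of the record.

Behavior on surrogates: noise-free periodic records ≈ 0; records from
chaotic configurations positive (≈ +2–3 s⁻¹, same sign and order as the
variational λ₁ ≈ +3.7 s⁻¹ of the generating configuration — the embedding
estimator is biased low, as expected at n = 12,500); any noisy record
positive, since additive noise is itself a divergence source.

## Surrogate experiment and the fit

Each surrogate subject draws an individual alpha frequency from 9.5 to
11.8 Hz, fixing τ = η_int/f_α; for each of 15 stimulus-to-alpha ratios
0.4–1.6 the model is driven at η = ratio·η_int, the pyramidal-PSP observer
is rendered to physical time by cubic interpolation onto the 200 Hz grid,
and 62.5 s (12,500 samples) are kept, plus white Gaussian measurement
noise at the design SNR (signal power = variance of the noise-free
series). The experimental train/rest structure (20 trains × 40 flashes) is
not reproduced: the analysis operates on contiguous segments, and
continuous stimulation of the analyzed length is the matching surrogate.
Stimulus-input noise (jitter on the pulse train at a set SNR, applied
inside the integrator) is a separate, independently configured channel.

What the surrogates do not emulate: real EEG background (1/f spectrum,
blinks, line noise, non-stationarity) and volume conduction. Passing tests
therefore show that the *pipeline* recovers what it assumes — not that
real recordings satisfy those assumptions.

The fit normalizes a subject's 15 exponents onto the model's exponent
range by the orientation-preserving affine map u + v·λ₁ (v > 0); the
bounds are the min/max of λ₁ over the non-positive cells of the reference
sweep (chaotic cells carry positive exponents and are excluded from the
bound definition — with the desk-scale sweep the bounds come out at
≈ −0.12 and ≈ −2e−4 per unit κ). Each empirical point is scored against
its four nearest model frequencies by Euclidean distance in the (ratio,
normalized λ₁) plane, relative to the maximum distance obtained by
substituting the model bound (lower bound if the query exponent is above
the bounds' midpoint, else upper); the per-point minima average into ε ∈
[0, 1] per amplitude, and the amplitude minimizing ε is the fit (ties
toward smaller ζ). Axes are deliberately left unrescaled in the distance.

Two caveats, both visible in the tests: the ε landscape at desk scale is
amplitude-biased — wide-range rows fit *any* range-normalized profile
comparatively well, so even noise profiles land near the top amplitudes —
and the frequency-sequence information is therefore carried by the
bootstrap, which shuffles the 15 exponents across frequencies and refits:
matched surrogates beat their shuffles (median p ≈ 0.05 vs ≈ 0.5 at
10 dB), which is the meaningful recovery evidence. Bonferroni correction
for the correlation test uses p/(4·N_amplitudes), counting amplitudes ×
nearest neighbors.

Robustness suite: following the re-estimation-under-added-noise protocol,
the base profile is the subject's records *as recorded* (for surrogates,
at their design SNR) and extra Gaussian noise is added at each listed
SNR. On 10 dB surrogates the profile correlation with the base stays
above ~0.5 down to 10 dB of extra noise and collapses at 0 dB. Starting
instead from noise-free records, added noise switches the estimator from
deterministic-divergence to noise-divergence mode and the correlation is
much weaker — one reason the base must be the recorded data, as in the
original protocol.

## Empirical input

Records arrive as two-column text (time, value) or one column plus a
sampling rate; preprocessing is polyphase anti-alias resampling to 200 Hz
and truncation to 12,500 samples, with shorter records rejected. The
acquisition-side filter passband is taken as given (hardware filtering);
no artifact rejection or multi-channel handling is attempted — one
occipital channel is the analysis object.

## Problem sizes

Defaults used by the test suite and the acceptance script: sweep 10 × 20
(tests) or 10 × 16 (script) cells at spans 2000–2500 κ; boundary scans at
grid step 0.002 with spans 3000–6000 κ; 20 surrogate subjects at 10 dB;
bootstrap at 100–200 replicates (5000 is the default for production use).
These are the package's desk-scale defaults; every routine accepts larger
spans and grids by argument.
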