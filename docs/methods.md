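# Methods

This note documents the models, numerical choices and known limitations of
the `ffcmri` virtual scanner and quantification chain.

## Dispersion models and the phantom library

All materials are described phenomenologically as

R1(f; c) = R1_baseline(f) + c · r1_specific(f) [+ c · peaks(f)]

with f the proton Larmor frequency (Hz; internally the canonical frequency
unit — fields are stored in tesla and converted only at the API boundary,
γ/2π = 42.578 MHz/T). Changing the concentration c shifts a material's
profile vertically without changing the shape of its specific term; this
linearity is what both the classification (shape) and the concentration
estimate (offset) exploit, and it is enforced by construction and covered
by property tests.

Three functional families are provided:

- **Power law** R1 = a·f^b — the standard empirical model for tissue; b < 0
  for a falling profile, b = 0 degenerates to a constant.
- **Lorentzian dispersion** R1 = R1_∞ + Σ A_i/(1+(2πfτ_i)²) — monotone
  non-increasing, the generic shape of paramagnetic solutions; R1(0) =
  R1_∞ + ΣA_i.
- **Quadrupolar peak set** — Lorentzian-in-frequency peaks
  A·w²/(w²+(f−f_c)²), non-negative, maximal at their centres. The default
  set sits at 0.66, 2.1 and 2.75 MHz (the ¹⁴N cross-relaxation proton
  frequencies), the dominant 2.75 MHz peak corresponding to ~65 mT. The
  centres are configurable.

The seven-bottle phantom library (MnCl2 0.38/0.52/0.74/1.00 mM; BSA
5/10/20 % w/w) uses **frozen fixture parameters, not measured
relaxivities**: the MnCl2 specific term is a two-term Lorentzian
(τ = 10⁻⁷ s and 5·10⁻⁹ s, 12 s⁻¹/mM each, 3 s⁻¹/mM plateau) and the BSA
specific term a shallow power law (a = 1.6, b = −0.16 per % w/w) plus the
peak set above. The MnCl2 correlation times were chosen so the smooth
profile is close to log-log linear across the imaging band; this matters
because the quadrupolar-amplitude feature measures the residual over a
power-law baseline, and a strongly curved smooth profile would register a
spurious "peak". The resulting T1 range across bottles is ~35 ms–1 s,
realistic for low-field work.

## Field cycling and magnetisation

A repetition of the field-cycling inversion-recovery spin-echo sequence is
built as: ramp 0 → B_pol, polarise (default 0.5 s at 0.2 T), ramp to the
detection field for a short inversion plateau (2 ms, ideal instantaneous
180°), ramp to the evolution field, evolve for t_evo, ramp back, wait the
stabilisation delay (15 ms — post-ramp field ringing with ~4 ms decay has
died out by then), excite and acquire. All ramps run at the protocol slew
rate (12 T/s default; 20 T/s hard ceiling). RF pulse shapes, slice
profiles and transverse dynamics are out of scope; the echo is modelled as
Mz at excitation × exp(−TE/T2) with a per-material T2.

Protocol validation enforces the thermal duty limit as the time-average of
(B/0.2)² over each repetition — resistive dissipation scales with I² and
hence B² — capped at 50 %. This reproduces both operating facts the limit
must encode: continuous 0.2 T (100 %) is forbidden while continuous 0.13 T
(42 %) is allowed.

Mz follows dMz/dt = (m0(B(t)) − Mz)/T1(B(t)) with m0(B) = B/0.2
(equilibrium normalised to 1 at full field). Constant-field segments use
the closed-form exponential; ramps are sub-stepped (default ΔB = 1 mT,
configurable) with the exponential evaluated at each sub-step's midpoint
field, second-order accurate. Against an adaptive high-order ODE solution
the propagator agrees to better than 10⁻⁶ relative at ΔB = 0.2 mT.
Dispersion models are never evaluated below 50 µT (the scanner's own field
floor), which keeps T1(B) defined on ramps through zero field.

Because only the evolution plateau length varies across an
inversion-recovery series, the detected signal is *exactly*
S(t_evo) = S_∞ + (S_0 − S_∞)·exp(−t_evo/T1(B_evo)) even with finite ramps —
the fixed ramps before and after the plateau apply a fixed affine map. The
three-parameter fit therefore recovers the evolution-field T1 without ramp
bias; ramps only shrink the exploitable amplitude.

## The virtual scanner

Acquisition is 2-D single slice, one phase-encode line per repetition,
linear top-to-bottom ordering, TR-spaced time stamps. Per line the
fluctuation model contributes a single phase factor e^{iφ}: a random
component (sd `phase_sd`), plus mains harmonics (k·50 Hz, 300 Hz dominant)
and monotone, saturating thermal drift (up to 500 ppm over 45 min)
converted to phase via an effective phase-accrual time (default TE).
Complex white Gaussian noise is added in k-space at a level set from the
requested image-domain SNR. Intra-readout field variation is not modelled
separately — the per-line phase is the artefact model, and it is exactly
what the ghost correction inverts. Navigator FIDs (256 points, 50 µs
dwell) are generated per repetition at the instantaneous drifted field.

**Ghost correction.** With per-line phases the reconstructed image is
I = Σ_l e^{iθ_l}·I_l, linear in the unit factors. The correction minimises
the image energy inside a user-supplied empty mask (≥10 % of the image):
coordinate descent first — each line's optimal phase is closed-form since
the masked energy is sinusoidal in θ_l — then a damped Gauss–Newton polish
on all phases jointly (the coordinate path zigzags in the ill-conditioned
valley the phases share), with backtracking so the objective never
increases. Phases are identifiable only up to a global constant, and lines
with negligible k-space content carry no phase information; on textured
32×32 instances the injected phases are recovered to <10⁻³ rad. The
remaining per-image global phase is removed before T1 fitting by rotating
each image with θ = ½·arg Σ I² over the object (exact for a real-valued
object and insensitive to the signed-voxel structure of inversion-recovery
images; the mod-π ambiguity is resolved by taking the rotation nearest
zero). Without this step the random global phase of each image scales its
real channel by cos φ and biases the voxel-wise R1 coherently by several
percent.

**Navigator and drift loop.** The field offset is the peak of the
zero-padded (×8) FID spectrum refined by three-point parabolic
interpolation on the log magnitude, divided by γ/2π. The control loop
subtracts the estimate quantised to the DAC step (0.2 T/2¹⁶ = 3.05 µT ≙
130 Hz) from the next repetition; under drift slower than one step per TR
the residual stays within one step.

**Stability metric.** The FID phase is unwrapped, a best-fit linear trend
(constant + frequency offset) removed, and each residual sample over the
first 10 ms converted to an equivalent relative field error
φ_res(t)/(2πf₀t); the metric is 3× the standard deviation of that series in
ppm. The phase-to-ppm normalisation admits more than one reading; this one
is calibrated by the paired generator `synthetic_fid`, which injects a
relative-field series ε(t) as phase 2πf₀·ε(t)·t — the exact inverse — so
injected 1.5 ppm (3σ) white noise reads back as ≈1.5 ppm. Physically
integrated (random-walk) phase noise would read lower; the metric reports
the time-averaged equivalent field error, not the instantaneous one.

**SNR.** Magnitude-image SNR is 0.655 × mean(signal)/sd(background): the
signal-free background of a magnitude image is Rayleigh, whose sd
overestimates the complex noise sd by exactly 1/√(2−π/2).

## Quantification chain

Voxel-wise T1 comes from the three-parameter fit (Levenberg–Marquardt via
`scipy.optimize.curve_fit`); non-convergent voxels are flagged NaN and
excluded downstream, never raised. For magnitude-only input the sign is
restored by flipping all points up to the minimum-magnitude index; the
near-null sample's sign is genuinely ambiguous, so both polarities are
fitted and the lower-residual solution kept (without this the stated ~1 %
recovery at SNR 100 degrades to ~6 % through misflipped nulls).

ROI profiles average R1 = 1/T1 over a one-voxel-eroded bottle mask
(standard error sd/√n). The power-law fit is linear least squares in
log–log space by default (unbiased on noiseless data, closed form, and the
natural space for a scale-free law); uncertainty-weighted and direct
nonlinear variants are available behind flags.

Clustering uses three features per voxel — overall span R1(B_min)−R1(B_max),
the discrete R1 drop across the grid points bracketing 20 mT ("dispersion
at 20 mT" is read as a local change, not a value; the plain value is
available via a flag), and the quadrupolar amplitude (max positive residual
in the 1.6–3.4 MHz band over a power-law baseline fitted with that band
excluded, clipped at zero) — z-scored and fed to k-means (10 restarts,
fixed seed). Clusters are matched to materials by nearest reference-model
features in the same standardised space, which makes the material
assignment invariant to cluster index permutation. Classification of a
profile against the reference library fits a single concentration scale
per reference (closed-form least squares on the specific term) and picks
the minimum SSR, ties broken by library order. Concentration is the least
squares scale of the baseline-subtracted profile onto the
baseline-subtracted reference, times the reference concentration — exactly
linear in the noiseless limit; negative scales are clipped to zero with a
warning.

## Study conditions and problem sizes

The standard virtual phantom study uses a 128×128 matrix (40 cm FOV, so the
35 mm bottles are ~11 px across), six evolution fields (2, 10, 30, 65, 120,
200 mT — chosen to cover the span extremes, bracket 20 mT, and sample the
quadrupolar band near 65 mT), six evolution times log-spaced 15 ms–3 s (the
bottle T1 range is ~35 ms–1 s), per-line phase sd 0.1 rad and voxel
SNR ≈ 100 referenced to the fully polarised detection signal of an average
bottle material. Bulk (non-imaging) relaxometry uses ten log-spaced fields
from 0.1 mT to 0.2 T with eight evolution times per field placed
near-D-optimally for the three-parameter fit (two early points pinning the
inverted amplitude, four near t ≈ T1 carrying the rate, two late points
pinning the plateau — about 40 % lower R1 variance than a log ladder at
the same budget) and FID SNR ≈ 500. Under these conditions the pipeline
recovers all seven concentrations to ~1–3 %, ROI R1 to ~2–5 % and bulk R1
to ~1–2 % — comfortably inside the 20 %/10 %/2 % accuracy the scanner's
own phantom validation is expected to meet.

## What the generator does and does not emulate

Emulated: field-proportional polarisation, T1(B) relaxation through ramps,
the three-level field cycle and its timing constraints, per-line phase
instability from mains/drift/random field noise, DAC-quantised field
control, Rician magnitude statistics, empty-space ghosting.

Not emulated: RF excitation/refocusing imperfections, coil sensitivities,
slice profiles, eddy currents, concomitant gradients, intra-readout field
evolution, 3-D encoding, susceptibility, chemical shift, motion, and any
microscopic relaxation theory (models are phenomenological fixtures).
Passing tests therefore demonstrate the correctness and statistical
behaviour of the algorithms under the stated artefact model, not
quantitative fidelity to any particular tissue or scanner.

## Shimming

The shim volume is a 2-D grid standing in for the 3-D volume; basis maps
are low-order polynomial harmonics (X, Y, XY, X²−Y², r²-type, cubics),
linearly independent by construction. The objective is the mean |FID| over
a configurable window (default 10 ms, 64 samples) of
Σ_r ρ(r)·e^{2πi·γ/2π·ΔB(r)t}·e^{−t/T2}: maximal for a homogeneous residual
and invariant to a uniform offset. TLBO is the canonical two-phase form —
teacher step X′ = X + r·(X_teacher − TF·X_mean) with TF ∈ {1,2}, learner
step toward/away from a random partner, greedy acceptance, bounds clipped —
with 6 learners and ≤50 iterations, seeded and bit-reproducible. One
population member starts at zero current (the scanner's actual starting
point). At this fixed budget individual runs on fully-correctable 4-channel
problems cancel 93–100 % of the inhomogeneity energy (mean ≈ 98 % over
seeds); the best-member trace is non-decreasing by construction.

## Degenerate inputs and tie-breaks

Flat profiles yield b = 0 and all-zero features; identical voxel features
set a `degenerate` flag on clustering (k-means cannot separate them);
classification ties resolve by library order; empty-mask ghost correction
degrades to an identity correction with a warning below 10 % coverage;
navigator estimation raises if no spectral peak clears the noise floor;
concentration scales below zero clip to zero with a warning.
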