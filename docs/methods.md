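# Methods

This note documents the models, numerical choices, and limitations of the
famfat toolkit: what is simulated, how it is fitted, and what the passing
tests do and do not demonstrate about real acquisitions.

## Signal model

A voxel contains water and fat proton densities `W = M0(1−PDFF)` and
`F = M0·PDFF`. The complex multi-echo CSE signal is

    s(TEₙ) = (W + F·c(TEₙ)) · exp(−R2*·TEₙ) · exp(+i·2π·ψ·TEₙ)

with a single effective R2* shared by both species (no species-specific R2*,
no separate T2, no multi-compartment water) and field offset ψ in Hz. The
fat phasor `c(TE) = Σₚ aₚ·exp(i·2π·fₚ·TE)` uses a six-peak liver fat
spectrum (offsets −3.80, −3.40, −2.60, −1.94, −0.39, +0.60 ppm; amplitudes
0.087, 0.693, 0.128, 0.004, 0.039, 0.048, renormalized to sum to one).
Frequencies are `fₚ = γ̄·B0·δₚ` with `γ̄ = 42.5775 MHz/T`; the config carries
the true B0 separately from the field-strength label, so systems labelled
"3T" but operating at 2.89 T are described exactly.

Sign conventions: positive ψ contributes phase `+2πψTE`; fat offsets are
negative for peaks precessing slower than water. Data acquired with the
conjugate convention should be conjugated before fitting.

**Temperature correction.** Aqueous-gel phantoms at room temperature shift
the water reference by ≈0.11 ppm relative to body temperature, so in phantom
mode all fat offsets are shifted by +0.11 ppm; in vivo mode applies no
shift. The flag lives in the run config (`phantom_temperature_correction`).

**Steady-state T1 bias.** A constant-flip spoiled-gradient-echo acquisition
in steady state scales each species by `g(T1) = sinα(1−E1)/(1−E1·cosα)`,
`E1 = exp(−TR/T1)`. The measured fat fraction is then
`F·g_f / (F·g_f + W·g_w)`; with liver-like T1s (fat ≈ 382 ms, water
≈ 809 ms), TR 6.4 ms and α = 3°, a true 30% voxel reads 31.7%. The bias
vanishes as α → 0 and is always an overestimate when fat T1 < water T1.

## FAM sequence design

Each slice is acquired sequentially (one excitation per phase-encode line,
per-slice footprint `TR·Ny`), with centric ordering: the DC line
(index ⌊Ny/2⌋, 0-based) first, then alternating +1, −1, +2, −2, … offsets,
positive first, clipped at the bounds. Slices are assumed fully relaxed at
the start of each slice (sequential 2D with a long effective revisit time),
and spoiling is assumed perfect — no transverse signal history and no
RF-spoiling phase schedule is simulated.

The transient signal obeys `S_j = Mz_j·sinα_j`,
`Mz_{j+1} = Mz_j·cosα_j·E1 + M0(1−E1)`, `Mz₁ = M0`. Because every species
starts from equilibrium, `S₁ = M0·sinα₁` independent of T1 — the mechanism
behind the method's T1 insensitivity at the center of k-space.

**Schedule solving.** The published FAM optimization is not reproduced here;
instead the solver tracks a parametric target signal profile by exact
algebraic inversion of the recursion (`α_j = asin(S_j/Mz_j)`, capped at a
configurable maximum, default 90°). The default target decays exponentially
from `sin(12°)` toward the steady-state signal of a 4° flip at the reference
T1 (1000 ms), with time constant `0.10·Ny` excitations. These defaults were
chosen for feasibility (the required flip never exceeds the starting flip at
any preset, so the cap is never reached) and modest filtering
(point-spread-function FWHM broadening ≈ 1.15, cross-T1 normalized
weighting discrepancy ≤ 7% confined to outer k-space); an earlier
slower-decaying candidate (asymptote 6°, time constant 0.25·Ny) was
discarded because it drained the magnetization to the flip cap. Designs are
validated post hoc by `psf_metrics` and `weighting_discrepancy` rather than
by re-deriving the published objective, whose exact form (flat-top lengths,
T1 ranges, constraint weights) is an open choice here.

**Echo-time noise performance.** `crlb_pdff_variance` evaluates the
Cramér–Rao lower bound of magnitude-based fitting with free parameters
(W, F, R2*), treating the magnitude data as Gaussian with known SD (valid at
the moderate-to-high SNRs simulated here). The bound is compared against
Monte-Carlo fit variance in the test suite (agreement within 15% at SNR 50).

**Timing convention.** The per-slice footprint is rounded to one decimal and
the total time is the rounded per-slice value times the slice count, so the
printed protocol-table values (1.7/1.8/1.3 s; 54.4/57.6/41.6 s) are
reproduced exactly.

## Digital phantom and simulator

The vial phantom is a 4 × 4 grid of cylinders covering all combinations of
PDFF {0, 10, 20, 30}% and water T1 {200, 600, 1000, 1400} ms; fat T1 is
300 ms everywhere. R2* defaults to 40 s⁻¹ (a typical agar-emulsion value —
the physical phantom's R2* is not specified) and ψ defaults to 0. Vial
diameter (3 cm) and spacing (4.4 cm) are free parameters of the layout; the
physical phantom's dimensions are not public. Vials are rendered with a
two-voxel anti-aliased proton-density edge, and analysis ROIs (1.4 cm
diameter, centered) never touch the rim, so the edge model cannot affect
quantitative results. **Orientation:** PDFF varies along the fully sampled
readout axis and T1w along the phase-encode axis. This is a deliberate
choice: phase-encode-direction ringing then couples vials that share a
nominal PDFF, keeping fat/water leakage between different-PDFF vials out of
the ROI statistics (with the transposed layout the noiseless FAM bias grows
from ≤1% to ≈1.6% at 3T purely through inter-vial leakage).

The simulator is species-separable: water and fat sub-images are grouped
into discrete T1 classes (exact for the phantom, where T1 is constant per
vial; an approximation for continuous T1 fields), each class's 2D spectrum
is multiplied along the phase-encode axis by its transient (FAM) or
steady-state (constant-flip) signal weights, and the echo image is the
inverse transform. Orthonormal FFTs are used throughout, so Parseval holds
and the k-space complex Gaussian noise SD equals the per-component image
noise SD. A single unit-sensitivity coil is assumed (no coil combination),
readouts are fully sampled and motion-free, and R2* decay is applied at the
echo center only. **Not emulated:** respiratory motion (the method's
motion robustness is an in vivo claim outside what a static simulation can
test), slice profiles, B1+ inhomogeneity, parallel imaging, and bipolar
readouts. Passing tests therefore demonstrate the T1-bias mechanism and its
removal by FAM encoding, not motion robustness or in vivo agreement.

The schematic liver phantom is an ellipse partitioned into nine angular
sectors standing in for the nine-segment whole-liver convention; only the
label bookkeeping is meaningful, not the geometry.

## Fitting

**Magnitude fitting** solves, per voxel, bounded trust-region least squares
of `|W + F·cₙ|·e^(−R2*·TEₙ)` against the magnitude data over (W, F, R2*)
with analytic Jacobian, W, F ≥ 0, R2* ∈ [0, 1000] s⁻¹, and tight tolerances
(1e−12) for deterministic results. Both water-dominant and fat-dominant
initializations are tried and the lower-residual solution kept; at exactly
50% fat the two are degenerate (documented tie). An optional per-species
scaling (g_w, g_f) lets the model match steady-state data exactly, which is
how the noiseless end-to-end recovery tests isolate the T1-bias mechanism.
No Rician noise-floor correction is applied: at the simulated SNRs (≥ 20)
the magnitude-noise bias is below test tolerances.

**Field-map estimation** minimizes
`Σ_v D_v(ψ_v) + λ·Σ_{(v,u)} |ψ_v − ψ_u|` on a discrete ψ grid spanning
±1/(2ΔTE) (step 2 Hz by default; the step must stay below a quarter of the
fat–water ambiguity period `1/ΔTE` or the call errors). `D_v` is the
variable-projection residual of the complex model, minimized over a small
R2* grid. The discrete optimizer is iterated conditional modes with
checkerboard sweeps and a coarse-to-fine initialization (the voxelwise
data-cost minimizer or the best constant field, whichever is cheaper); the
total cost is non-increasing by construction and this is asserted at run
time. ICM is a local optimizer: it can retain plateau artifacts at
intermediate λ that a global min-cut would remove, which is acceptable for
the smooth phantom fields simulated here and is the main known limitation
of the fitting stage.

**Complex fitting** demodulates the estimated ψ, finds R2* by bounded 1-D
search on the variable-projection residual (tolerance 1e−8), and solves
linearly for complex (W, F); magnitudes are reported. An ψ error equal to
the dominant fat–water shift produces the classic water/fat swap
(constructed and asserted in the tests as a documented failure mode).

**Hybrid fitting** minimizes
`w·‖complex residual‖² + (1−w)·‖magnitude residual‖²` per voxel over
(W, F, R2*, common phase), initialized from the complex fit; default
`w = 0.5` (the weighting used by published hybrid methods is not public;
the convex combination is this package's declared surrogate). The endpoints
w = 1 and w = 0 delegate to the pure complex and magnitude fits.

PDFF maps are reported in percent, display-clipped to [−5, 105]% with raw
values retained so statistics are never silently distorted; voxels without
usable signal are flagged invalid (NaN) rather than raising.

## Analysis conventions

ROI summaries average finite voxels; all SDs use the n−1 denominator (the
convention is not otherwise fixed). Agreement coefficients are `1.96·SD` of
the paired differences — limits of agreement between methods, repeatability
coefficient between test and retest, reproducibility coefficient between
field strengths. The reference convention for the vial phantom takes, for
each PDFF group, the T1w = 200 ms vial (closest to the fat T1) measured
with a 1° constant-flip steady-state acquisition, minimizing residual T1
bias in the reference itself (verified ≤ 0.2% in the tests). ROIs whose
summary R2* exceeds 276 s⁻¹ at 1.5T or 397 s⁻¹ at 3T are excluded
(strictly greater-than, so a value exactly at the threshold survives; the
rule is idempotent). The whole-liver value is the unweighted mean of the
available segment means; after exclusion the mean runs over the remaining
segments (no renormalization — a documented choice). Voxel-wise SD maps
across repeated acquisitions serve as the noise surrogate; per-system
normalization divides ROI SD summaries by the reference method's median ROI
SD. Mixed-effects variance decomposition and reader-study statistics are
out of scope; the ROI tables exported here are the raw input such analyses
would consume.

## Problem sizes and determinism

Simulations in the test suite run on 48×48 (or smaller) grids with
proportionally larger vials; the end-to-end bias analyses use the full
144×144 protocol matrices with fitting restricted to ROI voxels, which is
exact for ROI statistics since the per-voxel fits are independent. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`),
repetitions use consecutive seeds, and every pipeline artifact carries the
config hash and seed; re-running from an archived config reproduces outputs
bit-exactly, noise included.
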