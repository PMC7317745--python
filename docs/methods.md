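# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Defaults shown in parentheses are what the code
uses unless overridden.

## Substrates

Both substrates are periodic with continuous coordinates and the cell
spanning `[0, L)` per periodic axis.

**Cylinder lattice (nerve-bundle model).** Parallel, axis-aligned (z)
cylinders with radii drawn from a gamma distribution (shape 5.3316, scale
1.0242e-7 m; 100 cylinders; lattice 1.65e-5 m, periodic in x and y).
Placement is random sequential addition, largest radius first, with
rejection of overlapping positions; if a radius draw cannot be packed
within the retry budget the whole set is re-drawn with a new sub-seed.
At the default parameters the intracellular area fraction lands near
0.4–0.5, comfortably below the RSA jamming limit, so placement succeeds in
one or two draws. Cylinders are non-overlapping under the minimum-image
convention; undulation, dispersion, and myelin-like nested membranes are
out of scope.

**Sphere packing (yeast-suspension model).** 500 equal spheres of diameter
5 µm; the box side is fixed by the target volume fraction (0.62), which is
close to random close packing (~0.64). Random sequential addition cannot
reach this density and naive dilute-start inflation schemes stall, so the
builder seeds the box with a face-centred-cubic lattice (4·5³ = 500 sites;
at φ = 0.62 nearest neighbours still have ~12% of a radius of clearance)
and then disorders it with jitter-and-relax cycles: every centre receives a
uniform random kick on the order of the lattice clearance, and overlapping
pairs are pushed apart symmetrically until none remain (six cycles,
deterministic given the seed, < 1 s). The result is amorphous at short
range while exactly overlap-free at the target density; some medium-range
lattice order survives, which is irrelevant to the isotropically averaged
quantities measured here. Pairs are relaxed to 1e-10 m above contact so
that walkers never encounter a zero-width wedge between touching spheres.

## Random walk with permeable membranes

Walkers take fixed-length steps `ℓ = √(6 D dt)` in directions uniform on
the sphere, with intrinsic diffusivity identical inside and outside cells
(D = 2.0e-9 m²/s). When a step's segment crosses a membrane the walker
transmits with probability `p` (continuing along the same direction from
the crossing point) or reflects specularly; the remaining path length is
consumed iteratively through any further membrane interactions. After each
surface event the walker is nudged 1e-12 m off the surface along the local
normal so the same membrane is not immediately re-detected. In the rare
event that a walker exceeds 4096 surface interactions within one step
(a near-contact wedge), the remainder of that step is dropped; such events
are counted and reported, and the run errors out if more than 0.1% of
walkers are affected (observed rate: ~1 walker in 10⁴ per 1.5e8
walker-steps before the contact-clearance fix; none after).

The transmission probability maps to a membrane permeability `k` (m/s) via

    p = k · √(6 · dt / D),

so the macroscopic exchange rate is independent of the time step; the
package uses this relation in both directions. Under the full-scale time
step (400 ms / 16 000 = 25 µs), p = 0.0001 and 0.00055 correspond to
k = 0.37 and 2.0 µm/s, bracketing physiological membrane permeabilities.

Each walker owns an independent xoshiro256+ stream seeded via splitmix64
from (master seed, walker index), so results are independent of batching
order. Initial positions are uniform over the periodic cell. Membrane
queries use precomputed per-cell candidate lists (objects whose surface
lies within one step length of the cell), making the cost per step O(1).

Two simulation surfaces exist and agree exactly for matching seeds:
a trajectory-storing path (for inspection and small runs) and a
phase-accumulating path that folds each step's position directly into the
gradient phase integral with O(n_walkers) memory.

**Common random numbers.** A permeability sweep reuses the same walker
seed at every transit probability (and the same substrate), so differences
along the sweep are driven by the membrane physics rather than resampling
noise. This is the standard variance-reduction design for monotone
comparisons and matters at reduced walker counts.

## Acquisition synthesis

The DEXSY sequence is two pulsed-gradient pairs (duration δ, separation Δ,
the second lobe sign-reversed) separated by the mixing time `t_m`,
measured from the end of the first pair's second lobe to the start of the
second pair. Defaults: δ = 15 ms, Δ = 17 ms, t_m = 100 ms, G₁ and G₂ from
0 to 900 mT/m in 16 linear steps. Phases are integrated with the
finite-pulse waveform — the walker position at every simulation step
during the pulses contributes, since δ (600 steps) is far from the
narrow-pulse regime. Pulse timings are rounded to whole simulation steps
and the b-values used downstream, `b = γ²δ²G²(Δ − δ/3)` with
γ = 2.675e8 rad s⁻¹ T⁻¹, are recomputed from the rounded timings (at the
default dt they round exactly). The signal is the ensemble cosine mean
(real channel); its per-cell Monte Carlo standard error is attached to the
signal matrix and serves as the noise estimate for regularization. DOSY
uses a single pair with 256 amplitudes; FEXSY fixes the first pair at
68 mT/m (the filter) and varies the encode pair over 0–68 mT/m in 9 steps
at mixing times 0, 10, 100, 200, 300 ms.

The gradient direction is a configurable unit vector; sweeps default to an
axis perpendicular to the cylinder axes (the restriction-sensitive choice)
and the same axis for the isotropic sphere packing. T1/T2 relaxation,
imaging gradients and stimulated-echo storage losses during `t_m` are not
modelled.

## 2D inverse Laplace inversion

The spectrum solves

    min‖K₁ F K₂ᵀ − S‖²_F + α‖F‖²_F   s.t.  F ≥ 0,
    K_i[j,k] = exp(−b_i[j] · D[k]),

on a log-spaced diffusivity grid (64 points, 1e-12 to 1e-8 m²/s). The
lower bound sits below the apparent intracellular diffusivity of
micron-scale compartments under 15 ms pulses — for 5 µm spheres the
Murday–Cotts closed form gives ≈ 9.4e-12 m²/s, and the simulation matches
it to ~1.5% — so the grid brackets every expected peak; the upper bound
can be raised to 1e-7 for perfusion-contaminated in vivo data. Both
kernels are compressed by truncated SVD (singular values ≥ 1e-3 of the
largest; 16 b-values compress to ~8), the standard fast-2D-ILT route. The
constrained solve runs FISTA (accelerated projected gradient) on the
compressed objective: the problem is strictly convex, the iteration is
deterministic (zero start, objective-change tolerance 1e-12, cap 30 000),
and it reaches the same minimizer as active-set NNLS — a test cross-checks
the two on a reduced problem — in well under a second, which matters
because the discrepancy search below solves repeatedly. The 1D (DOSY)
inversion solves its augmented system with active-set NNLS directly.

**Regularization policy.** A caller-supplied α wins. Otherwise, when the
signal carries a noise estimate (Monte Carlo standard errors or a known
synthetic noise level) α is set by the discrepancy principle — bisection
on log α until the Frobenius misfit matches √N·σ within 10% — and for
noiseless input α falls back to a fixed 1e-8 of the largest squared
singular value of the joint kernel: at that level a noiseless
one-component input returns ≥ 95% of its mass within one grid cell with
0.13% round-trip residual. An L-curve strategy (maximum
curvature over a fixed α scan) is also available. The S₀ cell participates
in the fit. A diagnostic warning fires when more than 25% of recovered
mass sits on the grid boundary.

## Peak analysis and the DEI

Cells with amplitude ≥ 1% of the spectral maximum are segmented into
connected regions; regions with multiple internal maxima are split by
watershed; fragments whose centroids lie within 2 grid cells are re-merged
(the known split-diagonal-peak inversion artifact). A peak is diagonal iff
|log₁₀D₁ − log₁₀D₂| at its amplitude-weighted centroid is ≤ 0.15
(boundary inclusive) — wider than one grid cell, narrower than the
intracellular/extracellular separation in both substrates. Diagonal peaks
are labelled A (higher D, extracellular) and B (lower D, intracellular),
off-diagonal peaks C (above the identity line) and D (below). The A
anchor is the highest-D diagonal peak at or below a free-water ceiling
(5e-9 m²/s) — perfusion pseudo-diffusion lies well above it — and any
peak more than a decade above that anchor is left unassigned
(perfusion-like) before labelling and excluded from

    DEI = (V_C + V_D) / (V_A + V_B).

The 1% threshold suppresses the low-amplitude spurious peaks the
regularized inversion is known to produce while retaining the exchange
peaks across the studied permeability range. DEI is invariant to uniform
spectrum rescaling. Absolute DEI values depend on the segmentation
threshold, the diagonal tolerance and the regularization level, so DEI is
best read as a within-study ranking statistic; magnitudes from different
processing chains are not directly comparable.

## FEXSY and the AXR

The ADC at each mixing time is the through-origin least-squares slope of
−log(S/S₀) against the encode b-value, with S₀ the zero-encode signal
after the filter. The recovery model

    ADC(t_m) = ADC_eq · (1 − σ · e^(−AXR·t_m)),

is fitted by bounded nonlinear least squares (AXR ∈ [0, 100] s⁻¹,
σ ∈ [0, 1]) with a deterministic multi-start over AXR. A flat ADC(t_m)
(relative spread < 1e-6) is rejected as unidentifiable rather than
returning an arbitrary rate. With only five mixing times the fit is
noise-sensitive: sub-percent ADC noise visibly scatters the fitted rate
(see `examples/05_fexsy_axr.py`), which is why the rank correlation with
permeability needs either large ensembles or common random numbers, and
why the DEI is the more robust exchange summary.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — a
two-site equilibrium exchange (Kärger-type) picture: intracellular
fraction `f_i`, pool diffusivities, exchange rate `k_ex`, exchanged
fraction `f_ex = 1 − e^(−k_ex·t_m)`, cross weights
`w_C = w_D = f_i(1−f_i)f_ex` by detailed balance, and the remaining mass
split between the diagonal components in proportion to the pool
fractions. Signal noise is zero-mean Gaussian on the real channel with the
matrix renormalized to S(0,0) = 1. It deliberately does **not** model
restricted-diffusion non-Gaussianity, exchange during the encoding blocks,
intra-pool diffusivity distributions, Rician magnitude noise, or
perfusion. Passing the generator-based tests therefore demonstrates that
the inversion/segmentation/DEI chain is correct under the model
assumptions; agreement with walker simulations (which do contain
restriction and in-encoding exchange) is established separately by the
sweep tests.

## Reduced study scales

Full-scale simulations (100 000 walkers, 400 ms, 16 000 steps) are the
package defaults. The test suite and the acceptance script run reduced
versions chosen as the largest sizes that keep a full run in tens of
minutes on one CPU: 20 000 walkers for the sphere sweeps (370 ms when
FEXSY's 300 ms mixing time must fit, with the 25 µs time step retained so
the p↔k mapping is unchanged), 20 000 walkers / 170 ms for the
cylinder DEXSY sweeps, and 10 000 walkers for single-condition runs.
Six transit probabilities span 0.0001–0.00055. At these scales the
Monte Carlo standard error per signal cell is ≤ 1%, and both DEI and AXR
rank perfectly with permeability in the sphere substrate, as does DEI in
the cylinder substrate.

## Numerical conventions and edge cases

- Periodic wrap uses the minimum-image convention; walker steps must be
  shorter than a quarter of the periodic cell (checked).
- The diagonal-band boundary is inclusive; merged peaks take
  volume-weighted centroids.
- Degenerate inversion inputs fail loudly: constant b-vectors are
  rejected as under-determined; rank-deficient kernels after truncation
  report the truncation level; an all-ones signal inverts but warns about
  boundary mass.
- A DEI over peaks with zero diagonal volume, and an AXR over a flat
  ADC(t_m), are errors, not numbers.
- All randomness flows from explicit integer seeds (substrate seed, walk
  seed, noise seed); re-running any configuration reproduces its outputs
  exactly.

## Known limitations

- Apparent intracellular diffusivities here follow restricted-diffusion
  physics (Murday–Cotts-level motional averaging), which for 5 µm cells
  under 15 ms pulses puts the intracellular peak near 0.01e-9 m²/s —
  roughly an order of magnitude below in vitro yeast values, where larger
  effective compartments and membrane water contribute.
- The DEI depends on segmentation and regularization choices (above), so
  only its ordering across conditions, not its absolute value, is treated
  as meaningful.
- Exchange during the encoding blocks is present in the simulation but not
  in the Kärger-type synthetic generator; at high permeability this blurs
  peaks and is part of why spectra collapse.
- No relaxation weighting, no imaging gradients, no noise floor in the
  simulated signal (noise enters only through the synthetic generator or
  real data).
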