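# Methods

`ufdexsy` models diffusion-exchange spectroscopy (DEXSY): a 2D NMR
experiment that correlates a molecule's diffusion coefficient before and
after a mixing time, so that off-diagonal intensity in the resulting D–D
map reveals exchange between physical environments — here water moving
across a surfactant-vesicle bilayer between a free pool (F, fast diffusion)
and an encapsulated pool (E, slow diffusion).  The package implements both
acquisition modes in software: the conventional experiment, which samples an
N×M grid of gradient pairs one repetition at a time, and the single-scan
(ultrafast) experiment, which encodes the first diffusion weighting
spatially along the sample with frequency-swept pulses and reads the second
with a CPMG echo train under a read gradient.

## Spatial encoding (single-scan mode)

A chirp pulse of duration `t_F` sweeping `Δν` under gradient `G_SD` excites
the sample layer by layer; the excitation instant is linear in position and
the affected region spans `z = ±πΔν/(γ G_SD)`.  The paired π/2 and π sweeps
form a double spin echo whose total echo time is affine in z,

    t1(z) = 2 (1 − γ G_SD z / (πΔν)) t_F^{π/2},

and the echo amplitude decays as `exp(−γ²G_SD² t1³ D / 48)` — the /48
because the block is two back-to-back Hahn echoes of duration t1/2 under a
constant gradient (each contributes `γ²G²(t1/2)³D/12`).  As written, t1
spans `[0, 4 t_F^{π/2}]` across the encoding region, while the sequence
narrative describes a span of `[0, 2 t_F^{π/2}]`; this factor-2 ambiguity is
left to the caller via the `t1_prose_convention` flag (default: the explicit
formula).  Excitation is treated as instantaneous (no Bloch integration),
and the quadratic spatial phases of the sweeps — which the symmetric second
pulse pair cancels — are exposed for verification but do not enter the
amplitude-only signal model.

The CPMG read-out decays as `exp(−γ²G_Reff² τ² D t2 / 3)` with τ the
half-echo spacing and `G_Reff` the constant gradient equivalent in area to
the trapezoidal read pulse spread over τ.  T2 terms are available in the
scalar attenuation functions but omitted from the forward kernels: the
package targets the strong-gradient regime in which diffusion dominates.

Default acquisition parameters describe a 400 MHz vesicle study: 15/7.5 ms
sweeps over 144 kHz, G_SD = 508 mT/m, 32 echoes at 8 ms echo time,
G_R = 268 mT/m (0.5 ms ramps, 3.94 ms total), 128 points at 5 µs dwell.
With these values the encoding region is 6.66 mm, the imaging field of view
17.5 mm, and 48 of the 128 pixels fall inside the region.  The nominal
pixel size `FOV/points` with the plateau gradient is 137 µm; the effective
gradient during acquisition (and hence any finer effective resolution) is
not derivable from these parameters, so the planner reports the nominal
value and the encoding/read-out resolution coupling only.

## Two-site exchange

Site magnetizations evolve by `dM/dt = −K M` with

    K = [[k_FE, −k_EF], [−k_FE, k_EF]]   (site order F, E),

whose columns sum to zero (mass conservation) and whose null space under
detailed balance `k_FE x_F = k_EF x_E` is the equilibrium vector.  The total
rate is `k = k_EF + k_FE`; constructing a system from `k` splits it as
`k_EF = k x_F`, `k_FE = k x_E`.  The conventional signal including exchange
during the encodings is

    S(b1, b2) = S0 · 1ᵀ exp(−b1 D) exp(−t_enc K) exp(−τ_M (R1+K))
                     exp(−b2 D) exp(−t_enc K) M,

with `b = Δ γ² G² δ²` (the short-pulse approximation; a Stejskal–Tanner
`Δ − δ/3` correction is available as a flag).  The exchange factors attached
to the encodings are printed dimensionless in the source model; only
rate × time is dimensionless, so they are implemented as `exp(−t_enc K)`
with `t_enc` defaulting to the diffusion delay Δ and configurable (0 removes
them).  Mixing-time peak amplitudes follow the τ_M-dependent factor alone:
`I_ij(τ_M) = [exp(−τ_M(R1+K))]_{ij} M_j`.

## 2D inverse Laplace transform

The map P(D1, D2) ≥ 0 on a log-spaced grid (default 64×64 over
10⁻¹²…10⁻⁸ m²/s) minimises

    ½ ‖K1 P K2ᵀ − S‖²_F + λ ‖P‖₁,   P ≥ 0,

by monotone FISTA: gradient step 1/L with L = ‖K1‖₂²‖K2‖₂², proximal step =
soft-threshold then non-negativity projection, restart to plain ISTA on any
objective increase.  Defaults: 20 000 iterations, relative-objective
tolerance 10⁻⁸; non-convergence is flagged in the diagnostics, never
silent.  The sparsity penalty matches the physical prior of a few discrete
diffusion environments.  λ is per-dataset; `estimate_lambda` chooses it by
the discrepancy principle (smallest candidate whose residual reaches the
expected noise norm `σ√N`).

Two numerical points matter in practice.  First, the direct (CPMG)
dimension encodes slow diffusion weakly (the encapsulated pool decays only
~27 % over 32 echoes), and FISTA converges slowly along that flat
direction, so peak-position readouts should run the solver to convergence
(`max_iter` ≳ 2×10⁵, `tol` ≲ 10⁻¹²); quadrant integrals are far less
sensitive.  Second, a component whose true D falls between grid nodes is
represented as a small cluster of adjacent cells, so peak positions are
read as the amplitude-weighted log₁₀D centroid of the 8-connected cluster
containing the quadrant maximum (`peak_centroid` / `quadrant_peaks`), not
as a single-cell argmax.

## Fitting

`fit_mixing_model` fits the four peak-integral series over mixing time with
free parameters (k, x_F, R1E) and optionally an overall amplitude; T1 of
the free pool is fixed to an independently measured value, mirroring
experimental practice.  Standard errors come from the Jacobian covariance
scaled by residual variance; a seeded residual-resampling bootstrap is
available because the reference analysis does not state its error method.

`fit_full_model` fits the matrix-exponential model to one (b1, b2) surface.
Two identifiability facts shape its defaults:

- With the overall scale S0 free, the single-mixing-time surface determines
  exactly four site-to-site transfer amplitudes while (S0, k, x_F, R1F,
  R1E) are five parameters — an exact flat direction.  S0 is therefore
  fixed by default (normalized data).
- Even with S0 fixed, the surface is nearly flat in k once exchange is
  saturated on the experiment's time scales (k τ_M ≫ 1): the equilibrium
  vector is a fixed point of `exp(−t_enc K)`, so k enters only through
  O((R1E−R1F)/k) corrections, and a 1 % change in k moves the signal by
  parts in 10⁻⁶.  The fitter handles this by profiling over k (coarse grid
  then bounded scalar refinement, all other parameters re-optimised) so
  noiseless surfaces recover every parameter to <0.1 %.  With noise at
  SNR ~100, however, x_F and both diffusivities remain well determined
  while k and the T1 split are not — their estimates scatter far beyond
  their local standard errors.  Rate constants should be fitted from
  mixing-time series, not from a single-τ_M surface, whenever noise is
  present.

Vesicle sizing uses the Stokes–Einstein diameter `d = k_B T/(3πηD)` with
default T = 298 K and η = 1.13 mPa·s (90 % D₂O / 10 % H₂O solvent; D₂O-rich
water is ~20 % more viscous than H₂O, and the exact value is a required,
recorded parameter since the sizing scales with 1/η).  The aqueous core of
a bilayer vesicle is `d_outer − 4 × monomer length` (two monomer lengths of
wall on each side).

## Synthetic data

The generator emulates the study conditions end to end: a two-site system
with D_F = 1.9×10⁻⁹ and D_E = 6.0×10⁻¹¹ m²/s, x_F = 0.76, k = 28 s⁻¹ split
by mass conservation, T1F = 10.86 s, R1E = 8.5 s⁻¹; the single-scan profile
grid (48 z-rows × 32 echoes) whose joint (D1, D2) weights follow
`exp(−τ_M(R1+K))`; the conventional 16×16 surface over the 26.7–508 mT/m
gradient ramp (δ = 2.6 ms, Δ = 100 ms); additive real Gaussian noise at a
configurable SNR (max signal / σ), seeded and bit-reproducible; and an
optional schematic corruption of the two edge rows and the centre row of
the spatial profile, standing in for imperfect sweep-pulse onset, which
preprocessing (`trim_and_map`) removes before inversion along with rows
outside the encoding region.

What the generator does not emulate: complex-domain noise and phase errors
(noise is added to magnitude profiles), off-resonance and relaxation during
the sweeps, field inhomogeneity, temperature drift, and the actual
artefact profiles of a spectrometer.  Passing tests therefore demonstrate
the correctness and self-consistency of the forward models, the inversion
and the fits under the stated noise model — not instrument-level fidelity.
In particular, the reference study's measured constants (k = 28 ± 6 s⁻¹,
x_F = 0.76, R1E = 8.5 s⁻¹ and the rest) are NOT recomputed from
experimental data, which is unavailable; they serve as generating ground
truths of synthetic recovery experiments, and every quantitative claim this
package makes is a claim about recovery.

## Problem sizes and seeds

Recovery experiments use the 48×32 single-scan grid or the 16×16
conventional grid, 64×64 inversion grids, 6 mixing times (0.03–5 s), SNR
100, and 5–10 noise seeds with medians reported; these sizes keep the full
suite and the acceptance script in the minutes range while leaving every
recovered quantity comfortably inside its tolerance.  All stochastic steps
take explicit integer seeds; the solver itself is deterministic.
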