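# ufdexsy

Ultrafast diffusion-exchange NMR (DEXSY) in software: forward simulation of
both the conventional multi-repetition experiment and the single-scan,
spatially encoded variant; 2D inverse Laplace transformation of the signal
into D–D exchange maps; and two-site exchange-kinetics fitting.

It is written for NMR spectroscopists and methods developers who want to
prototype, validate or teach diffusion-exchange analyses without a
spectrometer: every acquisition step of the experiment has a faithful
numerical counterpart, and every analysis step runs on synthetic data whose
ground truth is known.

## The experiment in brief

DEXSY correlates a molecule's diffusion coefficient before and after a
mixing time τ_M.  For water in a surfactant-vesicle dispersion there are
two pools — free water (D_F ≈ 1.9×10⁻⁹ m²/s) and water encapsulated inside
vesicles (D_E ≈ 6×10⁻¹¹ m²/s, the vesicle's own diffusivity) — and
off-diagonal peaks in the D–D map count molecules that crossed the bilayer
during τ_M.  Conventionally each of the N×M gradient pairs needs its own
repetition (50×50 grid → 2500 repetitions → tens of hours).  The
single-scan variant encodes the first diffusion weighting spatially,

    t1(z) = 2(1 − γG_SD z / πΔν) t_F^{π/2},   E1 ∝ exp(−γ²G_SD² t1³ D1/48),

with chirped pulses under a gradient, and reads the second with a CPMG
train under a read gradient, E2 ∝ exp(−γ²G_Reff² τ² D2 t2/3), acquiring the
whole 2D surface in one shot.  The map P(D1, D2) is recovered by an
ℓ1-regularised, non-negative inverse Laplace transform (iterative
soft-thresholding / FISTA), and the four peak integrals versus mixing time
are fitted with first-order two-site exchange kinetics,
I_ij(τ_M) = [exp(−τ_M(R1+K))]_ij M_j, giving the exchange rate k, the pool
fractions and the encapsulated-pool relaxation rate.  Details, defaults and
identifiability caveats: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a six-mixing-time study at SNR 100, invert every dataset, and fit
the kinetics (`examples/exchange_kinetics.py`):

```python
import ufdexsy as u

result = u.run_uf_study(
    u.decanoate_water_system(),          # D_F=1.9e-9, D_E=6.0e-11, x_F=0.76, k=28
    u.default_encoding_block(),          # 15 ms / 144 kHz chirps, 508 mT/m
    u.default_cpmg_readout(),            # 32 echoes, 8 ms echo time
    mixing_times=[0.03, 0.1, 0.3, 1.0, 3.0, 5.0],
    snr=100.0, seed=0,
)
```

```
tau_M [s]   I_FF    I_EE    I_FE    I_EF
   0.03   0.686   0.105   0.082   0.086
   0.10   0.600   0.031   0.117   0.128
   ...
fitted:  k = 25.7 1/s (k_EF = 19.7, k_FE = 6.0), x_F = 0.766, R1E = 9.87 1/s
truth :  k = 28.0 1/s (k_EF = 21.3, k_FE = 6.7), x_F = 0.760, R1E = 8.50 1/s
```

The cross peaks (I_FE, I_EF) start at zero, grow as water crosses the
bilayer, and decay again once T1 relaxation — faster in the encapsulated
pool — wins; the fit recovers the generating rate within ~10 % at this
noise level.  Sizing the vesicles from the slow pool
(`examples/vesicle_sizing.py`):

```
vesicle hydrodynamic diameter: 6.44 nm
aqueous core diameter:         1.64 nm (bilayer wall = 2 x 1.2 nm per side)
```

The other examples cover the encoding geometry and acquisition planning
(`sequence_geometry.py`), a single map inversion with artefact trimming
(`exchange_maps.py`), and the full matrix-exponential fit of a conventional
surface (`full_model_fit.py`).

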