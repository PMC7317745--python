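# dexsy

Monte Carlo feasibility modelling of **diffusion exchange spectroscopy
(DEXSY)** measurements of cell membrane permeability.

Water exchange across the cell membrane changes in cancer, apoptosis and
neurodegeneration, making it an attractive imaging biomarker — but it is
hard to measure. DEXSY applies two diffusion encodings separated by a mixing
time `t_m`: spins that move between intracellular and extracellular pools
during `t_m` appear as **off-diagonal peaks** in a 2D diffusivity spectrum,
while non-exchanging spins stay on the diagonal. This package simulates the
whole measurement chain in silico so the relationship between membrane
permeability and the observed exchange signal can be studied quantitatively:

1. **Substrates** — a nerve-bundle model (parallel cylinders, gamma-distributed
   radii) and a yeast-suspension model (500 spheres, 5 µm diameter, packing
   fraction 0.62), both periodic.
2. **Random walks** — fixed-step walkers (`√(6 D dt)`) with specular
   reflection at membranes and transmission probability `p` per encounter,
   related to the permeability `k` (m/s) by `p = k √(6 dt / D)`.
3. **Acquisition** — finite-pulse phase integration of DEXSY
   (`δ = 15 ms, Δ = 17 ms, t_m = 100 ms`, `G₁, G₂ = 0–900 mT/m`, 16×16),
   DOSY (256 amplitudes) and FEXSY (filter 68 mT/m, 9 encode steps,
   `t_m = 0…300 ms`) sequences, with
   `b = γ²δ²G²(Δ − δ/3)` per gradient pair.
4. **Inversion** — the 2D inverse Laplace transform of
   `S/S₀ = Σ p(D₁,D₂) e^(−b₁D₁) e^(−b₂D₂)`:
   truncated-SVD kernel compression, then Tikhonov-regularized non-negative
   least squares on a 64×64 log-spaced diffusivity grid.
5. **Analysis** — peak segmentation and labelling
   (A extracellular / B intracellular / C, D exchange), the
   **Diffusion Exchange Index** `DEI = (V_C + V_D) / (V_A + V_B)`, and the
   FEXSY apparent exchange rate from
   `ADC(t_m) = ADC_eq (1 − σ e^(−AXR·t_m))`.

A synthetic-data generator (two-site equilibrium exchange with Gaussian
noise) makes every downstream stage testable without running walkers.

## Worked example

`examples/02_random_walk.py` checks the walker physics and the
permeability mapping:

```
free diffusion: MSD / (6 D t) = 0.9720 (should be ~1)
impermeable spheres: 0 compartment changes across 3000 walkers (should be 0)
intracellular walker fraction 0.622 (packing fraction is 0.62)
transit probability 0.0001 <-> permeability 0.37 um/s
transit probability 0.00055 <-> permeability 2.01 um/s
```

`examples/06_permeability_sweep.py` runs the full chain at three membrane
transit probabilities (3000 walkers each, ~1 min):

```
 probability  permeability_m_per_s      dei  axr_per_s  seed
     0.00010          3.651484e-07 0.096567        NaN    11
     0.00028          1.022415e-06 0.261374        NaN    11
     0.00055          2.008316e-06 0.443065        NaN    11
Spearman rho of DEI vs permeability: 1.0
```

Each row gives the transit probability, the membrane permeability it
implies, and the DEI measured from the inverted spectrum: more permeable
membranes put more spectral volume into the exchange peaks, and the DEI
ranks perfectly with permeability. The other examples cover substrate
construction, spectrum inversion and peak labelling, the synthetic
ground-truth chain, and AXR fitting.

A thin CLI wraps the same library calls, e.g.:

```sh
dexsy build-substrate --kind spheres --out yeast.txt
dexsy make-synthetic --k-ex 2 --out signal.txt
dexsy invert --signal signal.txt --out spectrum.txt --plot spectrum.png
dexsy peaks --spectrum spectrum.txt --out peaks.tsv
```

Acquired DEXSY matrices in the documented delimited-text format (first
row/column = gradient amplitudes, header records `δ, Δ, t_m, γ`) can be
ingested with `dexsy.ingest_acquired` and processed with the same
inversion/peak/DEI chain.

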