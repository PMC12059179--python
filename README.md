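# ktrkit

Desk-scale analysis toolkit for the biophysics of RCK-gated bacterial K⁺
channels of the KtrAB family. The package bundles, as one tested and
reproducible pipeline, the quantitative analyses used to characterize how a
short intrinsically disordered region (IDR) at the N-terminus of the pore
subunit KtrB couples nucleotide exchange in the cytosolic KtrA ring to
channel gating:

* **Trajectory observables** — fraction of native contacts *Q* between the
  IDR and the KtrA surface, residue–lipid contact counts, distributions of
  the vertical distance *z* to the membrane phosphate plane, and the
  end-to-end terminus length.
* **Pore profiling** — inscribed-sphere pore radius along the channel axis
  (a simplified HOLE-style scan) and the location of the gating
  constriction.
* **2D-class shape classification** — long/short diameters of ring-shaped
  negative-stain class averages and the oval (ADP state) vs square
  (ATP state) call at the diameter-ratio threshold 1.115.
* **Biophysical fits** — melting temperatures from differential scanning
  fluorimetry (first-derivative peak), one-site ITC binding fits (Wiseman
  isotherm), and Michaelis–Menten kinetics from whole-cell K⁺-uptake time
  courses.
* **DEER distance inversion** — forward simulation of dipolar evolution
  traces and model-free recovery of interspin distance distributions by
  non-negative Tikhonov regularization with L-curve selection.
* **Synthetic data** — seeded generators for every input above, so the
  whole pipeline runs and verifies without any external download.

## The statistics at the core

The fraction of native contacts of a configuration *X* is

```
Q(X) = (1/N) Σ_(i,j)  1 / (1 + exp[β (r_ij(X) − λ r⁰_ij)])
```

summed over the N heavy-atom pairs (i, j) — IDR residues 7–13 against the
KtrA surface — closer than 4.5 Å in the reference structure, with β = 5 Å⁻¹
and λ = 1.5. Residue–lipid contacts use a 3.5 Å heavy-atom cutoff, one
count per residue–lipid pair per frame.

The DEER form factor is F(t) = ∫ K(t, r) P(r) dr with the powder-averaged
dipolar kernel K(t, r) = ∫₀¹ cos[(1 − 3x²) ω_dd t] dx, ω_dd = 2π·D/r³,
D = 52.04 MHz nm³. P(r) is recovered from

```
min_p ‖K p − F‖² + α² ‖L p‖²   subject to p ≥ 0
```

with L the second-difference operator and α chosen at the L-curve corner.

Binding thermograms follow the exact single-site mass balance per injection
(with syringe-dilution correction), uptake kinetics the textbook
Y = V_max·X/(K_M + X).

## Worked example

```python
import numpy as np
from ktrkit import deer, fits, synthetic

# one-site binding: simulate a 20 x 2 µL titration at K_D = 3.4 µM and refit
tg = synthetic.generate_itc_thermogram(
    synthetic.ThermogramParams(kd=3.4, dh=-10.0, noise_sd=0.02, seed=1))
print(fits.OneSiteBindingModel(tg).fit().summary())

# DEER: forward trace from a Gaussian P(r) at 3.3 nm, invert it
r = np.arange(1.5, 8.0 + 1e-9, 0.02)
dist = deer.gaussian_distribution(r, 3.3, 0.15)
trace = synthetic.generate_deer_trace(
    synthetic.DeerTraceParams(distribution=dist, noise_sd=0.005, seed=1))
print(deer.TikhonovInverter(deer.background_correct(trace)).fit().summary())
```

prints

```
One-site binding fit (Wiseman isotherm)
----------------------------------------------
parameter         estimate     std err
K_D (µM)             3.415      0.0188
dH (per mol)           -10     0.00894
n (sites)                1    0.000663
residual norm: 0.0493 on 20 injections

Non-negative Tikhonov inversion (L-curve)
--------------------------------------------
alpha (L-curve corner) : 10
mode distance          : 3.291 nm
mean distance          : 3.277 nm
95% width              : 0.937 nm
residual norm          : 0.5853
```

The fitted K_D lands on the generating 3.4 µM within the noise, and the
recovered distance distribution peaks at the 3.3 nm ground truth — the same
round-trip logic the test suite applies to every stage.

A command-line surface wraps the same stages
(`ktrkit synth | contacts | pore | shape | fit-dsf | fit-itc | fit-mm |
deer-sim | deer-invert | report`); `ktrkit report --seed 1 --out out/` runs
the full demo pipeline and writes a manifest whose hash is identical across
reruns with the same seed.

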