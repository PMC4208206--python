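# watercolumn

Water-column correction toolbox for shallow-water benthic remote sensing —
coral-reef habitat mapping in particular.

## The problem

A satellite or airborne sensor looking at a reef does not see the seafloor:
it sees the seafloor *through* a water column that absorbs and scatters
light. The measured reflectance over a submerged substrate mixes two
signals — photons backscattered by the water body and photons reflected by
the bottom — and the bottom share shrinks exponentially with depth z and
with the diffuse attenuation coefficient K_d(λ). Mapping benthic habitat
(coral sand, algae, seagrass) from imagery therefore requires removing the
water-column effect to recover the bottom albedo ρ_b(λ), or at least a
depth-invariant quantity that separates substrates.

This package implements the full family of correction approaches used in
that field, the forward models needed to simulate test data, and an
inter-comparison harness:

* **optics_core** — radiometric conventions (`Spectrum`, irradiance
  reflectance R = E_u/E_d, remote-sensing reflectance ρ^RS = L_w/E_d in
  sr⁻¹, R = π·ρ^RS for a Lambertian water body), the air–water interface
  conversion ρ^RS(0⁻) = ρ^RS(0⁺)/(0.5 + 1.5 ρ^RS(0⁺)), Beer–Lambert
  attenuation E_d(z) = E_d(0⁻)e^(−K_d z), the penetration depth
  z₉₀ ≈ 2.3/K_d, and a bio-optical parameterization that maps constituent
  concentrations (chl-a, CDOM, detritus, two particle classes) to
  absorption a(λ), backscattering b_b(λ), u = b_b/(a+b_b), k = a+b_b and
  K_d = k/cos θ_s. Four canonical water types span clear oceanic
  (water-a) to turbid Case-2 (water-d) conditions.
* **forward_models** — two reflectance models over a submerged bottom:
  the two-flow model `R_w = R_∞ + (ρ_b − R_∞)e^(−2 K_d z)` and the
  semi-analytical quasi-single-scattering model
  `ρ^RS(0⁻) = ρ^RS_∞(1 − e^(−(1/cosθ_s + D_uC/cosθ_v) k z)) +
  (ρ_b/π) e^(−(1/cosθ_s + D_uB/cosθ_v) k z)` with
  D_uC = 1.03(1+2.4u)^0.5 and D_uB = 1.04(1+5.4u)^0.5; a rational
  single-bounce form with user-supplied Monte-Carlo coefficients; deep
  water closed by ρ^RS_∞ = (0.084 + 0.17u)u; parametric coral sand /
  green algae / brown algae albedo spectra.
* **band_correctors** — depth-invariant band-combination indices
  (Lyzenga log-ratio index and its K_d,i/K_d,j regression, the
  fixed-coefficient three-band variants, the sequential two-slope
  high/low-albedo partition, the known-depth index ∝ ρ_b, PCA rotation of
  log-differences) and pseudo-invariant-feature gain/offset normalization
  for multi-temporal stacks.
* **algebraic_correctors** — per-wavelength inversions that return an
  actual ρ_b spectrum: the two-flow inversion
  `ρ_b = (R − R_∞)e^(+2 K_d z) + R_∞`, the semi-analytical inversion, an
  above-surface variant with the 1/0.54 interface factor, a depth-free
  pseudo-depth correction that preserves spectral hue, a single-term
  exponential correction, and the rational-form inversion. Every
  retrieval carries per-wavelength validity flags.
* **matching** — spectral-library (LUT) construction over
  water/depth/bottom grids, spectral-angle-mapper classification, seeded
  multiplicative noise, and a bounded 7-parameter least-squares mixture
  inversion (a_phy(440), a_g(440), b_bp(440), three endmember weights,
  z).
* **benchmark** — the 48-scenario inter-comparison (4 waters × 4 depths
  × 3 bottoms): bottom-contribution percentages, validity filtering
  (contribution ≥ 0.5%, retrieved ρ_b inside (0,1), bottom-path
  attenuation above 0.0002), retrieval uncertainty, one-at-a-time
  sensitivity surfaces, detectable wavelength ranges and SAM confusion
  matrices.
* **io / cli** — plain-text spectrum and scene serialization, WorldView-2
  band preset (427/478/546/608/659/724/831/908 nm centers; correction
  restricted to ≤ 700 nm), boxcar band integration, per-pixel raster
  correction with flag rasters, fixture generation, and a `watercolumn`
  command with verbs `simulate / correct / classify / benchmark /
  sensitivity / fixtures`.

## Worked example

Simulate a green-algae bottom at 5 m in moderately turbid water with the
two-flow model, then invert the same model to recover the albedo:

```python
import numpy as np
import watercolumn as wc

grid = np.arange(400.0, 701.0)
water = wc.WATER_TYPES["water-b"]
bottom = wc.make_bottom("green_algae", grid)
geom = wc.Geometry()                      # nadir sun and view

iops = wc.build_iops(water, geom, grid)
deep = wc.deep_water_reflectance(iops)
scene = wc.Scenario(water, bottom, 5.0, geom)

rw = wc.m94_forward(scene, iops, deep)    # R(0-) over the bottom
result = wc.m94_invert(rw, deep, iops.kd, 5.0)

for wl in (450, 550, 650):
    i = int(np.where(grid == wl)[0][0])
    print(f"{wl} nm: Kd={iops.kd[i]:.4f} m^-1  R(0-)={rw.values[i]:.5f}  "
          f"rho_b true={bottom.values[i]:.5f}  retrieved={result.rho_b[i]:.5f}  "
          f"valid={bool(result.valid_mask[i])}")
print("z90 at 550 nm: %.1f m" % wc.penetration_depth_z90(iops.kd[grid == 550.0][0]))
```

prints

```
450 nm: Kd=0.0722 m^-1  R(0-)=0.02736  rho_b true=0.02591  retrieved=0.02591  valid=True
550 nm: Kd=0.0692 m^-1  R(0-)=0.08473  rho_b true=0.14951  retrieved=0.14951  valid=True
650 nm: Kd=0.3479 m^-1  R(0-)=0.00434  rho_b true=0.05342  retrieved=0.05342  valid=True
z90 at 550 nm: 33.2 m
```

Reading it: attenuation is weak in the blue-green (K_d ≈ 0.07 m⁻¹, so the
effective penetration depth z₉₀ ≈ 33 m) and an order of magnitude stronger
in the red, where only 0.4% reflectance survives the round trip to 5 m.
The same-model inversion recovers the albedo exactly; with real data the
errors come from misestimated K_d, depth and deep-water reflectance, which
is what the sensitivity analysis in `watercolumn.benchmark` quantifies.

The classification route, end to end:

```python
from watercolumn.benchmark import run_intercomparison
report = run_intercomparison(seed=1, n_seeds=25)
print(report["accuracy_by_class"])
# {'coral_sand': 96.75, 'green_algae': 91.0, 'brown_algae': 94.0}
```

which builds a 37,680-spectrum library, classifies 25 noisy realizations
of the 48 scenario spectra by minimum spectral angle, and reports
seed-averaged per-class accuracies (the misclassifications concentrate in
the two turbid Case-2 waters).

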