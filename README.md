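# afplight

Light-transport modelling and photoacoustic (PA) field analysis for an
**annular fiber probe** (AFP): a hollow cannula carrying 72 multimode
fibers (100 µm core, NA 0.22) in a ring between a 2.3 mm and a 3.4 mm
ferrule, built so a radiofrequency-ablation device can slide through its
lumen while the fibers illuminate tissue *interstitially* for PA-guided
needle placement and ablation monitoring.

The package is for researchers designing or characterizing interstitial
illumination probes. It provides:

- a voxelized **Monte Carlo photon transport** kernel (MCML conventions:
  exponential steps with `μt = μa + μs`, partial weight absorption
  `w·μa/μt`, Henyey–Greenstein scattering, Russian roulette), compiled
  with numba, with an independent plain-Python reference implementation
  for validation;
- tabulated **liver optical properties** (native and 70 °C-ablated, at
  650/900/1050 nm) and the conversion `μs = μs′/(1−g)`;
- the depth-resolved **fluence homogeneity statistic**
  `NFR_rel(z) = 100 · mean(NFR in a centered 1.96 mm ROI) / max(NFR in slice)`
  and its optimal (most homogeneous) depth;
- a perturbative **PA forward model** (`p ∝ Γ · μa · Φ`) with
  field-of-view summaries: on-axis penetration depth and lateral field
  width at dB thresholds;
- ROI-based **image SNR** `20·log10(S_R/S_n)` with sub-ROI resampling
  uncertainty, and synthetic phantoms/images with known ground truth for
  every analysis.

See `docs/methods.md` for model details and assumptions.

## Worked example

Simulate the 72-fiber ring in native liver at 650 nm and find the depth
where the beam becomes most homogeneous:

```python
from afplight import (annular_layout, homogeneous_grid, nfr_rel_profile,
                      optimal_depth, simulate, table_properties)

grid = homogeneous_grid(table_properties("native", 650))   # 4 x 4 x 5 mm
layout = annular_layout(n_fibers=72)                        # ring r = 1.425 mm
volume = simulate(grid, layout, photons_per_fiber=100_000, seed=1)
profile = nfr_rel_profile(volume)                           # NFR_rel(z), %
print(f"conservation residual: {volume.conservation_residual():.2e}")
print(f"optimal depth: {optimal_depth(profile):.2f} mm")
```

```
conservation residual: 8.71e-13
optimal depth: 2.00 mm
```

The residual confirms every launched photon's weight is accounted for
(deposited + escaped). The 2 mm optimum says the ring of 72 discrete
spots has diffused into its most homogeneous transverse profile about
2 mm in front of the probe — shallower slices show a ring-shaped pattern,
deeper slices a centered Gaussian-like spot. Ablated liver, which
scatters roughly four times more strongly, reaches its optimum nearer
1.5 mm, and longer wavelengths (weaker scattering) push the native
optimum deeper.

The same pipeline is scriptable from the shell:

```sh
afplight simulate --config run.yaml --out out/native650
afplight homogeneity out/native650 --out out/profile.csv
afplight pa-field --mu-a 0.5 --out out/liver_field.csv
```

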