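# Methods

`afplight` models the light delivery of an annular fiber probe (AFP): a
hollow cannula whose distal face carries 72 multimode fibers (100 µm core,
NA 0.22) in a ring between a 2.3 mm inner and a 3.4 mm outer ferrule. The
probe is inserted into tissue so that light is delivered interstitially,
and the fluence it produces drives photoacoustic (PA) imaging of nearby
absorbers. The package answers three questions about such a probe: how the
fluence in front of the ring homogenizes with depth, what PA field of view
the fluence supports, and how well structures stand out in the resulting
images.

## Photon transport

Light propagation is simulated with a voxelized Monte Carlo model using
standard MCML conventions:

- step length `s = -ln(ξ)/μt`, with `μt = μa + μs` taken from the voxel at
  the photon's current position;
- at each interaction the photon deposits the fraction `μa/μt` of its
  weight and scatters into a new direction drawn from the
  Henyey–Greenstein phase function with the local anisotropy `g`;
- weights below 1e-4 face Russian roulette: survival probability 1/10 with
  a tenfold weight boost;
- photons leaving the grid are terminated and their remaining weight booked
  as escaped. The refractive index is uniform (n = 1.33 in every region),
  so there is no Fresnel reflection or refraction at internal boundaries.

Fluence is scored with the collision estimator (each interaction adds
`w/μt` to its voxel). Where `μa > 0` this is algebraically identical to
the deposited-energy estimator `absorbed/(μa·V)`; in non-absorbing
scattering regions it remains defined, covering the degenerate case. The
normalized fluence rate (NFR) of a voxel is its score divided by voxel
volume and total launched photons, i.e. fluence per unit incident power in
1/cm².

Two bookkeeping choices matter for reproducibility:

- **Exact conservation.** Russian roulette transfers killed weight into the
  escaped total and debits survivor boosts from it, so
  `launched = deposited + escaped` holds to machine precision on every run
  (the escaped total therefore contains the zero-mean roulette residual).
  A conservation residual above 1e-6 relative aborts the run.
- **Per-fiber RNG streams.** Each fiber draws its launch states and its
  transport randomness from streams keyed by (seed, fiber index), so a run
  is bit-reproducible and independent of fiber ordering.

The step rule uses the departure voxel's `μt` for the full hop and the
arrival voxel's coefficients for the interaction. For homogeneous media —
every headline analysis here — this is exact. Near internal boundaries of
heterogeneous scenes it biases interaction placement at the scale of one
mean free path; layered scenes should therefore be read as qualitative.

An independent plain-Python reference implementation
(`afplight.reference`) restates the same physics with the
standard-library RNG and no vectorization; the test suite compares the two
on small grids.

## Probe and launch model

Fibers sit equally spaced on a circle of radius 1.425 mm — the midpoint of
the ferrule annulus, since the exact radius within the annulus is not
specified for the physical probe — with emission axes parallel to the
probe axis. Launch positions follow a radially Gaussian spot with
σ = core_radius/2 truncated at the core radius (the 2σ contour matches the
physical core); the polar launch angle is Gaussian with σ = θmax/2
truncated at θmax = asin(NA/n) ≈ 9.52°, the emission cone narrowed by the
tissue index; azimuth is uniform. The physical beam is specified only as
"Gaussian" with NA 0.22, so these truncation conventions are package
choices, fixed for reproducibility and configurable per fiber.

A collinear `surface_layout` stands in for the six-fiber bundle used for
extracorporeal illumination; its exact holder geometry is not documented,
so the arrangement (line of sources flanking the transducer position,
normal incidence) is approximate.

## Tissue optics

Native and thermally ablated (70 °C) liver properties at 650/900/1050 nm
are tabulated presets; `μs'` and `g` are authoritative and
`μs = μs'/(1−g)` is derived on demand. No interpolation between the three
wavelengths is offered — only these were characterized, and interpolating
would invent data. The liquid intralipid/India-ink phantom uses g = 0.7, a
standard intralipid-like value (the phantom recipe fixes only μa and μs');
chicken-mimicking media use μa = 0.1 cm⁻¹, μs' = 10 cm⁻¹, and blood
inclusions default to μa = 4 cm⁻¹ (within the quoted 2–7 cm⁻¹ whole-blood
range near 760 nm).

## Homogeneity statistic

For each transverse slice at depth z,

    NFR_rel(z) = 100 · mean(NFR over a centered 1.96 × 1.96 mm ROI) / max(NFR in slice)

The optimal depth is the argmax of NFR_rel. Because the slice maximum is
an extreme-value statistic, per-slice profiles at desk-scale photon counts
are noisy; slices are averaged into 0.25 mm depth bins (centers on
multiples of the width) before the argmax, and depths shallower than
0.1 mm are excluded — the first voxel layers contain launch-position
artifacts. Bin width, cutoff and ROI side are configurable; the ROI snaps
to the nearest voxel-aligned square and the effective side is recorded.

Two variance-reduction tools are available for the argmax, which sits on
a flat plateau (neighbouring bins differ by well under one percentage
point for the weakly scattering native tissue at 900/1050 nm):

- **Replicate averaging** (`average_profiles`): binned NFR_rel profiles
  from independent-seed runs are averaged before the argmax — plain Monte
  Carlo averaging of the statistic, converging to the estimator's
  expectation. The headline depth analyses average three replicate runs
  for native tissue and two for ablated.
- **Dihedral symmetrization** (`FluenceVolume.symmetrized_d4()`): an
  axis-centered ring whose fiber count is divisible by 4 is invariant
  under the square grid's eight symmetry operations, so averaging the
  volume over them is an unbiased ~8× variance reduction. Note that it
  changes the sampling distribution of the slice maximum (an extreme-value
  statistic), so NFR_rel values from symmetrized and raw volumes are not
  interchangeable; the depth analyses use replicate averaging of raw
  volumes, which preserves the statistic's definition exactly. Do not
  apply symmetrization to asymmetric layouts or heterogeneous media.

## Problem sizes

The physical-scale simulation of record (≈4.9 µm voxels, 3×10⁶ photons per
fiber) is far beyond interactive use. The package's desk-scale defaults
are 0.05 mm voxels on a 4 × 4 × 5 mm grid and 10⁵ photons/fiber for the
72-fiber ring (7.2×10⁶ photons, tens of seconds per run on one CPU with
the compiled kernel). The depth-binned homogeneity statistics are stable
at this scale; the residual seed-to-seed jitter of the binned argmax is
about one 0.25 mm bin on the flat plateaus of the low-scattering native
curves at 900/1050 nm. Field-of-view runs use a coarser, wider grid
(24 × 24 × 16 mm at 0.2 mm) because the PA field spans ±10 mm laterally.

## PA forward model

PA amplitude of an embedded absorber is `Γ · μa,abs · mean(NFR over the
absorber voxels)` with `Γ` a Grüneisen-like constant (relative units,
default 1): initial pressure is proportional to absorbed optical energy
density. The absorber is perturbative — the fluence is computed once for
the absorber-free medium — which is a first-order approximation justified
by the thinness of the reference target (0.19 mm line) relative to the
field. Maps over absorber positions are normalized to their maximum and
expressed as `20·log10(A/Amax)` dB (pressure-like convention); penetration
depth is the greatest on-axis depth above a dB threshold and field width
the lateral extent above a threshold at fixed depth, both linearly
interpolated between samples. Acoustic propagation, transducer bandwidth
and image reconstruction are outside the model, so measured dB maps are
matched in shape and trend, not absolute value.

## Image SNR

`SNR = 20·log10(S_R/S_n)` on normalized pixel values, with S_R the mean
over a signal ROI and S_n the mean over a background region. Images are
normalized by their maximum; a min-max rescaling was considered and
rejected because subtracting the image minimum breaks the ratio's scale
invariance and zeroes constant backgrounds. Uncertainty follows the
source study's procedure of re-estimating S_R several times: 10 randomly
placed sub-ROIs of about half the signal area (count configurable),
reported as mean ± standard deviation. The reported mean is the full-mask
SNR so closed-form cases are exact. Frame averaging is a pixelwise mean;
averaging N zero-mean-noise frames raises SNR by ≈ 20·log10(√N) dB.

## Synthetic data

The generator reproduces the study's scenes with known ground truth:
homogeneous liver volumes with the tabulated presets; the liquid phantom
with tunable μa/μs' and 0.19 mm line absorber; layered chicken(/liver)
blocks with a slab target at 15 or 32 mm, a 1 mm-ID blood tube, a
tumor-mimicking inclusion, and an ablated-liver lesion; and 2D PA-like
images whose structures are drawn at exact dB contrasts over mean-one
log-normal speckle (so region means, hence SNR, are unbiased). What the
synthetic images do **not** emulate: reconstruction artifacts,
transducer bandpass effects (tube signals appearing only at walls), and
system gain — passing metric tests shows the statistics are computed
correctly, not that real images will reach the same values. The metal
ablation tines are drawn structures in images only; they are not modelled
optically.

## Known limitations

- Heterogeneous transport carries the one-mean-free-path boundary bias
  described above.
- The probe's ferrules, sheath and epoxy are not optical boundaries; any
  reflectivity of the steel face behind the launch plane is unmodelled.
- The lateral 4 mm extent of the default grid truncates wide-angle
  scattered light for deep slices; the extent is configurable for
  sensitivity checks.
- dB thresholds from beamformed measured images include system gain; the
  simulated −20/−35 dB contours reproduce trends and orders of magnitude
  only.
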