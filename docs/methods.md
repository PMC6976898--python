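# Methods

## Transport model

The engine simulates steady-state photon transport through a cubic voxel
volume (default 36 mm side). Each voxel carries an optical quadruple
(μₐ, μₛ, g, n): absorption and scattering coefficients in 1/mm, the
Henyey–Greenstein anisotropy (mean cosine of the single-scattering
deflection), and the refractive index. Weighted photon packets are launched
with unit weight from a collimated rectangular source flush with the top
face and traced voxel-by-voxel (3-D digital differential traversal):

* **Scattering distances** are sampled as an exponential optical depth
  consumed against μₛ, re-accumulated across voxels whose μₛ differs. At
  each scattering site the deflection cosine is drawn from the closed-form
  Henyey–Greenstein inversion, azimuth uniform.
* **Absorption is continuous** (no absorption collisions): over a segment of
  length ℓ the weight is attenuated by `exp(−μₐℓ)` and the fluence tally of
  the traversed voxel receives the exponentially weighted track length
  `w(1 − exp(−μₐℓ))/μₐ` (`wℓ` when μₐ = 0). This estimator has two useful
  exactness properties: in a pure absorber the tallied depth decay equals
  Beer–Lambert with zero variance, and the absorbed-energy ledger equals
  Σ μₐ·Φ·V identically, so energy-conservation checks close to floating
  point rather than to Monte Carlo noise. A consequence of this design is
  that the hop length between scattering events in a homogeneous medium is
  exponential with mean 1/μₛ (not 1/μₜ as in collision-based schemes);
  either choice is an unbiased estimator of the same transport equation.
* **Interfaces**: when adjacent voxels differ in n (only in the phantom,
  milk n = 1.338 over gelatin n = 1.5), unpolarized Fresnel reflection /
  Snell refraction is applied at the shared face, with total internal
  reflection where applicable. Within the tissue studies n is uniform (1.4)
  and no internal events occur. All six outer faces absorb: photons crossing
  them permanently escape (tallied in the escape ledger). Photons enter
  through the source footprint with no specular entry loss (fiber pressed
  flush with the skin; no air gap or coupling gel is modeled).
* **Termination**: Russian roulette below weight 10⁻⁴ with survival
  probability 0.1 (survivor weight ×10). The signed weight created/destroyed
  by roulette is ledgered so `launched = absorbed + escaped + roulette_net +
  residual` holds exactly per run.
* **RNG**: counter-based splitmix64; every photon derives its stream from
  (seed, photon index), so results are bit-reproducible and independent of
  execution order. Every study condition draws its own seed by hashing the
  master seed with the condition labels.

The fluence grid is normalized to the total launched energy (units 1/mm²)
and then averaged with its mirror image across the imaging plane (x = 0),
which restores the symmetry of the physical dual-fiber-bundle probe while
simulating only one source.

A pure-Python reference engine implements the same rules independently of
the compiled kernel and is compared against it in the test suite at small
photon counts.

## Geometry and conventions

z is depth from the tissue surface, y runs along the transducer array, x is
the lateral offset from the imaging plane (the x = 0 mid-plane). The source
footprint (25 mm along y × 1.4 mm along x) is centered at (x = D, y = 0) on
the surface; the emission direction is tilted θ from +z toward −x, so the
central ray crosses the imaging plane at depth D/tanθ. The surface layer
(skin, or milk in the phantom) occupies `round(thickness/pitch)` top voxel
layers; a nonzero thickness that rounds to zero layers, or whose realized
thickness deviates more than 25% from the request, is rejected with a
suggestion to refine the pitch. At the 0.15 mm working pitch the 0.3 mm
mouse skin is exact (2 layers) and the 2.0 mm human skin is realized as
1.95 mm (13 layers).

## Reported quantities

* **ROI depth profile**: mean fluence over voxels with |x| ≤ 0.25 mm and
  |y| ≤ 10 mm, per z layer. At 0.15 mm pitch the x band covers the 4 voxel
  columns whose centers fall in the band (0.6 mm), the closest realizable
  to the nominal 0.5 mm.
* **Peak fluence**: profile maximum; ties break toward the shallower depth.
  "Maximum fluence" for the species ratio is the peak of the ROI depth
  profile maximized over the angle grid (the alternative reading — a single
  region-average — is not used; the profile peak is what the sweep tables
  store).
* **Species ratio**: that maximum with 0.3 mm skin divided by the one with
  2.0 mm skin, per tissue/wavelength.
* **Kernel SNR**: the ROI x band is collapsed by averaging into a (y, z)
  plane slice (a one-voxel slice at coarse pitch would make kernel
  statistics degenerate); a 0.5 × 0.5 mm kernel slides over it; per-voxel
  SNR = kernel mean / kernel std; flat kernels (std = 0, e.g. untouched
  deep voxels) are excluded; the plane average and minimum are reported.
  SNR grows as √(photon budget), which the tests verify over three budgets.

## Optical properties

The bundled table (`palight/data/optical_properties.tsv`) lists skin, fatty
and fibrous tissue at 700/800/900/1064 nm (all with g = 0.9, n = 1.4), and
the phantom materials milk (0.02, 7, 0.7, 1.338) and gelatin
(0.012, 0.05, 0.85, 1.5) at 1064 nm, gelatin's absorption/scattering
approximating water. Intermediate compositions are convex combinations of
the fatty and fibrous rows in μₐ and μₛ; they are always computed from the
endpoints, never tabulated. The test suite compares computed mixtures with
independently rounded published values: μₐ agrees at the printed precision;
μₛ is compared at 1% relative tolerance because the published mixed rows
were evidently rounded from unrounded endpoint values that are not
available (e.g. 5.666 computed vs 5.68 published at 40% fat).

## Study design and problem sizes

The study scale of record is 50 µm voxels with 10⁹ photons per condition
(`--preset full`); all desk and CI work uses scaled-down budgets at 0.15 mm
voxels, where one condition costs seconds to minutes instead of hours. The
derived quantities are ratios and argmaxes of ROI averages, which are
robust to this coarsening within the tolerances used:

* unit/property tests: 10³–10⁶ photons (the exact oracles are
  budget-independent);
* end-to-end findings tests: 10⁵ photons per condition for the ratio
  matrix (peak-fluence CV ≈ 1%, against 20% tolerances),
  0.5–3 × 10⁵ for optimal-angle checks (more where the angle margin is a
  few percent, less where it is a sub-percent near-tie that no affordable
  budget resolves);
* `scripts/acceptance.py`: 10⁵ photons per condition for ratio and distance
  targets, 1.5–2.5 × 10⁵ for optimal-angle targets (three master seeds
  each), ≈15 minutes total on one CPU.

At 10⁵ photons the peak-fluence CV is around 1%, so ratio statistics carry
≈1.5% Monte Carlo error — small against their 20% tolerances.

## Known limitations

* **Near-tie optimal angles through thin skin.** With 0.3 mm skin the peak
  fluences at 32.5° and 45° differ by under about 1% (measured at 10⁶–
  3×10⁶ photons at 0.15 and 0.075 mm pitch; the ordering is not resolvable
  at affordable precision and does not sharpen with finer voxels). The
  published finding that 45° is optimal with mouse skin — with 32.5° noted
  as "almost identical" — sits inside that band. Optimal-angle results for
  the thin-skin cases should therefore be read as "32.5°–45°, a near-tie";
  the thick-skin fibrous optimum (20°, ≈5% margin) is robust. The
  acceptance checks report the computed argmax honestly and may disagree
  with the printed single angle on the near-tie cases.
* The transducer body is not present (no shadowing), the source is
  perfectly collimated (no numerical aperture), anatomy is planar, and no
  acoustic propagation, beamforming or clutter modeling is included.
* The synthetic rod-scan generator emulates exactly the multiplicative
  structure (system factor once on PA, twice on US) under which the
  square-root US normalization is exact, plus i.i.d. multiplicative noise.
  Real acquisitions add effects outside that structure — beam obliquity
  varying with angle, transducer shadowing, speckle — so passing the
  recovery tests validates the normalization algebra and pipeline, not the
  acquisition physics.
* Full-scale outputs (e.g. the study-scale plane-average kernel SNR ≈ 15)
  are only reachable at the full preset; desk runs verify the √N
  convergence law instead and extrapolate.
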