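# palight

Voxel Monte Carlo simulation of **light delivery for combined
ultrasound/photoacoustic (US/PA) probes** — a linear transducer array with
external fiber-bundle illumination — across tissue types, wavelengths, and
skin thicknesses.

## The problem

In PA imaging the signal from an absorber is proportional to the local laser
fluence, so probe designers want to know how the fiber geometry — the offset
`D` between the light emission area and the transducer's imaging plane, and
the emission angle `θ` tilting the beam toward that plane — controls the
fluence delivered along the imaging plane. Crucially, the answer depends on
the highly scattering **skin layer**: ~0.3 mm thick in mice, ~2 mm in
humans. A thin layer preserves the beam's ballistic directionality (so
aiming at the plane with an intermediate angle pays off), while 2 mm of skin
fully diffuses the light (so shallow angles that keep energy near the
surface deliver more). The same probe therefore behaves differently in a
mouse study and in the clinic, and the package quantifies that gap.

## What it computes

The engine is a weighted-photon voxel Monte Carlo: collimated rectangular
source (25 × 1.4 mm² footprint at offset `D`, tilted `θ` from the depth
axis), Henyey–Greenstein scattering with anisotropy `g`, continuous
absorption `exp(−μₐℓ)` along each voxel segment with an exponentially
weighted track-length fluence tally, Snell/Fresnel handling of
refractive-index steps, Russian roulette termination, absorbing outer
boundaries, and mirror-averaging of the fluence across the imaging plane.
Fluence is normalized to the delivered energy (units 1/mm²).

On top of the engine:

* ROI **depth profiles** — fluence averaged over a 0.5 × 20 mm region
  centered on the imaging plane, per depth;
* **angle and distance sweeps** (θ = 20–70° in 12.5° steps at D = 7 mm;
  D = 5–13 mm at θ = 45°) and their peak fluences;
* the **species ratio** — max-over-angles peak fluence with 0.3 mm skin
  divided by that with 2.0 mm skin, per tissue/wavelength (fatty, fibrous,
  and fatty/fibrous mixtures from the bundled optical-property table);
* a **phantom validation** stage: milk-over-gelatin scene at 1064 nm, a
  synthetic graphite-rod scan generator (PA ∝ fluence × system factor, US ∝
  system factor², multiplicative noise, 4 repeats), and the square-root US
  normalization that cancels the depth-dependent system factor;
* a kernel **SNR convergence score** (mean/std over a 0.5 × 0.5 mm sliding
  kernel on the imaging-plane slice).

## Worked example

```python
from palight import metrics
from palight.optics_db import TissueSpec
from palight.sweeps import StudyPlan, run_angle_sweep

plan = StudyPlan(voxel_pitch=0.15, n_photons=300_000, master_seed=1)
mouse = run_angle_sweep(TissueSpec("fibrous", 700), 0.3, plan)
human = run_angle_sweep(TissueSpec("fibrous", 700), 2.0, plan)
print(mouse.table)
print("ratio:", round(metrics.species_ratio(mouse.peaks, human.peaks), 2))
```

prints (≈60 s on one CPU):

```
   theta_deg      peak  peak_depth_mm
0       20.0  0.002115          3.225
1       32.5  0.002260          3.225
2       45.0  0.002237          3.675
3       57.5  0.002003          3.675
4       70.0  0.001612          3.075
ratio: 2.27
```

i.e. for low-scattering fibrous bulk at 700 nm, an intermediate angle is
best through mouse-thickness skin (32.5° and 45° are a statistical tie
here), the peak fluence sits ~3 mm deep, and
the imaging plane receives ~2.3× more light than through human-thickness
skin — the mouse-to-human translation penalty for this condition.

The numbered drivers under `analysis/` run the full studies (angle factorial
and ratio matrix, distance falloff, phantom validation with synthetic scans,
SNR convergence, skin-scattering sections) and write tables under
`results/`. The `palight` CLI exposes the same pipelines
(`palight run`, `angle-sweep`, `distance-sweep`, `phantom`,
`section-figure`); YAML configs mirror all flags.

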