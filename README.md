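# aortaflow

Velocity-based level set segmentation and wall shear stress quantification
for 4D flow MRI of the thoracic aorta.

4D flow MRI acquires, over ~25 cardiac frames, a magnitude volume plus three
phase-difference volumes encoding the blood velocity vector in every voxel.
Haemodynamic biomarkers such as wall shear stress (WSS) require an accurate
lumen segmentation at systole, but vessel boundaries are low-contrast in the
anatomical images. `aortaflow` implements a segmentation pipeline that
exploits the *velocity* field instead, for researchers working with aortic
4D flow data (and anyone who needs its individual pieces: phase-offset
correction, PC-MRA synthesis, STAPLE fusion, DSC/Hausdorff evaluation,
near-wall WSS estimation).

## The method

Given the velocity field **v** (cm/s), the Gaussian-weighted velocity
structure tensor and its sorted eigenvalues λ₁ ≥ λ₂ ≥ λ₃ rank the locally
dominant flow directions:

```
M = G_σ * (v vᵀ),        R = 4 λ₁ λ₂ / (λ₁ + λ₂)²  ∈ [0, 1]
```

`R = 0` where one direction dominates (free lumen), `R → 1` where two
directions coexist — the signature of a vessel wall during a flow jet. A
signed distance function φ (negative inside) evolves under

```
φ_t + (χ − R) |∇φ| = 0,      χ = H_ε(|v| − δ)
```

where χ is a smoothed Heaviside gate (threshold δ, ramp half-width ε): the
front grows through high-velocity lumen and is arrested where R rises at the
wall. The front starts from an Otsu-thresholded synthetic angiography
(PC-MRA, `mean_t m·|v|^{2γ}` with γ = 0.2) and is frozen outside a permissive
PC-MRA support mask that excludes noise-dominated regions. Post-processing
keeps the largest 26-connected component and applies a 3 mm morphological
opening.

Around the core sit: Craiem-style phase-offset correction (3rd-degree
polynomial OLS fit to stationary tissue, subtracted from all frames), STAPLE
expectation–maximisation fusion of multiple observers' masks, Dice /
Hausdorff (mm) evaluation per aortic region with paired t-tests, and WSS via
marching-cubes surface extraction and an exact no-slip parabolic fit
(τ_w = μ·(4 v_t1 − v_t2)/(2h), μ = 3.2 cP).

Patient data are not distributed; `aortaflow.phantom` generates synthetic
flow phantoms (straight or U-bend tubes, Poiseuille flow, Rician/Gaussian
noise, polynomial phase offsets) with analytic ground truth — including the
closed-form wall shear stress 2 μ v_max / R — so every stage is testable.

## Worked example

```python
import aortaflow as af

# U-bend aorta analogue: 64³ voxels at 2 mm, 25 frames, 10 mm radius,
# 100 cm/s systolic peak, 2 cm/s velocity noise
cfg = af.PhantomConfig(geometry="u_bend", noise_sd=2.0, seed=7)
ds, truth = af.make_tube_phantom(cfg)

result = af.segment_dataset(ds, af.PipelineConfig(delta=0.55 * cfg.v_peak))
print("systolic frame:", result.systolic_frame)
print("level set iterations:", result.report["levelset_iterations"],
      "(converged:", str(result.report["levelset_converged"]) + ")")

report = af.regional_metrics(result.mask, truth.lumen_mask, truth.region_labels)
print(f"whole-vessel DSC: {report.whole.dsc:.3f}   HD: {report.whole.hd_mm:.1f} mm")
for name, rm in report.regions.items():
    print(f"  {name:22s} DSC {rm.dsc:.3f}   HD {rm.hd_mm:.1f} mm")

mesh, wss = af.compute_wss(result.mask, ds.velocity[..., result.systolic_frame, :])
summary = af.regional_max_wss(wss, mesh, truth.region_labels, ds.spacing)
print(f"max WSS (whole): {summary['whole']:.3f} Pa")
```

prints:

```
systolic frame: 8
level set iterations: 225 (converged: True)
whole-vessel DSC: 0.952   HD: 2.0 mm
  ascending incl. arch   DSC 0.957   HD 2.0 mm
  descending thoracic    DSC 0.944   HD 2.0 mm
  abdominal              DSC 0.954   HD 2.0 mm
max WSS (whole): 1.326 Pa
```

The detected systolic frame matches the phantom's waveform peak; DSC ≈ 0.95
means the automatic mask overlaps 95% of the true lumen, with no boundary
point further than 2 mm (one voxel) away. The max WSS exceeds the noise-free
analytic value (0.640 Pa for this tube) because a per-vertex maximum is an
extreme statistic of a noisy gradient estimate — the absolute difference
against the ground-truth mask's estimate on the same data is 0.22 Pa, which
is the comparison the evaluation module reports.

A CLI mirrors the library (`aortaflow phantom | preprocess | angio | systole |
discontinuity | segment | postprocess | fuse | evaluate | wss | run`); see
`aortaflow --help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the two analytically forced values of the
discontinuity function by building seeded velocity fields with one and with
two equally dominant flow directions and pushing them through the structure
tensor → eigenvalue → R chain.
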