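# pcammd — PCA-space multimaterial decomposition for dual-energy CT

`pcammd` quantifies iodine in dual-energy CT. Given a pair of virtual
monoenergetic images (VMIs, e.g. 70 and 150 keV), every voxel provides a
2-vector of Hounsfield units, μ(x) = (μ_L(x), μ_H(x)). With the volume
conservation constraint Σᵢ αᵢ = 1, three material fractions can be solved
per voxel — geometrically, the voxel is expressed in barycentric
coordinates of a triangle of basis materials in attenuation space. The
package targets the people who work with such maps: medical-physics and
image-analysis researchers evaluating iodine quantification accuracy,
residual (false-positive) iodine error, and virtual noncontrast (VNC)
imaging on photon-counting or conventional dual-energy scanners.

Two decomposition methods share a six-material library (air, water,
lipid, collagen, iodine, hydroxyapatite) partitioned into five
physiological triangle domains:

* **`BarycentricMMD`** — the classical benchmark: per voxel, solve

  ```
  [ μ_L,1  μ_L,2  μ_L,3 ] [α₁]   [ μ_L ]
  [ μ_H,1  μ_H,2  μ_H,3 ] [α₂] = [ μ_H ]
  [   1      1      1   ] [α₃]   [  1  ]
  ```

  domain by domain in declaration order, keeping the first feasible
  solution (all αᵢ ∈ [0, 1]); when none is feasible the nearest triangle
  is used and the raw solution may leave [0, 1] — the method's known
  failure mode under noise.

* **`PCAMMD`** — fits a 2-D PCA on the voxel cloud
  (C = X̃ᵀX̃/(N−1) = WΛWᵀ), rotates measurements and library vertices into
  the principal frame, and computes barycentric coordinates from signed
  triangle areas, λᵢ = A(p′, vⱼ′, vₖ′) / A(v₀′, v₁′, v₂′), never by matrix
  inversion. Voxels are assigned in three passes — (1) interior
  containment, smallest centroid distance dₖ = ‖p′ − cₖ′‖ among containing
  triangles; (2) edge adherence within a tolerance; (3) orthogonal
  projection onto the nearest edge of any triangle, recomputing λ at the
  projected point. Every voxel ends with λᵢ ∈ [0, 1], Σλᵢ = 1, by
  construction.

Around the decomposition: concentration conversion (C = f_iodine ×
20 mg/mL against the rod-calibrated iodine vertex), RMSE, weighted
unity-line regression, residual error (% of the measured 2 mg/mL
insert), CV with Excellent/Good/Acceptable categories, SSDE dose
arithmetic (AAPM-204 f-factors), VNC synthesis by iodine subtraction,
and a synthetic dual-energy thorax phantom (iodine rods 2–20 mg/mL,
calcium rods 50–400 mg/mL, lung/soft-tissue/bone background, three body
sizes, dose-scaled noise) so the whole stack is testable without
scanner data.

## Worked example

```python
from pcammd import (build_default_library, PhantomSpec, render_dual_energy,
                    decompose_pca, decompose_bc, fraction_to_concentration,
                    evaluate_quantification)

lib = build_default_library()
spec = PhantomSpec(size_class="large", dose_fraction=0.25, seed=42)
volume, rois = render_dual_energy(spec, lib)

for name, run in (("PCA-MMD", decompose_pca), ("BC-MMD", decompose_bc)):
    maps, _ = run(volume, lib)
    conc = fraction_to_concentration(maps.fraction("iodine"))
    rep = evaluate_quantification(conc, rois)
    print(f"{name}: slope={rep.slope:.3f}  R2={rep.r2:.4f}  "
          f"RMSE={rep.rmse_iodine:.3f} mg/mL  residual={rep.residual_error_percent:.1f}%")
```

prints

```
PCA-MMD: slope=0.906  R2=0.9922  RMSE=0.880 mg/mL  residual=47.0%
BC-MMD: slope=0.955  R2=0.9965  RMSE=0.519 mg/mL  residual=51.7%
```

Reading the numbers: the regression slope and R² describe linearity of
estimated vs. true rod concentration across the seven iodine rods; RMSE
is the absolute accuracy in mg/mL; the residual is the mean
false-positive iodine signal in calcium and lung ROIs as a percentage of
the measured 2 mg/mL insert. On this synthetic phantom the noise is
independent per channel — far harsher than scanner VMIs, whose channels
are strongly correlated — so both methods show large residuals; the PCA
method still suppresses residual error below the benchmark while keeping
every fraction physical (the benchmark emits fractions far outside
[0, 1] here). On noise-free phantoms the PCA method recovers all rod
concentrations exactly (slope 1.000, RMSE < 1e-9 mg/mL); see
`docs/methods.md` for what the synthetic noise model does and does not
show.

The same workflow is available from the shell:

```sh
pcammd simulate --size large --dose 0.25 --seed 42 --out scratch/phantom
pcammd decompose --method pca --in scratch/phantom --out scratch/frac
pcammd evaluate --fractions scratch/frac --rois scratch/phantom --out scratch/metrics.csv
pcammd vnc --in scratch/phantom --fractions scratch/frac --out scratch/v
```

## Library sensitivity: the three-material mixture study

A voxel mixing 40% water, 40% lipid, 20% iodine-rod material falls, under
the default five-domain library, into the water–air–iodine domain and its
iodine content is underestimated; augmenting the library with a
water–lipid–iodine domain restores exact recovery:

```python
from pcammd import MaterialDomain, augment_library
aug = augment_library(lib, MaterialDomain(("water", "lipid", "iodine")))
```

This is the built-in demonstration that false-negative iodine bias is a
property of the library configuration, not of the solver.

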