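# Methods

## Problem and model

Dual-energy CT yields two attenuation measurements per voxel. Under the
ideal-solution mixing model, a voxel containing volume fractions αᵢ of
three basis materials satisfies two linear attenuation equations plus
the volume-conservation constraint Σαᵢ = 1 — a 3×3 linear system, or
equivalently the barycentric coordinates of the measurement point within
a triangle of basis materials in the (μ_L, μ_H) plane. Because no triple
of materials spans all tissue, the attenuation plane is partitioned into
several three-material domains and each voxel is decomposed only within
its assigned domain.

Both implemented methods are deterministic, voxel-independent, and
parameter-light. They differ in (a) how coordinates are computed and
(b) how voxels are assigned to domains, especially voxels that noise has
pushed outside every triangle.

### Benchmark (first-feasible barycentric search)

Domains are scanned in declaration order; the first whose 3×3 solve
gives all fractions in [0, 1] (within 1e-9) wins. If none is feasible
the domain nearest in attenuation space is selected — for a single point
against a closed triangle the directed Hausdorff distance reduces to the
minimum Euclidean distance, which is what we implement — and its raw
solution is returned with a `feasible=False` flag. Those solutions can
lie far outside [0, 1]; preserving them faithfully is the point of the
benchmark.

### PCA-space three-pass method

A 2-D PCA (mean over all voxels, covariance with 1/(N−1), eigenvalues
descending) defines a rigid rotation of the measurement plane; voxels
and library vertices are projected with W. Coordinates are computed as
signed-area ratios (no matrix inversion); assignment is:

1. **Interior pass** — containing triangles are those with all
   λᵢ ∈ [−ε, 1+ε] (ε = 1e-6) and Σλ ≈ 1; among them the triangle with
   the smallest centroid distance wins.
2. **Edge pass** — otherwise, triangles with an edge within ε_edge of
   the point are candidates, again resolved by centroid distance.
3. **Projection pass** — otherwise the point is projected orthogonally
   onto the nearest point of the union of all triangle edges, exact
   distance ties resolved by centroid distance and then declaration
   order, and coordinates are recomputed at the projection.

After assignment, any coordinate marginally outside [0, 1] (round-off on
an edge, typically −1e-16) is clamped and the triple renormalized, which
makes the physicality guarantee — every fraction in [0, 1], per-voxel
sum 1 within 1e-9 — literally testable over arbitrary inputs, including
pure noise.

Because W is orthonormal, containment, centroid distances, edge
distances and barycentric coordinates are identical in the original and
rotated frames; the estimator's `rotation="identity"` mode exploits this
for single-point studies, and a property test asserts the equivalence.
The practical differences from the benchmark are therefore exactly the
selection rule (centroid distance instead of declaration priority) and
the constrained projection (bounded instead of extrapolated fractions).

## Material library

Six materials at 70/150 keV, stored in HU. Barycentric coordinates are
invariant under the per-energy affine map between linear attenuation and
HU, so the HU formulation is equivalent to one in cm⁻¹ and requires no
scanner spectra. Values derive from an embedded elemental
mass-attenuation grid (NIST-style total-with-coherent tabulations at
60/80/100/150 keV, log-log interpolated; oxygen anchored so water
reproduces its reference values exactly, making the HU scale exact by
construction). `scripts/make_attenuation_table.py` regenerates the
derived table. Mid-Z entries (N, P, Ca) are accurate to a few percent,
which shifts only the collagen and hydroxyapatite vertices slightly; no
reported quantity depends on them at that precision.

| material | HU @70 keV | HU @150 keV | note |
|---|---|---|---|
| air | −1000 | −1000 | HU definition |
| water | 0 | 0 | HU definition |
| lipid | −119.6 | −86.5 | triolein, ρ = 0.915 |
| collagen | +257.4 | +284.8 | dry collagen, ρ = 1.35 |
| iodine | +518.2 | +97.5 | water + 20 mg/mL I (rod vertex) |
| hydroxyapatite | +583.8 | +403.8 | water + 400 mg/mL HA (rod vertex) |

Contrast vertices are *rod-calibrated*: the iodine vertex is the
attenuation of the 20 mg/mL reference rod modeled as a dilute solution
(solute adds attenuation without displacing water), so fraction →
concentration is exactly linear with zero intercept (C = f × 20 mg/mL).
The hydroxyapatite vertex is analogously the 400 mg/mL calcium rod
rather than pure mineral; this keeps the phantom's calcium rods and the
library on the same water–HA edge with physical HU, and a pure-mineral
vertex is a one-line config change (`reference_concentration` and the
`composition` recipe are both library-file fields).

The five default domains capture the common physiological interfaces:
air–soft tissue (air, water, collagen), fat–muscle (lipid, water,
collagen), bone–soft tissue (water, collagen, hydroxyapatite), iodine
near air (water, air, iodine), and calcified tissue with iodine (water,
iodine, hydroxyapatite). Non-physiological triples such as
air–iodine–hydroxyapatite are deliberately excluded. The exact triples
are declared in `data/default_library.yaml` and overridable; declaration
order is meaningful (benchmark priority and tie-breaking) and preserved
by serialization.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `epsilon_inside` | 1e-6 | dimensionless (barycentric) | containment slack, pass 1 |
| `epsilon_edge` | 1e-6 | HU | edge-adherence band, pass 2 |
| `feasibility_tol` | 1e-9 | dimensionless | benchmark feasibility slack |
| degeneracy floor | 1e-9 | HU² | minimum triangle area |
| iodine reference | 20 | mg/mL | fraction→concentration scale |
| HA reference | 400 | mg/mL | calcium-rod edge scale |

`epsilon_edge` deserves a note: the containment tolerance is
dimensionless while the edge test compares a distance in HU, so a 1e-6
band is nearly inert — almost all out-of-triangle voxels go to pass 3,
whose projection subsumes the edge case. We keep the literal default for
fidelity and expose the parameter; a test demonstrates pass 2 engaging
at a widened band.

## Quantification metrics

* RMSE over ROI mean concentrations vs. truth.
* Weighted least-squares unity-line fit (C_est = m·C_ref + c); weights
  default to equal and may be 1/SD² of repeated measurements (the
  uncertainty-weighting convention); R² = 1 − SS_res/SS_tot computed on
  the estimated values.
* Residual error % = mean false-positive iodine concentration over all
  calcium and lung ROIs, divided by the measured concentration of the
  2 mg/mL insert, × 100. ROI statistics are volumetric means across the
  ROI's full z-extent.
* CV % across repeated acquisitions, categorized half-open:
  [0, 2) Excellent, [2, 5) Good, [5, 10) Acceptable, ≥ 10 Poor. The
  half-open convention removes the overlap ambiguity of the usual
  "<2 / 2–5 / 5–10" phrasing.
* SSDE = CTDI_vol × f(D_w), f linearly interpolated on the integer-cm
  AAPM-204 body table (materialized from the published exponential fit)
  and rounded to two decimals by default, matching how protocol tables
  print the factor. Note the directionality: 34.7 mGy × 1.72 = 59.7 mGy
  even though protocol tables derived in the reverse direction (CTDI
  from a target SSDE) print 59.6; the function computes forward and the
  rounding convention is a parameter.
* VNC = contrast VMI − f_iodine × (HU_iodine vertex − HU_water) at the
  VMI energy (low-energy/70 keV by default, configurable); linear in HU,
  equivalent up to the water offset to a formulation in attenuation
  units.
* Paired two-sided t-test on |error| differences with 95% CI, with a
  zero-variance guard (identical samples → Δ = 0, p = 1).

## Synthetic phantom: what it emulates, what it does not

The generator renders a thorax-like scene — body ellipse of soft tissue
(water + collagen, ≈30 HU), two lung fields (air + water, ≈−800 HU), a
spine insert (water + HA, ≈400 HU), and a ring of twelve rods (iodine
2, 2.5, 5, 7.5, 10, 15, 20 mg/mL; calcium 50–400 mg/mL) — every region
an exact mixture of library vertices. Rod edges are rendered with
area-weighted partial volume (supersampled rims) to exercise the
out-of-triangle passes; a hard-edge mode supports exact-recovery tests.
ROI masks (eroded rod interiors, lung ellipses) and the role/expected-
concentration table are emitted alongside.

Noise is additive Gaussian, independent per channel and voxel,
σ = σ_ref·√(1/dose)·size_factor with σ_ref = (12, 9) HU at full dose and
size factors 1.0/1.3/1.7 for small/medium/large (D_w 20.9/27.3/33.2 cm).
The default grid is 5×128×128 at (3, 2.5, 2.5) mm — large enough for
stable ROI statistics, small enough that full multi-seed studies run on
a laptop; the geometry is resolution-independent (defined in normalized
units), so denser grids are a parameter change.

What passing tests show: algorithmic correctness (exact recovery on
noise-free edges, the physicality guarantee under extreme noise, the
direction of the residual-error difference between the methods), not
scanner-level performance. Real VMI pairs have strongly *correlated*
noise between energies, plus beam hardening, scatter, and
reconstruction texture, none of which are simulated; with independent
channel noise the perpendicular scatter off the material manifold is
exaggerated, so absolute residual percentages here are far larger than
on scanner data, and the projection pass's clamping introduces a
visible shrinkage bias (regression slope slightly below 1) that the
unbounded benchmark does not share. Conclusions supported by the
synthetic studies are therefore directional and structural, not
absolute-accuracy claims.

## Numerical choices

* Eigenvector sign convention: each column's largest-magnitude entry is
  made positive; with equal eigenvalues the stable sort preserves the
  eigensolver's order, so an isotropic cloud maps to the identity. The
  decomposition is invariant to all of this; the convention only
  stabilizes serialized models.
* Degenerate voxel cloud (all measurements identical): zero covariance
  triggers a warning and an identity rotation.
* Ties: every selection (containing triangles, adhering edges, nearest
  edges, nearest fallback triangle) resolves by smallest centroid
  distance first, then declaration order. Exact floating-point ties on
  a shared edge may assign either owning domain; the fractions are
  identical either way (the shared vertices carry all the weight).
* Chunked evaluation bounds memory at ~40 MB per 2¹⁸-voxel block; a test
  asserts chunking does not change results bitwise.

## The mixture sensitivity study

For a synthetic voxel of 40% water, 40% lipid, 20% iodine-rod material,
the default library has no water–lipid–iodine domain; the voxel falls
inside water–air–iodine and the iodine fraction is underestimated
(0.169 with this library's vertices — the exact value is a linear
function of the lipid vertex's spectral spread, f = 0.2 + 0.4·(L₇₀ −
L₁₅₀)/(I₇₀ − I₁₅₀), so it moves with the lipid surrogate and rod recipe
chosen). Appending a water–lipid–iodine domain restores exact recovery
(0.200) through the ordinary centroid-based pass-1 selection. This
isolates false-negative iodine bias as a library-configuration effect,
not a solver effect.

## Known limitations

* Two energies, three materials per voxel; no spectral modeling of
  polychromatic beams, beam hardening, or scatter.
* No spatial regularization — decompositions are independent per voxel
  by design, preserving noise texture.
* The synthetic noise model is a stand-in (see above), and σ defaults
  are plausible placeholders, not measured scanner values.
* Accuracy within a domain depends on how well the basis vertices match
  the true object composition; the library file exists precisely so
  users can substitute measured rod recipes or alternative protein/lipid
  surrogates.
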