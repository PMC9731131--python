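# wmh3d

Shape, texture and growth-potential analysis of 3D white-matter
hyperintensity (WMH) lesions from FLAIR MRI.

WMH lesions — bright regions in T2-FLAIR images of cerebral white matter —
vary widely in size, shape and intensity texture, and those characteristics
appear to relate to how likely a lesion is to grow. `wmh3d` takes a FLAIR
volume plus a co-registered binary lesion mask (e.g., an LST/LPA probability
map thresholded at 0.5; segmentation itself is out of scope) and computes,
per connected lesion:

- **3D Zernike shape descriptors.** Each lesion is volume-normalised,
  centred in a cube mapped into the unit ball, and expanded in the
  orthogonal basis `V_nlm(r,θ,φ) = R_nl(r) Y_lm(θ,φ)` built from real
  orthonormal spherical harmonics and radial polynomials with
  `R_nl(1) = 1`, `∫₀¹ R_nl R_n'l r² dr = δ_nn'/(2n+3)`. The moments are
  `Z_nlm = (2n+3) ∫_B f · V_nlm dV`, and the per-(n,l) vector norms
  `‖Z_nl‖ = sqrt(Σ_m Z_nlm²)` form a rotation-invariant descriptor
  (2,601 dimensions at order 100; 15,876 at order 250). Both basis tables
  use stable recursions, so orders up to 250 are usable in double
  precision; truncated reconstructions and symmetric-difference error
  rates quantify how much shape detail an order preserves.
- **Fuzzy intensity histograms.** After discarding the dimmest 1% of
  voxels and min–max normalising, each intensity splits its unit mass
  linearly between the two nearest of 10 bin centres `(2j+1)/20`; the
  unit-sum histogram is a rotation- and size-invariant texture feature.
- **Cluster structure.** Descriptors (after PCA keeping 99.8% variance)
  and histograms are clustered by K-means restarted from 1,000 random
  row draws (lowest within-cluster dispersion W_k wins); the number of
  clusters is chosen by the gap statistic,
  `Gap(k) = (1/B) Σ_b log W*_kb − log W_k` against B = 30 uniform
  reference draws, selecting the smallest k with
  `Gap(k) ≥ Gap(k+1) − s_{k+1}`.
- **Potential Growth Index (PGI).** The penumbra of each lesion is split
  into l = 5 one-voxel dilation shells; shell voxels with intensity
  `f ≥ m − 2.5σ` (m, σ pooled over the subject's lesion voxels; 2.5σ
  admits 99.38% of lesion-like intensities under a Gaussian model) count
  as growth voxels, weighted `w_i = i / Σ_j j` so outer shells count
  more: `PGI = Σ_i GV_i w_i / Σ_i V_i ∈ [0,1]`.

A seeded synthetic-phantom generator (ellipsoids, tori, sphere unions with
smooth intensity falloff, configurable penumbra halos and Gaussian noise)
makes every stage testable without patient data, and a one-way ANOVA /
Bonferroni module reproduces the cluster-versus-PGI statistics.

## Worked example

```python
import numpy as np
from wmh3d import synth, zernike as z, pgi, texture
from wmh3d.lesions import extract_lesions, rescale_to_target_volume, embed_in_cube

# a synthetic FLAIR-like phantom: one 4x3x2-voxel-radius ellipsoid lesion
# with a 2-shell bright halo and mild noise
prim = synth.LesionPrimitive("ellipsoid", (20, 20, 20), (4, 3, 2))
spec = synth.PhantomSpec(shape=(40, 40, 40), lesions=[prim],
                         halo_thickness=2, noise_sd=2.0, seed=3)
vol, mask, _ = synth.make_phantom(spec)

lesions = extract_lesions(vol, mask, min_volume_mm3=30, subject_id="demo")
le = lesions[0]
print(f"lesion volume: {le.volume_voxels} voxels, centroid {tuple(map(float, le.centroid))}")

cube = embed_in_cube(rescale_to_target_volume(le, 80), 36)
grid = z.build_unit_ball_grid(36)
moments = z.forward_transform(cube.astype(float), grid, 40)
descriptor = z.compute_descriptor(moments)
print(f"descriptor length at order 40: {descriptor.values.size}")
err = z.reconstruction_error(cube, z.reconstruct(moments, grid, 40))
print(f"reconstruction error at order 40: {err:.3f}")

hist = texture.fuzzy_histogram(texture.normalize_intensities(le, 0.01), 10)
print("fuzzy histogram:", np.round(hist.frequencies, 3))

result = pgi.pgi_for_lesions(vol, lesions, gamma=2.5, l=5)[0]
print(f"PGI: {result.pgi:.4f}  (layer sizes {result.sizes.tolist()}, growth {result.growth.tolist()})")
```

prints

```
lesion volume: 99 voxels, centroid (20.0, 20.0, 20.0)
descriptor length at order 40: 441
reconstruction error at order 40: 0.400
fuzzy histogram: [0.296 0.466 0.108 0.018 0.    0.    0.    0.    0.037 0.075]
PGI: 0.0203  (layer sizes [250, 466, 730, 1042, 1402], growth [250, 466, 0, 0, 0])
```

The 99-voxel lesion is rescaled to ~80 voxels and embedded in a 36³ cube;
its 441-entry descriptor covers orders n ≤ 40. The error rate 0.400 means
40% of the lesion's voxel count differs between the shape and its
order-40 reconstruction — rescaling leaves a jagged surface, so full detail
needs higher orders (a smooth 80-voxel ellipsoid reaches error 0 by order
40, and the curve keeps falling with order for rescaled lesions). The
histogram shows most mass in the dim bins (boundary falloff) plus a bright
tail; the PGI of 0.0203 reflects growth voxels confined to the two
halo shells, down-weighted because the inner shells carry the small weights.

The same flow runs end-to-end from the shell:

```sh
wmh3d simulate --out runs/sim --subjects 3 --seed 1
wmh3d run-all --manifest runs/sim/manifest.json --out runs/report --seed 1
```

`run-all` writes per-lesion tables (volumes, descriptors, texture bins,
cluster labels, PGI with per-shell counts) and a JSON manifest with the gap
curves, ANOVA results and the full configuration.

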