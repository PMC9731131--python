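# Methods

This note records the models implemented in `wmh3d`, the numerical choices
behind them, and what the synthetic phantoms do and do not establish about
behaviour on real FLAIR data.

## 3D Zernike basis and transform

The basis on the unit ball is `V_nlm(r,θ,φ) = R_nl(r) Y_lm(θ,φ)` for
`l ≤ n`, `n − l` even, `|m| ≤ l`.

**Real spherical harmonics.** `Y_lm = √2 · P̃_l^|m|(cosθ) · cos(mφ)` for
`m > 0`, the `sin(|m|φ)` form for `m < 0`, and `P̃_l^0` for `m = 0`, where
`P̃_l^m` are associated Legendre functions normalised so the `Y_lm` are
orthonormal over the sphere (`P̃_0^0 = √(1/4π)`). They are evaluated by the
standard three-step recursion (diagonal, sub-diagonal, general degree
recursion), which is stable to degree 250 in double precision. We use the
convention without the Condon–Shortley phase; the phase cancels in
forward-plus-inverse transforms and never affects descriptor norms.

**Radial polynomials.** `R_nl(r) = r^l P_k^(0, l+1/2)(2r² − 1)` with
`k = (n−l)/2`, equivalently the unique polynomials with `R_nl(1) = 1` and
`∫₀¹ R_nl R_n'l r² dr = δ_nn'/(2n+3)`. They are computed by a
Kintner-style three-term recursion in `n` at fixed `l`, seeded by
`R_nn = rⁿ` and `R_n,n−2 = (n+½)rⁿ − (n−½)r^{n−2}`, with coefficients

    k0 = (n−l)(n+l+1)(2n−3)
    k1 = (2n−1)(2n+1)(2n−3)
    k2 = (−2n+1)(4l²+4l+1)/2 − k1/2
    k3 = −(n−l−2)(n+l−1)(2n+1)
    R_nl = [(k1 r² + k2) R_{n−2,l} + k3 R_{n−4,l}] / k0

derived from the Jacobi recurrence and verified against direct Jacobi
evaluation (max deviation ~5e−14 to order 30) and against the endpoint and
orthogonality identities (`R_nl(1) = 1` exactly to order 250; radial Gram
within 3e−15 of `diag(1/(2n+3))` for `n ≤ 50`). These identities — not any
particular printed form of the coefficients — are treated as the normative
definition.

**Discrete transform.** A voxel cube of side N is mapped into the ball by
centring at `(N−1)/2` per axis and dividing by a scale radius: by default
`√3·(N−1)/2` (`cube_in_ball`, every voxel centre inside the ball), or the
largest occupied-voxel distance plus half a voxel (`tight_fit`). Moments
are Cartesian voxel sums, `Z_nlm = (2n+3) Σ f·V_nlm·ΔV` with
`ΔV = scale⁻³`; the Cartesian measure equals dV, so no per-voxel Jacobian
is applied and the sum is exact for voxel-constant functions. At `r = 0`
we set `θ = φ = 0` (every basis value is finite there). Basis values are
produced by a streaming per-degree generator (two Legendre rows and one
radial stack in memory), which keeps order-100 transforms of 36³ cubes
tractable; the forward transform only visits foreground voxels.

**Descriptors, reconstruction, error rate.** The descriptor is the vector
of `‖Z_nl‖` ordered by (n, l); its length is `((n+2)/2)²` for even maximum
order and `(n+3)(n+1)/4` for odd. Reconstruction truncates the expansion at
order M; the error rate is the symmetric difference between the binary
original and the reconstruction thresholded at 0.5 (applied to the raw,
unclipped values), divided by the original foreground count.

**Quality gates.** Basis orthonormality is checked as a Gram-matrix
residual on a ball-covering quadrature. The raw voxel-centre sum at 64³
leaves a residual of ~0.018 concentrated at the jagged ball boundary, so
the quadrature subdivides cells within ~1.5 voxels of the surface into 4³
subcells (`zernike.ball_quadrature`); the residual is then ~0.007 at 64³
and shrinks monotonically with resolution (0.094 at 16³, 0.033 at 32³).
The remaining error is the midpoint rule inside interior cells.

## Lesion preparation

Connected components of the mask (26-connectivity by default; 6/18
configurable) with volume strictly greater than 30 mm³ become lesions,
carrying their voxel coordinates, intensities and unweighted binary
centroid. Lesions split into a small group (≤ 250 voxels, boundary
inclusive) and a large group. For shape analysis a lesion's binary
occupancy is zoomed isotropically by `(v′/v)^(1/3)` (tricubic by default),
then binarised at the interpolated value whose foreground count is closest
to the target `v′`, ties resolving to the lower threshold (larger volume);
the threshold search is provably optimal over achievable counts. Reference
targets are 80 voxels in a 36³ cube (small group) and 1,500 in 90³ (large
group); a single-voxel lesion upscales by block replication. Embedding
places the centroid at the cube centre `floor((N−1)/2)`, rounding to the
nearest voxel and refusing shapes whose bounding box does not fit.

## Texture

The lowest 1% of a lesion's intensities (linear-interpolation quantile,
computed per lesion) is discarded as likely segmentation false positives;
survivors are min–max normalised. Each normalised value splits its unit
mass linearly between the two nearest bin centres `(2j+1)/(2n)` of an
n-bin histogram (n = 10 by default, 2–15 supported); values outside the
centre range load the edge bin fully, and a value exactly at a centre
loads that bin fully (the common limit of both branches). The histogram is
divided by the voxel count, so it sums to one and depends only on the
intensity multiset — hence invariance under rotation, relabelling and
positive affine intensity rescaling (up to discard-set ties).

## Clustering and cluster-count selection

Descriptors are mean-centred and projected onto the fewest principal
components reaching 99.8% cumulative explained variance. K-means (Lloyd)
is restarted from initial centroids drawn uniformly without replacement
from the data rows — 1,000 restarts at reference settings — and the run
with the smallest within-cluster dispersion `W_k = Σ_r Σ_{x∈C_r} ‖x−x̄_r‖²`
is kept (k = 1 uses the global mean directly; duplicate-row cluster
collapse is absorbed by the restart scheme). The gap statistic compares
`log W_k` against B reference datasets drawn uniformly from the data's
per-dimension bounding box, with `sd_k` the population SD of the reference
log-dispersions and `s_k = sd_k·√(1+1/B)`; the selected count is the
smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}` (defaults N = 20, B = 30).
k is capped at one below the row count, where `W_k` would vanish
identically. All randomness flows from one seed through named sub-streams,
so results are exactly reproducible.

## Potential Growth Index

Subject-level intensity statistics m and σ (population SD) pool the voxel
intensities of all the subject's lesions. Penumbra shells are built by
iterated morphological dilation with the 3×3×3 (26-neighbour) structuring
element — one-voxel-thick shells in every direction; a 6-neighbour element
is available. Voxels belonging to any lesion are excluded from every shell
(they are disease, not potential growth), and image borders clip shells.
Shell voxels with `f ≥ m − γσ` count as growth voxels; γ = 2.5 by default,
matching one-sided Gaussian coverage Φ(2.5) = 99.38%. With weights
`w_i = i/Σj` (unit sum, strictly increasing), `PGI = Σ GV_i w_i / Σ V_i`
lies in [0, 1], is zero exactly when no shell voxel passes the threshold,
and is non-decreasing in γ.

## ANOVA reporting

One-way ANOVA F and p are computed across cluster labels (groups with
fewer than two members are excluded with a notice), plus all pairwise
two-group F tests. Following the way such tables are usually presented,
raw pairwise p-values are reported next to Bonferroni significance
thresholds `α/n_pairs` (0.05/10 = 5.0e−3 for five clusters,
0.05/6 ≈ 8.33e−3 for four) and a stricter `0.01/n_pairs` tier;
Bonferroni-adjusted p-values are included for convenience.

## Synthetic phantoms

`synth.make_phantom` places non-overlapping ellipsoids, tori or
sphere-union blobs in a background of constant intensity (default 100)
with optional Gaussian noise. Lesion intensity ramps from half the
core-background contrast at the boundary shell to the full core intensity
(default 200) over a cosine falloff (default 2 shells deep), emulating
partial-volume dimming at lesion edges. An optional halo sets the first
`halo_thickness` outside shells to a bright value (default 160), placing
them above the `m − 2.5σ` growth threshold by construction. The
ground-truth record carries exact per-lesion volumes, centroids and
per-shell sizes/growth counts computed with a chessboard distance
transform — an independent route from the dilation-based pipeline — so
noise-free phantoms give exact oracle predictions for the extraction and
PGI stages. `make_blob_features` places Gaussian clusters of unit SD at
regular-polygon vertices a configurable separation apart, for
gap-statistic recovery experiments.

What the phantoms do **not** emulate: MRI bias fields, anisotropic voxels,
partial-volume mixing beyond the cosine ramp, spatially correlated noise,
and the anatomical geometry of periventricular lesions. Passing tests
demonstrate the correctness of the implemented operators and their
invariances, not segmentation robustness or clinical effect sizes.

## Problem sizes used in tests and the acceptance script

These runs use scaled-down but structurally faithful conditions, chosen
once as the package's own study settings:

- Reconstruction convergence: an 80-voxel ellipsoid (radii 4.5, 2.2, 2.0
  voxels — exactly 80 foreground voxels) in a 36³ cube, orders 0–60 in
  steps of 5. The error reaches zero by order ~40 for this smooth shape;
  rescaled lesions converge more slowly, mirroring the need for order
  ~100 on real data.
- Gap-statistic recovery: planted k ∈ {2, 3, 4}, 50 points per cluster,
  separation 10 SDs, N = 6, B = 30, 10 restarts per fit, 20 seeded
  replicates per k. B = 30 matters: smaller reference counts make the
  selection rule fire spuriously at k = 1 when Gap(1) ≈ Gap(2), which is
  the marginal case for triangle-arranged blobs.
- Orthonormality gate: degrees n ≤ 10 at 16³/32³/64³ with the
  boundary-refined quadrature; radial orthogonality n ≤ 50 by 128-node
  Gauss–Legendre quadrature.
- End-to-end pipeline: 12 synthetic lesions across 3 subjects in 48³
  volumes, desk-mode settings (orders 16/20, cubes 24³/32³, 20 restarts,
  N = 6, B = 10), run twice to verify byte-identical reports.

## Known limitations and open choices

- Numbers derived from the original patient cohort (lesion counts
  280/206/74, 80/68 retained components, selected cluster counts, table
  F/p values, reconstruction error rates ~7e−4, the printed example PGIs,
  the 84.6% periventricular fraction) depend on the scans and cannot be
  recomputed here.
- Periventricular-versus-deep anatomical labelling needs ventricle
  geometry and is out of scope.
- Whether texture clustering optimally uses 4 or 5 clusters is left to
  the gap statistic on the user's data; the pipeline reports the selected
  k and accepts an override.
- Whether the 1% intensity discard and the min–max bounds should be per
  lesion or per subject is an open convention; per lesion is the default
  (it preserves the size-invariance goal), per subject is configurable.
- Penumbra voxels inside *other* lesions are excluded from shells — the
  conservative reading; including them would raise both V and GV.
- Lesions whose bounding box exceeds the normalisation cube raise an
  error rather than being silently cropped.
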