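# Methods

This note documents the models, defaults, and numerical choices behind
`headcirc`, and what the synthetic validation does and does not establish.

## Measurement model

The instrument treats the maximum head circumference as the perimeter of
the maximum-area axial slice of the outer-skin mask. The model assumptions
are those of a scanner-aligned axial stack: near-isometric in-plane pixels
(0.4–0.9 mm typical), coarser slice spacing (1–5 mm), and a head whose
cross-sectional area is unimodal along the inferior–superior axis.
Orientation handling is restricted to axis permutations and flips; volumes
whose acquisition axes deviate more than 1° from the grid axes are rejected
rather than resampled, since interpolation would alter the digitized
boundary the estimators operate on. Voxel indices are 0-based and a voxel's
physical center is `index × spacing`; masks and contours live on voxel
centers.

Finite slice spacing limits where the true maximum can sit: the selected
slice carries a z-localization uncertainty of half the slice thickness,
reported as `z_uncertainty_mm` on every result. Ties in slice area break
to the smaller (more inferior) index, a deterministic and reproducible
rule.

## Mask extraction

The out-skin mask is computed by Otsu's threshold (256 bins over the
observed range), per-slice morphological closing with a 2-pixel disk,
selection of the largest 3D connected component, and per-slice hole
filling. Closing and hole filling are 2D on purpose: 3D filling would fail
on cavities open to the outside (nasal passages, ear canals), and 3D
closing with coarse slices would smear across 5 mm of anatomy. A largest
component covering more than half of the volume border (excluding the
inferior face, where neck contact is expected) is treated as
background/foreground inversion and rejected. Intensity support at the
scalp is all the measurement needs; any residual boundary bias (e.g. the
half-voxel question of where a partial-volume edge "is") is exactly what
the calibration protocol absorbs into the correction factor.

## Perimeter estimators

The outer contour is traced with Moore-neighbor following into a closed
Freeman chain (start at the lexicographically smallest foreground pixel,
counter-clockwise orientation, closure detected when the first move from
the start pixel is about to repeat — exact, because the trace is
deterministic in its (pixel, backtrack) state). From the chain's N_e even
moves, N_d diagonal moves, and N_c direction changes:

| method | formula (× in-plane step) | bias on digital circles |
|---|---|---|
| `pixel_count` | N_e + 2·N_d | → 4/π ≈ +27% as r grows |
| `freeman` | N_e + √2·N_d | ≈ +5% |
| `corner_corrected` | 0.980·N_e + 1.406·N_d − 0.091·N_c | < 1% (measured ≤ 0.26% at r ≥ 100 px) |
| `subpixel` | 0.5-isolevel contour arc length | ≤ 0.15% at r ≥ 100 px |

`pixel_count` is deliberately the *uncorrected* city-block chain length:
it exhibits the classic 4/π digital-boundary overestimate and serves as
the reference point for how much bias the calibration has to absorb. (The
even-moves-only variant N_e + N_d *under*-estimates a circle by ~10% and
reproduces neither the 4/π limit nor the estimator ordering
pixel_count ≥ freeman ≥ corner_corrected, so it is not used.)

The `subpixel` method extracts the 0.5-isolevel by marching squares with
linear interpolation after smoothing the binary mask with a σ = 1.5 px
Gaussian. The smoothing is essential: on the raw binary grid the
interpolated polygon is still a staircase and overestimates a digitized
circle by ~5.5%; after smoothing the isolevel tracks the underlying smooth
boundary (curvature-induced inward shift is O(σ²/r), negligible at head
scales). It is the only estimator that handles anisotropic pixels natively;
the chain methods use the geometric-mean spacing and warn beyond 5%
anisotropy.

Degenerate single-pixel regions report 4 × pixel side with an explicit
flag. Two boundary conventions (pixel-center chain vs inter-pixel
isolevel) are both available because which one a hardware perimeter
estimator measures is ambiguous; the calibration makes either consistent.

## Phantom synthesis

The calibration rings are annular solids 5 mm tall with a 3 mm radial wall
(the wall is a package default — only the height is fixed by the physical
protocol; the *outer* boundary carries the certified circumference since
the physical diameter is calipered outside). The two ring sets follow the
published calibration record: nine rings spanning 35.5–49.3 cm
circumference (ages 0–3) and four spanning 51.2–55.3 cm (3–18). Outer
diameter is C/π. Rings stack along z with 2 mm gaps, faces aligned to the
1 mm slice grid so each ring occupies exactly five full slices — the
acquisition geometry of the protocol ("five readings per ring, no
resampling").

Rasterization emulates partial volume: each voxel's intensity is the
occupied fraction of `supersample` (default 8) subcells per axis times a
nominal foreground intensity (100). Interior/exterior pixels are certified
by a gradient bound on the normalized radius and only the boundary band is
subsampled, which is identical to full supersampling but much cheaper; for
z-extruded rings the in-plane and through-plane fractions factorize
exactly. Optional Rician noise (σ default 0 — calibration must be
reproducible) is seeded and bit-reproducible.

Synthetic heads are layered quasi-ellipsoids: cross-section semi-axes
(a·s(z), b·s(z)) with s(z) = (1 − (z/c)²)^(taper/2), taper 1 = ellipsoid,
taper 0 = elliptic cylinder; a scalp shell adds a constant to every
semi-axis so each slice's outer boundary stays an exact ellipse. Every
generated volume carries a manifest with analytic truth: ring
circumferences, and per-slice outer perimeters computed by adaptive
arc-length quadrature (there is no elementary closed form for an ellipse
perimeter; the quadrature oracle is verified against the Legendre
complete-elliptic-integral form in tests).

What the generator does *not* emulate: MR point-spread and k-space
truncation, bias fields, motion, print tolerance of physical rings, or
real cranial shape (sutures, ears, nose). Consequently the near-zero CF
derived from the noiseless digital phantom (+0.12 cm with the default
estimator) is *not* the clinical CF: on real scanner data the published
calibration found systematic over-reads of 2.6–3.6 cm, dominated by
physics the digital twin deliberately omits. Passing the closed-loop tests
shows the measurement chain itself is unbiased to < 0.5%; it does not
validate any particular clinical CF value.

## Calibration arithmetic

Per ring: reads are summarized as mean ± sample sd (n−1); the certified
value is C = Dπ with σ = π·σ_D (0.1 mm caliper default, though the
published record used ±0.3 cm per ring, whose provenance is unstated);
Difference = Real − Estimated with quadrature sd. Group CFs are the mean ±
sd of the group's differences. Full precision is kept internally; rounding
to 0.1 cm (half away from zero) happens only at reporting boundaries. The
reporting path recomputes the difference from the *rounded* est/real pair,
because that is how the published record combines its printed columns (its
own worked quadrature uses the rounded sds).

CF source precedence: user CF file > CF derived from a calibration run >
the `"paper2021"` preset (−2.8 ± 0.2 cm below 36 months, −3.7 ± 0.3 cm
from 36 months to 18 years). The preset values are shipped as *data*, not
recomputed: they do not equal the mean of the published per-ring
differences (−2.6 / −3.5 cm) and the discrepancy is unexplained in the
source record, so both routes are exposed and neither is silently
preferred. The 36-month boundary (inclusive for the older group) is a
package choice; the record states only that CFs were applied "depending on
age". An age outside all groups returns the raw value with an explicit
uncorrected flag.

Re-deriving the published record from its raw inputs reproduces 7 of 13
ring rows and 6 of 7 comparison rows exactly at 0.1 cm rounding; the
remaining rows are internally inconsistent in the record itself (e.g. a
read mean of 50.844 printed as 50.9, a difference of −3.4 printed as
−3.2). The tests assert the printed values and the mismatching rows are
reported, not papered over.

## Statistical harness

The cascade is fixed: per-sample moment screen (bias-uncorrected skewness
and *excess* kurtosis, both required in [−1, 1] — excess is the only
reading under which normal samples land in the band), Shapiro–Wilk, then
mean-centered Levene, then one-way ANOVA (≥ 3 groups) or pooled-variance
t-test (2 groups; pooling is justified because homogeneity is certified
first, Welch available by flag). Any failed screen refuses the final test
and names itself. All decisions follow "discard H0 if p ≤ α".

The operator simulator draws per-subject truths (default N(48, 4) cm, a
mixed-age pediatric spread) and adds per-operator bias and Gaussian
reading noise. Two sampling designs are exposed: `shared_subjects=True`
(the clinic protocol — every operator reads the same children) and
`False` (independent cohorts). Under the shared design the operators'
group means are correlated through the subjects, which makes one-way
ANOVA strongly conservative under the operator null (measured rejection
rate ≈ 0 at n = 52 with 4 cm subject spread); the type-I calibration
therefore uses the independent design, the regime in which the test
attains its nominal level (measured 0.041 at α = 0.05 over 1000
datasets). Power checks use a constant-truth cohort (operators
re-measuring a reference object), where a 0.5 cm bias against 0.4 cm
noise is detected essentially always. Statistics are cross-checked against
hand-computed sum-of-squares and pooled-t oracles to 1e-6.

## Charts

Reference charts are per-age normal bands (mean ± sd by sex), linearly
interpolated between tabulated ages — deliberately *not* LMS curves, which
would invent skewness structure the classic band-format charts lack.
z = (HC − mean)/sd, percentile = 100·Φ(z). No extrapolation beyond the
tabulated range. No real chart is bundled; `synthetic_example_chart()` is
clearly labeled synthetic and exists for demos and tests.

## Problem sizes and tolerances

The validation suite uses the protocol resolutions directly: the nine-ring
phantom and the 80 mm sphere are rasterized at 0.5 × 0.5 × 1.0 mm (≈ 7.5M
and 19M voxels), digitized circles up to r = 400 px, 1000 simulated
datasets for the type-I calibration, 120–200 per power point. Key
tolerances: subpixel ring reads within 0.5% of C = Dπ, corner-corrected
circle perimeters within 1%, end-to-end self-calibrated sphere reading
within 1 cm of 2πR, ANOVA type-I within 0.05 ± 0.02. Quadrature uses
`hypot` (under/overflow-safe); ANOVA on identical groups clamps the
cancellation artifact (tiny negative F, NaN p) to F = 0, p = 1.

## Known limitations

- No bias-field or noise robustness claims: extraction is plain Otsu;
  heavily shaded or low-SNR volumes may need an explicit threshold.
- Oblique acquisitions are rejected, not handled.
- The pipeline measures the single max-area slice (an `average_top_k`
  audit option exists); whether a clinical instrument should average
  neighboring slices is a protocol question, not settled here.
- Chain-based estimators assume near-isometric pixels; beyond 5%
  anisotropy use `subpixel`.
- The bundled CF presets apply to the instrument family they were
  calibrated for; a different scanner/sequence needs its own phantom run.
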