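# Methods

This note records the model, the default study conditions, the numerical
choices, and the limitations of the `elastinv` pipeline.  Every empirical
number quoted here was computed with this code at the stated seeds.

## 1. Constitutive model (`mr_core`)

Materials are incompressible Mooney–Rivlin solids with strain-energy
density

W = C10 (I1 − 3) + C01 (I2 − 3),

where I1, I2 are the first two invariants of the left Cauchy–Green tensor.
Under uniaxial stress with stretch λ and incompressibility
(λ1, λ2, λ3) = (λ, λ^−1/2, λ^−1/2), the axial Cauchy stress is

σ(λ) = 2 (λ² − 1/λ) (C10 + C01/λ).

Linearizing at λ = 1 gives the initial shear modulus μ0 = 2 (C10 + C01)
and, with ν = 1/2, the small-strain Young's modulus

E = 3 μ0 = 6 (C10 + C01).

Default material table (breast tissues):

| material       | C10 (Pa) | C01 (Pa) | E = 6(C10+C01) |
|----------------|---------:|---------:|---------------:|
| fat            |     2000 |     1333 |      19 998 Pa |
| fibroglandular |     3500 |   2333.3 |    34 999.8 Pa |
| tumor          |    10000 |     6667 |     100 002 Pa |

`stretch_from_stress` inverts σ(λ) with Brent's method on λ ∈ [0.2, 3];
the map is strictly monotone there for all physical (C10 + C01 > 0)
parameters.

## 2. Phantom and forward model (`phantom_forward`)

The phantom is a 100 mm (axial) × 60 mm (lateral) cross-section of a
15 mm fat layer over an 85 mm fibroglandular host, with a 10 × 10 mm
tumor at 65–75 mm depth, laterally centered (25–35 mm around the 30 mm
midline).  The distal face (z = 100 mm) is fixed; the proximal surface
carries a uniform sinusoidal traction

t(τ) = A sin(2π f τ),  A = 5000 Pa, f = 0.1 Hz,

sampled at the eight instants τ = 7.75, 8.00, …, 9.50 s (the negative
half-cycle, i.e. tensile load).  Loading at 0.1 Hz is quasi-static:
fields depend on the instantaneous traction only.

The deformation is a reduced one-dimensional series model: each axial
column is a stack of layers in series carrying the same axial Cauchy
stress −t(τ); each layer's stretch solves σ_m(λ) = −t with Brent's method,
and axial displacement integrates the engineering strain from the fixed
face upward, u(z) = −∫_z^L ε dz′.  Columns through the tumor's lateral
band include the tumor segment; others do not.  The column solution is
extruded laterally to a 2-D plane field on a 0.5 × 1.0 mm grid (bilinear
interpolation in between).  This captures the series load path and the
interface kinematics that the inversion uses; it neglects lateral
mechanical coupling and stress concentration around the inclusion
corners (see §7).

The *elastic reference* field replaces the tumor with a linear solid of
modulus E_ref = 1 Pa (the surrounding layers keep their nonlinear
constants) — displacements of the reference tumor then scale as 1/E,
which is the lever the inversion's modulus regression uses.

Observation points: 12 points on a 4 (lateral) × 3 (axial) grid spanning
the central 70 % of the tumor; displacements are sampled relative to the
tumor's distal face (z = 75 mm), so each observation is the integrated
tumor strain above the point.

## 3. RF synthesis (`rf_sim`)

Scatterers are seeded uniformly at 10 /mm² over the imaging window
(density and positions per-seed deterministic), with Rayleigh-distributed
amplitudes — except inside the tumor, where amplitudes are zero: the
lesion is anechoic.  Probe defaults: 3.5 MHz center frequency, 100 MHz
sampling, 512 lines at 0.08 mm pitch, Gaussian lateral beam (σ = 0.4 mm),
60 % fractional bandwidth Gaussian-cosine axial pulse, imaging window
45–95 mm.  Echo amplitude is deposited by bilinear binning in
(line, sample) and convolved with the separable point-spread function;
c = 1540 m/s maps depth to samples.

Frames are formed in the *probe frame*: the transducer rides on the
moving surface, so the surface row's displacement is subtracted from the
field before warping the scatterers.  At the default load this leaves a
bulk probe-frame translation of ≈ 11 mm at tumor depth between the
unloaded and loaded states, with layer strains up to ≈ 25 % in fat — which
is why tracking must proceed between consecutive load states (§4).

## 4. Displacement tracking (`tracking`, `pipeline_eval`)

`ncc_track` estimates displacement on a dense grid of overlapped windows
(default 96 samples × 5 lines, 80 % overlap) by maximizing the zero-mean
normalized cross-correlation over integer (axial, lateral) lags, with a
guided search seeded by the previously processed neighbor.  Sub-sample
refinement fits the three axial correlation samples around the peak with
a cosine, c(τ) = A cos(ω(τ − δ)) — the local shape of the correlation of
band-limited RF — falling back to a parabola when the cosine model is
undefined.  On noiseless synthetic frames, integer rigid shifts are
recovered exactly and a 0.3-sample shift is recovered within 0.07 samples
in every window (the parabolic fit alone leaves ~9 % of windows outside
0.1 samples; its bias on oscillatory correlation is well known).

The pipeline's tracked path follows standard quasi-static elastography
practice:

1. **Incremental, Lagrangian tracking.**  RF frames are synthesized at
   the eight load states and tracked pairwise between *consecutive*
   states, where inter-frame strain stays below ~2 % and speckle remains
   correlated.  Tracking any loaded state directly against the unloaded
   medium fails — several millimetres of bulk motion and several percent
   strain fully decorrelate the windows.  Correlation windows follow each
   point's accumulated displacement; each pair is seeded with the
   point's previous increment.  Search ranges are fixed a priori in
   physical units: ±2.5 mm for the first pair (no seed yet), ±0.8 mm
   around the seed thereafter.
2. **Anechoic-interior handling.**  The tumor returns no speckle, so its
   interior cannot be tracked directly.  The lesion's dark band is
   located in the first frame's envelope (longest contiguous run below
   0.35 × the median envelope near the lesion's lateral center, minimum
   extent 2 mm), and per lateral position a short column of four speckle
   windows is placed just above and below the band.  Column displacements
   are extrapolated linearly to the two interfaces, and the interior
   observation points are interpolated between the interfaces by
   fractional depth.  Under the (uniform-per-layer) lesion strain of the
   forward model this interpolation is exact, and uniform strain
   preserves fractional position, so the frame-coordinate columns remain
   congruent to the material observation points.
3. **Baseline-first differencing.**  Incremental tracking accumulates
   displacement from the first *sampled* state, not from the unloaded
   medium, so the observation vector is differenced against the first
   instant's block (kept in place as zeros).  The reference vector and
   every re-simulated candidate observation are differenced identically,
   which leaves the 1/E scaling — and hence the whole inversion — intact.

At the default full-size probe (seed 1), the tracked face-relative
displacements agree with the forward truth to 0.008 mm mean absolute
error, and the tracked effective modulus is within 3.8 % of the truth
(96.2 vs 100.0 kPa); the tracking-bypass path gives 98.4 kPa (1.6 %).

## 5. Inversion (`inverse`)

Given the observation vector y (12 points × 8 instants, face-relative,
optionally baseline-differenced) and the congruent reference vector d
from the 1 Pa reference simulation:

1. **Effective modulus.**  Displacements scale as 1/E in the linear
   regime, so the least-squares slope s = (dᵀy)/(dᵀd) of y on d gives
   E_realt = E_ref / s.
2. **Stress synthesis.**  Over a strain set ε_i (default −0.02 … −0.20,
   10 points; sign flipped to match the sign of the applied traction),
   synthetic stresses σ_i = E_realt · ε_i are formed, optionally with
   relative Gaussian jitter.
3. **Constitutive fit.**  (C10, C01) solve the linear least-squares
   problem σ_i = 2(λ_i² − 1/λ_i)(C10 + C01/λ_i), λ_i = 1 + ε_i.
4. **Forward verification.**  The candidate tumor is inserted into the
   forward model; the re-simulated observations Y_estt and re-regressed
   modulus E_estt are compared with the data.
5. **Decay loop.**  On failure the strain set shrinks by a factor 0.9 and
   the loop repeats (cap 50).  `exact` mode converges on absolute
   residuals against the data (1 % of the displacement scale and of
   E_realt by default); `noisy` mode on successive-iterate changes
   (0.1 % by default) — the appropriate criterion when the data carry
   measurement error that the model cannot and should not reproduce.

## 6. Identifiability: only the sum C10 + C01 is determined

Step 2 builds stresses *exactly proportional* to the strains.  Fitting
the Mooney–Rivlin law to data of the form σ = E ε selects the unique
(C10, C01) minimizing ‖A c − E ε‖² for the fixed design matrix A of step
3 — a point determined entirely by the strain set's geometry and E, and
not by the generating split.  As the strain set shrinks, both columns of
A converge to 6ε (each column's linearization at λ = 1 is 6ε, since
∂σ/∂ε|₁ = 6 for a unit C10 and likewise for C01): the columns become
collinear, the Fisher information matrix AᵀA becomes singular along the
direction C10 + C01 = const, and the data constrain only
E = 6 (C10 + C01).  The split the fit does return is the fixed bias of
the design (for the defaults: C10 high by ≈ 50 %, C01 low by ≈ 79 %),
repeatable but meaningless.

Consequences, all observed with this code:

- Inverse-crime recovery of the *sum* is at the ~1 % level (tracking
  bypass), but the individual constants never approach their generating
  values; the acceptance tests asserting sub-1 % per-constant recovery
  and single-digit median per-constant noise errors fail and are left
  failing rather than weakened.
- In the 2–10 % noise sweep (20 seeds/level, seed 1), the median error of
  6 (C10 + C01) stays near 1 % (1.19 / 0.83 / 1.38 / 1.14 % at
  2/5/8/10 %) — the identifiable quantity is strongly noise-resistant —
  while median per-constant errors sit at the split bias.

Identifying the split would require observations sensitive to the
*curvature* of σ(λ), i.e. accurate absolute stress–strain pairs at large
strain, which displacement ratios under a single load shape do not
provide.

## 7. Numerical choices and limitations

- **Root finding:** Brent's method, bracket λ ∈ [0.2, 3], tolerance
  machine-level; stress continuity across layers satisfied to < 1 µPa.
- **Grids:** forward fields on 0.5 mm (axial) × 1.0 mm (lateral) grids,
  bilinear interpolation; observation sampling raises outside the grid
  rather than extrapolating.
- **Determinism:** every stochastic element (scatterers, noise, jitter)
  is driven by an explicit seed; full-pipeline runs are bit-reproducible
  per seed.
- **Reduced mechanics:** the 1-D series model ignores lateral coupling,
  shear at the inclusion boundary, and stress concentration; the 2-D
  field is an extrusion, not a plane-strain solution.  The inversion only
  consumes axial displacements at interior tumor points, where the series
  approximation is at its best, but absolute field accuracy away from the
  tumor column is not claimed.
- **Noise model:** the robustness sweep perturbs the sampled observation
  vector (what the inversion consumes), not every tracked window.
- **Tracking:** lateral shifts are estimated at integer line resolution
  only; the anechoic-band locator assumes a single dominant lesion in the
  imaging window.
- **Scope:** synthetic data only; no beamforming, attenuation, or
  frequency-dependent scattering; no real-recording ingestion.
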