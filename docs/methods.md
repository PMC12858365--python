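# Methods

`qpactvi` is a desk-scale virtual-imaging testbed for quantitative
photoacoustic computed tomography (qPACT) of the breast. It reproduces, at
workstation problem sizes, the full chain of a cohort-level qPACT
evaluation: stochastic numerical breast phantoms, optical and acoustic
forward simulation under two study designs, spectral-unmixing baseline
estimators, a toy-scale dual-task learned estimator, and a quantitative
evaluation protocol. This note records the models, the parameters that
matter, the numerical choices, and the limitations a user should know
before interpreting results.

## Imaging model

Photoacoustic image formation couples two physics stages. A short laser
pulse at wavelength λ deposits energy where light is absorbed; the induced
initial pressure is

    p0(r, λ) = Γ · μa(r, λ) · Φ(r, λ),

with Γ the Grüneisen parameter (set to 1, the common soft-tissue
assumption; all pressures are then in absorbed-energy units), μa the
optical absorption coefficient and Φ the fluence. Absorption is a linear
combination of chromophore contributions,

    μa(r, λ) = THb·sO2·ε_HbO2(λ) + THb·(1−sO2)·ε_Hb(λ)
             + w_vf·ε_water(λ) + f_vf·ε_fat(λ) + m_vf·ε_mel(λ),

so multiwavelength measurements carry information about blood oxygen
saturation sO2 = c_HbO2 / (c_HbO2 + c_Hb). The chromophore table
(`data/chromophores.yaml`, 757/800/850 nm) uses rounded values from the
standard tissue-optics compilations; hemoglobin entries are per mM with the
ln(10) factor folded in, so μa values are Napierian. Users may substitute
their own calibration by editing the file; the condition number of the
HbO2/Hb extinction matrix is logged at load time because unmixing is only
as well posed as that matrix.

## Synthetic phantoms

Each phantom is a hemispherical breast (z the symmetry axis, chest wall at
z = 0) in a water bath:

- **Skin**: an epidermis shell (default 0.15 mm, at least one voxel) over a
  dermis shell (1.35 mm). Skin tone enters as the epidermal melanosome
  volume fraction, sampled from six monotone Fitzpatrick ranges
  (1–2% for tone 1 up to 25–40% for tone 6).
- **Interior**: fat and fibroglandular tissue partitioned by thresholding a
  smoothed Gaussian random field at the quantile matching the BI-RADS
  density class (A ≈ 8%, B ≈ 20%, C ≈ 42%, D ≈ 68% fibroglandular), with a
  centrality weight so glandular tissue concentrates near the axis.
- **Vessels**: independent arterial and venous trees grown by stochastic
  bifurcating random walks from chest-wall entry points; radii shrink by a
  Murray-like factor 0.6–0.85 at branch points, branches stop below a
  minimum radius or on leaving the interior. Arteries draw sO2 from
  0.92–0.98, veins from 0.60–0.80 — disjoint ranges, so the artery > vein
  ordering holds by construction.
- **Tumor** (optional, middle or posterior placement): a spiculated viable
  rim (multiplicative smooth noise on an ellipsoidal radius), a necrotic
  core at 45% of the viable radius, and a peripheral angiogenesis shell at
  1.35×. Blood volume fraction is elevated in the viable and angiogenesis
  regions — tumour angiogenesis modeled implicitly through perfusion rather
  than explicit peritumoral vessels.

Per-tissue optical (μs, g, n), acoustic (c, ρ, α0, y) and functional
(volume fractions, sO2) values live in `data/tissues.yaml` as fixed values
or uniform sampling ranges resolved once per phantom; total hemoglobin is
blood volume fraction × 2.33 mM (150 g/L whole blood). All stochastic
choices derive from one integer seed; the tumor uses a separate stream
derived from the same seed, so a tumor-bearing twin is voxel-identical to
its tumor-free base outside the inserted region (`paired_phantom`).
Cohorts apportion density classes by largest remainder (the clinical
1:4:4:1 A:B:C:D mix is the training default; evaluation cohorts use a
balanced mix).

## Optical stage

Fluence is computed by voxelized Monte Carlo photon transport
(numba-compiled): step lengths from the local scattering coefficient
consumed across voxels by a DDA march, Henyey–Greenstein deflection with
the local anisotropy, continuous absorption weighting (exact exponential
attenuation per voxel segment), a track-length fluence estimator, and
Russian roulette (threshold 1e-4, survival factor 10). The bookkeeping is
exact per realization: launched weight = absorbed + escaped + roulette net,
to ~1e-12 relative. Validation against closed forms: Beer–Lambert decay in
a non-scattering slab recovered to 0.04% at 10⁶ photons; the diffusion
Green's function for a point source in a μs′ = 1, μa = 0.01 mm⁻¹ medium
matched within ~5% for r = 2–6 mm.

The default illumination mirrors a hemispherical breast imager: 20
arc-shaped illuminators spanning 80° on a 145 mm shell, five fiber
segments each (100 line beams), every beam a 12.5° half-angle cone. When
the shell is larger than the grid, photons are propagated analytically to
the grid boundary, so the full-scale geometry works unchanged on desk
grids; with `shell_radius_mm=None` the shell scales to 1.5× the grid
half-extent.

Refractive-index boundaries are treated as matched — no Fresnel reflection
or refraction. The index map is carried but does not bend rays. This
overestimates fluence slightly near the skin–water interface and is the
main known simplification of the optical stage.

## Acoustic stage

The wave solver integrates the first-order acoustic equations for
pressure, particle velocity and split density on a staggered Fourier
collocation grid with k-space corrected derivatives (exact for homogeneous
media at any CFL below the limit), supporting heterogeneous sound speed
and density in 2D and 3D. A split-field perfectly-matched layer of 10
voxels absorbs outgoing waves; the CFL default is 0.3 and violating
configurations are rejected before stepping. The leapfrog-consistent
discrete energy (kinetic term from the product of half-step velocities) is
non-increasing after source release in lossless homogeneous runs.

Power-law absorption (α = α0 f^y) is applied as a per-trace
frequency-domain filter with path-averaged α0 and y over the straight ray
from the source centroid to each sensor — a deliberate surrogate for a
fractional-Laplacian loss operator. It preserves the Study-2 phenomenon
(unmodeled attenuation at reconstruction time) at much lower cost, but it
is not propagative: dispersion is neglected and the path average is crude
for strongly heterogeneous α0 maps.

Transducers are idealized points snapped to the nearest voxel centers
(full-scale default: 108 elements on a rotating 85 mm, 80° arc, 480 views,
3720 samples at 20 MHz; desk studies use reduced counts). Time reversal
re-emits the recorded traces backward in time as Dirichlet pressure values
at the sensor voxels of a homogeneous reconstruction medium and returns
the final-time field. On the coarser reconstruction grid (0.3 mm against
the 0.25 mm forward grid; ratio 1.2 at desk scale) duplicate snapped
positions are collapsed to one retained sensor and the count is logged.
Injected traces are low-passed with a cosine rolloff starting at half the
grid-supported band (f = c/2Δx): content above that band has no
propagating counterpart on the grid and otherwise excites aliased
checkerboard modes. This matters most for the Study-1 colored noise —
time-reversed iid sensor noise — whose interior lag-1 spatial
autocorrelation is ≈ 0.45–0.57 with smoothing (against ≈ 0 for iid voxel
noise) and slightly negative without it.

Measurement noise follows the 1% rule: iid zero-mean Gaussian with
standard deviation equal to 1% of the ensemble mean of the per-phantom
maximum absolute signal, pooled across the three wavelengths. In
`run_study` Study 1 at desk scale the reference level is taken from one
phantom's simulated measurements rather than the whole cohort, bounding
the acoustic cost of the otherwise acoustics-free study arm.

## Estimators

**Linear spectral unmixing** solves, per voxel, the least-squares fit of
the multiwavelength image values to the two hemoglobin spectra and forms
the sO2 ratio; the common scale (Γ, pulse energy, fluence magnitude)
cancels. Negative concentrations are clipped at zero by default; an exact
two-component nonnegative solver (axis projection) is available. Voxels
whose total-hemoglobin estimate falls below 1e-12 of the volume maximum
are marked invalid rather than assigned a ratio. All three wavelengths are
fit jointly (overdetermined), which is the natural reading of a
three-wavelength protocol.

**Fluence-compensated unmixing** divides each wavelength's image by an
estimated fluence before unmixing. The estimate assumes a known breast
segmentation with uniform optical properties — the voxel-weighted
ensemble averages over the cohort's breast voxels — and water properties
outside; it is floored (default 1e-6 of its maximum) before division.

**The learned estimator** is a five-level residual encoder with two
task-specific decoders: each level has one residual block (two 3×3×3
convolutions, leaky-ReLU slope 0.1, 1×1×1 shortcut), 2×2×2 max pooling
between levels, channel squeeze-excitation plus a single-channel spatial
gate at the bottleneck, transposed-convolution upsampling with encoder
skip concatenation, and sigmoid heads — one whole-volume sO2 map, one
segmentation probability for the target structures (arteries, veins,
viable tumor) inside a 15 mm depth shell. The composite loss is

    L = L_reg + η · L_seg,

with L_reg a voxel-weighted MSE on sO2 and L_seg a voxel-weighted binary
cross-entropy plus smoothed Dice loss; weights put a factor 10 on
target-structure voxels against the background (a chosen default — the
weighting countering sparse-vessel class imbalance admits many forms), and
η ramps linearly from 0 over the first 20% of epochs. Training uses Adam
and per-epoch data augmentation by z-rotations in multiples of 18°,
matching the 20-fold azimuthal symmetry of the illumination (masks rotate
nearest-neighbor, continuous maps linearly). The network runs on a small
reverse-mode automatic-differentiation engine over NumPy arrays written
for this package (`dl/autograd.py`); convolutions use strided sliding
windows with einsum, gradients verified against finite differences to
1e-6. Toy-scale training (24³ volumes, base width 8, three levels, a few
hundred steps) is the supported regime; the full-scale defaults (five
levels, step size 1e-5, batch 2) remain expressible in config. Network
input volumes are normalized per sample by the pooled multiwavelength
maximum.

## Evaluation protocol

Depth is everywhere the Euclidean distance transform inward from the
water–tissue interface; it defines the 15 mm segmentation shell, the depth
bins (default 3 mm) of the vessel-sO2 MAE table, and the 0.6 mm
superficial exclusion used before scoring out-of-distribution skin tones.
The unified predicted mask is separated morphologically: multiscale
Frangi vesselness (scales 1–3 voxels) thresholded at an absolute 0.1 of
the normalized response, erosion-then-dilation with a radius-1 ball to
disjoin touching structures, then 26-connected components classified as
vessels iff strictly more than 50% of their voxels carry vessel evidence.
A true tumor counts as detected iff the predicted-tumor overlap strictly
exceeds the threshold — 500 voxels for the reference 3808-voxel tumor at
0.25 mm, scaled as the constant fraction 500/3808 of the true tumor volume
on other grids. Dice uses the both-empty = 1 convention. Tumor sO2 is
reported as paired (true mean over the true region, estimated mean over
the model-identified region), tagged by location. The separation step is a
deterministic rule-only pipeline; no manual correction stage exists, so
misclassified components stay misclassified. Ball/tube discrimination by
the Frangi rule is reliable for tumors of radius ≳ 6 voxels and inherently
ambiguous below — desk configurations that exercise detection must keep
tumors above that size.

## Study designs

**Study 1** (idealized): the true p0 volumes are corrupted directly with
colored image-domain noise obtained by time-reversing iid sensor noise at
the water sound speed. Reconstruction artifacts are absent by design.

**Study 2** (realistic): heterogeneous forward simulation (sound speed,
density, attenuation) on the fine grid, sensor-domain noise, then time
reversal on the 1.2× coarser grid assuming the water sound speed, uniform
density and no attenuation — introducing aberration, blurring and
grid-mismatch artifacts. A matched-reconstruction flag (breast-mean sound
speed) exists for direction-only comparisons; matched reconstruction
correlates strictly better with the true p0 than the mismatched default.

## What the desk scale does and does not show

The generator emulates the statistical structure of full-scale anatomies
— label sets, functional ranges, paired tumor insertion, density and skin
tone mixes — but not their morphometry: desk breasts are 9–13 mm in
radius with ~1 mm voxels, so the one-voxel skin shell is ~12% of breast
voxels and vessels ~5%, far above their real fractions, and the maximum
depth is ~13 mm rather than the 15 mm shell of a ~70 mm breast.
Consequences measured with this package:

- Naive unmixing underestimates arterial sO2 robustly (bias ≈ −0.07 to
  −0.20 across configurations), mirroring the spectral-coloring
  phenomenology of cohort studies at full scale.
- At desk scale that bias is dominated by *intra-vessel self-shielding* —
  the spectral filtering of fluence inside optically thick vessels. A
  controlled experiment (1 mm artery, spectrally flat background) gives a
  −0.16 bias that compensation with the *true* fluence removes to machine
  precision, while *homogeneous-property* compensation cannot remove it at
  all, because a homogeneous model contains no vessels. Over a ≤13 mm
  breast the depth-coloring component that homogeneous compensation does
  fix is comparatively small, so the compensated baseline is near-neutral
  on the desk cohort — unlike at full scale, where coloring accumulates
  over 15 mm of tissue. The compensation benefit is therefore demonstrated
  where its mechanism operates: a two-layer phantom with a blood-rich
  absorbing overburden above thin vessels, where it cuts the bias roughly
  in half (−0.12 → −0.07).
- The toy-trained network beats naive unmixing on held-out vessel MAE
  (≈ 0.14–0.17 vs ≈ 0.19–0.25) after minutes of CPU training — a
  direction-only statement; nothing at this scale estimates the accuracy a
  fully trained model would reach.

## Numerical choices and degenerate inputs

Seeds: every stochastic stage takes an explicit seed; cohort members,
tumor streams and noise draws derive deterministically from a master seed.
Zero-scattering media propagate ballistically (not an error); all-zero p0
yields all-zero traces; empty masks yield empty separations; two empty
masks score Dice 1. The sO2 ratio is clipped to [0, 1]; probability 0.5 is
excluded from the segmentation mask (strict threshold). HDF5 containers
round-trip phantoms and sensor data losslessly; NIfTI export preserves the
voxel spacing in the header.

## Problem sizes used by the shipped tests and the acceptance script

Unit and acceptance tests run at 24³–128² grids with 10⁴–10⁶ photons;
study smoke runs use 2–4 phantoms at 24³–32³; the toy training runs use
16–20 training samples at 24³ for ~100–200 optimizer steps. These sizes
were chosen so a full check of the pipeline — phantom statistics, physics
limits, both study designs and a trained toy model — completes on a single
CPU in well under an hour while keeping every qualitative phenomenon
measurable.
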