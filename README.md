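# qpactvi

Virtual-imaging studies for 3D quantitative photoacoustic computed
tomography (qPACT) of the breast, at desk scale.

Quantitative PACT aims to estimate physiological quantities — above all
blood oxygen saturation, sO2 — from multiwavelength photoacoustic images.
Validating estimators *in vivo* is hard because reference sO2 maps do not
exist; virtual-imaging studies fill the gap by pairing stochastic numerical
breast phantoms, whose optical, acoustic and functional maps are known
exactly, with physics-based simulation of the whole acquisition chain.
`qpactvi` implements such a testbed end to end for anyone developing or
benchmarking qPACT estimators: phantom generation, Monte Carlo optics,
k-space acoustics with time-reversal reconstruction, spectral-unmixing
baselines, a toy-scale dual-task neural estimator, and a cohort evaluation
protocol — all runnable on a single CPU.

## The model in brief

The induced initial pressure at position r and wavelength λ is

    p0(r, λ) = Γ μa(r, λ) Φ(r, λ),    Γ = 1,

with the absorption coefficient a chromophore sum

    μa = THb·sO2·ε_HbO2(λ) + THb·(1−sO2)·ε_Hb(λ)
       + w·ε_water(λ) + f·ε_fat(λ) + m·ε_melanin(λ)

over the three illumination wavelengths 757, 800 and 850 nm. Linear
spectral unmixing inverts this per voxel assuming wavelength-invariant
fluence; the fluence-compensated variant first divides by a homogeneous-
property fluence estimate; the learned estimator maps the three
reconstructed p0 volumes directly to an sO2 map plus a vessel/tumor
segmentation, trained with the composite loss L = L_reg + η·L_seg. Two
study designs probe robustness: Study 1 corrupts the true p0 with colored
image-domain noise only; Study 2 adds heterogeneous acoustics, sensor
noise, and time reversal under mismatched homogeneous assumptions.
`docs/methods.md` describes every stage, its parameters and its
limitations.

## Worked example

Run the idealized study on a two-phantom cohort and print the evaluation:

```sh
$ qpactvi study1 --n 2 --seed 7 --size 32 --voxel 0.75 --radius 9 \
      --photons 20000 --out demo_study1
study 1 outputs in demo_study1
$ qpactvi evaluate demo_study1/summary.json
study 1  phantoms 2  seed 7
  linear_unmix: Dice 0.448+/-0.057  tumors TP 1 FP 0 FN 1
    depth 0-3 mm: MAE 0.1025 (n=11)
    depth 3-6 mm: MAE 0.1495 (n=85)
    depth 6-9 mm: MAE 0.0267 (n=1)
  fluence_compensated: Dice 0.448+/-0.057  tumors TP 1 FP 0 FN 1
    depth 0-3 mm: MAE 0.1937 (n=11)
    depth 3-6 mm: MAE 0.2166 (n=85)
    depth 6-9 mm: MAE 0.3489 (n=1)
```

Reading this: two tumor-bearing phantoms were generated at 32³ voxels
(0.75 mm), imaged at three wavelengths with 20k Monte Carlo photons each,
and corrupted with colored noise. The depth rows give the mean absolute
error of the estimated vessel sO2 on the normalized 0–1 scale (0.15 ≈ 15
percentage points) per 3 mm depth bin; Dice scores the morphological
vessel separation against the true vessel mask; the tumor counts apply the
strict overlap rule (one of the two tumors is recovered at this tiny
scale). Naive unmixing errs by 10–15 points and grows with depth —
spectral coloring at work. The `make-phantoms`, `simulate-optics`,
`unmix`, `study2`, `train-toy` and `report` subcommands expose the other
stages; every command takes an explicit `--seed` and is bit-reproducible.

The same pipeline is available as a library:

```python
from qpactvi.workbench import StudyConfig, run_study
result = run_study(StudyConfig(study=2, n_phantoms=4, seed=0))
print(result.summary["linear_unmix"]["dice_mean"])
```

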