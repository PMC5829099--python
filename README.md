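# lcacomp

A computational model of how the retina compensates for **longitudinal
chromatic aberration (LCA)** — the ~2-diopter wavelength dependence of the
eye's refractive power that leaves the S-cone (blue) image badly defocused
while L/M images stay sharp. Optically, this should paint blue–yellow
fringes on every luminance edge; perceptually, it doesn't. The model
explains the compensation with two properties of the S pathway: the
high-resolution *form* channel is built from L and M cones only, and the
blue–yellow signal travels through large, spatially **coextensive type-II
receptive fields** (small bistratified cells) that give a null response to
achromatic structure — blurred or not.

The package is aimed at visual-neuroscience and computational-vision work:
it simulates retinal images under LCA, encodes them with adapted cone
signals feeding opponent receptive fields, and inverts the opponent code to
reconstruct the perceived image.

## Model in brief

For cone planes L, M, S (linear units), with `*` denoting convolution:

- adaptation: `x_ad = x/(x + σ_x) · (x + x_rem)`, `σ_x = a·x + b + c·x_rem`,
  where `x_rem` is a weighted mean over a 35-px remote annulus
  (a = c = 1, b = 3);
- type-I opponent cells (DOG): `L+M- = L_ad*f_c − M_ad*f_s`,
  `M+L- = M_ad*f_c − L_ad*f_s`, with Gaussian kernels of decay 1 px
  (center) and 3 px (surround);
- type-II cell: `S+(L+M)- = [S_ad − (L_ad+M_ad)/2] * f_s`;
- inverse transform: solve `L+M- = L_per − M_per*f_s`,
  `M+L- = M_per − L_per*f_s` for the perceived planes (least squares, four
  interchangeable solvers), then `S_per = S+(L+M)- + (L_per+M_per)/2`.

Because the type-II channel ignores achromatic contrast entirely, the
defocus-induced S distortion at luminance edges never reaches the perceived
image; what survives is genuine low-frequency blue–yellow content — which
also predicts assimilative chromatic induction on S-cone ring patterns.

See `docs/methods.md` for assumptions, parameters, and numerical details.

## Worked example

```python
from lcacomp import fringe_experiment, induction_experiment

# 1. achromatic 256x256 grid, 64-px squares, default optics (1.5 D S defocus)
fr = fringe_experiment()
print(fr["retinal_fringe"], fr["perceived_fringe"], fr["reduction"])
# 4.2468 1.2655 0.702

# 2. S-cone ring pattern, two inducer variants, identical test ring
rep = induction_experiment()["report"]
print(rep.variant_a_contrast, rep.variant_b_contrast, rep.shift)
# 0.6824 0.3460 0.3365
```

In the first experiment, the maximum deviation of the blue/yellow ratio
B/((R+G)/2) from the achromatic value 1 near square borders is 4.25 in the
simulated retinal image but 1.27 in the model's perceived image — the model
removes 70% of the chromatic fringing that the optics created.

In the second, the physically identical test ring reads a mean
S/(L+M) chromatic contrast of 0.68 when flanked by purple (high-S) rings
and 0.35 when flanked by lime (low-S) rings: a shift of ~0.34 *toward* the
adjacent inducer, i.e., the assimilative color-shift phenomenon reported
for S-cone patterns.

A command-line interface mirrors the library:

```sh
lcacomp fixtures grid --out grid.png
lcacomp simulate-optics --input grid.png --out retinal.png --defocus-s 1.5
lcacomp run --fixture grid --outdir out/        # full pipeline + manifest
lcacomp profile --input out/perceived.png --row 32 --out profile.csv
lcacomp induction                               # ring-pattern prediction
```

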