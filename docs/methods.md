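# Methods

`chromacc` is a desk-scale computational study of color constancy in
convolutional networks.  Networks are trained to report the surface
reflectance class of an object rendered under varying natural
illuminations; constancy is then measured psychophysics-style, by probing
the trained models with novel illuminants and manipulated scenes.  This
note records the model, the synthetic-data design, the numerical choices,
and what the desk-scale results do and do not show.

## Colorimetry

Spectra are sampled on a 20-band grid spanning 380–830 nm (the channel
count of the emulated multispectral renders); sensor tables are resampled
onto the working grid at load time and integrals use trapezoidal
quadrature.  Two bundled constant tables drive everything: the CIE
daylight component spectra S0/S1/S2 (10 nm) and the CIE 1931 2°
color-matching functions (10 nm).  Daylight spectra for a correlated
color temperature T are reconstructed as S0 + M1·S1 + M2·S2 with the
standard chromaticity polynomial and weight formulas; the reconstruction
reproduces the locus chromaticity to ~1e-4 on a fine grid.

Cone fundamentals are defined as the Hunt–Pointer–Estevez linear
transform of the 1931 observer (negative side lobes, ~1e-5 of peak,
clipped at zero).  Defining LMS this way, rather than bundling an
independent cone table, keeps LMS ↔ XYZ an exact 3×3 linear map, so
chromaticity measurements on rendered LMS images need no fitted
conversion matrix.  Which cone tabulation the original study used is not
stated anywhere we could verify, so the choice is a fixed convention of
this package, not a reproduction claim.

CIELab uses the CIE 1976 formulas against a scene white point: the XYZ of
the brightest neutral reflectance (flat 0.9) under D65.  ΔE is the
Euclidean Lab distance; the chromatic distance drops L*.

**Illuminant chromaticity anchoring.**  The Lab transfer is a cube root,
so chromatic differences compress as luminance falls.  An illuminant's
(a*, b*) chromaticity is therefore measured with its luminance pinned to
that of an 18 % mid-gray reference surface (`GRAY_ANCHOR`) — the
lightness regime of the chip set itself — rather than at L* = 100.
Under this convention a test illuminant placed 10 ΔE from the gray point
induces chip-level chromaticity shifts of ~9.5–14 ΔE across the catalog,
which restores the study premise that illuminant shifts exceed the
7.3 ΔE class spacing (and reproduces the ~10 ΔE errors expected of a
non-constant observer).  Anchoring at the white point instead compresses
chip shifts to ~6 ΔE and silently breaks that premise.

## Reflectance catalog

The label space is a cylindrical grid in Lab: hue → angle (circular, 10
hues by default), chroma → radius (4 steps of 2 Munsell chroma units),
value → L* (4 rows), plus a neutral column, ≈164 classes.  Reflectances
are logistic squashes of three smooth basis functions (constant + two
broad Gaussians at 610 and 460 nm), solved per class by least squares so
the chip's D65 Lab lands on its grid target; the squash keeps every
spectrum inside (0, 1).  Classes whose target cannot be reached within
0.5 ΔE are dropped — the analogue of the measured chip set's limited
gamut (none are dropped at the default desk scale).

A global scale on the chromatic radius and L* spread is iterated
(secant-style, ≤4 rounds) until the median ΔE between adjacent classes
equals the 7.3 ΔE spacing of the measured Munsell set within 2 %.
Adjacency means one grid step in exactly one coordinate, hue circular;
neutrals neighbor only along their value column (whether the measured
set's "adjacent" includes diagonals is unstated; this convention is
recorded in the catalog manifest).  All adjacent pairs exceed the 2.3 ΔE
just-noticeable difference.

The evaluation subset is a World-Color-Survey-like sheet: the most
saturated chip per (hue, value) cell plus the neutral column (44 classes
at desk scale, standing in for the 330-chip subset at full scale).

## Scenes and illuminants

The renderer is a direct-illumination Lambertian approximation: every
pixel is `project(E × R, LMS) × shading` with a smooth, illuminant-
independent shading field; no interreflections, shadows, or camera
model.  This preserves exactly the statistical structure the analysis
needs — illuminant-induced chromaticity shifts on the object, plus
constant contextual cues — at a fraction of the cost of global
illumination.  The scene is a fixed "room": ceiling, floor, back wall and
two side walls with near-neutral reflectances, six constant colorful cue
patches on the back wall (red / yellow / green / blue directions plus a
light and a dark neutral), and a procedural blob object (smoothed random
polar harmonics, pseudo-spherical shading) floating below the patch
strip, never occluding the patches or the image border.  Desk images are
32×32; 128×128 is config-reachable.

Training illuminants: `n_dseries` D-series spectra at evenly spaced CCTs
over 4000–12000 K plus `n_jittered` spectra built by Gaussian jitter of
the D65 daylight-basis weights (emulating the measured forest
illuminations, whose published statistic is their chromatic spread).
The jitter amplitude is calibrated by root finding so the whole set's
(a*, b*) standard deviation equals 8.55 ΔE ± 3 %.  The full-scale set is
43 + 236 = 279; the desk set keeps the same D-series fraction (5 + 35).
Spectral shapes of the real forest illuminations beyond their chromatic
spread are not reproduced — jittered daylight is an explicit emulation.

Test illuminants Y/B/G/R are daylight-basis spectra placed by least
squares exactly 10 ΔE from the gray point in (a*, b*): Y/B along the
locus tangent, G/R orthogonal to it; their areas under curve are
equalized to D65's.  The four conditions are rendered per trial:
`normal`; `no_patch` (patches replaced by wall); `wrong_patch` (patches
under D65); `wrong_background` (everything but the object under D65);
plus six single-patch masks.

## Networks and training

The classifier is a sequential ConvNet: conv 16/32/64 kernels of size
5/3/3 (stride 1, no padding), each with ReLU and 2×2 max pooling, two
250-unit fully connected ReLU layers, 40 % dropout, linear head — 3.6 M
parameters at 128×128 / 1600 classes.  `width_scale` shrinks channels
and units proportionally (desk default 0.5).  Implementation is plain
numpy (im2col convolution, explicit backward passes, He initialization,
seeded); max-pool gradients split evenly across ties so training is
deterministic.  Inputs are divided channel-wise by the white chip's cone
excitations — a fixed unit convention, not an adaptive correction.

Training: Adam, cross-entropy, learning rate 1e-3 divided by 10 every 30
epochs, 90 epochs at full scale.  Desk recipes keep the same ÷10-per-
third shape with fewer epochs.  Datasets split 90/10 with held-out
object shape seeds, and held-out illuminant ids when illumination varies.
Linear readout probes take the post-ReLU, pre-pool activations of a
layer; the backbone is frozen (verified bit-exactly).

## Metrics

Top-1 / top-5, Muns3 (within a cube of side 3 in Munsell coordinates,
hue circular), the selected-chromaticity ΔE (Lab distance between the
predicted and true chips' D65 reference chromaticities), and the Color
Constancy Index

    CCI = 1 − ‖C_I^N − C_I^M‖ / ‖C_D65^M − C_I^M‖

with chip chromaticities computed from flat, unshaded renders (full Lab;
whether the original index uses (a*, b*) only is unstated — full Lab is
the default and a config switch).  The index is undefined (excluded,
counted) when the denominator is below 1e-6, e.g. under D65 itself.

Baselines estimate the illuminant (Gray World = scene mean, White Patch
= per-channel maximum, simplified ASM = contrast-adaptive pooling of the
1–20 % brightest pixels), apply a global von Kries division, and measure
the segmented object's mean chromaticity against the same trial rendered
under D65.  Estimates carry no absolute scale, so object chromaticities
are compared at the anchored mid-gray luminance, which makes the
comparison scale-invariant.  The ASM here is a one-sentence-description
reimplementation with logged parameters, not a claim of equivalence to
the original algorithm.

Representational analysis: class-mean activations over the evaluation
classes under D65+Y/B/G/R → correlation-distance RDM → classical
(Torgerson) MDS → ordinary Procrustes (rotation/reflection, translation,
isotropic scale) onto a cylindrical Munsell embedding (hue angle, chroma
radius, value × 2 — the axis scale is a convention, config-exposed) or
onto CIELab coordinates.  Because the reference embedding's scaling is a
convention, absolute explained-variance percentages are not reproduction
targets; only orderings across layers and the trained-vs-random contrast
are asserted.

## Desk scale: what it shows

The desk recipe runs on one CPU: 164 classes, 40 training illuminants,
32×32 images, `width_scale` 0.5, three instances per training variant.
Choices that differ from the full-scale recipe, made once for the
few-shot regime (tens of images per class instead of hundreds):

* object radius 20 % of image height, so the labeled surface occupies a
  substantial share of the frame, as in the rendered room scenes;
* two images per (class, illuminant) for the varying-illumination
  dataset (~11.8k training images) and 40 per class for the D65-only
  dataset;
* learning rate 2e-3 with the same ÷10-per-third step shape over 45
  epochs, and dropout 0.2 instead of 0.4 — at this data scale the
  failure mode is underfitting, not overfitting.  The first schedule
  stage must be long enough (15 epochs) for every seed to clear the
  slow early phase before the rate drops; shorter stages leave some
  seeds stranded at a fraction of their reachable accuracy.

Under these conditions training instances reach ~73–86 % validation
top-1 on the varying-illumination task, and
the evaluation under Y/B/G/R reproduces the study's qualitative
structure: near-ceiling constancy in the normal condition, graded
degradation when cues are removed, collapse to the D65-trained model's
level when the background is falsified, a daylight-locus advantage
(Y ≈ B > G > R), constancy rising with readout depth, and the classical
baseline ordering.  Full-scale published accuracies are not desk
targets; every number the tests and the acceptance script assert is
computed fresh at run time at these desk sizes.
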