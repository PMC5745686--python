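# Methods

## Signal model

Porphyrins synthesized by anaerobic bacteria in mature plaque absorb
violet light near 405 nm (the Soret band) and fluoresce red near 640 nm;
sound enamel and dentin autofluoresce green under the same illumination.
A color photograph taken under 405 nm light therefore encodes the plaque
map in hue: reds are plaque, greens are uncovered tooth, everything else
(lips, gingiva, shadow, non-fluorescent restorations) is background.
The package treats this purely as a per-pixel color classification
problem — no spatial prior, no morphology, no learning.

## Pipeline and parameters

**Normalization.** Each RGB channel is independently min-max rescaled to
[0, 1] per image. This is the simplest operator that makes all three
channels "span the same range"; it is idempotent, and a zero-range
(constant) channel maps to all zeros by convention. It assumes each
channel attains its extremes somewhere in the frame — true of real
intraoral shots, which contain deep shadow and specular highlights. For
inputs that are already normalized the step can be disabled
(`normalize=False` / config `normalize: false`).

**HSV thresholds (fluorescence mode).** Membership is closed-interval on
every band; hue is circular on [0, 1] with 1 ≡ 0, so both endpoints of
the red union H ∈ [0, 0.1] ∪ [0.82, 1] are included. The saturation
floor 0.15 rejects washed-out near-achromatic pixels (achromatic pixels
have S = 0 exactly) and the value floor 0.1 rejects near-black pixels.
The tooth band H ∈ [0.16, 0.50] with the same S/V floors is this
package's own default — green enamel autofluorescence centers near hue
1/3 — chosen disjoint from the red union; unlike the plaque bands it has
no published counterpart, and it is fully configurable. If a user
supplies overlapping custom bands, plaque wins.

**L\*a\*b\* thresholds (reference mode).** The reference device recolors
plaque yellow/deep orange; those signatures are isolated by
L\* ∈ [0, 90], a\* ∈ [−20, 13], b\* ∈ [17, 78] (all three must hold).
Conversion assumes sRGB primaries with the D65 white point — the
device's camera profile is unknown, so this standard choice is
documented rather than derived. The conversion wraps scikit-image but
rescales XYZ by the white point implied by the sRGB matrix itself, so
gray pixels land exactly on a\* = b\* = 0 instead of ~2×10⁻³ off (an
artifact of the rounded matrix). Channels are *not* renormalized in
this mode: the bands are stated on the absolute 8-bit sRGB scale.
Because the device only marks plaque, the coverage denominator needs an
interpretive tooth definition: any non-plaque pixel with HSV value ≥ 0.1
(the same floor the fluorescence bands use) counts as tooth. This is an
operational choice that makes the two devices' ratios commensurable.

**Coverage ratio.** r = n_plaque / (n_plaque + n_tooth). The
denominator includes plaque pixels: only then does full coverage give
r = 1 and no plaque give r = 0. If an image shows no tooth area at all
the ratio is undefined (None), never 0. Hygiene baselines partition
[0, 1]: excellent [0, 0.05), fair [0.05, 0.15], poor (0.15, 1]. The
poor band being strictly above 0.15 fixes 0.15 as fair; assigning the
boundary 0.05 to fair is this package's convention. Per-subject
aggregation defaults to pixel pooling, Σ n_plaque / Σ (n_plaque +
n_tooth), which equals the tooth-area-weighted mean of per-image ratios
(an identity the tests check numerically); an unweighted mean of ratios
is available as `method="mean"`. Device deltas are r_ref − r_fluor,
rounded to 4 decimals for reporting; cohort summaries count positive,
negative and exactly-zero deltas as three disjoint buckets.

## Phantom generator

The generator emulates only the color logic of a 405 nm photograph, not
its optics. Geometry is schematic: a horizontal band of `n_teeth`
rectangles separated by 1–3 px interproximal gaps, sized so the tooth
region holds exactly round(tooth_fraction · H · W) pixels. Plaque
pixels are the round(plaque_fraction · region) region pixels closest —
with a small seeded jitter that roughens blob outlines — to the gingival
margin at the top of the band or to a gap, mimicking where plaque
accumulates. Optional restoration patches fill the deepest band
interior, render dark/achromatic (restorations lack autofluorescence),
carry their own truth label, and are excluded from the coverage
denominator: the pipeline correctly sees them as background.

Colors are drawn uniformly from strictly inside the target threshold
bands with margin ε (default 0.02 for the built-in models; the
`sample_in_band` primitive defaults to ε = 0.01 and rejects bands
narrower than 2ε), so float round-off through HSV→RGB→HSV cannot cross
a closed band edge. Background is dark achromatic (V < 0.1).
Each phantom plants one pure-black and one pure-white background pixel
so per-channel min-max normalization is the identity on the noise-free
image — this stands in for the full dynamic range of real photographs
and is what makes exact recovery provable. Optional sensor noise is
additive Gaussian in RGB after rendering, clipped to [0, 1]; it is
applied before the pipeline's own normalization, which is then part of
what is being tested.

Defaults (chosen once as plausible study conditions): 192×256 px,
tooth_fraction 0.6, plaque_fraction 0.079 — the average clinical
coverage ratio — 4 teeth, no restorations, no noise.

**What passing phantom tests shows and does not show.** Exact noise-free
recovery demonstrates that the implementation's normalization,
conversion, band logic and counting are internally consistent, and the
corruption sweep characterizes robustness to pixel noise. It says
nothing about threshold validity on real tissue, specular highlights,
stain/dentin confounds, or camera color response — those require
clinical images, which were never deposited.

A measured caveat on the noise model: because noise is clipped to
[0, 1], the underlying color still biases which rail each channel
saturates at, and a ratio pooled over thousands of pixels detects that
bias. Monte-Carlo puts the correlation between recovered and true
ratios at ≈ 0.8 at noise sd = 1 and below 0.5 only from sd ≈ 2; "extreme
noise" decorrelates the score far more slowly than per-pixel error rates
would suggest.

## Numerical choices and degenerate inputs

- All thresholding is exact float comparison on closed intervals; no
  tolerances are applied at band edges.
- Achromatic pixels take hue 0 by convention and saturation exactly 0.
- Empty images, negative counts, out-of-range ratios or channels, and
  inverted bands (lo > hi) raise `ValueError` (config errors name the
  offending key).
- The analysis pipeline is fully deterministic; the only randomness in
  the package is the phantom generator's seeded `numpy` Generator.
- Segmentation is vectorized but specified by the scalar
  `classify_pixel_fluorescence`; the test suite enforces bit-identical
  agreement between the two routes.

## Problem sizes

The test suite and acceptance script validate on phantoms of 48–128 px
per side, 50 random specifications for the exact-recovery check and 20
images for the oracle-equivalence check — sizes at which every property
under test is scale-invariant (ratio invariance under upsampling is
itself one of the checks).

## Known limitations

- The green/tooth band has no published reference value and cannot be
  validated against clinical images.
- Reference-mode tooth pixels (and hence that mode's denominator) are an
  operational definition, not a published one.
- Whether the published analysis normalized channels before the
  reference device's L\*a\*b\* segmentation is unknown; this
  implementation does not.
- No tooth-instance separation, plaque maturity staging, caries
  detection, or multi-view registration.
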