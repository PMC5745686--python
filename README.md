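# fluoroplaque

Segmentation and quantification of dental plaque from fluorescence
photographs.

Mature dental plaque harbors porphyrin-producing anaerobic bacteria.
Under 405 nm (violet) illumination these porphyrins fluoresce red
(~640 nm) while sound enamel autofluoresces green, so a plain color
photograph separates plaque from uncovered tooth surface without
disclosing dye. `fluoroplaque` implements the image analysis for this
kind of screening: it is intended for researchers and tool builders
working with low-cost fluorescence intraoral cameras who need a
deterministic, auditable plaque score per image and per subject.

## Method

For each image the pipeline is:

1. **Normalize** — each RGB channel is min-max rescaled to [0, 1] per
   image, equalizing exposure differences between shots.
2. **Convert** — pixels are mapped to HSV (hue *H* ∈ [0, 1] circular,
   saturation *S*, value *V*).
3. **Threshold** — a pixel is **plaque** if
   *H* ∈ [0, 0.1] ∪ [0.82, 1], *S* ∈ [0.15, 1], *V* ∈ [0.1, 1]
   (the red fluorescence signature), **tooth** if
   *H* ∈ [0.16, 0.50] with the same *S*/*V* floors (green
   autofluorescence), and **background** otherwise. All intervals are
   closed; every band is configurable.
4. **Score** — the plaque coverage ratio is

   r = n_plaque / (n_plaque + n_tooth),

   ranging 0 (no plaque) to 1 (total coverage of the visible tooth
   area), with clinical hygiene baselines *excellent* (r < 0.05),
   *fair* (0.05 ≤ r ≤ 0.15) and *poor* (r > 0.15). Per-subject scores
   pool pixel counts across that subject's images.

A second mode segments the recolored plaque of a commercial plaque-mode
intraoral camera by CIE L\*a\*b\* thresholds
(L\* ∈ [0, 90], a\* ∈ [−20, 13], b\* ∈ [17, 78], isolating its
yellow/deep-orange plaque enhancement), so scores from both devices can
be compared subject by subject via Δ = r_ref − r_fluorescence.

Because no clinical image set is distributed, the package ships a seeded
phantom generator (`fluoroplaque.synthetic`) producing schematic
intraoral images — green tooth rectangles, red plaque blobs along the
gingival margin and interproximal gaps, dark non-fluorescent restoration
patches — with exact per-pixel ground truth, used throughout the test
suite.

## Worked example

Generate three phantom views of one subject with known coverage, then
score them:

```python
from fluoroplaque import PhantomSpec, generate_phantom
from fluoroplaque.io_utils import write_image

for name, frac, seed in [("S1_view0", 0.03, 1), ("S1_view1", 0.12, 2),
                         ("S1_view2", 0.22, 3)]:
    ph = generate_phantom(PhantomSpec(height=96, width=128,
                                      plaque_fraction=frac, seed=seed))
    write_image(f"in/{name}.png", ph.image)
```

```
$ fluoroplaque batch in -o out
3 images, 1 subjects -> out

$ cat out/images.csv
image_id,subject_id,mode,n_plaque,n_tooth,ratio,category
S1_view0.png,S1,fluorescence,221,7152,0.0299742302997423,excellent
S1_view1.png,S1,fluorescence,885,6488,0.12003255120032551,fair
S1_view2.png,S1,fluorescence,1622,5751,0.21999186219991862,poor

$ cat out/subjects.csv
subject_id,n_images,aggregate_ratio,category
S1,3,0.1233328812333288,fair
```

Each per-image ratio recovers the generating plaque fraction to within
one pixel of rounding (0.03, 0.12, 0.22), and the subject-level score
pools all three views' pixels (1233/21324 visible-tooth pixels are
plaque, category *fair*). `out/` also holds a mask PNG (0/128/255 =
background/tooth/plaque) and a plaque-highlighted overlay per image.

Comparing the two devices on the bundled five-subject example cohort:

```python
from fluoroplaque import device_delta, summarize_cohort
from fluoroplaque.datasets import example_device_cohort

comps = [device_delta(r.ref_ratio, r.pf_ratio, r.subject_id)
         for r in example_device_cohort().itertuples(index=False)]
for c in comps:
    print(c.subject_id, c.ref_ratio, c.pf_ratio, c.delta)
print(summarize_cohort(comps).n_positive_delta, "of", len(comps), "positive")
```

```
M2 0.4158 0.1891 0.2267
M3 0.367 0.0213 0.3457
M18 0.2274 0.0418 0.1856
M24 0.4869 0.0099 0.477
M100 0.3494 0.0561 0.2933
5 of 5 positive
```

A positive delta means the reference device scored more plaque than red
fluorescence did — here for every subject in the example cohort.

CLI subcommands: `segment` (one image), `batch` (a directory, grouped by
a subject-id filename pattern), `phantom` (synthetic images), `compare`
(paired-device deltas from images or a ratio table). Thresholds and run
options load from YAML/JSON via `--config`; an empty config reproduces
the defaults above.

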