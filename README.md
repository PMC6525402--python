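# pcotex

Texture-based grading of **posterior capsule opacification (PCO)** in
digital retroillumination images.

PCO — clouding of the lens capsule behind an intraocular lens (IOL) after
cataract surgery — is graded from photographs of the posterior capsule lit
by light reflected from the fundus. `pcotex` implements a fully automated
qualitative *and* quantitative grader: every pixel of the central 4.0 mm
optic disc is classified into one of six opacification textures, and the
per-pixel classification is condensed into a single severity score. It is
aimed at researchers studying PCO progression or PCO-preventing IOL designs
who need observer-independent grading.

## Method

For every pixel, four families of local texture features are computed over
a square window (default 17 px, reflect-padded borders):

1. **GLCM statistics** — energy, entropy, contrast, homogeneity and
   correlation of a windowed gray-level co-occurrence matrix accumulated
   over four displacement directions;
2. **first-order statistics** — window mean, standard deviation, skewness,
   excess kurtosis, histogram entropy;
3. **Gabor filter-bank responses** — locally averaged response magnitude
   and its local spread per (frequency, orientation) channel
   (3 frequencies × 4 orientations);
4. **local fractal dimension** by differential box counting.

A subset of these 35 planes is chosen by sequential forward floating
selection (SFFS) with cross-validated accuracy of a diagonal-Gaussian Bayes
classifier as the wrapper criterion; the same classifier then labels each
pixel with one of six classes, each carrying a severity weight *w*:

| class            | color  | weight |
|------------------|--------|--------|
| clear            | black  | 0      |
| honeycomb A      | cyan   | 0.8    |
| honeycomb B      | blue   | 1      |
| plate            | green  | 2      |
| pearl plate      | yellow | 3      |
| Elschnig pearls  | red    | 4      |

With *p<sub>n</sub>* the number of pixels assigned class *n*, the global
score is the weighted mean

```
score = ( Σₙ pₙ·wₙ ) / ( Σₙ pₙ ),        n = 1 … 6
```

reported after linear rescaling to 0–100. Saturated Purkinje-reflex pixels
are detected, dilated, and excluded from both sums. The color-coded class
map (per the table above) is the qualitative output.

Because clinical image sets of this kind are not redistributable, the
package ships a first-class synthetic generator (`pcotex.synthetic`) that
renders labelled scenes spanning the severity continuum, plus repeat images
(exact 90° rotations and re-rendered "consecutive" exposures) for
repeatability studies. Validity is quantified as the Pearson correlation
between graded score and reference severity; repeatability as the
Bland–Altman mean difference, its 95% CI (1.96·sd/√n), and the coefficient
of repeatability CR = 1.96·sd of the paired differences.

## Worked example

```python
import pcotex as pt

# train on a small labelled synthetic dataset
scenes, manifest = pt.generate_dataset(12, seed=101)
grader = pt.PCOGrader(random_state=101).fit(scenes)
print("selected features:", ", ".join(grader.selected_features_))

# grade an unseen scene
test = pt.generate_scene(55.0, seed=2024)
score, cmap = grader.grade(test.image, roi=test.truth_map.mask)
print(f"truth severity : {test.truth_severity:.2f}")
print(f"raw score      : {score.raw:.4f}")
print(f"scaled score   : {score.scaled:.2f}")
```

prints

```
selected features: fo_mean, glcm_homogeneity, fo_skewness
truth severity : 54.93
raw score      : 2.2741
scaled score   : 56.85
```

The SFFS wrapper settled on three features (window mean, GLCM homogeneity,
window skewness) for these textures; the graded score 56.85 sits within two
points of the ground-truth severity 54.93 on the 0–100 scale. The raw score
2.27 is the average class weight over the ~14,500 scored ROI pixels;
`pt.render_classmap(cmap)` (or `pt.save_classmap_png`) yields the
color-coded segmentation.

The same pipeline is scriptable from the shell:

```
pcotex simulate --n 72 --seed 7 --outdir data/
pcotex train    --data data/ --out-model model.json --seed 7
pcotex grade    --model model.json --outdir out/ data/scene_00*.png
pcotex evaluate --mode validity --scores out/scores.csv \
                --truth data/manifest.csv --out report.json
```

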