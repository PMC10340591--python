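# berryprint

Identify the geographic origin of a fruit from a single photograph.

Produce regions matter for medicinal and food crops — for Chinese
wolfberry (*Lycium barbarum*) the four main origins (Gansu, Inner
Mongolia, Ningxia, Qinghai) yield berries that differ in texture
ruggedness, shape and color, and origin identification is traditionally
done by eye. `berryprint` implements an image-based alternative: crop the
fruit out of its background, describe it with hand-crafted texture and
shape features, and classify the feature vector with a random forest.

## Method

For an image of one fruit on a light background:

1. **Preprocess** — grayscale (`0.299R + 0.587G + 0.114B`), Otsu
   threshold k\* = argmax σ²_B(k)/σ²_G, Sobel contour magnitude
   √(G²x + G²y), a noise-tolerant bounding-box crop, and morphological
   cleanup that sets every background pixel to exactly (0,0,0).
2. **HSI transform** — H = θ or 2π−θ with
   θ = arccos(½[(R−G)+(R−B)] / √((R−G)²+(R−B)(G−B))),
   S = 1 − 3·min(R,G,B)/(R+G+B), I = (R+G+B)/3.
3. **Texture** — one complex Gabor filter per HSI channel
   (λ = 13, 10, 10 px; θ = π/4, π/3, π/12), response magnitude
   histogrammed into 256 bins per channel → **768** texture features.
4. **Shape** — the 7 Hu invariant moments H1…H7 of the preprocessed
   grayscale image → **7** shape features.
5. **Classify** — the fused 775-vector feeds a random forest
   (2000 trees, mtry = 50), evaluated by repeated stratified 8:2
   train/test splits with per-sample misjudgment analysis.

Because origin-labelled fruit photo sets are rarely distributable, the
package includes a synthetic generator (four ellipse classes with
class-specific ridge texture, shape and color on a near-white background)
that serves as the test bed for every stage.

## Worked example

```python
import numpy as np
from berryprint import (FruitFeatureExtractor, LabeledDataset, RfConfig,
                        SplitSpec, repeated_eval)
from berryprint.synthetic import generate_dataset

dataset = generate_dataset(per_class=90, seed=1)        # 360 images, 4 classes
X = FruitFeatureExtractor().fit_transform(dataset.images)
ds = LabeledDataset(X, np.array(dataset.labels), np.array(dataset.ids))

report = repeated_eval(ds, SplitSpec(train_fraction=0.8, seed=0),
                       RfConfig(n_trees=2000, mtry=50, seed=0), repeats=10)
print(f"mean accuracy: {report.mean_accuracy:.2f}%")
print(report.confusion)
print(report.per_class_error_rates().round(2))
```

prints

```
mean accuracy: 99.31%
     GS   NM   NX   QH
GS  177    0    2    0
NM    0  180    0    0
NX    3    0  178    0
QH    0    0    0  180
label
GS    1.67
NM    0.00
NX    1.11
QH    0.00
dtype: float64
```

i.e. the four synthetic classes are almost perfectly separable: out of
10 × 72 test predictions (confusion rows = predicted, columns = actual)
only five were wrong, all confusions between the two "delicate"-texture
classes (GS, NX), and the per-class error rates (percent of test draws
misclassified) identify GS as the hardest class. The same protocol on the
identical-recipe control set gives ≈25% — chance for four classes —
confirming the features, not a leak, carry the signal.

The CLI mirrors the library:

```bash
berryprint synth --out imgs --per-class 90 --seed 7
berryprint extract imgs --labels imgs/manifest.csv -o features.csv
berryprint eval features.csv --repeats 200 --train-frac 0.8 --seed 1 -o report.json
berryprint sweep features.csv --fractions 0.1,0.5,0.9 --repeats 20 -o sweep.csv
berryprint grid features.csv --repeats 5 -o grid.csv
```

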