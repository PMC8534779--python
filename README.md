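# entrotex

Texture recognition by fusing pretrained-CNN descriptors of an image with
descriptors of its **local non-additive entropy map**.

Texture — the spatial pattern of pixel intensities that characterises a
surface — is what distinguishes, say, the leaf surfaces of plant species,
fabric types, or materials photographed in the wild. Convolutional networks
used as black-box feature extractors describe textures well, but they look
only at the raw image. This package adds a second viewpoint: a
representation in which each pixel is replaced by a measure of the
*disorder* of its neighbourhood, computed with the Tsallis (non-additive)
generalisation of entropy. Fusing the two viewpoints gives a descriptor
that separates classes neither stream separates alone.

## The method

For a grayscale image `I` with intensities in `[0, L−1]` (L = 256):

1. **Local entropy transform.** Around each pixel `(x, y)` take the square
   window of radius `r` (side `2r+1`), build its intensity histogram with
   bin width `h_b` (`k_max = L / h_b` bins, normalised to probabilities
   `p_k`), and replace the pixel by the reduced Tsallis entropy

       S′_q(x, y) = Σ_k p_k^q .

   The entropic index `q > 0` weights rare versus common bins: `q < 1`
   amplifies rare intensities, `q > 1` suppresses them (acting as a
   regulariser); as `q → 1` the family recovers the Shannon
   (Boltzmann–Gibbs) entropy `−Σ p log p`, which is substituted at `q = 1`.
   The resulting real-valued field `I_q` is the entropy map.

2. **Dual-stream description.** The original image and the (rescaled,
   channel-replicated) entropy map are each pushed through a pretrained
   backbone's penultimate layer — canonically the 4096-unit fully connected
   layer of an ImageNet-pretrained VGG19 — and the two descriptors are
   concatenated. A weight-free `pooled-stats` extractor (channel means,
   variances and fixed-seed random projections) implements the same
   contract offline and is the default.

3. **Classification.** PCA (component count chosen from a grid by 5-fold
   cross-validation on the training set, capped at 200) followed by linear
   discriminant analysis. Evaluation protocols: leave-one-acquisition-
   sample-out (`sample_holdout`) and per-class random halves repeated ten
   times (`half_half`). The index `q` itself is selected by K-fold
   cross-validation over the training images.

## Worked example

```python
from entrotex import (FeatureCache, TextureClassifier, evaluate,
                      generate_texture_dataset, make_split_plan)

ds = generate_texture_dataset(n_per_class=20, side=64, seed=0)
plan = make_split_plan(ds, "half_half", repetitions=10, seed=0)
report = evaluate(ds, plan, TextureClassifier(q=1.5), cache=FeatureCache())
print(f"mean accuracy over {len(report.per_fold_accuracy)} folds: "
      f"{report.mean_accuracy:.3f}")
print(report.confusion)
```

prints

```
mean accuracy over 10 folds: 1.000
[[100   0   0   0]
 [  0 100   0   0]
 [  0   0 100   0]
 [  0   0   0 100]]
```

The four synthetic classes differ in the amplitude of their local intensity
fluctuations — exactly the signal the entropy stream measures — and the
fused descriptor separates them perfectly in every one of the ten
half/half splits (the confusion matrix counts the 100 test decisions per
class pooled over folds).

The same pipeline is scriptable from the shell; subcommands compose:

```bash
entrotex synth --n-per-class 20 --side 64 --out ds/
entrotex evaluate ds/ --q 1.5 --protocol half_half --reps 10 --offline --out report.json
entrotex qsweep ds/ --q-grid 0.5,1.0,1.5,2.0 --kfold 5 --offline --out sweep.tsv
entrotex transform ds/smooth/smooth_000.png --q 2.0 --out emap.txt
entrotex fig2 --trials 200 --out perturbation.tsv
```

Benchmark texture databases (KTH-TIPS-2b, FMD, UIUC, UMD, 1200Tex) are not
redistributed here; point `evaluate` at any directory laid out as one
subdirectory per class (use `--tag-pattern` to parse acquisition-sample
tags for the `sample_holdout` protocol, and `--backbone vgg19-penultimate`
when pretrained weights are available).

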