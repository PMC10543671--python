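# braggcam

Explainable CNN hit finding for serial femtosecond crystallography (SFX),
at desk scale.

In an SFX experiment, X-ray pulses hit a jet of protein microcrystals and a
detector records one diffraction snapshot per pulse.  Only a small fraction
of frames contain crystal diffraction — in one early European XFEL run,
14 445 of 3 215 616 frames (0.4%) — so frames must be classified into *hit*
(Bragg peaks present) and *miss* before any downstream analysis.  CNN
classifiers do this well but opaquely.  `braggcam` packages, end to end, the
machinery needed to train such classifiers on synthetic frames with known
Bragg-peak ground truth and to *explain* them:

* **synthetic frames** — a generator emulating the five-class DiffraNet
  taxonomy (Blank, No-crystal, Weak, Good, Strong: Gaussian Bragg peaks of
  increasing count and amplitude over amorphous rings and detector noise),
  emitting per-frame peak coordinates for quantitative checks;
* **classifiers** — size-parameterized AlexNet-style and residual CNNs on a
  self-contained numpy engine with explicit backprop, trained with Adam and
  an exponentially decaying learning rate;
* **Grad-CAM / guided Grad-CAM** — for class score `y^c` and conv feature
  maps `A^k`: importance weights `α_k^c = mean_{ij} ∂y^c/∂A^k_{ij}`, heat map
  `L^c = ReLU(Σ_k α_k^c A^k)` upsampled onto the input, plus guided-ReLU
  pixel gradients; a ground-truth localization score quantifies how much
  heat falls on Bragg peaks;
* **representation inversion** — reconstruct an image from a layer's
  activations by minimizing
  `‖Φ(σx) − Φ_0‖²/‖Φ_0‖² + λ_α Σ|x_i − x̄|^α + λ_TV TV_β(x)` (β = 1),
  revealing what each layer retains;
* **spot-finding baseline** — Peakfinder8-style counting of connected pixel
  groups above a radially dependent background threshold, size-filtered, with
  hit/miss calling at `n_peaks`;
* **metrics** — confusion matrices, accuracy/precision/recall tables and 2×2
  hit/miss cross-tabulations.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

Train a hit/miss classifier on a small synthetic dataset and summarize it:

```python
import braggcam as bc
from braggcam import DiffractionClassifier

ds = bc.binarize_labels(bc.generate_dataset(60, seed=0, test_fraction=0.2))
results = DiffractionClassifier(ds, binary=True, seed=1).fit()
print(results.summary())
```

```
Diffraction frame classifier
============================================================
architecture     : alexnet_style (127,618 parameters)
input            : 64x64, 1 channel(s)
task             : hit/miss
epochs           : 15 (final lr 2.29e-04)
final train loss : 0.0009
train accuracy   : 100.0%
test accuracy    : 100.0%

              miss      hit  Recall(%)
     miss       24        0      100.0
      hit        0       36      100.0
 Prec.(%)    100.0    100.0
```

The 300-frame toy problem separates perfectly; rows are true classes,
columns predictions, with one-vs-rest recall and precision margins.
Explanations hang off the results object — `results.gradcam(frame)` returns
the heat map and importance weights for one frame, `results.invert(frame)`
the per-layer reconstructions.

The metrics module also carries the reference test-set confusion matrix of a
full-scale AlexNet trained on DiffraNet, as a worked example for the metric
formulas:

```python
from braggcam import metrics as m
cm = m.ConfusionMatrix(m.DIFFRANET_ALEXNET_TEST_CONFUSION, bc.CLASS_NAMES)
print(m.format_confusion(cm)); print("accuracy:", m.round1(m.accuracy(cm)))
```

```
               Blank NoCrystal      Weak      Good    Strong   Recall(%)
     Blank      2069         0         0         0         0       100.0
 NoCrystal         2      3266         0         0         0        99.9
      Weak         3        24      3273        46         0        97.8
      Good         0         0        62      2341        41        95.8
    Strong         0         0         0        60      1412        95.9
  Prec.(%)      99.8      99.3      98.1      95.7      97.2
accuracy: 98.1
```

Misclassification sits between neighbouring classes (Weak/Good,
Good/Strong) — exactly the pattern expected when classes are defined by
increasing intensity.

## Command line

```sh
braggcam simulate --n-per-class 100 --size 64 --seed 1 --out data.h5
braggcam train    --data data.h5 --arch alexnet_style --seed 1 --out model.h5
braggcam evaluate --model model.h5 --data data.h5 --out report.json
braggcam spotfind --data data.h5 --snr 3 --npeaks 3 --out peaks.json
braggcam explain  --model model.h5 --data data.h5 --frame-index 0 --out exp/
braggcam invert   --model model.h5 --data data.h5 --frame-index 0 --out inv/
braggcam study    --seed 1 --out study_out/   # the full pipeline + report
```

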