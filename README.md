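# dmclibs

Origin authentication of medicinal plant material from laser-induced
breakdown spectroscopy (LIBS), for analytical-spectroscopy and
chemometrics practitioners.

A laser pulse ablates a pressed tablet of ground herb into a plasma whose
emission lines reveal its elemental composition; material grown in
different regions carries different element signatures (here Ca 616.22 nm,
Na 589.14 nm, N 656.26 nm, K 766.49 nm). `dmclibs` implements the full
analysis stack around that idea:

- **Preprocessing** — min–max normalisation `x' = (x − min X)/(max X − min X)`,
  Savitzky–Golay smoothing (sliding-window least-squares polynomial fit,
  default order p = 5, window 2m+1 = 7, weights `c = (XᵀX)⁻¹Xᵀ` at the
  window centre), iterative polynomial baseline correction (repeat: fit a
  degree-d polynomial, clamp the working signal to `min(signal, fit)` until
  the baseline converges), wavelet denoising and an SNR-based method
  comparison, SNR = 10·log₁₀(‖d‖²/‖raw − d‖²) dB.
- **Classifier** — a double-stream, multi-scale residual/channel-attention
  1-D CNN: the spectrum and its backward difference
  `f'(x) ≈ (f(x) − f(x−h))/h` form two streams; each stream passes three
  parallel convolutions (kernels 1/3/5), max-pooling and a merge
  convolution, then a residual block `y = F(x,{Wᵢ}) + x` (Res_Basic) and a
  strided residual block with 1×1-convolution shortcut (Res_Down), both
  with squeeze-and-excitation channel attention
  `z = σ(W₂ ReLU(W₁ s))` placed after normalisation and before activation.
  The two streams share weights (2 × 3 shared-parameter branches), are
  fused and classified by an MLP with 50% dropout. Trained with SGD on
  cross-entropy. Implemented in NumPy with explicit forward/backward
  passes — no deep-learning framework required.
- **Baselines** — 1-D LeNet, a modified AlexNet (first two max-pools
  replaced by batch normalisation), 1-D ResNet18, plus KNN / random forest
  / decision tree (scikit-learn) under a 7:3 split with five-fold
  cross-validation, all scored by accuracy = (TP+TN)/(TP+TN+FP+FN).
- **Interpretation** — 1-D Grad-CAM: channel weights are the global
  average of the class-score gradient over a convolutional feature map;
  the rectified weighted channel sum, interpolated to the wavelength grid,
  shows which emission lines drive a prediction.
- **Synthetic data** — a generator emulating the study design (2 origins ×
  20 tablets × 50 shots on a 370–1100 nm grid of 2048 points) with
  Gaussian emission lines, per-class line multipliers, per-tablet jitter,
  polynomial baseline drift and detector noise, so every stage is testable
  without proprietary spectra.

## Worked example

```python
import dmclibs as d

ds = d.generate(d.default_angelica_like_config(seed=0))   # 2000 spectra
pp = d.preprocess_pipeline(ds, d.PreprocessConfig())      # normalise, SG(5,7), baseline
train, val, test = d.split_dataset(pp, (0.6, 0.2, 0.2), seed=0)
print(len(train), len(val), len(test))

model = d.build_model(d.DMCNNConfig(), seed=0)
model, hist = d.train(model, train, val,
                      d.TrainConfig(learning_rate=0.01, epochs=2, seed=0))
res = d.evaluate(model, test, hist)
print(f"test accuracy {res.accuracy:.3f}  confusion "
      f"TP={res.tp} TN={res.tn} FP={res.fp} FN={res.fn}")

sm = d.grad_cam_1d(model, next(test.spectra), target_layer="scales")
print(f"saliency argmax at {sm.argmax_nm:.2f} nm")
```

prints

```
1200 400 400
test accuracy 1.000  confusion TP=200 TN=200 FP=0 FN=0
saliency argmax at 615.00 nm
```

The split reproduces the 6:2:2 bookkeeping (1200/400/400 of 2000); the
classifier separates the two synthetic origins perfectly because their
element-line signatures are cleanly distinct at this noise level; and the
saliency map peaks beside the Ca line (616.22 nm) — the line with the
largest class contrast in the generator — so the model is looking at the
right part of the spectrum.

The same stages are scriptable from the shell:

```sh
dmclibs generate --out spectra.csv --seed 0
dmclibs preprocess --in spectra.csv --out prep.csv --sg-order 5 --sg-window 7
dmclibs train --in prep.csv --out rundir --epochs 2 --lr 0.01
dmclibs compare --in spectra.csv --methods knn,rf,dt --out table.csv
dmclibs run --config run.yaml
```

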