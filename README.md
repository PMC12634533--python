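# sobelnet

EEG-based screening for major depressive disorder (MDD) with a convolutional
network whose first layer is a **fixed bank of Sobel gradient kernels**.
Resting-state multichannel EEG is cut into 4-s windows and treated as a
channels × time image; depression-related signatures such as frontal alpha
asymmetry appear in that image as spatial gradients and edge-like
transitions, which is exactly what a Sobel operator responds to.

The package is aimed at biosignal/ML researchers who want to study this
architecture end to end without access to clinical EEG: a seeded synthetic
EEG generator with a tunable class effect stands in for patient data, and a
noise-injection harness quantifies what the Sobel layer does to signal
quality.

## The model

For an epoch image `X ∈ R^{H×W}` (H electrodes, W samples):

1. **Sobel layer (fixed, not learned).** The horizontal/vertical kernel pair

   ```
   Gx = [[-0.1 0 0.1], [-0.2 0 0.2], [-0.1 0 0.1]],   Gy = Gxᵀ
   ```

   is replicated `nf` times (default 10) and applied as a stride-1,
   zero-padded SAME convolution, giving a gradient map `H×W×2nf`. Both
   kernels sum to zero, so constant activity is suppressed and local
   transitions are emphasised.
2. **Conv block.** 20 filters of size 2×9 (valid, ReLU) →
   `(H−1)×(W−8)×20`; then 18 filters of size 8×7 (valid, linear) →
   `(H−8)×(W−14)×18`.
3. **Dense head.** Flatten to `Df=(H−8)(W−14)·18`; dense 350 with sigmoid;
   dense 60 linear; dense 1 with sigmoid → MDD score in (0, 1).

Training minimises the mean squared error `L = mean((y − ŷ)²)` with SGD,
learning rate `η = 0.01`, momentum `γ = 0.9`, Nesterov acceleration, and
inverted dropout (`p = 0.03`) on the raw input. The forward and backward
passes are implemented directly in numpy and checked against finite
differences.

## Worked example

```python
import sobelnet as sn

# 8 MDD + 8 HC synthetic subjects, 60 s at 64 Hz, strong frontal alpha asymmetry
recs = sn.generate_dataset((8, 8), seed=7, duration_s=60.0,
                           sampling_rate=64.0, effect_size=3.0)
epochs = sn.dataset_epochs(recs, window_s=4.0, stride_s=4.0)

cfg = sn.TrainConfig(seed=7, n_epochs=8, batch_size=32, nf=10)
params, curve = sn.train(epochs, cfg)
print(curve[["epoch", "train_loss", "val_acc"]].tail(3).to_string(index=False))
```

prints (numbers from this exact run):

```
 epoch  train_loss  val_acc
     6    0.000080      1.0
     7    0.000044      1.0
     8    0.000031      1.0
```

i.e. on strongly separable synthetic data the network drives the training
MSE to ~3e-5 and classifies every held-out validation epoch correctly —
with `effect_size=0` the same pipeline stays at chance. The same objects
are reachable from a shell:

```bash
sobelnet simulate --n-mdd 8 --n-hc 8 --duration 60 --rate 64 \
         --effect-size 3 --seed 7 --out data/
sobelnet train --data data/ --stride 4 --epochs 8 --seed 7 --out run/
sobelnet evaluate --checkpoint run/checkpoint.h5 --data data/ --stride 4 --seed 7
sobelnet robustness --checkpoint run/checkpoint.h5 --data data/ --stride 4 \
         --snr 20,15,10,5,0,-5 --seed 7 --out run/
```

The robustness command injects white noise at each nominal SNR and reports,
per condition, the measured input SNR, the SNR/PSNR/SSIM change of the
Sobel-processed signal relative to the Sobel transform of the clean signal,
and classification accuracy on the noisy epochs. Because the Sobel layer is
linear and the injected noise is white, its SNR gain is flat across noise
levels.

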