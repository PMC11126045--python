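# aifcorr

Saturation correction of arterial input functions (AIFs) for
quantitative myocardial perfusion MRI, using a bidirectional LSTM
trained entirely on Bloch-simulated data.

## The problem

Quantifying myocardial blood flow from dynamic contrast-enhanced
cardiac MRI requires the arterial input function — the gadolinium
concentration over time in the left-ventricular blood pool.  At the
saturation-recovery times used for 3D myocardial imaging (SRT ≈ 100 ms)
the MRI signal is strongly nonlinear in concentration, and acquisition
imperfections (B1-driven flip-angle errors, T2* shortening, imperfect
saturation) bias the measured AIF even after dictionary-based
signal-to-concentration conversion.  Errors in the AIF propagate
roughly reciprocally into the transfer constant ktrans (∝ myocardial
blood flow) fitted with the compartment model

    C_tiss(t) = C_AIF(t−Δt) ⊗ ktrans·e^(−kep·t) + vp·C_AIF(t−Δt).

`aifcorr` implements the full simulation-to-correction loop:

1. **aif_population** — 12-parameter gamma-variate + sigmoid AIF model
   with population sampling ranges (peaks 3–9 mM).
2. **tissue_kinetics** — compartment-model tissue curves, including the
   fixed-ktrans ladder (0.3, 0.5, …) used as network inputs.
3. **sequence_signal** — Bloch recursion for the saturation-recovery
   stack-of-stars readout; monotone SI↔[Gd] dictionary; flip-angle /
   T2* / residual-magnetization bias factors; signal-domain noise.
4. **data_factory** — seeded train/val/test curve-set datasets; a
   synthetic clustered-pixel stand-in for in vivo myocardium; K-means
   reduction and curve preprocessing.
5. **correction_network** — 4-layer Bi-LSTM (32 hidden/direction,
   Adam, batch 16), NumPy + numba implementation with hand-verified
   gradients; AIF L1 loss plus optional parameter-loss and
   model-tissue-loss terms.
6. **pk_fitting** — bounded Levenberg–Marquardt-type fits of
   (ktrans, kep, vp, Δt).
7. **evaluation** — peak / ktrans percentage errors, Pearson, linear
   fit, Bland–Altman.
8. **cli** — `aifcorr` command with `simulate`, `build-dict`, `train`,
   `correct`, `fit`, `evaluate` and `experiment` subcommands.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Simulate a small dataset, train briefly, and evaluate the baseline:

```python
import numpy as np
from aifcorr import (DatasetSpec, make_dataset, NetworkConfig, LossConfig,
                     train, peak_errors)
from aifcorr.experiments import test_inputs

spec = DatasetSpec(n_train=2000, n_val=500, n_test=1000, n_tissue=10, seed=11)
splits = make_dataset(spec)                      # ~4 s

base = peak_errors(splits["test"].sat_aif, splits["test"].true_aif)
print(f"dictionary baseline peak error: {base.mean():+.2f} +/- {base.std():.2f} %")

model = train(splits, NetworkConfig(input_channels=11, epochs=30, seed=7),
              LossConfig())                      # ~6 min on one CPU
pred = model.predict(test_inputs(splits["test"], 11))
err = peak_errors(pred, splits["test"].true_aif)
print(f"network peak error:             {err.mean():+.2f} +/- {err.std():.2f} %")
```

Output from this exact run:

```
dictionary baseline peak error: +15.50 +/- 30.67 %
network peak error:             +0.56 +/- 5.04 %
```

The dictionary baseline is biased and widely spread — symmetric
acquisition biases and noise pass through the convex inverse of the
compressive signal dictionary, inflating and scattering the inverted
peaks — while the network, given the saturated AIF plus ten tissue
curves (which live in the linear low-concentration regime), recovers
the true peak to well under a percent on average with a much tighter
spread.

The same pipeline is available from the shell:

```sh
aifcorr simulate --seed 11 --out runs/data
aifcorr train --dataset runs/data/dataset.h5 --epochs 30 --out runs/model
aifcorr evaluate --dataset runs/data/dataset.h5 --model runs/model/model \
        --out runs/report.json
```

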