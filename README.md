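# deepmpm

Quantitative analysis of deep-tissue multiphoton microscopy. The package
implements the measurement suite used to characterise high-pulse-energy,
low-repetition-rate infrared (3-photon/4-photon) imaging of strongly
scattering tissue, for microscopists and image analysts who need these
numbers from their own z-stacks and time-lapse movies:

* **Excitation-process order** — the order *n* of the nonlinear process is
  fitted from image series at stepwise-varied pulse energy *P* via
  *S*(*P*) = *A·Pⁿ*, where *S* is the normalised, bleaching-corrected,
  background-subtracted signal
  *S*(*P*) = *F*·[*I*(*P*) − *B*(*P*)] / [*I*(*P*₀) − *B*(*P*₀)]
  against interleaved fixed-energy reference frames at *P*₀. The fit is an
  orthogonal distance regression weighting both energy and signal errors,
  gated on reduced χ² < 2 and adjusted R² > 0.995.
* **SNR depth profiling** — per depth, SNR = (*I*ₘ − *B*ₘ)/σ_B with *I*ₘ the
  mean of the brightest pixel fraction of the median-filtered plane, and the
  SNR = 3 crossing (linearly interpolated) as the imaging-depth limit.
* **Effective attenuation length** — the power- and order-normalised signal
  *S*(*z*) = *N*·[(*I*ₘ − *B*ₘ)/*Pⁿ*]^(1/*n*) is fitted with
  *A*·exp(−*z*/*l*ₑ); over one *l*ₑ the ballistic excitation falls by 1/e and
  an order-3 signal by 1/e³. Layered tissue is handled with per-layer fit
  windows.
* **Axial resolution scoring** — the maximum derivative (δI/δz)ₘₐₓ of 0–1
  normalised intensity z-profiles through fluorescent features.
* **Phototoxicity** — per-cell GCaMP/Sytox trace analysis (responder if the
  trace crosses baseline mean + 3·SD; Sytox as the background-subtracted
  nucleus/cytosol ratio) and the image-area analysis (threshold over the 95%
  dimmest pre-exposure ROI pixels, dilated pre-exposure mask subtraction,
  responding-area fraction).
* **Synthetic data** — seeded generators for depth stacks, power series and
  two-channel viability movies with full ground truth, so every estimator is
  testable without microscope data.

Pulse-energy bookkeeping follows *E* = *E*_obj·exp(−α·d) for the immersion
path, and average power = pulse energy x repetition rate (nJ x MHz = mW).

## Worked example

Fit the excitation order of a simulated 3-photon power series and recover an
attenuation length:

```python
import numpy as np
from deepmpm.core_io import Roi
from deepmpm.depth_metrics import attenuation_signal, fit_attenuation, snr_profile
from deepmpm.excitation_order import fit_power_law, normalize_power_series, qc_fit
from deepmpm.synthetic import SceneConfig, make_depth_stack, make_power_series

series, _ = make_power_series(a=50.0, n=3, energies_nj=np.linspace(1, 8, 8),
                              shot_noise=True, read_sd=2.0, seed=1)
fit = fit_power_law(normalize_power_series(series))
print(f"n = {fit.n:.3f} +/- {fit.n_se:.3f}, QC pass: {qc_fit(fit)[0]}")

stack, _ = make_depth_stack(SceneConfig(seed=1, l_e_um=220.0))
profile = snr_profile(stack, 0, top_fraction=0.01, median_radius_px=1,
                      background_roi=Roi.from_rect(0, 10, 0, 10, stack.frame_shape))
att = fit_attenuation(profile.depths_um, attenuation_signal(profile), order_n=3)
print(f"l_e = {att.l_e_um:.1f} +/- {att.l_e_se_um:.1f} um")
```

prints

```
n = 3.009 +/- 0.005, QC pass: True
l_e = 219.9 +/- 0.2 um
```

i.e. the fitted order identifies the cubic (3-photon) intensity dependence,
and the attenuation fit recovers the generative 220 µm effective attenuation
length within its standard error.

The same pipelines are scriptable from the shell; each subcommand takes a
YAML config and writes CSV/JSON artifacts plus a reproducibility log:

```bash
deepmpm simulate --config scene.yaml --seed 1 --out run/
deepmpm attenuation --config att.yaml --out run/
```

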