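# kdespike

Removal of RF spike artifacts ("k-space spikes") from MR images by
robust principal component analysis.

Brief bursts of RF noise during MR acquisition — loose coils, gradient
vibrations during diffusion imaging, faulty shielding — deposit
high-intensity outliers in a few k-space samples, which turn into stripe
artifacts spread across the whole image. `kdespike` removes them
retrospectively from complex raw data: the measured k-space matrix
**M** is decomposed into a low-rank component **L** (the artifact-free
data) and a sparse component **S** (the spikes) by principal component
pursuit,

```
min_{L,S}  ||L||_* + λ_eff ||S||_1   subject to  M = L + S,
```

where `||·||_*` is the nuclear norm, `||·||_1` the sum of entry moduli,
and `λ_eff = κ·λ` scales the canonical weight `λ = 1/√(max dim of M)` by
a user factor κ that protects the peaked k-space center from being
classified as sparse. The problem is solved with an inexact augmented
Lagrange multiplier method extended to complex data (magnitude
soft-thresholding with phase preservation; complex SVD). For a dynamic
series, **M** is the k-t Casorati matrix (each frame one column); a
single frame is decomposed as its kx-ky matrix. Finally, connected
clusters of sparse energy touching the central 16×16 k-space window are
automatically refilled into **L**, and **L** is inverse Fourier
transformed to give the despiked images.

The package is aimed at MR researchers who have saved complex raw data
from spike-corrupted sessions (Look-Locker T1 mapping, cine, diffusion
tensor imaging, fMRI, …) and want the artifacts removed without
touching the underlying signal. Magnitude-only data is not supported:
the method requires complex k-space.

## Worked example

```python
import numpy as np
from kdespike import (DespikeConfig, LookLockerSpec, SpikeModel,
                      add_spikes, background_noise_std, despike,
                      make_look_locker_series, reconstruct_images, roi_t1)

# artifact-free Look-Locker phantom: 128x128, 50 inversion times,
# myocardial ring with corrected T1 = 1.2 s
phantom = make_look_locker_series(LookLockerSpec(seed=0))
corrupted, ledger = add_spikes(phantom.kspace, SpikeModel(seed=5))

clean, spikes, diag = despike(corrupted, DespikeConfig(kappa=5))
print(f"converged={diag.converged}  rank_L={diag.rank_L}  "
      f"refilled={np.mean([r.n_refilled_pixels for r in diag.refill_reports]):.1f} px/frame")

for name, series in [("original", phantom.kspace), ("corrupted", corrupted),
                     ("despiked", clean)]:
    img = reconstruct_images(series)
    t1 = roi_t1(img, phantom.inversion_times, phantom.roi_mask).T1
    print(f"{name:9s}  T1 = {1000 * t1:7.2f} ms   background std = "
          f"{background_noise_std(img):.4f}")
```

prints

```
converged=True  rank_L=50  refilled=17.5 px/frame
original   T1 = 1198.38 ms   background std = 0.0130
corrupted  T1 = 1197.48 ms   background std = 0.1347
despiked   T1 = 1198.38 ms   background std = 0.0132
```

The spikes raised the background noise tenfold (stripe artifact);
despiking returns it to within ~2% of the artifact-free level and the
fitted myocardial T1 to within a fraction of a millisecond, while the
low-rank component keeps the full rank (50) of the series — the signal
of interest is untouched.

A command-line interface wraps the same pipeline for HDF5 k-space
containers:

```
kdespike simulate --type t1 --seed 1 -o phantom/
kdespike despike phantom/corrupted_kspace.h5 --kappa 5 -o out/
kdespike validate phantom/clean_kspace.h5 out/despiked_kspace.h5
```

Validated κ values: 5 for Look-Locker T1 series, 6 for cine, 3 for a
single static frame, 5 for diffusion-weighted volumes, 6–9 for low-b
reference volumes (despiked separately per shell via
`--group-by-bvalue`).

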