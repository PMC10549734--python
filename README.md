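# psoct — dermal collagen birefringence from polarization-sensitive OCT

`psoct` quantifies the *effective birefringence* of dermal collagen from
polarization-sensitive optical coherence tomography (PS-OCT) volumes of
skin.  It is written for groups using PS-OCT to monitor structural change
in the dermis — for example the collagen compaction that accompanies
topical-corticosteroid-induced skin atrophy — and packages the complete
analysis chain from raw fringes to cohort-level paired statistics,
together with a forward phantom simulator so every stage can be validated
against known ground truth without patient data.

## The method

A swept-source PS-OCT system with a single circular input polarization
records complex backscatter amplitudes A_H and A_V in two orthogonal
detection channels over a (z, x, y) volume.  Per voxel the Stokes vector

    I = |A_V|² + |A_H|²,   Q = |A_V|² − |A_H|²,
    U = 2|A_V||A_H| cos Δθ,   V = 2|A_V||A_H| sin Δθ,   Δθ = arg A_V − arg A_H,

is normalized by I to a point Ŝ on the Poincaré sphere.  Birefringent
dermal collagen (fast axis assumed fixed with depth) rotates Ŝ about a
fixed axis, so the dot product with the state at the skin surface traces
an amplitude-modulated cosine of the round-trip phase retardance:

    Ŝ_ref · Ŝ(z_i) = A(z_i) · cos φ_r(z_i).

The phase φ_r is extracted from the analytic signal of this profile,
unwrapped (multiples of ±2π added wherever a neighboring-pixel jump
exceeds ±π), and regressed against depth over ~200 µm (50 axial pixels)
beneath the dermal-epidermal junction (DEJ).  The slope m (rad/pixel)
converts to birefringence by

    Δn = m · λ₀ · RI / (4π · Δz),

with λ₀ = 1301 nm, axial pixel Δz = 4 µm (in air) and tissue refractive
index RI = 1.4.  Fits above 600×10⁻⁶ are treated as noise-induced
unwrapping errors and re-evaluated on the wrapped phase.

Around this core the package provides: spectral reconstruction
(wavenumber resampling + inverse FFT), wavelet-FFT stripe-artifact
removal, sub-pixel surface and DEJ segmentation with a 40×40-median /
10-pixel outlier rule and manual-override hooks, en-face Δn maps, and
per-arm descriptive tables with within-subject paired t-tests
(day 29 vs day 1).  See `docs/methods.md` for model details and the
design choices.

## Worked example

Simulate a phantom with known birefringence, quantify it, and run the
cohort statistics on a scan-summary table:

```bash
psoct simulate --seed 7 --out phantom.h5
psoct quantify --volume phantom.h5 --out run/
```

The default phantom carries a dermal birefringence of 500×10⁻⁶ at 20 dB
detector SNR; `quantify` prints

```
mean dn = 498.9e-6 over 4096 columns
```

i.e. the volume-mean effective birefringence recovered from the full
chain (surface → DEJ → Stokes → retardance → fit → mitigation) lands
within ~0.2% of the simulated truth, and `run/` holds the en-face TIFF/CSV
map, the HDF5 diagnostics and a `scan_summaries.csv` row.  Python API:

```python
from psoct import (PhantomConfig, simulate_volume, compute_intensity,
                   detect_surface, detect_dej, birefringence_map)
from psoct.io import BoundarySet
import numpy as np

vol, truth = simulate_volume(PhantomConfig(shape=(128, 64, 64),
                                           surface_depth=16, dn_true=500e-6,
                                           seed=7))
iv = compute_intensity(vol)
surface, s_ok, _, _ = detect_surface(iv)
dej, d_ok, _ = detect_dej(iv, surface)
m = birefringence_map(vol, BoundarySet(surface, dej, s_ok & d_ok))
print(np.nanmean(m.dn[m.valid_mask]))   # ~5.0e-4
```

For the study-level statistics, `psoct cohort --summaries scans.csv --out report/`
writes a descriptive table (quartiles, mean, SD, SEM per arm and day), a
paired-test table (mean difference, 95% CI, t, p per arm) and a
per-subject change plot.

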