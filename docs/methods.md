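# Methods

This note documents the model behind `psoct`, the parameters that matter,
what the phantom simulator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Optical model and its assumptions

Skin is treated as two layers: a non-birefringent epidermis over a dermis
whose collagen gives it a uniform linear birefringence Δn with a fast
axis θ that does not vary with depth.  Because the medium is reciprocal,
the round trip through such a dermis acts as a single linear retarder
whose retardance doubles the single-pass value; no diattenuation is
modeled (none is measured by the analysis).  Under these assumptions the
normalized Stokes vector of the backscattered light rotates on the
Poincaré sphere about a fixed equatorial axis set by θ, and the rotation
angle — the round-trip phase retardance — grows linearly with physical
depth below the dermal-epidermal junction (DEJ):

    φ_rt(z) = 4π·Δn·z_phys/λ₀,   z_phys = (z − z_DEJ)·Δz/RI,

where Δz is the axial pixel in air and RI converts it to tissue depth.
The measured quantity is therefore an *effective* birefringence: real
dermal collagen ("basket-weave" fiber organization) can have a
depth-varying fast axis, which this model absorbs into a lower apparent
Δn.  The slope m of the unwrapped phase per axial pixel inverts through
Δn = m·λ₀·RI/(4π·Δz); with the defaults (λ₀ = 1301 nm, Δz = 4 µm,
RI = 1.4) a Δn of 500×10⁻⁶ corresponds to m = 0.013798 rad/pixel.

## Phase extraction: the analytic signal

The surface-referenced dot product d(z) = Ŝ_ref·Ŝ(z) = A(z)·cos φ_r(z)
must be converted to a phase profile.  Two constructions are provided:

* **Geometric (default).**  The rotation axis â is estimated as the
  normalized sum of cross products Ŝ(z)×Ŝ(z+L) at lag L = n/4 (long lags
  make the estimate robust to noise; the arc per lag stays below π for
  physiological Δn over the profile lengths used).  The quadrature is the
  projection of Ŝ onto â×Ŝ_ref, so d + i·q = A·e^{iφ} exactly for the
  retarder model, at any phase span.  The axis sign is set so the net
  phase change is non-negative; for pure noise the sign is arbitrary and
  irrelevant after the mitigation rule.
* **Hilbert (`quadrature="hilbert"`).**  The classical FFT analytic
  signal (zeroed negative frequencies) of the mean-removed dot profile.
  This is accurate only when the profile contains several oscillation
  cycles; at the sub-cycle phase spans typical of a 50-pixel dermal
  window (≤ 0.69 rad at 500×10⁻⁶) it is strongly biased, which is why it
  is not the default.  Its inherent spectral-leakage ripple on a finite
  cosine segment is ~0.05–0.08 rad even mid-profile (measured on
  cos(0.2z), 100 samples), though fitted slopes remain accurate to ~1%.

Unwrapping follows the minimal-jump rule: whenever a neighboring-sample
jump leaves (−π, π], multiples of 2π are added; the first sample is kept
and output − input is a multiple of 2π everywhere.  The dermal fit is
plain unweighted least squares of the unwrapped phase over the 50 axial
pixels (~200 µm) starting at ⌈z_DEJ⌉.  Fits above 600×10⁻⁶ — almost
always caused by noise-triggered spurious unwrapping, which can only
inflate the slope — are re-evaluated on the wrapped phase over the same
window and flagged (`used_wrapped`); the threshold is a strict
inequality.  Negative fitted slopes are kept as negative Δn by default
(configurable clamp), and fit windows with fewer than 10 usable samples
are flagged invalid.

Before normalization the Stokes components (I, Q, U, V) are smoothed
with a 3×3×3 boxcar.  Linear filtering of the raw components commutes
with the projections used above and leaves a linear phase slope exactly
unchanged, while suppressing speckle and diluting isolated depolarized
voxels; measured on phantoms at 20 dB SNR and 95% polarization retention
it reduces the volume-mean bias at Δn = 200×10⁻⁶ from −5% (lateral-only
3×3) to below −2%.  Setting `smooth=False` reproduces the literal
unfiltered chain.  A per-voxel SNR floor (99th percentile of
above-surface "air" intensity, capped at half the median tissue
intensity so noise-dominated inputs still flow through) marks sub-noise
voxels invalid for the reference-state average.

## Segmentation

Edges are detected per A-scan on the laterally 3×3-smoothed intensity
(speckle control) after an axial Gaussian of σ = 1 pixel: local maxima of
the derivative above a noise-adaptive threshold (4×robust σ via MAD, with
a 2%-of-range floor) become candidates, each refined by *area balance*:
with plateau levels L (dark) and H (bright) estimated beside the
transition, the edge sits at j_hi + ½ − Σ (p−L)/(H−L) over the transition
window.  This is exact for an ideal step sampled by pixel areas (the
partial-area principle) and invariant to symmetric smoothing.  The
surface is the largest positive (dark→bright) edge per column; the
resulting map is compared with its own 40×40 median-filtered version,
deviations > 10 axial pixels (hairs, ghost surface copies) are replaced
by 2-D linear interpolation from non-outlier pixels, and each column is
finally re-locked to the nearest candidate within 10 pixels (equidistant
ties break toward the shallower edge; median filtering uses reflective
padding).  The DEJ repeats the procedure on the surface-flattened,
en-face-median-filtered (21×21) volume within 10–60 pixels below the
surface, which removes laterally narrow dark structures (lymphatic-like
inclusions) whose lower edge would otherwise mimic the epidermis→dermis
transition.  Manual overrides re-lock a column to the candidate nearest
an operator hint (±10 px) and re-interpolate the surrounding
neighborhood; hints with no nearby edge are rejected with a warning.

## The phantom simulator

The simulator implements exactly the forward model the analysis inverts,
plus the nuisance structure needed to exercise every pipeline rule:

* smooth random surface and DEJ topography (band-limited Gaussian fields
  with set SD and correlation length);
* circular input state, Jones linear retarder J(θ, φ_rt) below the DEJ;
* multiplicative circular complex Gaussian speckle common to both
  channels (intensity exponentially distributed; speckle therefore
  cancels from normalized Stokes vectors, as in a real single-scattering
  voxel), switchable off for idealized sub-pixel tests;
* amplitude attenuation e^{−µ(z−z_surf)} with µ = 0.0092 per axial pixel
  (~20 dB intensity drop over 1 mm in air pixels, typical skin OCT);
* per-channel additive circular complex Gaussian detector noise scaled
  to `snr_db` (surface signal power over total detector-noise power);
* depolarization: each voxel's polarization state is replaced by a
  uniform random state on the sphere with probability 1 − dop;
* epidermis/dermis backscatter contrast (intensity ratio 0.5 by
  default) creating the DEJ's dark→bright edge, with sub-pixel partial
  coverage of boundary pixels, and an optional bright entry band;
* hair artifacts: a bright streak 15 px above the surface plus 80%
  signal suppression below, over disjoint 3×3 column groups (exercises
  the 40×40/10-px outlier rule);
* horizontal stripe artifacts: constant additive rows in selected
  frames (exercises the destriper).

All draws derive from a single seeded generator, so identical
configurations give bit-identical volumes.  Not emulated: wavelength-
dependent scattering, depth-varying fast axis, multiple scattering and
spectral speckle decorrelation.  Passing phantom tests therefore shows
the chain is a correct inverse of the stated model at realistic noise
levels — not that real dermis satisfies the fixed-axis assumption.

Typical study-condition defaults used in tests and in the acceptance
script: Δn_true ∈ {100…540}×10⁻⁶ (the cohort's observed range), 20 dB
SNR, dop 0.95, surface undulation SD 3 px, epidermis ~22–30 px.  Volumes
are simulated at 128×64×64 or smaller rather than the instrument's
512×600×600; the per-column analysis is identical and the smaller grids
keep every validation in seconds.

## Preprocessing

Fringes sampled in wavelength are linearly interpolated onto a uniform
k = 2π/λ grid (same sample count), DC-subtracted per A-scan, Hann
windowed and inverse-FFT'd; the positive-depth half is kept.  Stripe
removal is the combined wavelet-FFT scheme: Daubechies-4 decomposition
(5 levels, periodization mode), Gaussian notch 1 − e^{−f²/2σ²}
(σ = 2.0 frequency bins) applied along the lateral axis of each
horizontal-detail band, reconstruction.  In the end-to-end pipeline the
filter operates on log-intensity B-scans (standard for destriping, since
stripes are multiplicative over orders of magnitude of dynamic range);
the function itself is domain-agnostic.  Ghost surface copies from
polarization-maintaining-fiber misalignment are not filtered separately:
the largest-positive-edge rule plus the median-filter rejection in
segmentation handles them.

## Cohort statistics

Scan-level mean Δn values (up to 3 repeats per subject, arm and day) are
averaged to subject level before testing, avoiding pseudo-replication.
Per arm and day the report gives 25/50/75th percentiles (linear
interpolation between order statistics), mean, sample SD (n−1) and SEM.
The within-subject comparison is a two-sided paired t-test on
d = day29 − day1 with t = mean(d)/(sd(d)/√n), df = n − 1, and a 95% CI of
mean(d) ± t₀.₉₇₅,ₙ₋₁·sd(d)/√n.  No multiple-testing adjustment is applied
across the two arms.  The same routine accepts a printed (mean, SD, n)
summary triple, which is how the published BMV arm's significance bound
(t ≈ 5.48, p < 10⁻⁴ at n = 32) is reproduced; recomputing the published
crisaborole p from its rounded summary row gives 0.765 versus the printed
0.7757 — agreement only up to input rounding, as expected without raw
data.

## Degenerate inputs and tie-breaks

Constant intensity profiles yield no edge candidates; columns without
candidates or without a valid DEJ window are flagged and interpolated or
excluded, never fatal.  A pure-noise volume runs to completion and
reports either an empty flagged summary or a high mitigated fraction.
Profiles shorter than 8 samples, fit windows under 10 samples, and
all-invalid reference windows are flagged per column.  Exactly-π phase
jumps stay at +π (the interval is (−π, π]).  The file schema stores
complex data as float32 real/imaginary pairs; round trips are exact at
that precision.

## Known limitations

Fast-axis orientation is estimated only as an internal by-product, not
mapped; depth-resolved (local) birefringence is out of scope.  The
geometric quadrature assumes a single dominant rotation axis over the
profile — strong depth-variation of the fast axis would violate it and
the fixed-axis model alike.  Destriping margins (stripe residual vs.
distortion of stripe-free content) depend on B-scan width; the defaults
are calibrated for instrument-scale (≥ several hundred columns) frames.
The segmentation loops are pure Python over columns and process a
600×600 lateral grid in minutes, not seconds.
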