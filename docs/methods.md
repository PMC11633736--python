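# Methods

## Signal model

The probe waveform for one pixel dwell is a train of pulses at
f_probe = 80 MHz, each rendered as a single-sample-wide rectangle
carrying the pulse energy (the 2-ps physical pulse width is orders of
magnitude below the detector-limited sample period of 0.78 ns at the
default 1.28 GS/s and is kept as metadata only). Two modulations
multiply the pulse energies:

* **Stokes gating.** The Stokes beam is square-wave gated at
  f_mod = 20 MHz with 50% duty, so the repeating pattern over four
  probe pulses is on, on, off, off (first pulse on, phase 0 at t = 0).
  Gated pulses lose the fraction δ_SRL. The electro-optic modulator is
  treated as ideal (perfect extinction).
* **Photothermal envelope.** 500-ns IR pulses at f_IR = 100 kHz drive
  a phenomenological single-exponential thermal response: during the
  pulse the transmission modulation rises as 1 − exp(−t/τ_rise)
  toward the depth δ_PT; after the pulse it decays as exp(−t/τ_decay).
  The envelope is evaluated in its periodic steady state, whose
  cycle endpoints are the fixed point of the rise/decay recursion
  (m₁ = P(1−a)/(1−ab), m₀ = m₁b with a = e^(−T_on/τ_rise),
  b = e^(−T_off/τ_decay)). Because the envelope is linear in its peak
  depth, its cycle average and Fourier harmonics have closed forms,
  used for calibration and for the cross-talk prediction.

Defaults: τ_rise = 200 ns, τ_decay = 1 µs. Neither time constant is a
measured quantity; they are free parameters chosen so the photothermal
harmonics remain visible through the low-megahertz region of the power
spectrum while the envelope still relaxes within the 10-µs IR period.
Detector noise is per-sample Gaussian relative-intensity noise
(default sd 5×10⁻³, a plausible figure for a high-bandwidth photodiode
plus amplifier at gigasample rates) and an optional Gaussian/Poisson
shot-noise term; there is no 1/f term.

Small-signal regime: both modulation depths are validated to
[0, 0.2). The contrast renderer clips above 0.2 with a warning; the
synthesizer refuses depths outside the range.

## Contrast forward model

δ_SRL = k_SRL · P_pump · P_Stokes · Σ_s [C_s ⊛ PSF_Raman] · R_s(ν_R) and
δ_PT = k_PT · P_IR · Σ_s [C_s ⊛ PSF_IR] · A_s(ν_IR), with unit-sum
Gaussian kernels and reflective boundaries (total signal conserved to
1e-9 relative). The Raman channel's pump×Stokes focal product and the
photothermal channel's thermal-diffusion blur are absorbed into the
configured FWHMs (defaults 398 nm and 561 nm); no Airy or vector PSFs,
no heat-diffusion PDE. Band spectra are amplitude-normalized
Lorentzians (Gaussian optional) — the conventional vibrational line
shape; relative band amplitudes in the species presets are plausible
configuration values, not literature cross sections. The photothermal
sign convention is a transmission decrease at the detector, consistent
with the SRL-channel decrease under IR heating.

## Demodulation

The software lock-in mixes with quadrature references (phase 0 at
t = 0) and filters with `filter_order` (default 4) cascaded
single-pole stages. The configured time constant is the cascade's
overall response scale — each stage uses τ/order — so the cascade
settles within the discarded interval of 5τ; the remainder is
averaged. Magnitude output is calibrated to return the cosine
amplitude (2·√(I²+Q²)), not RMS. Default τ is dwell/10.

The virtual scan (`scan_image`) renders the contrast pair, simulates
one dwell per pixel and demodulates both channels from that single
trace. The default fast path evaluates the demodulated amplitude as
the discrete Fourier amplitude of the per-pulse energy sequence — the
limit the lock-in converges to — and carries the identical per-pulse
noise model (noise on empty samples is zero in the full path, so the
two paths are statistically equivalent); it agrees with the full
waveform path to better than 1% on noiseless inputs. Per-pixel noise
seeds derive deterministically from (global seed, y, x), making noisy
scans bit-reproducible. In the noiseless fast path, channel outputs
that are analytically zero (no corresponding modulation, reference
frequency off the active harmonic grid) are returned as exact zeros
rather than float-cancellation residue.

Spectral sweeps are quasi-simultaneous two-pass acquisitions (IR pass
at 2 cm⁻¹ spacing over the 915–2335 cm⁻¹ source range, then a Raman
pass at 8 cm⁻¹), analytic by default with a full-waveform verification
mode.

## Cross-talk

The product (1 − δ_SRL·g)(1 − m) places sidebands around the 20-MHz
carrier at ±f_IR. Amplitude modulation by the envelope's fundamental
A₁cos(2πf_IR t) gives sidebands of A₁/2 relative to the carrier, so
the predicted ratio is half the envelope's first-harmonic amplitude
(closed form), independent of δ_SRL in the small-signal regime. The
FFT-measured sidebands of a synthesized trace agree within 5%; the
residual asymmetry between upper and lower sidebands comes from the
direct photothermal harmonic of the pulse train at the same
frequencies, which adds coherently with a different phase. At
film-like depths with default detector noise, both sidebands fall at
the noise floor of a 1-ms acquisition — the mixing products exist at
the predicted level but are not observable — while the carrier stands
two orders of magnitude above it.

## Operating points

Two configured operating points reproduce the instrument's printed
characterization figures end to end:

* **Film point** (spectral architecture): uniform oil film,
  pump/Stokes/IR powers 315/315/5 mW, gains chosen so the film gives
  δ_SRL ≈ 5×10⁻³ and δ_PT = 1.8% per mW of IR power. The 1-ms
  noiseless power spectrum then shows its three dominant non-dc peaks
  at exactly 100 kHz, 20 MHz and 80 MHz (Welch, Hann, 10-kHz
  resolution; Parseval holds as sum(psd)·df against the raw mean
  square).
* **Cross-modulation point**: the measured quantity "fractional SRL
  decrease per mW" is the *cycle average* of the photothermal
  envelope, because the lock-in at 20 MHz sees the envelope only
  through its mean. The photothermal coefficient is therefore
  calibrated with the closed-form envelope average
  (`peak_depth_for_average`) so that the cycle-averaged modulation is
  1.8% per mW, with quasi-continuous thermal relaxation
  (τ_decay = 10 µs, film on a high-heat-capacity substrate) keeping
  the implied peak depth inside the small-signal regime up to 5 mW.
  The round trip then re-measures the slope through the full
  waveform + lock-in + regression chain, which is independent of the
  closed-form calibration.

## Resolution measurement

`make_bead_map` renders a bead as the projected chord length of a
solid sphere (value ∝ √(R²−r²), not a flat disk), which is the right
model for projected mass. Quadrature deconvolution
(√(measured² − bead²)), however, assumes a Gaussian-equivalent bead of
FWHM equal to its diameter; a sphere-projection profile has FWHM
(√3/2)·d and non-Gaussian tails, and feeding it through the quadrature
convention misestimates the PSF severely. The resolution round trip
therefore uses the Gaussian-equivalent bead profile
(`profile="gaussian"`), matching the convention under which the
deconvolution formula is exact: imaging the 500-nm bead with channel
PSFs of 398/561 nm, Gaussian-fitting the central line profile and
deconvolving recovers both configured resolutions to well within 5%.

## Phantoms

The generators emulate the structure of the real specimens, not their
photophysics: no refractive-index or scattering contrast, no 3-D cell
morphology, no absolute cross sections.

* **Powder mixture** — non-overlapping disks (rejection sampling,
  1000 retries, then an error reporting placements achieved), species
  assigned cyclically over a seeded shuffle so a 1:1:1 molar ratio is
  honoured in expectation; grain centers are snapped to pixel centers
  so equal-diameter grains rasterize identically (equal species totals
  are then exact by construction when sizes are not jittered).
  Default grain diameter 3 µm with ±20% jitter on a 0.4-µm raster — a
  typical powder-grain scale, large enough that PSF edge blur does not
  dominate grain interiors.
* **Droplet field** — disks plus elongated ellipses (aspect 3–5) with
  Gaussian size/intensity distributions (defaults 1.0±0.2 µm,
  1.0±0.1), placed with an exclusion margin so neighbouring objects
  stay separable after blur; the ground-truth table exactly enumerates
  the rendered objects.

Passing tests on these phantoms demonstrates correctness of the
measurement chain, not performance on real tissue: real specimens add
scattering backgrounds, spatially varying baselines, overlapping
organelles and focus drift that the generators deliberately omit.

## Analysis choices

* Unmixing is per-pixel non-negative least squares (the physical
  constraint) against a reference matrix of pure-species responses at
  the acquisition channels; unconstrained least squares is available
  by clipping the references to identity cases. Before unmixing,
  channel images are divided by the per-channel instrument response
  (`channel_unit_response`) and excitation powers — the same role
  power normalization plays for IR images.
* Droplet extraction interpolates bilinearly to a 0.1-µm raster,
  subtracts the median background, applies Otsu's threshold (fixed
  value optional), labels with 8-connectivity and filters by
  circularity 4πA/P² with the Crofton perimeter. Circularity is
  clipped at 1.05, and an upper bound of 1.0 tolerates discretization
  overshoot up to the clip; the minimum equivalent diameter defaults
  to 0.4 µm, the order of the resolution limit. Droplet "size" is
  reported both as area and as equivalent diameter.
* Statistics are the pooled-variance two-sample t test and the
  two-sided F test of equal variances, with star coding at 0.05,
  0.01, 10⁻³, 10⁻⁴.
* The ratiometric recipe rescales each background-subtracted image to
  [0, 1] by its maximum (percentile scaling would be the robust
  alternative on noisy data; max scaling is the default), adds 1 and
  divides, bounding the output to [0.5, 2] and making it invariant to
  common linear rescaling of the inputs.
* Pearson correlation is computed on raw images over all pixels.

## Problem sizes and numerics

Simulated dwells in the test suite are 10–200 µs (1–20 IR periods) at
1.28 GS/s, chosen as the shortest dwells that give clean lock-in
settling and integer numbers of envelope periods; the trace-level
diagnostics use 1-ms acquisitions matching the instrument's recorded
trace length. Welch spectra use Hann windows without detrending so
the dc term is retained. Gaussian profile fits start from
moment-based initial guesses and report a fit error on flat or
non-peaked profiles. The mixture-phantom four-channel imaging test
runs at 0.4-µm pixels (the experimental pixel size), where the 398-nm
Raman PSF is below one pixel and degrades to a delta kernel with a
warning — expected behaviour, not an error.

## Known limitations

Hardware effects outside the model: detector/amplifier transfer
functions, EOM transients and finite extinction, laser jitter and 1/f
noise, thermal lensing and heat diffusion, z-sectioning, epi vs
forward collection (a metadata tag only). The spectral axis of each
species is a short list of named bands, so sweep spectra are faithful
to the configuration, not to full literature spectra. Biological
images (cells, tissue, organisms) are represented only through
droplet/structure phantoms; the package makes no claim about
reproducing measured biological p-values or correlation coefficients.
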