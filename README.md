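# inspiresim

A digital twin of a single-probe pump–probe vibrational microscope that
detects mid-infrared photothermal (MIP) and stimulated Raman loss (SRL)
contrast **simultaneously on one probe beam**. The package is for
instrument builders and image analysts who want to study the
frequency-multiplexed detection scheme — how the two chemical channels
share one waveform, how they are separated by lock-in demodulation, how
cross-talk between them behaves — and to prototype the downstream
analysis (spectral unmixing, ratiometric imaging, droplet morphometry)
on fully synthetic, ground-truth-known specimens.

## The signal model

The probe is an 80-MHz picosecond pulse train. Two modulations are
imprinted multiplicatively on the pulse energies:

* **SRL** — the Stokes beam is gated by a 20-MHz square wave (pattern
  `on, on, off, off` over four probe pulses). When the pump–Stokes
  detuning matches a Raman-active band, each gated pulse loses a
  fraction δ_SRL of its energy:  bilinear in pump and Stokes power.
* **MIP** — 500-ns mid-IR pulses at 100 kHz heat the focal volume when
  the IR wavenumber hits an IR-active band. The transmission
  modulation m(t) rises exponentially (τ_rise) toward the depth δ_PT
  during each IR pulse and relaxes exponentially (τ_decay) afterwards;
  the periodic steady state has a closed geometric-series form.

Pulse energy:  E_k = E₀ · (1 − δ_SRL·g_k) · (1 − m(t_k)),
with g_k the Stokes gate. Because the two processes occupy cleanly
separated frequency windows (100 kHz vs 20 MHz), quadrature lock-in
demodulation recovers both channels from the *same* trace — the
simultaneity guarantee that defines the technique. Software lock-in
here means mixing with cos/sin references and a cascaded single-pole
low-pass, calibrated so a cosine of amplitude A returns A.

Around this core the package provides:

* `phantoms` — Lorentzian band spectra for preset species (PMMA, oil,
  palmitic acid, 1,4-diphenylbutadiyne, triphenylphosphine, generic
  lipid/protein/proteoglycan) with separate IR and Raman band lists
  (complementary selection rules), plus bead, powder-mixture and
  droplet-field concentration maps with ground-truth tables.
* `optics` — Gaussian channel PSFs (defaults 398 nm Raman / 561 nm IR)
  and the linear contrast forward model.
* `waveform` — pulse-train synthesis, thermal envelope, noise model,
  and the closed-form cross-talk sideband prediction.
* `demod` — lock-in, Welch power spectra, virtual piezo scanning
  (`scan_image`) and quasi-simultaneous spectral sweeps
  (`sweep_spectrum`), with an analytic fast path that matches the full
  waveform path to better than 1%.
* `analysis` — per-pixel non-negative least-squares unmixing, Pearson
  correlation specificity, the background-subtract/normalize/add-one
  ratiometric recipe, droplet extraction (bilinear upsampling to
  0.1 µm, Otsu threshold, circularity 0.8–1.0) with two-sample t and
  variance tests, and bead-profile resolution measurement by Gaussian
  fit plus quadrature deconvolution.
* `io` / `cli` — TIFF/CSV/YAML round trips and an `inspire` command
  with `simulate-trace`, `simulate-image`, `demod`, `psd`, `sweep`,
  `unmix`, `ratio`, `droplets`, `stats`, `resolution`, `make-phantom`.

## Worked example

Simulate one millisecond of the probe waveform for a uniform oil film
(pump/Stokes/IR powers 315/315/5 mW, IR 1750 cm⁻¹ ester C=O, Raman
2850 cm⁻¹ CH₂) and demodulate both channels:

```python
import inspiresim as ins

lib = ins.SPECIES_PRESETS
film = ins.uniform_map("oil", shape=(1, 1), pixel_size=1.0)
exc = ins.ExcitationConfig(ir_wavenumber=1750.0, raman_wavenumber=2850.0,
                           p_pump=315.0, p_stokes=315.0, p_ir=5.0)
pair = ins.render_contrast(film, lib, ins.PSFModel(398.0), ins.PSFModel(561.0),
                           exc, gains=(5e-8, 0.0036))
dsrl, dpt = float(pair.delta_srl[0, 0]), float(pair.delta_pt[0, 0])
print(f"delta_srl = {dsrl:.4f}   delta_pt = {dpt:.4f}")

cfg = ins.PulseTrainConfig(dwell=1e-3)
trace = ins.synth_trace(dsrl, dpt, cfg, ins.ThermalConfig())
f, psd = ins.power_spectrum(trace, segment=100e-6)
print("low band peak :", ins.dominant_peak(f, psd, fmax=150e3) / 1e3, "kHz")
print("mid band peak :", ins.dominant_peak(f, psd, fmin=5e6, fmax=50e6) / 1e6, "MHz")
print("high band peak:", ins.dominant_peak(f, psd, fmin=50e6, fmax=150e6) / 1e6, "MHz")

ir = ins.lockin(trace, ins.LockinConfig(f_ref=100e3))
raman = ins.lockin(trace, ins.LockinConfig(f_ref=20e6))
print(f"IR channel (100 kHz): {ir:.4g}   Raman channel (20 MHz): {raman:.4g}")
```

Output:

```
delta_srl = 0.0050   delta_pt = 0.0180
low band peak : 100.0 kHz
mid band peak : 20.0 MHz
high band peak: 80.0 MHz
IR channel (100 kHz): 2.992e+05   Raman channel (20 MHz): 2.838e+05
```

The film produces a 0.5% per-pulse Raman loss and a 1.8% photothermal
modulation depth at 5 mW of IR. Its power spectrum is dominated by
exactly the three modulation rates — the photothermal repetition rate
(100 kHz), the Stokes gating rate (20 MHz) and the probe repetition
rate (80 MHz) — and the lock-in amplitudes at the first two are the
simultaneous IR and Raman chemical readouts of the same trace.

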