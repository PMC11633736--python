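"""Time-domain probe waveform synthesis for one pixel dwell.

The probe is an 80-MHz pulse train. Each pulse's energy carries two
multiplicative modulations:

* stimulated Raman loss, gated by the 20-MHz square-wave Stokes
  modulation (pattern on,on,off,off over four probe pulses), removing a
  fraction ``delta_srl`` of the pulse energy on gated pulses;
* the photothermal envelope ``m(t)``: during each 500-ns mid-IR pulse
  (100-kHz repetition) the transmission modulation rises exponentially
  toward the configured depth and relaxes exponentially afterwards.

Pulse energy:  E_k = E0 * (1 - delta_srl * gate_k) * (1 - m(t_k)).

Pulses are rendered as single-sample-wide rectangles carrying the pulse
energy (the 2-ps physical pulse width is far below the detector-limited
sample period and is carried as metadata only). Detector noise is
applied per sample afterwards.

The periodic steady state of the exponential rise/decay envelope has a
closed form (geometric-series fixed point), used both for synthesis and
for the analytic predictions (cycle average, Fourier harmonics,
multiplicative cross-talk sidebands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "PulseTrainConfig",
    "ThermalConfig",
    "NoiseConfig",
    "TimeTrace",
    "ir_envelope",
    "srl_gate",
    "synth_trace",
    "multiplicative_crosstalk_depth",
    "envelope_average",
    "envelope_fourier_amplitude",
    "peak_depth_for_average",
    "pulse_times",
    "pulse_energies",
]


@dataclass(frozen=True)
class PulseTrainConfig:
    """Excitation timing. Frequencies in Hz, times in seconds."""

    f_probe: float = 80e6
    f_stokes_mod: float = 20e6
    f_ir: float = 100e3
    ir_pulse_width: float = 500e-9
    probe_pulse_width: float = 2e-12  # metadata only
    sample_rate: float = 1.28e9
    dwell: float = 100e-6

    def __post_init__(self):
        ratio = self.f_probe / self.f_stokes_mod
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) % 2 != 0:
            raise ValueError(
                f"f_probe/f_stokes_mod must be an even integer, got {ratio}"
            )
        if self.sample_rate < 2 * self.f_probe:
            raise ValueError("sample_rate must be >= 2 * f_probe (aliasing guard)")
        if self.ir_pulse_width >= 1.0 / self.f_ir:
            raise ValueError("ir_pulse_width must be shorter than the IR period")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")

    @property
    def gate_ratio(self) -> int:
        return int(round(self.f_probe / self.f_stokes_mod))

    @property
    def n_samples(self) -> int:
        return int(round(self.dwell * self.sample_rate))

    @property
    def n_pulses(self) -> int:
        # pulses with t_k = k / f_probe strictly inside the dwell
        return int(math.ceil(self.dwell * self.f_probe - 1e-9))


@dataclass(frozen=True)
class ThermalConfig:
    """Phenomenological single-exponential thermal response.

    tau_rise: heating time constant during the IR pulse (s).
    tau_decay: relaxation time constant after the pulse (s).
    peak_depth: transmission-modulation depth the envelope rises toward
    (dimensionless; overridden per pixel by the rendered delta_pt).
    """

    tau_rise: float = 200e-9
    tau_decay: float = 1e-6
    peak_depth: float = 0.018

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("thermal time constants must be positive")
        if self.peak_depth < 0:
            raise ValueError("peak_depth must be non-negative")


@dataclass(frozen=True)
class NoiseConfig:
    """Detector noise model.

    relative_intensity_noise: per-sample Gaussian sd relative to the
    sample value. shot_noise_scale: photons per sample at unit sample
    amplitude (0 disables the Poisson term).
    """

    relative_intensity_noise: float = 5e-3
    shot_noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_intensity_noise < 0 or self.shot_noise_scale < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class TimeTrace:
    """Sampled probe-intensity waveform with its configuration provenance."""

    samples: np.ndarray
    sample_rate: float
    train: PulseTrainConfig
    thermal: Optional[ThermalConfig] = None
    noise: Optional[NoiseConfig] = None
    delta_srl: float = 0.0
    delta_pt: float = 0.0

    @property
    def dwell(self) -> float:
        return self.samples.size / self.sample_rate


# ---------------------------------------------------------------------------
# Photothermal envelope (periodic steady state)
# ---------------------------------------------------------------------------


def _steady_state(cfg: PulseTrainConfig, th: ThermalConfig, peak: float):
    """Envelope values at IR-pulse start (m0) and end (m1).

    Fixed point of one heating/relaxation cycle:
      m1 = peak + (m0 - peak) * a,  m0 = m1 * b
    with a = exp(-T_on/tau_rise), b = exp(-T_off/tau_decay).
    """
    T = 1.0 / cfg.f_ir
    t_on = cfg.ir_pulse_width
    a = math.exp(-t_on / th.tau_rise)
    b = math.exp(-(T - t_on) / th.tau_decay)
    denom = 1.0 - a * b
    m1 = peak * (1.0 - a) / denom
    m0 = m1 * b
    return m0, m1


def _envelope_at(t: np.ndarray, cfg: PulseTrainConfig, th: ThermalConfig, peak: float):
    T = 1.0 / cfg.f_ir
    t_on = cfg.ir_pulse_width
    m0, m1 = _steady_state(cfg, th, peak)
    u = np.mod(t, T)
    heating = u < t_on
    m = np.empty_like(u)
    m[heating] = peak + (m0 - peak) * np.exp(-u[heating] / th.tau_rise)
    m[~heating] = m1 * np.exp(-(u[~heating] - t_on) / th.tau_decay)
    return m


def ir_envelope(
    cfg: PulseTrainConfig,
    th: ThermalConfig,
    t: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Photothermal transmission-modulation envelope m(t) over the dwell.

    Periodic at f_ir with the first IR pulse starting at t = 0 (phase
    convention); evaluated in the periodic steady state, so
    0 <= m(t) <= peak_depth everywhere. Pass ``t`` to evaluate at
    arbitrary times instead of the dwell's sample grid.
    """
    if t is None:
        if cfg.dwell < 1.0 / cfg.f_ir:
            raise ValueError("dwell must cover at least one IR period")
        t = np.arange(cfg.n_samples) / cfg.sample_rate
    return _envelope_at(np.asarray(t, dtype=float), cfg, th, th.peak_depth)


def envelope_average(cfg: PulseTrainConfig, th: ThermalConfig, peak: float = None) -> float:
    """Closed-form cycle average of the steady-state envelope."""
    if peak is None:
        peak = th.peak_depth
    T = 1.0 / cfg.f_ir
    t_on = cfg.ir_pulse_width
    t_off = T - t_on
    m0, m1 = _steady_state(cfg, th, peak)
    a = math.exp(-t_on / th.tau_rise)
    b = math.exp(-t_off / th.tau_decay)
    heat = peak * t_on + (m0 - peak) * th.tau_rise * (1.0 - a)
    cool = m1 * th.tau_decay * (1.0 - b)
    return (heat + cool) / T


def envelope_fourier_amplitude(
    cfg: PulseTrainConfig, th: ThermalConfig, n: int = 1, peak: float = None
) -> float:
    """Closed-form amplitude of the n-th harmonic (at n * f_ir) of m(t).

    Returns A_n = 2 |c_n| so that a pure cosine component
    A_n cos(2 pi n f_ir t + phi) has amplitude A_n.
    """
    if n < 1:
        raise ValueError("harmonic index must be >= 1")
    if peak is None:
        peak = th.peak_depth
    T = 1.0 / cfg.f_ir
    t_on = cfg.ir_pulse_width
    t_off = T - t_on
    m0, m1 = _steady_state(cfg, th, peak)
    w = 2.0 * math.pi * n / T
    iw = 1j * w
    g_r = 1.0 / th.tau_rise + iw
    g_d = 1.0 / th.tau_decay + iw
    i1 = peak * (1.0 - np.exp(-iw * t_on)) / iw
    i1 += (m0 - peak) * (1.0 - np.exp(-g_r * t_on)) / g_r
    i2 = m1 * np.exp(-iw * t_on) * (1.0 - np.exp(-g_d * t_off)) / g_d
    return float(2.0 * abs(i1 + i2) / T)


def peak_depth_for_average(
    target_average: float, cfg: PulseTrainConfig, th: ThermalConfig
) -> float:
    """Peak depth whose steady-state cycle average equals ``target_average``.

    The envelope is linear in its peak depth, so this is a single
    division. Used to configure the instrument model from a measured
    (lock-in, i.e. cycle-averaged) fractional transmission change.
    """
    unit = envelope_average(cfg, th, peak=1.0)
    if unit <= 0:
        raise ValueError("degenerate envelope: zero cycle average")
    return target_average / unit


# ---------------------------------------------------------------------------
# Pulse train
# ---------------------------------------------------------------------------


def srl_gate(cfg: PulseTrainConfig, n_pulses: Optional[int] = None) -> np.ndarray:
    """Per-probe-pulse Stokes gate (1 = Raman loss active).

    Square wave at f_stokes_mod with 50% duty; with the default 80/20
    ratio the repeating pattern over four probe pulses is
    [on, on, off, off], and the first pulse is "on".
    """
    ratio = cfg.gate_ratio
    if n_pulses is None:
        n_pulses = cfg.n_pulses
    k = np.arange(n_pulses)
    return ((k % ratio) < ratio // 2).astype(float)


def pulse_times(cfg: PulseTrainConfig, n_pulses: Optional[int] = None) -> np.ndarray:
    """Centers of the probe pulses within the dwell, t_k = k / f_probe."""
    if n_pulses is None:
        n_pulses = cfg.n_pulses
    return np.arange(n_pulses) / cfg.f_probe


def pulse_energies(
    delta_srl: float,
    delta_pt: float,
    cfg: PulseTrainConfig,
    th: ThermalConfig,
    e0: float = 1.0,
) -> np.ndarray:
    """Noiseless per-pulse energies E_k over the dwell."""
    t_k = pulse_times(cfg)
    gate = srl_gate(cfg)
    m = _envelope_at(t_k, cfg, th, delta_pt)
    return e0 * (1.0 - delta_srl * gate) * (1.0 - m)


def _check_small_signal(delta_srl: float, delta_pt: float):
    for name, v in (("delta_srl", delta_srl), ("delta_pt", delta_pt)):
        if not 0.0 <= v < 0.2:
            raise ValueError(f"{name} = {v} outside small-signal range [0, 0.2)")


def synth_trace(
    delta_srl: float,
    delta_pt: float,
    cfg: PulseTrainConfig,
    th: Optional[ThermalConfig] = None,
    noise: Optional[NoiseConfig] = None,
    e0: float = 1.0,
) -> TimeTrace:
    """Synthesize the probe-intensity waveform for one pixel dwell.

    With both modulations zero and noise off the result is a
    constant-amplitude 80-MHz pulse train. Each pulse occupies one
    sample period; the sample value is E_k * sample_rate so that the
    trace integral (sum * dt) equals the total pulse energy.
    """
    _check_small_signal(delta_srl, delta_pt)
    if th is None:
        th = ThermalConfig()
    th = replace(th, peak_depth=delta_pt)
    energies = pulse_energies(delta_srl, delta_pt, cfg, th, e0=e0)
    n = cfg.n_samples
    samples = np.zeros(n)
    idx = np.round(pulse_times(cfg) * cfg.sample_rate).astype(int)
    keep = idx < n
    samples[idx[keep]] = energies[keep] * cfg.sample_rate
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.relative_intensity_noise > 0:
            samples = samples * (
                1.0 + noise.relative_intensity_noise * rng.standard_normal(n)
            )
        if noise.shot_noise_scale > 0:
            scale = noise.shot_noise_scale
            samples = rng.poisson(np.clip(samples, 0, None) * scale) / scale
        np.clip(samples, 0.0, None, out=samples)
    return TimeTrace(
        samples=samples,
        sample_rate=cfg.sample_rate,
        train=cfg,
        thermal=th,
        noise=noise,
        delta_srl=delta_srl,
        delta_pt=delta_pt,
    )


def multiplicative_crosstalk_depth(
    delta_srl: float,
    delta_pt: float,
    cfg: PulseTrainConfig,
    th: Optional[ThermalConfig] = None,
) -> float:
    """Predicted sideband-to-carrier amplitude ratio at f_stokes_mod +/- f_ir.

    The product modulation (1 - delta_srl * gate) * (1 - m) places
    sidebands around the 20-MHz SRL carrier at offsets of the
    photothermal repetition rate. Amplitude modulation by a component
    A_1 cos(2 pi f_ir t) of m produces sidebands of A_1 / 2 relative to
    the carrier, so the predicted ratio is half the first-harmonic
    amplitude of the envelope (independent of delta_srl in the
    small-signal regime).
    """
    _check_small_signal(delta_srl, delta_pt)
    if delta_pt == 0.0:
        return 0.0
    if th is None:
        th = ThermalConfig()
    return envelope_fourier_amplitude(cfg, th, n=1, peak=delta_pt) / 2.0
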