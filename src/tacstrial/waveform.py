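"""Theta-gamma tACS waveform synthesis and independent verification.

The active protocol delivers a 6 Hz theta carrier at 2 mA peak-to-peak
for 20 minutes (15 s linear fade-in/out), with an 80 Hz gamma burst of
exactly six cycles superimposed on every positive theta peak.  The burst
is amplitude-modulated (raised-cosine envelope by default) so its
peak-to-peak maximum — 0.9 mA — coincides with the theta peak:
phase-amplitude coupling, with gamma silent in the troughs.

The sham protocol delivers current only at the start and end of the
period: two 90 s ramp blocks (15 s fade-in, 60 s of the full 2 mA
peak-to-peak active waveform, 15 s fade-out) bracketing a continuous
85 Hz sinusoid at 50 uA peak-to-peak, which keeps skin sensation
comparable without stimulating cortex.

``verify_signal``/``verify_sham`` re-measure every protocol parameter
from the raw samples alone (spectral peaks, least-squares sinusoid fits,
burst detection and cycle counting) and serve as the independent oracle
for the synthesizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal

MINUTES_PER_SESSION = 20
N_STIM_SESSIONS = 16


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of the active theta-gamma protocol."""

    theta_freq: float = 6.0  # Hz
    gamma_freq: float = 80.0  # Hz
    theta_amp_pp: float = 2.0  # mA peak-to-peak
    gamma_amp_pp_max: float = 0.9  # mA peak-to-peak at the theta peak
    cycles_per_burst: int = 6
    fade_in_s: float = 15.0
    fade_out_s: float = 15.0
    duration_s: float = 1200.0  # 20 minutes
    sample_rate: float = 10_000.0  # Hz
    burst_envelope: str = "hann"  # or "rectangular"
    coupling: str = "peak"  # or "trough"

    def __post_init__(self) -> None:
        if not self.gamma_freq > self.theta_freq > 0:
            raise ValueError("need gamma_freq > theta_freq > 0")
        if self.theta_amp_pp <= 0 or self.gamma_amp_pp_max < 0:
            raise ValueError("amplitudes must be positive")
        if self.cycles_per_burst / self.gamma_freq > 1.0 / self.theta_freq:
            raise ValueError("burst longer than one theta period")
        if self.sample_rate < 4 * self.gamma_freq:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz under-resolves "
                f"{self.gamma_freq} Hz gamma (need >= {4 * self.gamma_freq})"
            )
        if self.burst_envelope not in ("hann", "rectangular"):
            raise ValueError("burst_envelope must be 'hann' or 'rectangular'")
        if self.coupling not in ("peak", "trough"):
            raise ValueError("coupling must be 'peak' or 'trough'")


@dataclass(frozen=True)
class ShamSpec:
    """Parameters of the sham protocol."""

    block_duration_s: float = 90.0
    block_fade_s: float = 15.0  # per side; 60 s full amplitude between
    carrier_freq: float = 85.0  # Hz
    carrier_amp_pp: float = 0.05  # mA (50 uA)
    duration_s: float = 1200.0
    sample_rate: float = 10_000.0
    active: WaveformSpec = field(default_factory=WaveformSpec)

    def __post_init__(self) -> None:
        if self.duration_s <= 2 * self.block_duration_s:
            raise ValueError("duration must exceed the two ramp blocks")
        if self.sample_rate < 4 * self.carrier_freq:
            raise ValueError("sample_rate under-resolves the sham carrier")


@dataclass
class StimulationSignal:
    """A sampled stimulation current with structural annotations."""

    sample_rate: float
    samples: np.ndarray  # mA
    annotations: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _fade_envelope(n: int, fs: float, fade_in_s: float, fade_out_s: float) -> np.ndarray:
    env = np.ones(n)
    n_in = int(round(fade_in_s * fs))
    n_out = int(round(fade_out_s * fs))
    if n_in > 0:
        env[:n_in] = np.linspace(0.0, 1.0, n_in, endpoint=False)
    if n_out > 0:
        env[n - n_out :] = np.linspace(1.0, 0.0, n_out, endpoint=False)
    return env


def synthesize_active(spec: WaveformSpec) -> StimulationSignal:
    """Sample the active theta-gamma waveform.

    The theta carrier is ``(pp/2) sin(2 pi f t)``; one gamma burst of
    ``cycles_per_burst`` cycles is centred on each positive theta peak
    (or trough for the trough-coupled control), cosine-phased at its
    centre so the compound maximum is ``(theta_pp + gamma_pp)/2``.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    theta = (spec.theta_amp_pp / 2.0) * np.sin(2 * np.pi * spec.theta_freq * t)

    period = 1.0 / spec.theta_freq
    first_peak = period / 4.0 if spec.coupling == "peak" else 3.0 * period / 4.0
    centers = np.arange(first_peak, spec.duration_s, period)
    half_w = spec.cycles_per_burst / spec.gamma_freq / 2.0

    gamma = np.zeros(n)
    burst_windows = []
    for tc in centers:
        i0 = max(0, int(np.ceil((tc - half_w) * fs)))
        i1 = min(n, int(np.floor((tc + half_w) * fs)) + 1)
        if i1 <= i0:
            continue
        tau = t[i0:i1] - tc
        if spec.burst_envelope == "hann":
            env = 0.5 * (1.0 + np.cos(np.pi * tau / half_w))
        else:
            env = np.ones_like(tau)
        gamma[i0:i1] += (
            (spec.gamma_amp_pp_max / 2.0)
            * env
            * np.cos(2 * np.pi * spec.gamma_freq * tau)
        )
        burst_windows.append((tc - half_w, tc + half_w))

    env = _fade_envelope(n, fs, spec.fade_in_s, spec.fade_out_s)
    samples = env * (theta + gamma)
    return StimulationSignal(
        sample_rate=fs,
        samples=samples,
        annotations={
            "mode": "active",
            "spec": spec,
            "burst_windows": burst_windows,
            "fade_windows": [
                (0.0, spec.fade_in_s),
                (spec.duration_s - spec.fade_out_s, spec.duration_s),
            ],
        },
    )


def synthesize_sham(spec: ShamSpec) -> StimulationSignal:
    """Sample the sham protocol: two ramp blocks around a weak carrier."""
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    samples = (spec.carrier_amp_pp / 2.0) * np.sin(2 * np.pi * spec.carrier_freq * t)

    from dataclasses import replace

    block = synthesize_active(
        replace(
            spec.active,
            duration_s=spec.block_duration_s,
            fade_in_s=spec.block_fade_s,
            fade_out_s=spec.block_fade_s,
            sample_rate=fs,
        )
    ).samples
    nb = len(block)
    samples[:nb] = block
    samples[n - nb :] = block

    segs = [
        ("ramp_block", 0.0, spec.block_duration_s),
        ("carrier", spec.block_duration_s, spec.duration_s - spec.block_duration_s),
        ("ramp_block", spec.duration_s - spec.block_duration_s, spec.duration_s),
    ]
    return StimulationSignal(
        sample_rate=fs,
        samples=samples,
        annotations={"mode": "sham", "spec": spec, "segments": segs},
    )


@dataclass
class SignalReport:
    """Measurements recovered from raw samples by ``verify_signal``."""

    theta_freq_hz: float
    gamma_freq_hz: float | None
    theta_amp_pp: float
    gamma_amp_pp_max: float
    n_bursts: int
    bursts_per_theta_period: float
    cycles_per_burst: float
    peak_coupled: bool
    fade_in_estimate_s: float
    fade_out_estimate_s: float
    fades_monotone: bool


def _dominant_freq(x: np.ndarray, fs: float, fmin: float, fmax: float) -> float | None:
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    amp = np.abs(np.fft.rfft(x - x.mean()))
    sel = (freqs >= fmin) & (freqs <= fmax)
    if not np.any(sel) or amp[sel].max() == 0:
        return None
    return float(freqs[sel][np.argmax(amp[sel])])


def _sinusoid_fit(x: np.ndarray, t: np.ndarray, freq: float) -> tuple[float, np.ndarray]:
    """Least-squares amplitude of a sinusoid at ``freq``; returns
    (amplitude, fitted waveform)."""
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef)), design @ coef


def _refine_freq(x: np.ndarray, t: np.ndarray, f0: float, half_width: float) -> float:
    """Sharpen an FFT-bin frequency estimate by maximizing the fitted
    sinusoid amplitude in a bracket around ``f0`` (golden-section)."""
    res = scipy.optimize.minimize_scalar(
        lambda f: -_sinusoid_fit(x, t, f)[0],
        bounds=(f0 - half_width, f0 + half_width),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def verify_signal(signal: StimulationSignal) -> SignalReport:
    """Measure the active-waveform parameters from raw samples only.

    Uses the spectral peak for the carrier frequencies, a least-squares
    sinusoid fit for the theta amplitude, envelope thresholding for burst
    windows, and sign-change counting for gamma cycles.  The synthesis
    functions must round-trip through this oracle.
    """
    fs = signal.sample_rate
    x = signal.samples
    t = signal.times
    dur = signal.duration_s

    theta_freq = _dominant_freq(x, fs, 0.5, 20.0)
    if theta_freq is None:
        raise ValueError("no theta-band component found")

    # steady state: exclude a generous margin at both ends
    margin = min(dur / 4.0, 20.0)
    core = slice(int(margin * fs), int((dur - margin) * fs))
    theta_freq = _refine_freq(x[core], t[core], theta_freq, 2.0 * fs / len(x))
    theta_amp, theta_fit = _sinusoid_fit(x[core], t[core], theta_freq)

    resid = x[core] - theta_fit
    coarse_gamma = _dominant_freq(resid, fs, 5 * theta_freq, fs / 2.0)

    # burst detection on the rectified residual envelope.  The threshold
    # sits as low as the theta-fit ripple allows: a very low cut keeps
    # the tapered burst edges (and their zero crossings), while the
    # median of the envelope estimates the inter-burst ripple floor.
    gamma_guess = coarse_gamma or 80.0
    win = max(3, int(fs / gamma_guess / 2))
    envelope = (
        np.convolve(np.abs(resid), np.ones(win) / win, mode="same") * np.pi / 2.0
    )
    noise_floor = 0.01 * theta_amp  # residual theta-fit error, not a burst
    thresh = max(0.01 * envelope.max(), 4.0 * np.percentile(envelope, 20))
    if envelope.max() <= noise_floor:
        above = np.zeros(len(envelope), dtype=bool)
    else:
        above = envelope > thresh
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    segments = list(zip(idx[::2], idx[1::2]))
    # re-join splits within one burst (inter-burst gaps are at least
    # 1/theta - burst width, well above a fifth of a period), then drop
    # sub-cycle slivers
    merged: list[list[int]] = []
    gap_n = int(0.2 * fs / theta_freq)
    for i0, i1 in segments:
        if merged and i0 - merged[-1][1] < gap_n:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    bursts = []
    for i0, i1 in merged:
        if i0 == 0 or i1 >= len(envelope):
            continue  # truncated by the analysis window
        if (i1 - i0) / fs > 1.0 / gamma_guess:
            bursts.append((i0, i1))

    cycles, pps, at_peak, freqs = [], [], [], []
    theta_core = theta_fit
    for i0, i1 in bursts:
        seg = resid[i0:i1]
        sign = np.sign(seg)
        changes = np.flatnonzero(np.diff(sign) != 0)
        cycles.append(len(changes) / 2.0)
        pps.append(2.0 * np.abs(seg).max())
        center = (i0 + i1) // 2
        at_peak.append(theta_core[center] >= 0.8 * theta_amp)
        if len(changes) >= 2:
            # sub-sample zero-crossing times -> mean half-period -> freq
            tz = changes + seg[changes] / (seg[changes] - seg[changes + 1])
            freqs.append((len(changes) - 1) / (2.0 * (tz[-1] - tz[0])) * fs)
    gamma_freq = float(np.median(freqs)) if freqs else coarse_gamma

    n_periods = (len(x[core]) / fs) * theta_freq
    n_bursts = len(bursts)
    peak_coupled = bool(n_bursts > 0 and np.mean(at_peak) > 0.9)

    # fade estimates: time for the per-period peak envelope to reach 95%
    period_n = max(1, int(fs / theta_freq))
    n_per = len(x) // period_n
    per_peak = np.abs(x[: n_per * period_n]).reshape(n_per, period_n).max(axis=1)
    steady = np.median(per_peak[n_per // 3 : 2 * n_per // 3])
    rising = np.flatnonzero(per_peak >= 0.95 * steady)
    # a linear ramp crosses 95% of steady at 0.95 of the fade duration
    fade_in = float(rising[0] * period_n / fs / 0.95) if len(rising) else np.nan
    fade_out = (
        float((n_per - 1 - rising[-1]) * period_n / fs / 0.95)
        if len(rising)
        else np.nan
    )
    fin = per_peak[: max(1, int(fade_in / (period_n / fs)))]
    fout = per_peak[n_per - max(1, int(fade_out / (period_n / fs))) :]
    monotone = bool(
        np.all(np.diff(fin) >= -1e-6 * steady) and np.all(np.diff(fout) <= 1e-6 * steady)
    )

    return SignalReport(
        theta_freq_hz=theta_freq,
        gamma_freq_hz=gamma_freq,
        theta_amp_pp=2.0 * theta_amp,
        gamma_amp_pp_max=float(max(pps)) if pps else 0.0,
        n_bursts=n_bursts,
        bursts_per_theta_period=n_bursts / n_periods if n_periods else np.nan,
        cycles_per_burst=float(np.median(cycles)) if cycles else 0.0,
        peak_coupled=peak_coupled,
        fade_in_estimate_s=fade_in,
        fade_out_estimate_s=fade_out,
        fades_monotone=monotone,
    )


@dataclass
class ShamReport:
    block_durations_s: tuple[float, float]
    total_ramp_s: float
    interior_freq_hz: float
    interior_amp_pp: float


def verify_sham(signal: StimulationSignal) -> ShamReport:
    """Measure the sham structure from raw samples only."""
    fs = signal.sample_rate
    x = signal.samples
    # ramp blocks are orders of magnitude stronger than the carrier;
    # window longer than a theta period so block envelopes stay contiguous
    period_n = max(1, int(fs * 0.25))
    n_per = len(x) // period_n
    per_peak = np.abs(x[: n_per * period_n]).reshape(n_per, period_n).max(axis=1)
    # the interior carrier level dominates the median; anything well
    # above it belongs to a ramp block (including most of the fades)
    strong = per_peak > 2.0 * np.median(per_peak)
    idx = np.flatnonzero(np.diff(np.r_[0, strong.astype(int), 0]))
    blocks = [(i0, i1) for i0, i1 in zip(idx[::2], idx[1::2])]
    if len(blocks) != 2:
        raise ValueError(f"expected 2 ramp blocks, found {len(blocks)}")
    durations = tuple((i1 - i0) * period_n / fs for i0, i1 in blocks)

    i_in0 = blocks[0][1] * period_n + int(fs)
    i_in1 = blocks[1][0] * period_n - int(fs)
    interior = x[i_in0:i_in1]
    t = np.arange(len(interior)) / fs
    freq = _dominant_freq(interior, fs, 1.0, fs / 2.0)
    amp, _ = _sinusoid_fit(interior, t, freq)
    return ShamReport(
        block_durations_s=durations,
        total_ramp_s=float(sum(durations)),
        interior_freq_hz=float(freq),
        interior_amp_pp=2.0 * amp,
    )


def total_stimulation_minutes(
    n_sessions: int = N_STIM_SESSIONS,
    minutes_per_session: float = MINUTES_PER_SESSION,
) -> float:
    """Total stimulation exposure over the treatment schedule (minutes)."""
    return n_sessions * minutes_per_session


def export_csv(signal: StimulationSignal, path: str) -> None:
    """Write (time_s, current_ma) rows."""
    import pandas as pd

    pd.DataFrame({"time_s": signal.times, "current_ma": signal.samples}).to_csv(
        path, index=False
    )
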