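"""Continuous-trace preprocessing and extracellular spike extraction.

Covers the steps upstream of any spike-phase analysis: removal of the
narrow-band stimulation artifact by spectral interpolation, 300-3000 Hz
zero-phase Butterworth band-pass, robust noise estimation, amplitude
threshold detection with waveform snippets, and the cluster
signal-to-noise ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "ContinuousRecording",
    "DetectionConfig",
    "WaveformCluster",
    "remove_artifact_spectral",
    "bandpass",
    "estimate_noise_sigma",
    "detect_spikes",
    "compute_snr",
]


@dataclass(frozen=True)
class ContinuousRecording:
    """Single-channel continuous voltage trace."""

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = "ch0"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size < 1:
            raise ValueError("recording must contain at least one sample")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def save(self, path) -> None:
        """Write raw little-endian float32 binary plus a JSON sidecar."""
        path = Path(path)
        self.samples.astype("<f4").tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"sampling_rate_hz": self.sampling_rate, "channel_id": self.channel_id}))

    @classmethod
    def load(cls, path) -> "ContinuousRecording":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = np.fromfile(path, dtype="<f4").astype(float)
        return cls(samples, meta["sampling_rate_hz"], meta.get("channel_id", "ch0"))


@dataclass(frozen=True)
class DetectionConfig:
    """Detection parameters: threshold = lambda_factor * sigma_n."""

    lambda_factor: float = 4.0
    band_low: float = 300.0
    band_high: float = 3000.0
    filter_order: int = 4
    pre_samples: int = 8
    post_samples: int = 24
    censor_ms: float = 1.0  # refractory window after each detection

    @property
    def snippet_length(self) -> int:
        return self.pre_samples + self.post_samples

    def validate_band(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0.0 < self.band_low < self.band_high < nyq):
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz invalid for "
                f"sampling rate {sampling_rate} Hz (Nyquist {nyq} Hz)")


@dataclass(frozen=True)
class WaveformCluster:
    """Detected spikes: times, aligned waveform snippets and optional SNR."""

    spike_times: np.ndarray         # seconds
    waveforms: np.ndarray           # (n_spikes, snippet_length)
    sampling_rate: float
    pre_samples: int = 8
    snr: float | None = None
    n_dropped_edge: int = 0         # snippets that fell off the trace ends

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def waveforms_to_csv(self, path) -> None:
        np.savetxt(path, self.waveforms, delimiter=",", fmt="%.8g")

    def spikes_to_csv(self, path) -> None:
        peaks = self.waveforms[:, self.pre_samples] if self.n_spikes else np.array([])
        with open(path, "w") as fh:
            fh.write("time_s,peak_amplitude,polarity\n")
            for t, a in zip(self.spike_times, peaks):
                fh.write(f"{t:.8f},{a:.6g},{'+' if a >= 0 else '-'}\n")


def remove_artifact_spectral(rec: ContinuousRecording, target_freqs,
                             halfwidth: float = 0.5) -> ContinuousRecording:
    """Remove narrow-band artifacts by spectral interpolation.

    For every target frequency the amplitude spectrum inside
    ``target +/- halfwidth`` is replaced by a linear interpolation of the
    mean amplitudes in the flanking bands of equal width; phases are
    preserved, so the inverse transform returns a real trace of identical
    length.
    """
    freqs = np.atleast_1d(np.asarray(target_freqs, dtype=float))
    if freqs.size == 0:
        return rec
    nyq = rec.sampling_rate / 2.0
    for f0 in freqs:
        if f0 + halfwidth >= nyq:
            raise ValueError(f"target band {f0}+/-{halfwidth} Hz exceeds Nyquist {nyq} Hz")
    x = rec.samples
    spec = np.fft.rfft(x)
    fgrid = np.fft.rfftfreq(x.size, d=1.0 / rec.sampling_rate)
    amp = np.abs(spec)
    phase = np.angle(spec)
    for f0 in freqs:
        inside = (fgrid >= f0 - halfwidth) & (fgrid <= f0 + halfwidth)
        if not inside.any():
            continue
        lo_flank = (fgrid >= f0 - 2 * halfwidth) & (fgrid < f0 - halfwidth)
        hi_flank = (fgrid > f0 + halfwidth) & (fgrid <= f0 + 2 * halfwidth)
        lo = amp[lo_flank].mean() if lo_flank.any() else amp[hi_flank].mean()
        hi = amp[hi_flank].mean() if hi_flank.any() else lo
        idx = np.flatnonzero(inside)
        amp[idx] = np.interp(idx.astype(float),
                             [idx[0] - 1.0, idx[-1] + 1.0], [lo, hi])
    cleaned = np.fft.irfft(amp * np.exp(1j * phase), n=x.size)
    return ContinuousRecording(cleaned, rec.sampling_rate, rec.channel_id)


def bandpass(rec: ContinuousRecording, cfg: DetectionConfig | None = None) -> ContinuousRecording:
    """Zero-phase (forward-backward) Butterworth band-pass of the trace."""
    cfg = cfg or DetectionConfig()
    cfg.validate_band(rec.sampling_rate)
    sos = signal.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                        btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return ContinuousRecording(filtered, rec.sampling_rate, rec.channel_id)


def estimate_noise_sigma(rec: ContinuousRecording) -> float:
    """Robust background-noise SD: sigma_n = median(|x|) / 0.6745.

    The median-based estimator is insensitive to the spikes themselves,
    unlike the ordinary standard deviation.
    """
    return float(np.median(np.abs(rec.samples)) / 0.6745)


def detect_spikes(rec: ContinuousRecording, cfg: DetectionConfig | None = None,
                  sigma: float | None = None) -> WaveformCluster:
    """Amplitude-threshold spike detection on a band-passed trace.

    Threshold crossings of ``|x| > lambda_factor * sigma_n`` are aligned
    to the local extremum of the dominant polarity; snippets of
    ``pre_samples`` before and ``post_samples`` after the extremum are
    stored.  A censor window (default 1 ms) after each detection prevents
    double detection of one event; snippets extending beyond the trace
    ends are dropped and counted in ``n_dropped_edge``.
    """
    cfg = cfg or DetectionConfig()
    x = rec.samples
    if sigma is None:
        sigma = estimate_noise_sigma(rec)
    th = cfg.lambda_factor * sigma
    fs = rec.sampling_rate
    censor = max(int(round(cfg.censor_ms * 1e-3 * fs)), 1)
    search = censor  # look for the aligning extremum within one censor window

    above = np.abs(x) > th
    # rising edges of the exceedance mask
    edges = np.flatnonzero(above & ~np.roll(above, 1))
    if above.size and above[0]:
        edges = np.concatenate(([0], edges[edges != 0]))

    times, waves = [], []
    dropped = 0
    last_peak = -censor - 1
    for e in edges:
        if e <= last_peak + censor:
            continue
        stop = min(e + search, x.size)
        seg = x[e:stop]
        peak = e + int(np.argmax(np.abs(seg)))
        if peak <= last_peak + censor:
            continue
        start = peak - cfg.pre_samples
        end = peak + cfg.post_samples
        if start < 0 or end > x.size:
            dropped += 1
            last_peak = peak
            continue
        times.append(peak / fs)
        waves.append(x[start:end])
        last_peak = peak
    waves = np.array(waves) if waves else np.empty((0, cfg.snippet_length))
    return WaveformCluster(np.asarray(times), waves, fs,
                           pre_samples=cfg.pre_samples, n_dropped_edge=dropped)


def compute_snr(cluster: WaveformCluster) -> float:
    """Cluster signal-to-noise ratio.

    SNR = (1/n_c) * sum_i (max(s_i) - min(s_i)) / (2 * std(eps_i)) where
    eps_i = s_i - s_bar is each waveform's deviation from the cluster
    mean waveform; std is the sample standard deviation over snippet
    samples.
    """
    w = cluster.waveforms
    if w.shape[0] < 2:
        raise ValueError("SNR requires at least 2 waveforms")
    eps = w - w.mean(axis=0)
    spread = eps.std(axis=1, ddof=1)
    if np.any(spread == 0):
        raise ValueError("degenerate noise estimate: identical waveforms (eps = 0)")
    snr = float(np.mean((w.max(axis=1) - w.min(axis=1)) / (2.0 * spread)))
    return snr
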