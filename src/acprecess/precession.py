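"""Sliding-window phase-precession analysis of single-unit spiking.

Spike times are assigned a phase of the stimulation reference (an ideal
sinusoid at the block frequency, or the band-passed LFP's analytic
phase), summarized per sliding window (PLV, preferred phase, Rayleigh
p), and each unit is classified by a three-step framework:

1. responsiveness — Rayleigh p < 0.05 in at least ``max(min_windows,
   50% of windows)`` windows, otherwise *non-responsive*;
2. consistency — circular-linear correlation of preferred phase against
   window index with r > 0.5 and p < 0.05, otherwise *non-uniform*;
3. magnitude — unwrapped total shift between the first and last
   responsive window exceeding 15 deg, otherwise *stable*; the sign of
   the shift gives *clockwise* (negative) or *counter-clockwise*
   (positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .circular import (
    CircularSummary,
    PhaseSample,
    angular_difference,
    circ_lin_corr,
    summarize,
    wrap_deg,
)
from .preproc import ContinuousRecording

__all__ = [
    "StimulationReference",
    "WindowingScheme",
    "WindowedPhaseTrack",
    "PrecessionClassification",
    "extract_stim_phase",
    "window_track",
    "classify_precession",
    "summarize_population",
    "pre_during_post_compare",
]

LABELS = ("counter-clockwise", "clockwise", "stable", "non-uniform", "non-responsive")


@dataclass(frozen=True)
class StimulationReference:
    """The oscillation against which spike phases are measured.

    In ``ideal`` mode the phase is 360 * frac(f * (t - block_start)) with
    0 deg at the stimulation peak (cosine convention).  In ``lfp`` mode
    the recorded LFP is band-passed (2nd-order Butterworth, frequency
    +/- 1 Hz) and the instantaneous phase taken from the analytic
    signal, whose zero angle falls at the oscillation peak.
    """

    frequency: float
    mode: str = "ideal"                      # "ideal" | "lfp"
    lfp: ContinuousRecording | None = None
    block_start: float = 0.0
    block_end: float = 360.0
    ramp: float = 10.0

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.block_end <= self.block_start:
            raise ValueError("block_end must exceed block_start")
        if self.mode not in ("ideal", "lfp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "lfp" and self.lfp is None:
            raise ValueError("lfp mode requires an LFP recording")

    @property
    def block_length(self) -> float:
        return self.block_end - self.block_start


def extract_stim_phase(ref: StimulationReference, times) -> PhaseSample:
    """Assign each spike time the stimulation phase at which it occurred."""
    t = np.asarray(times, dtype=float).ravel()
    outside = (t < ref.block_start) | (t > ref.block_end)
    if outside.any():
        raise ValueError(
            f"{outside.sum()} spike time(s) outside block bounds "
            f"[{ref.block_start}, {ref.block_end}]: "
            f"{t[outside][:5].tolist()} ...")
    if ref.mode == "ideal":
        frac = np.mod(ref.frequency * (t - ref.block_start), 1.0)
        return PhaseSample(2.0 * np.pi * frac)
    lfp = ref.lfp
    sos = signal.butter(2, [ref.frequency - 1.0, ref.frequency + 1.0],
                        btype="bandpass", fs=lfp.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, lfp.samples)
    inst_phase = np.angle(signal.hilbert(filtered))  # 0 at the peak
    idx = np.clip(np.round(t * lfp.sampling_rate).astype(int), 0, lfp.n_samples - 1)
    return PhaseSample(inst_phase[idx])


@dataclass(frozen=True)
class WindowingScheme:
    """Sliding windows covering one stimulation block."""

    window_length: float
    step: float
    n_windows: int

    def __post_init__(self):
        if self.window_length <= 0 or self.step <= 0 or self.n_windows < 1:
            raise ValueError("window_length, step and n_windows must be positive")

    def span(self) -> float:
        return self.window_length + (self.n_windows - 1) * self.step

    def check_block(self, block_length: float, rtol: float = 1e-6) -> bool:
        """True when the windows exactly tile the block (warning otherwise)."""
        ok = abs(self.span() - block_length) <= rtol * max(block_length, 1.0)
        if not ok:
            import warnings

            warnings.warn(
                f"windowing span {self.span()} does not match block length "
                f"{block_length}", stacklevel=2)
        return ok

    def bounds(self, offset: float = 0.0):
        starts = offset + self.step * np.arange(self.n_windows)
        return starts, starts + self.window_length


@dataclass(frozen=True)
class WindowedPhaseTrack:
    """Per-sliding-window circular summaries for one unit or session."""

    summaries: tuple
    unit_id: str = "unit"
    #: magnitudes for polar-vector tracks; PLV re-used for spike tracks
    magnitudes: tuple | None = None

    @property
    def n_windows(self) -> int:
        return len(self.summaries)

    @property
    def responsive_flags(self) -> np.ndarray:
        return np.array([s.rayleigh_p < 0.05 and s.phase_defined
                         for s in self.summaries])

    @property
    def preferred_phases(self) -> np.ndarray:
        return np.array([s.preferred_phase for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window": np.arange(self.n_windows),
            "plv": [s.plv for s in self.summaries],
            "preferred_phase_deg": self.preferred_phases,
            "rayleigh_p": [s.rayleigh_p for s in self.summaries],
            "n": [s.n for s in self.summaries],
            "responsive": self.responsive_flags,
        })


def window_track(spike_times, phases: PhaseSample, scheme: WindowingScheme,
                 block_starts=(0.0,), block_length: float | None = None,
                 min_spikes: int = 10, unit_id: str = "unit") -> WindowedPhaseTrack:
    """Build a sliding-window phase track, pooling blocks at matched windows.

    ``spike_times``/``phases`` are parallel arrays over all blocks; for
    each window index the spikes falling in that window of *any* block
    are pooled into one phase sample.  Windows with fewer than
    ``min_spikes`` events are marked non-responsive (Rayleigh p forced
    to 1), not an error.
    """
    t = np.asarray(spike_times, dtype=float).ravel()
    ph = phases.phases
    if t.size != ph.size:
        raise ValueError("spike_times and phases must be parallel")
    if block_length is not None:
        scheme.check_block(block_length)
    summaries = []
    for w in range(scheme.n_windows):
        mask = np.zeros(t.size, dtype=bool)
        for b0 in block_starts:
            lo = b0 + scheme.step * w
            hi = lo + scheme.window_length
            mask |= (t >= lo) & (t < hi)
        sub = PhaseSample(ph[mask])
        if sub.n < min_spikes:
            s = summarize(sub)
            summaries.append(CircularSummary(s.plv, s.preferred_phase, 1.0,
                                             s.n, phase_defined=False))
        else:
            summaries.append(summarize(sub))
    return WindowedPhaseTrack(tuple(summaries), unit_id=unit_id)


@dataclass(frozen=True)
class PrecessionClassification:
    label: str
    total_shift: float
    r_circlin: float
    p_circlin: float
    n_responsive_windows: int
    unit_id: str = "unit"


def unwrapped_shift(phases_deg) -> float:
    """Cumulative unwrapped shift from first to last phase, signed degrees.

    Summing successive minimal rotations means a drift through 360 deg is
    not aliased back into (-180, 180].
    """
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size < 2:
        return 0.0
    steps = [angular_difference(a, b)
             for a, b in zip(phases_deg[:-1], phases_deg[1:])]
    return float(np.sum(steps))


def classify_precession(track: WindowedPhaseTrack, min_windows: int = 10,
                        r_threshold: float = 0.5,
                        shift_threshold: float = 15.0) -> PrecessionClassification:
    """Three-step precession framework (see module docstring)."""
    flags = track.responsive_flags
    n_resp = int(flags.sum())
    need = max(min_windows, int(np.ceil(0.5 * track.n_windows)))
    if n_resp < need:
        return PrecessionClassification("non-responsive", 0.0, 0.0, 1.0,
                                        n_resp, track.unit_id)
    idx = np.flatnonzero(flags)
    phases = track.preferred_phases[idx]
    shift = unwrapped_shift(phases)
    try:
        r, p = circ_lin_corr(PhaseSample.from_degrees(phases), idx.astype(float))
    except ValueError:
        # (near-)constant phase track: no drift by definition
        return PrecessionClassification("stable", shift, 0.0, 1.0,
                                        n_resp, track.unit_id)
    if not (r > r_threshold and p < 0.05):
        return PrecessionClassification("non-uniform", shift, r, p,
                                        n_resp, track.unit_id)
    if abs(shift) <= shift_threshold:
        return PrecessionClassification("stable", shift, r, p, n_resp, track.unit_id)
    label = "counter-clockwise" if shift > 0 else "clockwise"
    return PrecessionClassification(label, shift, r, p, n_resp, track.unit_id)


def summarize_population(classifications) -> pd.DataFrame:
    """Counts and arithmetic mean signed shift per label."""
    if not classifications:
        raise ValueError("empty classification list")
    rows = []
    by_label = {}
    for c in classifications:
        by_label.setdefault(c.label, []).append(c.total_shift)
    for label in LABELS:
        shifts = by_label.get(label, [])
        rows.append({
            "label": label,
            "count": len(shifts),
            "mean_shift_deg": float(np.mean(shifts)) if shifts else float("nan"),
        })
    return pd.DataFrame(rows)


def pre_during_post_compare(spike_times, ref: StimulationReference,
                            segments) -> pd.DataFrame:
    """Firing rate and PLV per (name, start, stop) segment.

    Phases are taken against the reference's virtual waveform so the
    comparison is meaningful outside the stimulation span too.
    """
    segs = [(str(n), float(a), float(b)) for n, a, b in segments]
    for i, (_, a, b) in enumerate(segs):
        if b <= a:
            raise ValueError(f"segment {i} has non-positive length")
        for j, (_, a2, b2) in enumerate(segs):
            if i < j and a2 < b and a < b2:
                raise ValueError(f"segments {i} and {j} overlap")
    t = np.asarray(spike_times, dtype=float).ravel()
    rows = []
    for name, a, b in segs:
        sel = t[(t >= a) & (t < b)]
        rate = sel.size / (b - a)
        frac = np.mod(ref.frequency * (sel - ref.block_start), 1.0)
        s = summarize(PhaseSample(2.0 * np.pi * frac))
        rows.append({
            "segment": name, "start_s": a, "stop_s": b, "n_spikes": sel.size,
            "rate_hz": rate, "plv": s.plv,
            "preferred_phase_deg": s.preferred_phase if s.phase_defined else float("nan"),
            "phase_defined": s.phase_defined,
        })
    return pd.DataFrame(rows)
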