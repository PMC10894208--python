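"""Seeded synthetic-data generators.

Each generator emulates the statistical structure its downstream
analysis assumes — von Mises spike phases with an optional linear phase
drift, extracellular traces with injected templates plus a sinusoidal
artifact, and phase-tuned MEP trial tables — and returns the ground
truth next to the data, so every pipeline test consumes (data, truth)
pairs.  Rate and phase are generated independently: precession in the
generator never changes the firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mep import MEPSeries, PHASE_LABELS
from .preproc import ContinuousRecording

__all__ = [
    "SpikeGenSpec",
    "MEPGenSpec",
    "gen_spike_train",
    "gen_extracellular_trace",
    "gen_mep_series",
    "biphasic_template",
]


@dataclass(frozen=True)
class SpikeGenSpec:
    """Spike train with von Mises phases drifting linearly in time.

    ``drift`` is the total preferred-phase change (degrees) over the
    whole duration: mu(t) = mu0 + drift * t / duration.  kappa = 0 gives
    uniform phases; negative drift is clockwise.
    """

    duration: float = 360.0
    rate: float = 5.0
    kappa: float = 2.0
    mu0: float = 90.0
    drift: float = 0.0
    stim_frequency: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.duration <= 0 or self.stim_frequency <= 0:
            raise ValueError("duration and stim_frequency must be positive")

    def mu_at(self, t):
        return self.mu0 + self.drift * np.asarray(t, dtype=float) / self.duration


def gen_spike_train(spec: SpikeGenSpec) -> tuple[np.ndarray, dict]:
    """Generate spike times whose stimulation phases are von Mises.

    A homogeneous Poisson count of spikes is scattered over the
    duration; each spike keeps its cycle but its within-cycle position
    is redrawn from von Mises(mu(t), kappa), so the phase against an
    ideal reference at ``stim_frequency`` follows the planted law while
    the rate stays homogeneous.
    """
    rng = np.random.default_rng(spec.seed)
    n = rng.poisson(spec.rate * spec.duration)
    t0 = np.sort(rng.uniform(0.0, spec.duration, size=n))
    mu = np.deg2rad(spec.mu_at(t0))
    if spec.kappa == 0:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        theta = np.mod(rng.vonmises(mu, spec.kappa, size=n), 2.0 * np.pi)
    cycle = np.floor(t0 * spec.stim_frequency)
    times = (cycle + theta / (2.0 * np.pi)) / spec.stim_frequency
    times = np.sort(times[(times >= 0) & (times < spec.duration)])
    truth = dict(asdict(spec), kind="spike_train", n_spikes=times.size)
    return times, truth


def biphasic_template(n_samples: int = 32, peak_index: int = 8,
                      amplitude: float = 1.0) -> np.ndarray:
    """A simple biphasic extracellular spike template, negative main peak."""
    t = np.arange(n_samples, dtype=float) - peak_index
    wave = -np.exp(-0.5 * (t / 2.0) ** 2) + 0.45 * np.exp(-0.5 * ((t - 6.0) / 4.0) ** 2)
    wave /= np.max(np.abs(wave))
    return amplitude * wave


def gen_extracellular_trace(template: np.ndarray | None = None,
                            n_spikes: int = 40,
                            noise_sigma: float = 1.0,
                            artifact_amplitude: float = 0.0,
                            artifact_frequency: float = 10.0,
                            duration: float = 10.0,
                            sampling_rate: float = 30000.0,
                            min_gap_s: float = 0.003,
                            seed: int = 0) -> tuple[ContinuousRecording, dict]:
    """Gaussian noise + placed spike templates + optional sinusoid artifact."""
    rng = np.random.default_rng(seed)
    if template is None:
        template = biphasic_template(amplitude=8.0 * noise_sigma)
    template = np.asarray(template, dtype=float)
    n_samp = int(round(duration * sampling_rate))
    if template.size > n_samp:
        raise ValueError("template longer than trace")
    gap = int(round(min_gap_s * sampling_rate)) + template.size
    if n_spikes * gap > n_samp - 2 * template.size:
        raise ValueError("infeasible placement density")
    # draw sorted insertion points with the minimal gap enforced
    slack = n_samp - 2 * template.size - n_spikes * gap
    offsets = np.sort(rng.uniform(0, slack, size=n_spikes))
    starts = (template.size + offsets + gap * np.arange(n_spikes)).astype(int)
    x = rng.normal(0.0, noise_sigma, size=n_samp)
    for s in starts:
        x[s:s + template.size] += template
    if artifact_amplitude > 0:
        t = np.arange(n_samp) / sampling_rate
        x += artifact_amplitude * np.sin(2.0 * np.pi * artifact_frequency * t)
    peak_offset = int(np.argmax(np.abs(template)))
    truth = {
        "kind": "extracellular_trace",
        "true_spike_times_s": ((starts + peak_offset) / sampling_rate).tolist(),
        "noise_sigma": noise_sigma,
        "artifact_amplitude": artifact_amplitude,
        "artifact_frequency": artifact_frequency,
        "sampling_rate_hz": sampling_rate,
        "seed": seed,
    }
    return ContinuousRecording(x, sampling_rate, "synthetic"), truth


@dataclass(frozen=True)
class MEPGenSpec:
    """Phase-tuned MEP series with drifting preferred phase.

    amplitude_i = base * (1 + depth*cos(phi_i - mu(t_i)))
                  * lognormal(cv) * (1 + trend * frac_within_block).
    The preferred phase drifts linearly from mu_start to mu_end within
    each block (phase resets between blocks); labels cycle over
    0/90/180/270 so trials are allocated evenly over the four phases.
    """

    n_blocks: int = 4
    trials_per_block: int = 150
    modulation_depth: float = 0.07
    mu_start: float = 90.0
    mu_end: float = 180.0
    amplitude_cv: float = 0.25
    trend_slope: float = 0.0       # fractional amplitude gain over one block
    base_amplitude: float = 1.0    # mV
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation_depth must be in [0, 1)")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")

    def mu_within_block(self, frac):
        return self.mu_start + (self.mu_end - self.mu_start) * np.asarray(frac, float)


def gen_mep_series(spec: MEPGenSpec) -> tuple[MEPSeries, dict]:
    rng = np.random.default_rng(spec.seed)
    n = spec.trials_per_block
    sigma_ln = np.sqrt(np.log1p(spec.amplitude_cv ** 2))
    rows = []
    for b in range(spec.n_blocks):
        within = np.arange(n)
        frac = within / max(n - 1, 1)
        mu = spec.mu_within_block(frac)
        # cycle the four phase labels in a per-block shuffled repeating order
        labels = np.array([PHASE_LABELS[i % 4] for i in rng.permutation(n)])
        mod = 1.0 + spec.modulation_depth * np.cos(np.deg2rad(labels - mu))
        noise = np.exp(rng.normal(-0.5 * sigma_ln ** 2, sigma_ln, size=n))
        amp = spec.base_amplitude * mod * noise * (1.0 + spec.trend_slope * frac)
        for i in range(n):
            rows.append({
                "trial_index": b * n + i,
                "block": b,
                "phase_deg": int(labels[i]),
                "amplitude_mv": float(amp[i]),
            })
    df = pd.DataFrame(rows)
    truth = dict(asdict(spec), kind="mep_series")
    return MEPSeries(df), truth
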