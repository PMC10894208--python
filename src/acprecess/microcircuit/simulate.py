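"""Run microcircuit simulations, field coupling, sweeps and reports."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..circular import PhaseSample, CircularSummary, summarize
from . import channels
from .config import (
    CircuitConfig,
    FieldSpec,
    NEURON_NAMES,
    build_default_circuit,
)
from .engine import integrate, dual_exp_peak_norm

__all__ = [
    "SimulationResult",
    "simulate",
    "apply_extracellular_field",
    "stimulation_phase",
    "nmda_weight_sweep",
    "weight_sweep",
    "entrainment_report",
]

MAX_RATE_HZ = 200.0  # spike-buffer headroom per neuron


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationResult:
    """Spike output (and optional voltages) of one microcircuit run."""

    spike_times: dict                # neuron -> seconds
    t_on: float
    t_off: float
    field: FieldSpec
    config_echo: dict
    seed: int
    voltages: dict | None = None     # neuron -> (2, n_rec) mV
    v_times: np.ndarray | None = None

    def rate(self, neuron: str, t_start: float, t_stop: float) -> float:
        t = self.spike_times[neuron]
        return float(np.sum((t >= t_start) & (t < t_stop)) / (t_stop - t_start))

    def spikes_to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("neuron,time_s\n")
            for name in NEURON_NAMES:
                for t in self.spike_times[name]:
                    fh.write(f"{name},{t:.6f}\n")


def stimulation_phase(field: FieldSpec, times) -> PhaseSample:
    """Phase of the stimulation waveform (0 deg = field peak) at given
    times; outside the stimulation span the same virtual waveform
    extends in both directions."""
    t = np.asarray(times, dtype=float)
    frac = np.mod(field.frequency * (t - field.t_on), 1.0)
    return PhaseSample(2.0 * np.pi * frac)


def apply_extracellular_field(config: CircuitConfig, field: FieldSpec, t):
    """Extracellular potential V_e = -E(t).r per neuron compartment (mV).

    Returns {neuron: (V_e_soma, V_e_dendrite)} with each entry an array
    over ``t`` (seconds).  E(t) = amplitude * envelope(t) *
    cos(2*pi*f*(t - t_on)) * direction; the envelope ramps linearly at
    onset and offset.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    env = np.zeros_like(t)
    inside = (t >= field.t_on) & (t < field.t_off)
    if field.ramp > 0:
        up = (t - field.t_on) / field.ramp
        down = (field.t_off - t) / field.ramp
        env[inside] = np.clip(np.minimum(up, down), 0.0, 1.0)[inside]
    else:
        env[inside] = 1.0
    e_scal = field.amplitude_vm * env * np.cos(
        2.0 * np.pi * field.frequency * (t - field.t_on))
    direction = np.asarray(field.direction, dtype=float)
    out = {}
    for name, spec in config.neurons.items():
        r_soma = np.asarray(spec.position, dtype=float)
        r_dend = r_soma + np.asarray(spec.axis, dtype=float) * spec.axis_length_um
        # um * V/m = 1e-3 mV
        ve_soma = -e_scal * np.dot(direction, r_soma) * 1e-3
        ve_dend = -e_scal * np.dot(direction, r_dend) * 1e-3
        out[name] = (ve_soma, ve_dend)
    return out


def _pack(config: CircuitConfig, field: FieldSpec, seed: int):
    """Translate the configuration into the kernel's flat arrays."""
    n = len(NEURON_NAMES)
    shape = (n, 2)
    area = np.empty(shape); cm = np.empty(shape)
    g_leak = np.empty(shape); e_leak = np.empty(shape)
    g_na = np.empty(shape); g_kv = np.empty(shape); g_km = np.empty(shape)
    g_ca = np.empty(shape); g_kca = np.empty(shape)
    v_t = np.empty(n); gc_us = np.empty(n); dve_coeff = np.empty(n)
    direction = np.asarray(field.direction, dtype=float)
    for i, name in enumerate(NEURON_NAMES):
        spec = config.neurons[name]
        for c, comp in enumerate((spec.soma, spec.dendrite)):
            area[i, c] = comp.area_cm2
            cm[i, c] = comp.cm
            g_leak[i, c] = comp.g_leak
            e_leak[i, c] = comp.e_leak
            g_na[i, c] = comp.g_na
            g_kv[i, c] = comp.g_kv
            g_km[i, c] = comp.g_km
            g_ca[i, c] = comp.g_ca
            g_kca[i, c] = comp.g_kca
        v_t[i] = spec.v_t
        gc_us[i] = spec.coupling_us
        # dVe = V_e(dend) - V_e(soma) = -E . axis * L; coefficient per
        # unit field scalar (V/m -> mV across the axis)
        dve_coeff[i] = -float(np.dot(direction, np.asarray(spec.axis, float))) \
            * spec.axis_length_um * 1e-3

    dt = config.dt_ms
    idx = {name: i for i, name in enumerate(NEURON_NAMES)}
    syn_src, syn_tgt, syn_comp, syn_e, syn_nmda = [], [], [], [], []
    dec_r, dec_d, inc_amp, delay_steps = [], [], [], []

    def add_syn(src, tgt, comp, e, nmda, tau1, tau2, w, delay_ms):
        syn_src.append(src)
        syn_tgt.append(tgt)
        syn_comp.append(comp)
        syn_e.append(e)
        syn_nmda.append(1 if (nmda and config.mg_block_enabled) else 0)
        dec_r.append(np.exp(-dt / tau1))
        dec_d.append(np.exp(-dt / tau2))
        inc_amp.append(w / dual_exp_peak_norm(tau1, tau2))
        delay_steps.append(max(int(round(delay_ms / dt)), 1))

    pois_syn_ids = []
    for p in config.poisson_inputs:
        pois_syn_ids.append(len(syn_src))
        add_syn(-1, idx[p.target], 1, p.e_syn, False, p.tau1, p.tau2,
                p.weight_us, 0.0)
    for cdef in config.connections:
        s = cdef.synapse
        add_syn(idx[cdef.source], idx[cdef.target],
                0 if s.target_compartment == "soma" else 1,
                s.e_syn, s.receptor == "NMDA", s.tau1, s.tau2,
                s.weight_us, s.delay_ms)

    n_syn = len(syn_src)
    out_lists = [[] for _ in range(n)]
    for s in range(n_syn):
        if syn_src[s] >= 0:
            out_lists[syn_src[s]].append(s)
    out_start = np.zeros(n + 1, dtype=np.int64)
    out_syn = []
    for i in range(n):
        out_start[i + 1] = out_start[i] + len(out_lists[i])
        out_syn.extend(out_lists[i])

    total_s = config.duration_baseline_s + config.duration_stim_s
    n_steps = int(round(total_s * 1000.0 / dt))

    # Poisson background events, one independent child stream per input
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.poisson_inputs))
    ev_steps, ev_syn = [], []
    for p, child, sid in zip(config.poisson_inputs, children, pois_syn_ids):
        if p.rate_hz <= 0:
            continue
        rng = np.random.default_rng(child)
        t_acc, times = 0.0, []
        mean_gap = 1.0 / p.rate_hz
        block = max(int(p.rate_hz * total_s * 1.1) + 100, 100)
        while t_acc < total_s:
            gaps = rng.exponential(mean_gap, size=block)
            cum = t_acc + np.cumsum(gaps)
            times.append(cum)
            t_acc = cum[-1]
        times = np.concatenate(times)
        times = times[times < total_s]
        steps = np.floor(times * 1000.0 / dt).astype(np.int64)
        ev_steps.append(steps)
        ev_syn.append(np.full(steps.size, sid, dtype=np.int64))
    if ev_steps:
        ev_steps = np.concatenate(ev_steps)
        ev_syn = np.concatenate(ev_syn)
        order = np.argsort(ev_steps, kind="stable")
        ev_steps, ev_syn = ev_steps[order], ev_syn[order]
    else:
        ev_steps = np.empty(0, dtype=np.int64)
        ev_syn = np.empty(0, dtype=np.int64)

    packed = dict(
        n_steps=n_steps, dt=dt,
        area=area, cm=cm, g_leak=g_leak, e_leak=e_leak,
        g_na=g_na, g_kv=g_kv, g_km=g_km, g_ca=g_ca, g_kca=g_kca,
        v_t=v_t, gc_us=gc_us, dve_coeff=dve_coeff,
        syn_src=np.asarray(syn_src, dtype=np.int64),
        syn_tgt=np.asarray(syn_tgt, dtype=np.int64),
        syn_comp=np.asarray(syn_comp, dtype=np.int64),
        syn_e=np.asarray(syn_e, dtype=float),
        syn_is_nmda=np.asarray(syn_nmda, dtype=np.int64),
        dec_r=np.asarray(dec_r, dtype=float),
        dec_d=np.asarray(dec_d, dtype=float),
        inc_amp=np.asarray(inc_amp, dtype=float),
        delay_steps=np.asarray(delay_steps, dtype=np.int64),
        out_start=out_start, out_syn=np.asarray(out_syn, dtype=np.int64),
        pois_steps=ev_steps, pois_syn=ev_syn,
    )
    return packed, n_steps


def simulate(config: CircuitConfig, field: FieldSpec | None = None,
             record_voltage: bool = False, record_dt_ms: float = 1.0,
             v_init: float = -70.0) -> SimulationResult:
    """Integrate the microcircuit; deterministic given (config, field, seed).

    The field turns on after the baseline period: t_on is forced to
    ``duration_baseline_s`` and t_off to the end of the simulation.
    """
    if field is None:
        field = FieldSpec(amplitude_vm=0.0, frequency=10.0)
    t_on = config.duration_baseline_s
    t_off = config.duration_baseline_s + config.duration_stim_s
    field = dataclasses.replace(field, t_on=t_on, t_off=t_off)

    packed, n_steps = _pack(config, field, config.seed)
    dt = config.dt_ms
    max_spikes = int(MAX_RATE_HZ * (n_steps * dt / 1000.0)) + 100
    spike_steps = np.zeros((3, max_spikes), dtype=np.int64)
    spike_counts = np.zeros(3, dtype=np.int64)
    if record_voltage:
        rec_stride = max(int(round(record_dt_ms / dt)), 1)
        n_rec = (n_steps - 1) // rec_stride + 1
    else:
        rec_stride = 0
        n_rec = 1
    v_rec = np.zeros((3, 2, n_rec))

    status = integrate(
        packed["n_steps"], packed["dt"],
        packed["area"], packed["cm"], packed["g_leak"], packed["e_leak"],
        packed["g_na"], packed["g_kv"], packed["g_km"], packed["g_ca"],
        packed["g_kca"], packed["v_t"], packed["gc_us"], packed["dve_coeff"],
        channels.E_NA, channels.E_K, channels.E_CA,
        channels.ALPHA_CA, channels.CA_REST, channels.TAU_CA,
        channels.KD_KCA, channels.MG_CONC, channels.TAU_MAX_M,
        field.amplitude_vm, field.frequency * 1e-3,
        field.t_on * 1000.0, field.t_off * 1000.0, field.ramp * 1000.0,
        packed["syn_src"], packed["syn_tgt"], packed["syn_comp"],
        packed["syn_e"], packed["syn_is_nmda"],
        packed["dec_r"], packed["dec_d"], packed["inc_amp"],
        packed["delay_steps"], packed["out_start"], packed["out_syn"],
        packed["pois_steps"], packed["pois_syn"],
        spike_steps, spike_counts, v_rec, rec_stride, v_init)
    if status >= 0:
        raise DivergenceError(
            f"membrane potential diverged (|V| > {200} mV) at "
            f"t = {status * dt / 1000.0:.4f} s")

    spikes = {}
    for i, name in enumerate(NEURON_NAMES):
        k = min(int(spike_counts[i]), max_spikes)
        spikes[name] = spike_steps[i, :k] * dt / 1000.0
    voltages = None
    v_times = None
    if record_voltage:
        voltages = {name: v_rec[i] for i, name in enumerate(NEURON_NAMES)}
        v_times = np.arange(n_rec) * rec_stride * dt / 1000.0
    return SimulationResult(spike_times=spikes, t_on=t_on, t_off=t_off,
                            field=field, config_echo=config.to_dict(),
                            seed=config.seed, voltages=voltages, v_times=v_times)


def _stim_phase_summary(result: SimulationResult, exclude_ramp: bool = True
                        ) -> CircularSummary:
    """Circular summary of BA4_PY spike phases over the stimulation span."""
    return phase_summary(result, "BA4_PY", exclude_ramp=exclude_ramp)


def phase_summary(result: SimulationResult, neuron: str,
                  exclude_ramp: bool = True) -> CircularSummary:
    t = result.spike_times[neuron]
    lo = result.t_on + (result.field.ramp if exclude_ramp else 0.0)
    hi = result.t_off - (result.field.ramp if exclude_ramp else 0.0)
    sel = t[(t >= lo) & (t < hi)]
    return summarize(stimulation_phase(result.field, sel))


def weight_sweep(config: CircuitConfig, field: FieldSpec,
                 source: str, target: str, receptor: str,
                 n_trials: int = 20, increment: float = 1.0,
                 independent_trials: bool = False) -> pd.DataFrame:
    """Systematically scale one synaptic weight over trials.

    Trial k (k = 0..n_trials-1) uses weight w0 * (1 + k * increment)
    while all other parameters stay unchanged.  By default every trial
    re-uses the same Poisson realization, isolating the weight effect;
    with ``independent_trials`` each trial gets its own stream.
    Returns one row per trial with the weight, BA4_PY firing rate during
    stimulation, PLV and preferred phase.
    """
    if n_trials < 2:
        raise ValueError("sweep needs at least 2 trials")
    w0 = config.get_weight(source, target, receptor)
    rows = []
    for k in range(n_trials):
        w = w0 * (1.0 + k * increment)
        if w < 0:
            raise ValueError(f"trial {k} weight {w} is negative")
        cfg = config.replace_weight(source, target, receptor, w)
        if independent_trials:
            cfg = dataclasses.replace(cfg, seed=(config.seed + 7919 * (k + 1)) % (2 ** 31))
        res = simulate(cfg, field)
        s = _stim_phase_summary(res)
        dur = res.t_off - res.t_on
        rows.append({
            "trial": k + 1,
            "weight_us": w,
            "rate_hz": res.rate("BA4_PY", res.t_on, res.t_off),
            "plv": s.plv,
            "preferred_phase_deg": s.preferred_phase if s.phase_defined else np.nan,
            "n_spikes": s.n,
            "phase_defined": s.phase_defined,
        })
    return pd.DataFrame(rows)


def nmda_weight_sweep(config: CircuitConfig, field: FieldSpec,
                      n_trials: int = 20, increment: float = 1.0,
                      independent_trials: bool = False) -> pd.DataFrame:
    """Plasticity sweep over the BA6->BA4 NMDA weight (see weight_sweep)."""
    return weight_sweep(config, field, "BA6_PY", "BA4_PY", "NMDA",
                        n_trials=n_trials, increment=increment,
                        independent_trials=independent_trials)


def entrainment_report(result: SimulationResult) -> pd.DataFrame:
    """Per-neuron firing rate and phase locking, baseline vs stimulation.

    Baseline phases are taken against the virtual waveform extending the
    stimulation reference backwards in time.
    """
    if result.t_on <= 0 or result.t_off <= result.t_on:
        raise ValueError("need non-empty baseline and stimulation spans")
    rows = []
    for name in NEURON_NAMES:
        t = result.spike_times[name]
        for span, lo, hi in (("baseline", 0.0, result.t_on),
                             ("stimulation", result.t_on + result.field.ramp,
                              result.t_off - result.field.ramp)):
            sel = t[(t >= lo) & (t < hi)]
            s = summarize(stimulation_phase(result.field, sel))
            rows.append({
                "neuron": name, "span": span,
                "rate_hz": sel.size / (hi - lo),
                "plv": s.plv,
                "preferred_phase_deg": s.preferred_phase if s.phase_defined else np.nan,
                "n_spikes": sel.size,
            })
    return pd.DataFrame(rows)
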