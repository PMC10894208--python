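"""Configuration objects for the 3-neuron cortical microcircuit.

The circuit holds a premotor pyramidal cell (BA6_PY), a primary-motor
pyramidal cell (BA4_PY) and a fast-spiking interneuron (IN).  BA6_PY's
somatodendritic axis is anti-parallel to BA4_PY's and IN's, mimicking
the opposing banks of the precentral gyrus, so a uniform field along the
axis polarizes the two pyramidal cells with opposite sign at every
instant.  Connectivity: BA6->BA4 (AMPA + NMDA, 2 ms delay), BA6->IN
(AMPA + NMDA, 2 ms delay), BA4->IN (AMPA, short local delay) and
IN->BA4 (GABA_A, short local delay).  Excitatory synapses target the
dendrite, the inhibitory synapse targets the soma.  Every neuron
receives an excitatory Poisson background synapse (E = 0 mV, rise 2 ms,
decay 10 ms) whose rate and weight set the baseline firing rate:
condition "alpha" tunes the pyramidal cells to ~10 spikes/s, "beta" to
~17 spikes/s (with the BA6->IN NMDA weight reduced to keep the
interneuron rate comparable across conditions).

All morphology and weight constants here are package defaults chosen to
satisfy those behavioral targets; they are fully exposed through this
module and echoed next to every simulation result.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CompartmentSpec",
    "NeuronSpec",
    "SynapseSpec",
    "Connection",
    "PoissonInput",
    "FieldSpec",
    "CircuitConfig",
    "build_default_circuit",
    "NEURON_NAMES",
]

NEURON_NAMES = ("BA6_PY", "BA4_PY", "IN")

EXCITATORY = ("AMPA", "NMDA")


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry and maximal conductances of one cylindrical compartment.

    Conductances in mS/cm^2; geometry in um; capacitance in uF/cm^2.
    """

    name: str
    length_um: float
    diameter_um: float
    cm: float = 1.0
    g_leak: float = 0.1
    e_leak: float = -70.0
    g_na: float = 0.0
    g_kv: float = 0.0
    g_km: float = 0.0
    g_ca: float = 0.0
    g_kca: float = 0.0

    def __post_init__(self):
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("compartment geometry must be positive")
        for g in (self.g_leak, self.g_na, self.g_kv, self.g_km, self.g_ca, self.g_kca):
            if g < 0:
                raise ValueError("conductances must be non-negative")

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder surface area."""
        return np.pi * self.length_um * self.diameter_um * 1e-8


@dataclass(frozen=True)
class NeuronSpec:
    """Two-compartment neuron: soma + dendrite joined by a lumped axial
    conductance, with a somatodendritic axis for field coupling."""

    name: str
    soma: CompartmentSpec
    dendrite: CompartmentSpec
    coupling_us: float            # soma-dendrite axial conductance, uS
    v_t: float = -55.0            # spike-threshold shift of Na/Kv kinetics
    axis: tuple = (1.0, 0.0, 0.0)  # unit vector, soma -> dendrite
    axis_length_um: float = 500.0
    position: tuple = (0.0, 0.0, 0.0)  # soma coordinates, um

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("somatodendritic axis must be a unit vector")
        if self.coupling_us <= 0:
            raise ValueError("axial coupling must be positive")

    @property
    def is_interneuron(self) -> bool:
        return self.soma.g_km == 0 and self.soma.g_ca == 0 and self.soma.g_kca == 0


@dataclass(frozen=True)
class SynapseSpec:
    """Dual-exponential conductance synapse.

    ``tau1`` is the rise and ``tau2`` the decay time constant (ms); the
    conductance transient is normalized so its peak equals ``weight_us``.
    """

    receptor: str                  # AMPA | NMDA | GABA_A
    e_syn: float                   # mV
    tau1: float                    # ms (rise)
    tau2: float                    # ms (decay)
    weight_us: float               # uS
    delay_ms: float = 0.0
    target_compartment: str = "dendrite"

    def __post_init__(self):
        if self.tau1 == self.tau2:
            raise ValueError("dual-exponential requires tau1 != tau2")
        if self.weight_us < 0:
            raise ValueError("synaptic weight must be non-negative")
        if self.receptor in EXCITATORY and self.target_compartment != "dendrite":
            raise ValueError("excitatory synapses target the dendrite")
        if self.receptor == "GABA_A" and self.target_compartment != "soma":
            raise ValueError("the inhibitory synapse targets the soma")


@dataclass(frozen=True)
class Connection:
    source: str
    target: str
    synapse: SynapseSpec


@dataclass(frozen=True)
class PoissonInput:
    target: str
    rate_hz: float
    weight_us: float
    e_syn: float = 0.0
    tau1: float = 2.0
    tau2: float = 10.0


@dataclass(frozen=True)
class FieldSpec:
    """Uniform sinusoidal extracellular field.

    Temporal waveform amplitude * envelope(t) * cos(2*pi*f*(t - t_on))
    along ``direction``; the envelope ramps linearly over ``ramp``
    seconds after t_on and before t_off.  Phase 0 deg is the field peak
    in the BA4-depolarizing (posterior-anterior) direction.
    """

    amplitude_vm: float = 3.0
    frequency: float = 10.0
    direction: tuple = (1.0, 0.0, 0.0)
    t_on: float = 0.0
    t_off: float = 0.0
    ramp: float = 10.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValueError("field direction must be a unit vector")
        if self.amplitude_vm < 0:
            raise ValueError("field amplitude must be non-negative")


@dataclass(frozen=True)
class CircuitConfig:
    neurons: dict
    connections: tuple
    poisson_inputs: tuple
    dt_ms: float = 0.025
    duration_baseline_s: float = 360.0
    duration_stim_s: float = 360.0
    seed: int = 0
    mg_block_enabled: bool = True
    condition: str = "alpha"

    def __post_init__(self):
        if set(self.neurons) != set(NEURON_NAMES):
            raise ValueError(f"neurons must be exactly {NEURON_NAMES}")
        if self.dt_ms > 0.05:
            raise ValueError("dt must be <= 0.05 ms")
        for c in self.connections:
            if c.source not in self.neurons or c.target not in self.neurons:
                raise ValueError(f"unknown neuron in connection {c.source}->{c.target}")

    def replace_weight(self, source: str, target: str, receptor: str,
                       weight_us: float) -> "CircuitConfig":
        """Return a config with one synaptic weight replaced."""
        if weight_us < 0:
            raise ValueError("synaptic weight must be non-negative")
        out, hit = [], False
        for c in self.connections:
            if c.source == source and c.target == target and c.synapse.receptor == receptor:
                out.append(Connection(c.source, c.target,
                                      dataclasses.replace(c.synapse, weight_us=weight_us)))
                hit = True
            else:
                out.append(c)
        if not hit:
            raise KeyError(f"no {receptor} connection {source}->{target}")
        return dataclasses.replace(self, connections=tuple(out))

    def get_weight(self, source: str, target: str, receptor: str) -> float:
        for c in self.connections:
            if c.source == source and c.target == target and c.synapse.receptor == receptor:
                return c.synapse.weight_us
        raise KeyError(f"no {receptor} connection {source}->{target}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def _py(name: str, axis, position) -> NeuronSpec:
    soma = CompartmentSpec("soma", length_um=30.0, diameter_um=30.0, cm=1.5,
                           g_leak=0.07, e_leak=-70.0,
                           g_na=50.0, g_kv=5.0, g_km=0.15, g_ca=0.08, g_kca=0.25)
    dend = CompartmentSpec("dendrite", length_um=500.0, diameter_um=3.0, cm=1.5,
                           g_leak=0.03, e_leak=-70.0)
    return NeuronSpec(name, soma, dend, coupling_us=0.008, v_t=-55.0,
                      axis=axis, axis_length_um=500.0, position=position)


def _in(name: str, axis, position) -> NeuronSpec:
    soma = CompartmentSpec("soma", length_um=25.0, diameter_um=25.0, cm=1.0,
                           g_leak=0.15, e_leak=-65.0, g_na=50.0, g_kv=10.0)
    dend = CompartmentSpec("dendrite", length_um=300.0, diameter_um=2.0, cm=1.0,
                           g_leak=0.05, e_leak=-65.0)
    return NeuronSpec(name, soma, dend, coupling_us=0.005, v_t=-55.0,
                      axis=axis, axis_length_um=300.0, position=position)


# synaptic kinetics defaults (ms); decay constants chosen within the
# standard ranges for cortical AMPA / NMDA / GABA_A receptors
AMPA_TAUS = (0.5, 5.0)
NMDA_TAUS = (2.0, 26.0)
GABA_TAUS = (0.5, 15.0)

# default connection weights (uS) per condition; the BA6->BA4 NMDA
# weight is the base value w0 of the plasticity sweep
DEFAULT_WEIGHTS = {
    "alpha": {
        "poisson_rate": 5000.0,
        "poisson_weight_ba6": 3.66e-5, "poisson_weight_ba4": 4.6e-5,
        "ba6_ba4_ampa": 0.0008, "ba6_ba4_nmda": 0.0003,
        "ba6_in_ampa": 0.0005, "ba6_in_nmda": 0.004,
        "ba4_in_ampa": 0.0008, "in_ba4_gaba": 0.005,
        "poisson_rate_in": 300.0, "poisson_weight_in": 0.00025,
    },
    "beta": {
        "poisson_rate": 5000.0,
        "poisson_weight_ba6": 4.5e-5, "poisson_weight_ba4": 6.1e-5,
        "ba6_ba4_ampa": 0.0008, "ba6_ba4_nmda": 0.0003,
        "ba6_in_ampa": 0.0005, "ba6_in_nmda": 0.002,
        "ba4_in_ampa": 0.0008, "in_ba4_gaba": 0.005,
        "poisson_rate_in": 300.0, "poisson_weight_in": 0.00025,
    },
}


def build_default_circuit(condition: str = "alpha", seed: int = 0,
                          duration_baseline_s: float = 360.0,
                          duration_stim_s: float = 360.0) -> CircuitConfig:
    """Fully parameterized default microcircuit for one condition.

    ``alpha`` tunes the pyramidal Poisson drive for ~10 spikes/s
    baseline firing, ``beta`` for ~17 spikes/s with a reduced BA6->IN
    NMDA weight so the interneuron rate stays comparable.
    """
    if condition not in DEFAULT_WEIGHTS:
        raise ValueError(f"condition must be 'alpha' or 'beta', got {condition!r}")
    w = DEFAULT_WEIGHTS[condition]
    neurons = {
        "BA6_PY": _py("BA6_PY", axis=(1.0, 0.0, 0.0), position=(0.0, 0.0, 0.0)),
        "BA4_PY": _py("BA4_PY", axis=(-1.0, 0.0, 0.0), position=(1000.0, 0.0, 0.0)),
        "IN": _in("IN", axis=(-1.0, 0.0, 0.0), position=(1000.0, 200.0, 0.0)),
    }
    conns = (
        Connection("BA6_PY", "BA4_PY",
                   SynapseSpec("AMPA", 0.0, *AMPA_TAUS, w["ba6_ba4_ampa"], 2.0)),
        Connection("BA6_PY", "BA4_PY",
                   SynapseSpec("NMDA", 0.0, *NMDA_TAUS, w["ba6_ba4_nmda"], 2.0)),
        Connection("BA6_PY", "IN",
                   SynapseSpec("AMPA", 0.0, *AMPA_TAUS, w["ba6_in_ampa"], 2.0)),
        Connection("BA6_PY", "IN",
                   SynapseSpec("NMDA", 0.0, *NMDA_TAUS, w["ba6_in_nmda"], 2.0)),
        Connection("BA4_PY", "IN",
                   SynapseSpec("AMPA", 0.0, *AMPA_TAUS, w["ba4_in_ampa"], 1.0)),
        Connection("IN", "BA4_PY",
                   SynapseSpec("GABA_A", -80.0, *GABA_TAUS, w["in_ba4_gaba"], 1.0,
                               target_compartment="soma")),
    )
    pois = (
        PoissonInput("BA6_PY", w["poisson_rate"], w["poisson_weight_ba6"]),
        PoissonInput("BA4_PY", w["poisson_rate"], w["poisson_weight_ba4"]),
        PoissonInput("IN", w["poisson_rate_in"], w["poisson_weight_in"]),
    )
    return CircuitConfig(neurons=neurons, connections=conns, poisson_inputs=pois,
                         seed=seed, condition=condition,
                         duration_baseline_s=duration_baseline_s,
                         duration_stim_s=duration_stim_s)
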