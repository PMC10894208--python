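"""Microcircuit simulator: determinism, passive oracle, field coupling."""

import dataclasses

import numpy as np
import pytest

from acprecess.microcircuit import (
    CircuitConfig,
    FieldSpec,
    SynapseSpec,
    apply_extracellular_field,
    build_default_circuit,
    entrainment_report,
    simulate,
    stimulation_phase,
)


def passive_config(duration_s=6.0):
    """Default circuit with all active conductances and inputs removed."""
    cfg = build_default_circuit("alpha", seed=0, duration_baseline_s=0.0,
                                duration_stim_s=duration_s)
    neurons = {}
    for name, spec in cfg.neurons.items():
        soma = dataclasses.replace(spec.soma, g_na=0.0, g_kv=0.0, g_km=0.0,
                                   g_ca=0.0, g_kca=0.0)
        dend = dataclasses.replace(spec.dendrite, g_na=0.0, g_kv=0.0)
        neurons[name] = dataclasses.replace(spec, soma=soma, dendrite=dend)
    pois = tuple(dataclasses.replace(p, rate_hz=0.0) for p in cfg.poisson_inputs)
    conns = tuple(
        dataclasses.replace(c, synapse=dataclasses.replace(c.synapse, weight_us=0.0))
        for c in cfg.connections)
    return dataclasses.replace(cfg, neurons=neurons, poisson_inputs=pois,
                               connections=conns)


def lock_in(times, x, freq, t_start, t_stop=5.4):
    """Amplitude and phase of the ``freq`` component of x(t) (cos reference)."""
    sel = (times >= t_start) & (times <= t_stop)
    t, x = times[sel], x[sel]
    x = x - x.mean()
    n_cyc = int(np.floor((t[-1] - t[0]) * freq))
    keep = t < t[0] + n_cyc / freq
    t, x = t[keep], x[keep]
    c = 2 * np.mean(x * np.cos(2 * np.pi * freq * t))
    s = 2 * np.mean(x * np.sin(2 * np.pi * freq * t))
    return np.hypot(c, s), np.arctan2(-s, c)


def analytic_two_compartment(spec, field_amp, freq):
    """Closed-form phasor response of the passive soma to a uniform field."""
    area_s, area_d = spec.soma.area_cm2, spec.dendrite.area_cm2
    cs = spec.soma.cm * area_s * 1e3          # nF... work in mS/ms units: uF
    cd = spec.dendrite.cm * area_d * 1e3
    gs = spec.soma.g_leak * area_s * 1e3      # mS -> with uF, time in ms
    gd = spec.dendrite.g_leak * area_d * 1e3
    gc = spec.coupling_us * 1e-3 * 1e3
    omega = 2 * np.pi * freq * 1e-3           # rad/ms
    dve = -1.0 * spec.axis_length_um * 1e-3 * field_amp * np.dot(
        (1.0, 0.0, 0.0), np.asarray(spec.axis))
    a = 1j * omega * cs + gs + gc
    b = 1j * omega * cd + gd + gc
    # a Vs - gc Vd = gc dVe ; b Vd - gc Vs = -gc dVe
    vs = (gc * dve * b - gc * gc * dve) / (a * b - gc * gc)
    return abs(vs), np.angle(vs)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_spikes(self):
        cfg = build_default_circuit("alpha", seed=7, duration_baseline_s=5.0,
                                    duration_stim_s=0.0)
        r1 = simulate(cfg)
        r2 = simulate(cfg)
        for name in r1.spike_times:
            np.testing.assert_array_equal(r1.spike_times[name],
                                          r2.spike_times[name])

    def test_zero_poisson_weight_silences_network(self):
        cfg = build_default_circuit("alpha", seed=1, duration_baseline_s=3.0,
                                    duration_stim_s=0.0)
        pois = tuple(dataclasses.replace(p, weight_us=0.0)
                     for p in cfg.poisson_inputs)
        cfg = dataclasses.replace(cfg, poisson_inputs=pois)
        res = simulate(cfg)
        assert all(len(t) == 0 for t in res.spike_times.values())

    def test_spike_times_strictly_increasing_within_span(self):
        cfg = build_default_circuit("alpha", seed=3, duration_baseline_s=5.0,
                                    duration_stim_s=0.0)
        res = simulate(cfg)
        for t in res.spike_times.values():
            assert np.all(np.diff(t) > 0)
            if t.size:
                assert t[0] >= 0 and t[-1] <= 5.0


class TestPassiveOracle:
    def test_polarization_matches_rc_closed_form(self):
        cfg = passive_config()
        field = FieldSpec(amplitude_vm=3.0, frequency=10.0, ramp=0.5)
        res = simulate(cfg, field, record_voltage=True, record_dt_ms=0.5)
        vs = res.voltages["BA6_PY"][0]
        amp, phase = lock_in(res.v_times, vs, 10.0, t_start=3.0)
        amp_ref, phase_ref = analytic_two_compartment(
            cfg.neurons["BA6_PY"], 3.0, 10.0)
        assert amp == pytest.approx(amp_ref, rel=0.05)
        assert phase == pytest.approx(phase_ref, abs=np.deg2rad(5))

    def test_field_linearity_in_passive_limit(self):
        cfg = passive_config()
        amps = []
        for a in (3.0, 6.0):
            res = simulate(cfg, FieldSpec(amplitude_vm=a, frequency=10.0, ramp=0.5),
                           record_voltage=True, record_dt_ms=0.5)
            amps.append(lock_in(res.v_times, res.voltages["BA6_PY"][0],
                                10.0, 3.0)[0])
        assert amps[1] == pytest.approx(2 * amps[0], rel=0.01)

    def test_perpendicular_field_produces_no_polarization(self):
        cfg = passive_config()
        field = FieldSpec(amplitude_vm=3.0, frequency=10.0,
                          direction=(0.0, 1.0, 0.0), ramp=0.5)
        res = simulate(cfg, field, record_voltage=True, record_dt_ms=0.5)
        vs = res.voltages["BA6_PY"][0]
        assert np.ptp(vs[res.v_times > 3.0]) < 1e-6


class TestFieldGeometry:
    def test_three_v_per_m_gives_1p5_mv_across_500um_axis(self):
        cfg = build_default_circuit("alpha")
        field = FieldSpec(amplitude_vm=3.0, frequency=10.0, t_on=0.0, t_off=100.0,
                          ramp=0.0)
        t_peak = 1.0  # integer number of cycles after onset -> cos = 1
        ve = apply_extracellular_field(cfg, field, [t_peak])
        vs, vd = ve["BA6_PY"]
        assert abs(vd[0] - vs[0]) == pytest.approx(1.5, rel=1e-6)

    def test_anti_parallel_cells_polarize_with_opposite_sign(self):
        cfg = build_default_circuit("alpha")
        field = FieldSpec(amplitude_vm=3.0, frequency=10.0, t_on=0.0, t_off=100.0,
                          ramp=0.0)
        t = np.linspace(0.5, 2.5, 21)
        ve = apply_extracellular_field(cfg, field, t)
        d6 = ve["BA6_PY"][1] - ve["BA6_PY"][0]
        d4 = ve["BA4_PY"][1] - ve["BA4_PY"][0]
        ratio = d6[np.abs(d4) > 1e-9] / d4[np.abs(d4) > 1e-9]
        np.testing.assert_allclose(ratio, -500.0 / 500.0, rtol=1e-9)


class TestDriveResponse:
    def test_rate_increases_monotonically_with_input_weight(self):
        rates = []
        for scale in (1.0, 1.3, 1.6):
            cfg = build_default_circuit("alpha", seed=2, duration_baseline_s=5.0,
                                        duration_stim_s=0.0)
            pois = tuple(dataclasses.replace(p, weight_us=p.weight_us * scale)
                         for p in cfg.poisson_inputs)
            cfg = dataclasses.replace(cfg, poisson_inputs=pois)
            res = simulate(cfg)
            rates.append(res.rate("BA6_PY", 0.0, 5.0))
        assert rates[0] < rates[1] < rates[2]

    def test_dt_convergence_of_spike_counts(self):
        counts = {}
        for dt in (0.025, 0.0125):
            cfg = build_default_circuit("alpha", seed=4, duration_baseline_s=30.0,
                                        duration_stim_s=0.0)
            cfg = dataclasses.replace(cfg, dt_ms=dt)
            res = simulate(cfg)
            counts[dt] = {n: len(t) for n, t in res.spike_times.items()}
        for n in counts[0.025]:
            c1, c2 = counts[0.025][n], counts[0.0125][n]
            assert abs(c1 - c2) / max(c1, 1) < 0.02


class TestEntrainmentReport:
    def test_zero_field_leaves_plv_at_baseline_level(self):
        cfg = build_default_circuit("alpha", seed=6, duration_baseline_s=20.0,
                                    duration_stim_s=20.0)
        res = simulate(cfg, FieldSpec(amplitude_vm=0.0, frequency=10.0, ramp=1.0))
        rep = entrainment_report(res).set_index(["neuron", "span"])
        for n in ("BA6_PY", "BA4_PY"):
            d = rep.loc[(n, "stimulation"), "plv"]
            b = rep.loc[(n, "baseline"), "plv"]
            assert abs(d - b) < 0.1

    def test_alpha_field_entrains_without_changing_rate(self):
        cfg = build_default_circuit("alpha", seed=6, duration_baseline_s=30.0,
                                    duration_stim_s=40.0)
        res = simulate(cfg, FieldSpec(amplitude_vm=3.0, frequency=10.0, ramp=5.0))
        rep = entrainment_report(res).set_index(["neuron", "span"])
        assert rep.loc[("BA4_PY", "stimulation"), "plv"] > \
            rep.loc[("BA4_PY", "baseline"), "plv"]
        r_b = rep.loc[("BA4_PY", "baseline"), "rate_hz"]
        r_d = rep.loc[("BA4_PY", "stimulation"), "rate_hz"]
        assert abs(r_d - r_b) / r_b < 0.10


class TestConfigValidation:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec("AMPA", 0.0, 0.5, 5.0, -1.0)

    def test_excitatory_synapse_must_target_dendrite(self):
        with pytest.raises(ValueError):
            SynapseSpec("NMDA", 0.0, 2.0, 26.0, 0.001, target_compartment="soma")

    def test_inhibitory_synapse_must_target_soma(self):
        with pytest.raises(ValueError):
            SynapseSpec("GABA_A", -80.0, 0.5, 15.0, 0.001,
                        target_compartment="dendrite")

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec("AMPA", 0.0, 5.0, 5.0, 0.001)

    def test_dt_bound_enforced(self):
        cfg = build_default_circuit("alpha")
        with pytest.raises(ValueError):
            dataclasses.replace(cfg, dt_ms=0.1)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            build_default_circuit("gamma")

    def test_yaml_echo_round_trips(self, tmp_path):
        import yaml

        cfg = build_default_circuit("beta", seed=5)
        text = cfg.to_yaml(tmp_path / "cfg.yaml")
        loaded = yaml.safe_load(text)
        assert loaded["seed"] == 5
        assert loaded["condition"] == "beta"
        assert set(loaded["neurons"]) == {"BA6_PY", "BA4_PY", "IN"}

    def test_replace_weight_on_missing_connection_raises(self):
        cfg = build_default_circuit("alpha")
        with pytest.raises(KeyError):
            cfg.replace_weight("IN", "BA6_PY", "GABA_A", 0.001)

    def test_interneuron_has_no_slow_currents(self):
        cfg = build_default_circuit("alpha")
        assert cfg.neurons["IN"].is_interneuron
        assert not cfg.neurons["BA6_PY"].is_interneuron


class TestStimulationPhase:
    def test_zero_degrees_at_field_peak(self):
        field = FieldSpec(amplitude_vm=3.0, frequency=10.0, t_on=2.0, t_off=10.0)
        s = stimulation_phase(field, [2.0, 2.05, 2.1])
        np.testing.assert_allclose(s.degrees, [0.0, 180.0, 0.0], atol=1e-6)
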