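"""Ion-channel rate functions and kinetic constants.

This is the single reference file for all channel kinetics used by the
two-compartment neurons.  Pyramidal (regular-spiking) cells carry a fast
sodium current I_Na, a delayed-rectifier potassium current I_Kv, a slow
non-inactivating potassium current I_Km, a high-threshold calcium
current I_Ca with a first-order calcium pool, a calcium-dependent
potassium current I_KCa and leak.  Fast-spiking interneurons carry only
I_Na, I_Kv and leak.  The rate functions follow the standard minimal
Hodgkin-Huxley formulations for cortical regular-spiking and
fast-spiking cells (Traub-style Na/Kv with an adjustable threshold
parameter V_T, a slow sigmoid for the M-current, and a Reuveni-style
L-type Ca current); all rates are in 1/ms, voltages in mV.
"""

from __future__ import annotations

import numba
import numpy as np

# reversal potentials (mV)
E_NA = 50.0
E_K = -90.0
E_CA = 120.0

# M-current time constant ceiling (ms); fast enough that spike-frequency
# adaptation advances the phase of the entrained rate response
TAU_MAX_M = 100.0

# calcium pool: d[Ca]/dt = -ALPHA_CA * I_Ca - ([Ca] - CA_REST) / TAU_CA
# [Ca] in uM, I_Ca in uA/cm^2
ALPHA_CA = 0.002
CA_REST = 0.05
TAU_CA = 150.0
KD_KCA = 30.0  # half-activation of I_KCa (uM)

# NMDA magnesium block (Jahr-Stevens sigmoid), [Mg] in mM
MG_CONC = 1.0


@numba.njit(cache=True, inline="always")
def vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (np.exp(x / y) - 1.0)


@numba.njit(cache=True, inline="always")
def na_rates(v, vt):
    """I_Na activation/inactivation rates (alpha_m, beta_m, alpha_h, beta_h)."""
    am = 0.32 * vtrap(-(v - vt - 13.0), 4.0)
    bm = 0.28 * vtrap(v - vt - 40.0, 5.0)
    ah = 0.128 * np.exp(-(v - vt - 17.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v - vt - 40.0) / 5.0))
    return am, bm, ah, bh


@numba.njit(cache=True, inline="always")
def kv_rates(v, vt):
    """Delayed-rectifier activation rates (alpha_n, beta_n)."""
    an = 0.032 * vtrap(-(v - vt - 15.0), 5.0)
    bn = 0.5 * np.exp(-(v - vt - 10.0) / 40.0)
    return an, bn


@numba.njit(cache=True, inline="always")
def km_gate(v, tau_max):
    """M-current gate: (p_inf, tau_p)."""
    p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    return p_inf, tau_p


@numba.njit(cache=True, inline="always")
def ca_rates(v):
    """High-threshold Ca current gates q (activation, squared) and r."""
    aq = 0.055 * vtrap(-27.0 - v, 3.8)
    bq = 0.94 * np.exp((-75.0 - v) / 17.0)
    ar = 0.000457 * np.exp((-13.0 - v) / 50.0)
    br = 0.0065 / (np.exp((-15.0 - v) / 28.0) + 1.0)
    return aq, bq, ar, br


@numba.njit(cache=True, inline="always")
def mg_block(v, mg):
    """Sigmoidal NMDA magnesium unblock factor in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-0.062 * v) * (mg / 3.57))
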