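"""Voltage-gated membrane currents for mossy-fiber axon compartments.

Four current species:

* ``i_na`` — Hodgkin-Huxley sodium, g_na * m^3 * h * (V - E_Na)
* ``i_k`` — "backbone" delayed-rectifier potassium (Kv3-like, TEA-sensitive),
  g_k * n^4 * (V - E_K), with an optional slow cumulative inactivation gate
  used only in train protocols
* ``i_k_comp`` — compensatory potassium (Kv1-like, dendrotoxin-sensitive),
  a lower-threshold Boltzmann-gated current that can be distributed
  non-uniformly (density per compartment)
* ``i_ca`` — a Goldman-Hodgkin-Katz calcium current carried by a mixture of
  P/Q-, N- and R-type channels (ratio 6.5:2.5:1), each with one power-2
  activation gate, Q10 = 2.5 temperature scaling of gate rates

Rate functions default to the canonical squid-axon Hodgkin-Huxley equations,
translated along the voltage axis by a configurable shift and sped up by a
configurable overall rate scale so that the default axon fires an AP peaking
near +20 mV that repolarizes within ~1 ms at 35 degC.

Units: mV, ms, mS/cm^2, mA/cm^2, cm/s (permeability), mM, degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveDensities",
    "CaSubtype",
    "CaChannelMixture",
    "hh_rates",
    "ghk_current",
    "q10_scale",
    "membrane_current",
    "gate_steady_state",
    "GATE_IDS",
]

FARADAY = 96485.332  # C/mol
GAS_R = 8.314462     # J/(mol*K)


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants (defaults of the homogeneous axon model)."""

    cm: float = 1.0       # uF/cm^2
    ra: float = 150.0     # Ohm*cm
    rm: float = 50.0      # kOhm*cm^2
    e_leak: float = -80.0  # mV

    def __post_init__(self) -> None:
        if min(self.cm, self.ra, self.rm) <= 0:
            raise ValueError("cm, ra and rm must be positive")

    @property
    def g_leak(self) -> float:
        """Leak conductance density, mS/cm^2 (1/rm with rm in kOhm*cm^2)."""
        return 1.0 / self.rm

    @property
    def tau_m(self) -> float:
        """Membrane time constant rm*cm, ms."""
        return self.rm * self.cm


@dataclass(frozen=True)
class ActiveDensities:
    """Channel densities and reversals; g_k_comp may be scalar or per-compartment."""

    g_na: float = 290.0    # mS/cm^2
    g_k: float = 17.0      # mS/cm^2
    g_k_comp: float | np.ndarray = 0.0
    e_na: float = 70.0     # mV
    e_k: float = -90.0     # mV
    # kinetics knobs (per species; h has its own pair so the sodium
    # activation/inactivation balance — which sets the AP peak — is tunable)
    shift_na: float = 5.0      # mV translation of the rate equations
    shift_h: float = 0.0
    shift_k: float = 5.0
    rate_scale_na: float = 4.0  # overall speed-up of the canonical rates
    rate_scale_h: float = 14.0
    rate_scale_k: float = 4.0
    # slow cumulative inactivation of the backbone K current (train
    # protocols): develops fast while depolarized, recovers slowly at rest
    slow_k_inactivation: bool = False
    slow_k_tau: float = 300.0       # ms, recovery below vhalf
    slow_k_tau_depol: float = 15.0  # ms, entry above vhalf
    slow_k_vhalf: float = -50.0  # mV
    slow_k_slope: float = 8.0    # mV
    slow_k_floor: float = 0.2    # residual availability

    def __post_init__(self) -> None:
        if self.g_na < 0 or self.g_k < 0 or np.any(np.asarray(self.g_k_comp) < 0):
            raise ValueError("densities must be nonnegative")

    def with_(self, **kw) -> "ActiveDensities":
        return replace(self, **kw)


@dataclass(frozen=True)
class CaSubtype:
    """One Ca channel subtype: power-2 Boltzmann activation gate."""

    name: str
    vhalf: float   # mV
    slope: float   # mV
    tau_min: float = 0.15  # ms, at the reference temperature
    tau_amp: float = 0.8   # ms


# Half-activations stagger from high-voltage-activated P/Q down to R, so the
# mixture opens on the AP upstroke and deactivates on repolarization.
DEFAULT_SUBTYPES = (
    CaSubtype("P/Q", vhalf=-5.0, slope=6.0),
    CaSubtype("N", vhalf=-12.0, slope=6.5),
    CaSubtype("R", vhalf=-20.0, slope=7.0),
)


@dataclass(frozen=True)
class CaChannelMixture:
    """GHK Ca channel mixture (P/Q : N : R = 6.5 : 2.5 : 1 by permeability)."""

    total_permeability: float = 2e-4   # cm/s, summed over subtypes
    ratio: tuple[float, float, float] = (6.5, 2.5, 1.0)
    subtypes: tuple[CaSubtype, ...] = DEFAULT_SUBTYPES
    q10: float = 2.5
    temperature: float = 35.0      # degC
    reference_temperature: float = 24.0  # degC, where gate taus are stated
    ca_in: float = 1e-4   # mM
    ca_out: float = 2.0   # mM

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratio) or self.q10 <= 0:
            raise ValueError("ratio entries and q10 must be positive")
        if len(self.ratio) != len(self.subtypes):
            raise ValueError("one ratio entry per subtype")

    @property
    def permeabilities(self) -> np.ndarray:
        """Per-subtype permeability, cm/s."""
        r = np.asarray(self.ratio, dtype=float)
        return self.total_permeability * r / r.sum()

    @property
    def rate_factor(self) -> float:
        """Q10 speed-up of gate rates at the working temperature."""
        return q10_scale(1.0, self.temperature, self.reference_temperature, self.q10)

    @property
    def temperature_kelvin(self) -> float:
        return self.temperature + 273.15


GATE_IDS = ("m", "h", "n")


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the analytic limit y at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / y / 2.0), safe / np.expm1(safe / y))
    return out


def hh_rates(v, gate_id: str, shift: float = 0.0, rate_scale: float = 1.0):
    """Canonical squid-axon opening/closing rates, 1/ms.

    ``shift`` translates the voltage dependence (positive shift = channel
    activates at more depolarized potentials); ``rate_scale`` multiplies both
    rates.  Removable singularities are evaluated by their analytic limits.
    """
    u = np.asarray(v, dtype=float) - shift
    if gate_id == "m":
        alpha = 0.1 * _vtrap(-(u + 40.0), 10.0)
        beta = 4.0 * np.exp(-(u + 65.0) / 18.0)
    elif gate_id == "h":
        alpha = 0.07 * np.exp(-(u + 65.0) / 20.0)
        beta = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
    elif gate_id == "n":
        alpha = 0.01 * _vtrap(-(u + 55.0), 10.0)
        beta = 0.125 * np.exp(-(u + 65.0) / 80.0)
    else:
        raise KeyError(f"unknown gate id {gate_id!r}")
    return {"alpha": rate_scale * alpha, "beta": rate_scale * beta}


def gate_steady_state(v, gate_id: str, shift: float = 0.0):
    r = hh_rates(v, gate_id, shift=shift)
    return r["alpha"] / (r["alpha"] + r["beta"])


def comp_gate_inf_tau(v, vhalf: float = -30.0, slope: float = 8.0,
                      tau_min: float = 0.2, tau_amp: float = 1.0):
    """Compensatory (Kv1-like) activation gate: steady state and tau (ms)."""
    v = np.asarray(v, dtype=float)
    x_inf = 1.0 / (1.0 + np.exp(-(v - vhalf) / slope))
    tau = tau_min + tau_amp / np.cosh((v - vhalf) / (2.0 * slope))
    return x_inf, tau


def ca_gate_inf_tau(v, subtype: CaSubtype, rate_factor: float = 1.0):
    """Ca subtype activation gate; ``rate_factor`` divides tau (Q10)."""
    v = np.asarray(v, dtype=float)
    x_inf = 1.0 / (1.0 + np.exp(-(v - subtype.vhalf) / subtype.slope))
    tau = (subtype.tau_min
           + subtype.tau_amp / np.cosh((v - subtype.vhalf) / (2.0 * subtype.slope)))
    return x_inf, tau / rate_factor


def q10_scale(rate, T: float, T_ref: float, q10: float):
    """Scale a kinetic rate by q10^((T - T_ref)/10)."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return rate * q10 ** ((T - T_ref) / 10.0)


def ghk_current(v, permeability: float, z: int, c_in: float, c_out: float, T: float):
    """Goldman-Hodgkin-Katz current density, mA/cm^2.

    ``v`` in mV, ``permeability`` in cm/s, concentrations in mM, ``T`` in K.
    Inward (negative) whenever c_out * exp(-zvF/RT) > c_in; continuous across
    v = 0 (the limit there is z*F*P*(c_in - c_out), concentrations in
    mol/cm^3).
    """
    if c_in < 0 or c_out < 0:
        raise ValueError("concentrations must be nonnegative")
    if T <= 0:
        raise ValueError("temperature must be positive")
    v = np.asarray(v, dtype=float)
    u = z * FARADAY * (v * 1e-3) / (GAS_R * T)  # dimensionless
    ci = c_in * 1e-6   # mol/cm^3
    co = c_out * 1e-6
    # u / (1 - exp(-u)) evaluated stably; -> 1 as u -> 0
    with np.errstate(over="ignore"):
        ratio = np.where(np.abs(u) < 1e-12, 1.0,
                         u / np.where(np.abs(u) < 1e-12, 1.0, -np.expm1(-u)))
        flux = ci - co * np.exp(-u)
    amps = permeability * z * FARADAY * flux * ratio  # A/cm^2
    return amps * 1e3  # mA/cm^2


def membrane_current(v, gates: dict, densities: ActiveDensities,
                     mixture: CaChannelMixture, passive: PassiveParams):
    """Decompose the membrane current density by species, mA/cm^2.

    ``gates`` maps gate names to values in [0, 1]: "m", "h", "n", optionally
    "k_slow" (backbone-K availability), "k_comp", and "ca_<subtype name>".
    mS/cm^2 * mV = uA/cm^2, hence the 1e-3 factor to mA/cm^2.
    """
    for key, val in gates.items():
        arr = np.asarray(val)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"gate {key!r} outside [0, 1]")
    m, h, n = gates["m"], gates["h"], gates["n"]
    k_slow = gates.get("k_slow", 1.0)
    i_na = densities.g_na * m ** 3 * h * (v - densities.e_na) * 1e-3
    i_k = densities.g_k * n ** 4 * k_slow * (v - densities.e_k) * 1e-3
    i_k_comp = (np.asarray(densities.g_k_comp)
                * gates.get("k_comp", 0.0) * (v - densities.e_k) * 1e-3)
    i_ca = 0.0
    T = mixture.temperature_kelvin
    for perm, sub in zip(mixture.permeabilities, mixture.subtypes):
        gate = gates.get(f"ca_{sub.name}", 0.0)
        i_ca = i_ca + np.asarray(gate) ** 2 * ghk_current(
            v, perm, 2, mixture.ca_in, mixture.ca_out, T)
    i_leak = passive.g_leak * (v - passive.e_leak) * 1e-3
    total = i_na + i_k + i_k_comp + i_ca + i_leak
    return {"i_na": i_na, "i_k": i_k, "i_k_comp": i_k_comp,
            "i_ca": i_ca, "i_leak": i_leak, "total": total}
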