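"""Per-population dynamical laws of the activity-based locomotor network.

Each neural population is a non-spiking "activity" unit characterised by its
average membrane potential V (mV).  Rhythm-generating (RG) flexor and extensor
centres additionally carry a slowly inactivating persistent-sodium current
(I_NaP) whose inactivation gate h endows them with intrinsic oscillatory
properties; all other populations are plain leaky units.  A piecewise-linear
output function f(V) maps the membrane potential onto the integrated
population activity in [0, 1], which is what synapses transmit.

Units are self-consistent throughout: V in mV, conductances in nS, currents
in pA, capacitance in pF, time in ms (nS * mV = pA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "NaPParams",
    "NoiseParams",
    "PopulationSpec",
    "SynapseParams",
    "DriveLaw",
    "PopulationState",
    "output_activity",
    "drive_strength",
    "nap_activation",
    "nap_inactivation_steady",
    "nap_inactivation_tau",
    "nap_kinetics",
    "evaluate_currents",
    "noise_step",
    "state_derivative",
]

Side = Literal["left", "right"]


class InvalidParameterError(ValueError):
    """A parameter violates its documented constraint."""


class StateCorruptionError(RuntimeError):
    """A state variable left its admissible range."""


@dataclass(frozen=True)
class NaPParams:
    """Persistent-sodium current parameters for an oscillatory centre.

    The current is I_NaP = g_NaP * m_inf(V) * h * (V - E_Na) with an
    instantaneous sigmoidal activation m_inf and a slow inactivation gate h
    relaxing towards h_inf(V) with voltage-dependent time constant tau_h(V).
    """

    g_nap: float = 2.7  # nS
    e_na: float = 50.0  # mV
    m_half: float = -40.0  # activation half-voltage, mV
    m_slope: float = -6.0  # activation slope, mV (< 0: opens with depolarisation)
    h_half: float = -40.0  # inactivation half-voltage, mV
    h_slope: float = 5.0  # inactivation slope, mV (> 0: closes with depolarisation)
    tau_max: float = 200.0  # peak inactivation time constant, ms

    def __post_init__(self) -> None:
        if self.g_nap < 0:
            raise InvalidParameterError("g_nap must be >= 0")
        if self.m_slope >= 0:
            raise InvalidParameterError("m_slope must be < 0 (activation)")
        if self.h_slope <= 0:
            raise InvalidParameterError("h_slope must be > 0 (inactivation)")
        if self.tau_max <= 0:
            raise InvalidParameterError("tau_max must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck noise-current parameters."""

    sigma: float = 0.005  # stationary standard deviation, pA
    tau: float = 10.0  # relaxation time, ms

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Identity plus intrinsic parameters of one neural population."""

    name: str
    side: Side
    compartment: str
    girdle: str = ""  # "", "fore", "hind" (spinal) or "cervical", "lumbar" (relay)
    dynamics_class: Literal["nap-oscillatory", "plain"] = "plain"
    C: float = 10.0  # pF
    g_l: float = 5.0  # nS
    e_l: float = -60.0  # mV
    v_thr: float = -50.0  # mV
    v_max: float = 0.0  # mV
    nap: NaPParams | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.v_max <= self.v_thr:
            raise InvalidParameterError(
                f"{self.name}: v_max ({self.v_max}) must exceed v_thr ({self.v_thr})"
            )
        if self.C <= 0 or self.g_l <= 0:
            raise InvalidParameterError(f"{self.name}: C and g_l must be > 0")
        if (self.dynamics_class == "nap-oscillatory") != (self.nap is not None):
            raise InvalidParameterError(
                f"{self.name}: nap parameters present iff dynamics_class is nap-oscillatory"
            )

    @property
    def key(self) -> str:
        """Canonical identifier '<name>:<side>[:<girdle>]'."""
        if self.girdle:
            return f"{self.name}:{self.side}:{self.girdle}"
        return f"{self.name}:{self.side}"

    def with_nap(self, **kwargs) -> "PopulationSpec":
        if self.nap is None:
            raise InvalidParameterError(f"{self.name} has no NaP current")
        return replace(self, nap=replace(self.nap, **kwargs))


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based synapse model shared by the whole network.

    Weighted presynaptic activity is converted to conductance with fixed
    scale factors; excitatory drives enter the excitatory conductance the
    same way via the drive scale.
    """

    e_syn_e: float = -10.0  # excitatory reversal, mV
    e_syn_i: float = -75.0  # inhibitory reversal, mV
    g_bar_e: float = 8.0  # nS per unit weighted excitatory activity
    g_bar_i: float = 8.0  # nS per unit weighted inhibitory activity
    g_bar_d: float = 1.75  # nS per unit drive

    def __post_init__(self) -> None:
        if self.e_syn_e <= self.e_syn_i:
            raise InvalidParameterError("e_syn_e must exceed e_syn_i")
        if min(self.g_bar_e, self.g_bar_i, self.g_bar_d) < 0:
            raise InvalidParameterError("conductance scales must be >= 0")


@dataclass(frozen=True)
class DriveLaw:
    """Linear stimulation law D(alpha) = m * alpha + b for one target population."""

    target: str  # population name, e.g. "CnF-Glu"
    side: Side | Literal["both"]
    m: float
    b: float

    def __call__(self, alpha: float) -> float:
        return drive_strength(alpha, self.m, self.b)


@dataclass
class PopulationState:
    """Instantaneous state of one population."""

    v: float
    h: float | None = None  # NaP inactivation gate, nap-oscillatory only
    noise: float = 0.0  # pA

    def validate(self) -> None:
        if not math.isfinite(self.v) or not math.isfinite(self.noise):
            raise StateCorruptionError("non-finite state")
        if self.h is not None and not 0.0 <= self.h <= 1.0:
            raise StateCorruptionError(f"h={self.h} outside [0, 1]")


def output_activity(v, v_thr: float = -50.0, v_max: float = 0.0):
    """Piecewise-linear output function f(V).

    Exactly 0 below ``v_thr``, exactly 1 at or above ``v_max`` and linear in
    between; accepts scalars or arrays.
    """
    if v_max <= v_thr:
        raise InvalidParameterError("v_max must exceed v_thr")
    return np.clip((np.asarray(v, dtype=float) - v_thr) / (v_max - v_thr), 0.0, 1.0)[()]


def drive_strength(alpha: float, m: float, b: float) -> float:
    """Linear drive law D(alpha) = m * alpha + b."""
    return m * alpha + b


def nap_activation(v, p: NaPParams):
    """Instantaneous steady-state activation m_inf(V) of I_NaP."""
    return 1.0 / (1.0 + np.exp((v - p.m_half) / p.m_slope))


def nap_inactivation_steady(v, p: NaPParams):
    """Steady-state inactivation h_inf(V): 0.5 at h_half, closing with depolarisation."""
    return 1.0 / (1.0 + np.exp((v - p.h_half) / p.h_slope))


def nap_inactivation_tau(v, p: NaPParams):
    """Voltage-dependent inactivation time constant tau_h(V), ms; peaks at h_half."""
    return p.tau_max / np.cosh((v - p.h_half) / (2.0 * p.h_slope))


def nap_kinetics(v, h, p: NaPParams):
    """Persistent-sodium current and gate derivative.

    Returns ``(I_NaP [pA], dh/dt [1/ms])``.  The relaxation form
    dh/dt = (h_inf - h)/tau_h keeps h in [0, 1] without clipping.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0.0) or np.any(h_arr > 1.0):
        raise StateCorruptionError(f"h outside [0, 1]: {h}")
    i_nap = p.g_nap * nap_activation(v, p) * h_arr * (np.asarray(v, float) - p.e_na)
    dhdt = (nap_inactivation_steady(v, p) - h_arr) / nap_inactivation_tau(v, p)
    return i_nap[()], dhdt[()]


def evaluate_currents(
    v: float,
    spec: PopulationSpec,
    syn: SynapseParams,
    weighted_exc_input: float,
    weighted_inh_input: float,
    total_drive: float = 0.0,
):
    """Leak and synaptic currents (pA) for one population.

    ``weighted_exc_input``/``weighted_inh_input`` are sums of weight x
    presynaptic activity over positive-weight connections and over magnitudes
    of negative-weight connections respectively; ``total_drive`` is the sum of
    attached excitatory drives.  Negative drives are clamped to zero at the
    conductance stage (a conductance cannot be negative).
    """
    if weighted_exc_input < 0 or weighted_inh_input < 0:
        raise InvalidParameterError("weighted synaptic inputs must be >= 0")
    i_l = spec.g_l * (v - spec.e_l)
    g_e = syn.g_bar_e * weighted_exc_input + syn.g_bar_d * max(total_drive, 0.0)
    g_i = syn.g_bar_i * weighted_inh_input
    i_syn_e = g_e * (v - syn.e_syn_e)
    i_syn_i = g_i * (v - syn.e_syn_i)
    return i_l, i_syn_e, i_syn_i


def noise_step(
    current_noise: float,
    dt: float,
    sigma: float,
    tau: float,
    rng: np.random.Generator,
) -> float:
    """One Euler-Maruyama step of the Ornstein-Uhlenbeck noise current.

    dI = -I/tau dt + sigma*sqrt(2/tau) dW, whose stationary standard
    deviation is ``sigma``.  With sigma = 0 the current decays
    deterministically to zero.
    """
    if dt <= 0 or tau <= 0:
        raise InvalidParameterError("dt and tau must be > 0")
    drift = current_noise - current_noise * dt / tau
    if sigma == 0.0:
        return drift
    return drift + sigma * math.sqrt(2.0 * dt / tau) * rng.standard_normal()


def state_derivative(
    v: np.ndarray,
    h: np.ndarray,
    noise: np.ndarray,
    specs: list[PopulationSpec],
    syn: SynapseParams,
    weights: np.ndarray,
    drive: np.ndarray,
):
    """Network-wide time derivatives (reference implementation).

    ``weights[i, j]`` is the signed connection weight from population j onto
    population i; ``drive`` is the per-population total excitatory drive.
    Returns ``(dV/dt, dh/dt)`` with dh/dt = 0 for plain populations.  This
    pure-NumPy path is the oracle against which the compiled kernels are
    verified; it is used directly for small fixtures.
    """
    n = len(specs)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(h)) and np.all(np.isfinite(noise))):
        bad = [
            s.key
            for s, ok in zip(
                specs, np.isfinite(v) & np.isfinite(h) & np.isfinite(noise)
            )
            if not ok
        ]
        raise StateCorruptionError(f"non-finite state in populations {bad}")
    v_thr = np.array([s.v_thr for s in specs])
    v_max = np.array([s.v_max for s in specs])
    f = np.clip((v - v_thr) / (v_max - v_thr), 0.0, 1.0)
    w_pos = np.where(weights > 0, weights, 0.0)
    w_neg = np.where(weights < 0, -weights, 0.0)
    exc = w_pos @ f
    inh = w_neg @ f
    dv = np.empty(n)
    dh = np.zeros(n)
    for i, spec in enumerate(specs):
        i_l, i_se, i_si = evaluate_currents(v[i], spec, syn, exc[i], inh[i], drive[i])
        total = i_l + i_se + i_si + noise[i]
        if spec.nap is not None:
            i_nap, dh[i] = nap_kinetics(v[i], h[i], spec.nap)
            total += i_nap
        dv[i] = -total / spec.C
    return dv, dh
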