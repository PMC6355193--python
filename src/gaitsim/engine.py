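"""Numerical integration, continuation sweeps, drive grids and robustness.

Deterministic trajectories are integrated with a fixed-step classical
Runge-Kutta scheme (default dt = 0.1 ms, small against the fastest membrane
time constant); stochastic trajectories with fixed-step Euler-Maruyama.
Continuation sweeps follow the settled state from one stimulation strength
to the next (warm starting), separately on the increasing and decreasing
branches, which is what exposes bistability between adjacent gaits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels, gait_analysis
from .connectome import Network, apply_lesion, build_default_network, perturb_weights
from .population_dynamics import (
    DriveLaw,
    InvalidParameterError,
    NaPParams,
    PopulationSpec,
    SynapseParams,
    nap_inactivation_steady,
)

__all__ = [
    "Stimulation",
    "Protocol",
    "SimulationResult",
    "SettleResult",
    "BifurcationDiagram",
    "RobustnessReport",
    "IntegrationError",
    "integrate",
    "settle_at_alpha",
    "bifurcation_sweep",
    "noisy_sweep",
    "drive_grid",
    "robustness_suite",
    "calibrate_rg_center",
    "build_isolated_center",
]

RG_KEYS = (
    "RG-F:left:hind",
    "RG-F:right:hind",
    "RG-F:left:fore",
    "RG-F:right:fore",
)

#: Output-sample spacing (ms) used for cycle analysis.
RECORD_DT = 1.0

#: Convergence tolerance on the circular SD of each phase difference.
PHASE_SD_TOL = 1e-3

#: Baseline noise-current SD (pA) present in every population by default.
BASELINE_SIGMA = 0.005

#: Default fixed time steps (ms): RK4 for sigma = 0, Euler-Maruyama otherwise.
DT_DETERMINISTIC = 0.1
DT_STOCHASTIC = 0.05

QUIESCENT_AMPLITUDE = 0.05
QUIESCENT_SILENCE_MS = 3000.0


class IntegrationError(RuntimeError):
    """Numerical blow-up during integration."""

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms


@dataclass(frozen=True)
class Stimulation:
    """A drive law applied to one (or both) sides of a target population."""

    law: DriveLaw
    alpha: float | None = None  # fixed alpha; sweeps supply alpha per step

    def drive(self, alpha: float | None = None) -> float:
        a = self.alpha if alpha is None else alpha
        if a is None:
            raise InvalidParameterError("no alpha supplied for stimulation")
        return self.law(a)


@dataclass(frozen=True)
class Protocol:
    """A complete description of one simulation run."""

    stimulations: tuple[Stimulation, ...] = ()
    extra_drives: dict[str, float] = field(default_factory=dict)
    lesions: tuple[str, ...] = ()
    sigma_noise: float | None = None  # pA; None keeps per-population defaults
    duration: float = 10.0  # s
    dt: float = 0.1  # ms
    seed: int = 0
    record_dt: float = RECORD_DT  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidParameterError("duration and dt must be > 0")
        for stim in self.stimulations:
            a = stim.alpha
            if a is not None and not -1e-12 <= a <= 1.05 + 1e-12:
                raise InvalidParameterError(f"alpha {a} outside [0, 1.05]")


@dataclass
class SimulationResult:
    """Time grid plus per-population membrane potential and output traces."""

    time: np.ndarray  # ms
    keys: list[str]
    v: np.ndarray  # (n_samples, n_keys) mV
    f: np.ndarray  # (n_samples, n_keys) activity in [0, 1]
    protocol: Protocol
    seed: int

    def trace(self, key: str) -> np.ndarray:
        return self.f[:, self.keys.index(key)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.f, columns=self.keys)
        frame.insert(0, "time_ms", self.time)
        return frame


class _Compiled:
    """Flat-array view of a network for the numba kernels."""

    def __init__(self, net: Network):
        self.net = net
        self.order = net.order
        self.index = {k: i for i, k in enumerate(self.order)}
        specs = [net.populations[k] for k in self.order]
        self.specs = specs
        n = len(specs)
        self.n = n
        self.is_nap = np.array(
            [s.dynamics_class == "nap-oscillatory" for s in specs], dtype=np.bool_
        )
        self.C = np.array([s.C for s in specs])
        self.gL = np.array([s.g_l for s in specs])
        self.EL = np.array([s.e_l for s in specs])
        self.Vthr = np.array([s.v_thr for s in specs])
        self.Vmax = np.array([s.v_max for s in specs])

        def nap_field(attr: str, default: float) -> np.ndarray:
            return np.array(
                [getattr(s.nap, attr) if s.nap else default for s in specs]
            )

        self.gNaP = nap_field("g_nap", 0.0)
        self.ENa = nap_field("e_na", 50.0)
        self.mHalf = nap_field("m_half", -40.0)
        self.mSlope = nap_field("m_slope", -6.0)
        self.hHalf = nap_field("h_half", -45.0)
        self.hSlope = nap_field("h_slope", 4.0)
        self.tauMax = nap_field("tau_max", 1.0)
        self.sigma_default = np.array([s.noise.sigma for s in specs])
        self.tauNoise = np.array([s.noise.tau for s in specs])
        self.conn_src = np.array(
            [self.index[c.source] for c in net.connections], dtype=np.int64
        )
        self.conn_tgt = np.array(
            [self.index[c.target] for c in net.connections], dtype=np.int64
        )
        self.conn_w = np.array([c.weight for c in net.connections])
        syn = net.synapse
        self.syn_args = (syn.e_syn_e, syn.e_syn_i, syn.g_bar_e, syn.g_bar_i, syn.g_bar_d)

    def param_args(self):
        return (
            self.is_nap,
            self.C,
            self.gL,
            self.EL,
            self.Vthr,
            self.Vmax,
            self.gNaP,
            self.ENa,
            self.mHalf,
            self.mSlope,
            self.hHalf,
            self.hSlope,
            self.tauMax,
            self.conn_src,
            self.conn_tgt,
            self.conn_w,
            *self.syn_args,
        )

    def initial_state(self, bias: dict[str, float] | None = None):
        """Rest state: V = E_L, h = h_inf(E_L), zero noise current.

        ``bias`` adds deterministic voltage offsets (mV) to named populations;
        used to break the exact left-right symmetry in noise-free studies.
        """
        v = self.EL.copy()
        for key, dv in (bias or {}).items():
            v[self.index[key]] += dv
        h = np.ones(self.n)
        for i, s in enumerate(self.specs):
            if s.nap is not None:
                h[i] = float(nap_inactivation_steady(v[i], s.nap))
        return State(v, h, np.zeros(self.n))

    def activity(self, v: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        thr = self.Vthr if idx is None else self.Vthr[idx]
        vmx = self.Vmax if idx is None else self.Vmax[idx]
        return np.clip((v - thr) / (vmx - thr), 0.0, 1.0)


@dataclass
class State:
    """Flat network state in canonical population order."""

    v: np.ndarray
    h: np.ndarray
    noise: np.ndarray

    def copy(self) -> "State":
        return State(self.v.copy(), self.h.copy(), self.noise.copy())


def _kernel_seed(root_seed, *branch) -> int:
    """A sub-2^31 kernel seed derived from the protocol seed and a branch path."""
    ss = np.random.SeedSequence([int(root_seed), *[int(b) & 0x7FFFFFFF for b in branch]])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_chunk(
    comp: _Compiled,
    state: State,
    drive: np.ndarray,
    duration_ms: float,
    dt: float,
    sigma: np.ndarray,
    record_idx: np.ndarray,
    record_every: int,
    seed: int,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Advance the state in place; return recorded V (n_rec, len(record_idx))."""
    n_steps = int(round(duration_ms / dt))
    n_rec = n_steps // record_every if record_every > 0 else 0
    out = np.empty((n_rec, len(record_idx)))
    stochastic = bool(np.any(sigma > 0))
    status, step = _kernels.run_fixed(
        state.v,
        state.h,
        state.noise,
        drive,
        *comp.param_args(),
        sigma,
        comp.tauNoise,
        dt,
        n_steps,
        record_every,
        record_idx,
        out,
        stochastic,
        seed,
    )
    if status != _kernels.STATUS_OK:
        t = t0_ms + step * dt
        i = int(np.argmax(~np.isfinite(state.v) | (np.abs(state.v) > 200.0)))
        raise IntegrationError(
            f"membrane potential blow-up in {comp.order[i]} at t = {t:.1f} ms", t
        )
    return out


def _protocol_sigma(comp: _Compiled, protocol: Protocol) -> np.ndarray:
    if protocol.sigma_noise is None:
        return comp.sigma_default.copy()
    return np.full(comp.n, float(protocol.sigma_noise))


def _protocol_drive(
    net: Network, protocol: Protocol, alpha: float | None = None
) -> np.ndarray:
    extra: dict[str, float] = dict(protocol.extra_drives)
    for stim in protocol.stimulations:
        d = stim.drive(alpha)
        for key in net.resolve(stim.law.target, stim.law.side):
            extra[key] = extra.get(key, 0.0) + d
    return net.drive_vector(extra)


def integrate(net: Network, protocol: Protocol) -> SimulationResult:
    """Integrate a protocol on a network, recording all populations.

    With ``sigma_noise = 0`` the run is solver-deterministic; with noise the
    fixed-step stochastic integration is reproducible from ``protocol.seed``.
    """
    if protocol.lesions:
        net = apply_lesion(net, protocol.lesions)
    comp = _Compiled(net)
    state = comp.initial_state()
    drive = _protocol_drive(net, protocol)
    sigma = _protocol_sigma(comp, protocol)
    record_every = max(1, int(round(protocol.record_dt / protocol.dt)))
    out = _run_chunk(
        comp,
        state,
        drive,
        protocol.duration * 1000.0,
        protocol.dt,
        sigma,
        np.arange(comp.n, dtype=np.int64),
        record_every,
        _kernel_seed(protocol.seed, 0),
    )
    time = (1 + np.arange(out.shape[0])) * record_every * protocol.dt
    return SimulationResult(
        time=time,
        keys=list(comp.order),
        v=out,
        f=comp.activity(out),
        protocol=protocol,
        seed=protocol.seed,
    )


# ---------------------------------------------------------------------------
# Settling / continuation
# ---------------------------------------------------------------------------


@dataclass
class SettleResult:
    """Converged phase differences and frequency at one stimulation strength."""

    alpha: float
    status: str  # converged | timeout | quiescent
    frequency: float  # Hz, nan if quiescent
    phases: tuple  # four circular-mean phase differences, nan if quiescent
    phase_sd: tuple  # circular SDs of the last five cycles, nan if unmeasurable
    gait: str
    state: State
    elapsed_s: float


def _cycle_stats(time, traces):
    """Last-five-cycle means and circular SDs of the four phase differences."""
    records = gait_analysis.cycles_from_traces(time, *traces)
    if len(records) < 5:
        return None
    last = records[-5:]
    phases = np.array([r.phases for r in last], dtype=float)
    if np.any(np.isnan(phases)):
        return None
    means = tuple(gait_analysis.circular_mean(phases[:, j]) for j in range(4))
    sds = tuple(gait_analysis.circular_std(phases[:, j]) for j in range(4))
    freq = float(np.mean([r.frequency for r in last]))
    return means, sds, freq


def settle_at_alpha(
    net_or_comp,
    stimulation: Stimulation,
    alpha: float,
    state: State | None = None,
    chunk_s: float = 10.0,
    max_s: float = 200.0,
    dt: float | None = None,
    sigma_noise: float = BASELINE_SIGMA,
    seed: int = 0,
    extra_drives: dict[str, float] | None = None,
) -> SettleResult:
    """Integrate in fixed chunks until the rhythm's phase differences settle.

    After each chunk the four phase differences are measured over the last
    five locomotor cycles; the step has converged when each of their circular
    standard deviations is below 0.001.  If the reference flexor centre shows
    no onset for 3 s, or its output peak-to-trough amplitude falls below 0.05
    over the last 5 s, the step is classified quiescent.  Hitting ``max_s``
    without convergence gives status ``timeout``.
    """
    comp = net_or_comp if isinstance(net_or_comp, _Compiled) else _Compiled(net_or_comp)
    if dt is None:
        dt = DT_STOCHASTIC if sigma_noise > 0 else DT_DETERMINISTIC
    state = comp.initial_state() if state is None else state
    drive = _protocol_drive(
        comp.net,
        Protocol(stimulations=(stimulation,), extra_drives=extra_drives or {}),
        alpha,
    )
    sigma = np.full(comp.n, float(sigma_noise))
    record_idx = np.array([comp.index[k] for k in RG_KEYS], dtype=np.int64)
    record_every = max(1, int(round(RECORD_DT / dt)))
    history = np.empty((0, 4))
    elapsed = 0.0
    status = "timeout"
    means: tuple = (np.nan,) * 4
    sds: tuple = (np.nan,) * 4
    freq = np.nan
    chunk_no = 0
    while elapsed < max_s - 1e-9:
        out = _run_chunk(
            comp,
            state,
            drive,
            chunk_s * 1000.0,
            dt,
            sigma,
            record_idx,
            record_every,
            _kernel_seed(seed, 1, chunk_no),
            t0_ms=elapsed * 1000.0,
        )
        history = np.vstack([history, comp.activity(out, record_idx)])
        elapsed += chunk_s
        chunk_no += 1
        time = (1 + np.arange(history.shape[0])) * RECORD_DT
        ref = history[:, 0]
        tail5s = ref[-int(5000 / RECORD_DT):]
        onsets = gait_analysis.detect_onsets(ref, dt=RECORD_DT)
        silent_ms = (
            time[-1] - onsets[-1] if onsets.size else time[-1]
        )
        if (tail5s.max() - tail5s.min() < QUIESCENT_AMPLITUDE) or (
            silent_ms > QUIESCENT_SILENCE_MS
        ):
            status = "quiescent"
            break
        stats = _cycle_stats(time, [history[:, j] for j in range(4)])
        if stats is None:
            continue
        means, sds, freq = stats
        if max(sds) < PHASE_SD_TOL:
            status = "converged"
            break
    gait = (
        "quiescent"
        if status == "quiescent"
        else gait_analysis.classify_gait(np.array(means) % 1.0)
        if not np.any(np.isnan(means))
        else "unclassified"
    )
    if status == "quiescent":
        means, sds, freq = (np.nan,) * 4, (np.nan,) * 4, np.nan
    return SettleResult(
        alpha=alpha,
        status=status,
        frequency=freq,
        phases=means,
        phase_sd=sds,
        gait=gait,
        state=state,
        elapsed_s=elapsed,
    )


@dataclass
class BifurcationDiagram:
    """Converged frequency and phase differences on the up and down branches."""

    up: pd.DataFrame
    down: pd.DataFrame
    stimulation: Stimulation

    @property
    def branches(self) -> dict[str, pd.DataFrame]:
        return {"up": self.up, "down": self.down}

    def max_frequency(self) -> float:
        freqs = pd.concat([self.up, self.down])["frequency_hz"]
        return float(freqs.max(skipna=True))

    def gaits(self, branch: str = "up") -> list[str]:
        frame = self.branches[branch]
        return [g for g in frame["gait"] if g not in ("quiescent", "unclassified")]


def _branch_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "alpha",
            "status",
            "frequency_hz",
            "phase_hind_lr",
            "phase_fore_lr",
            "phase_homolateral",
            "phase_diagonal",
            "phase_sd_max",
            "gait",
        ],
    )


def bifurcation_sweep(
    net: Network,
    stimulation: Stimulation,
    n_steps: int = 1000,
    alpha_max: float = 1.05,
    chunk_s: float = 10.0,
    max_s: float = 200.0,
    dt: float | None = None,
    sigma_noise: float = BASELINE_SIGMA,
    seed: int = 0,
    burn_in_s: float = 2.0,
    branches: str = "both",
    progress=None,
) -> BifurcationDiagram:
    """Continuation sweep of the stimulation strength, up then down.

    Alpha increases from 0 to ``alpha_max`` in ``n_steps`` equally spaced
    steps and then decreases back, each step warm-started from the previous
    step's final state; the down branch continues from the up branch's final
    state.  Returns both branches so bistability regions (up != down) are
    exposed; ``branches="up"`` skips the descending branch (its frame is
    left empty) when only the ascending continuation is needed.
    """
    comp = _Compiled(net)
    if dt is None:
        dt = DT_STOCHASTIC if sigma_noise > 0 else DT_DETERMINISTIC
    alphas = np.linspace(0.0, alpha_max, n_steps)
    state = comp.initial_state()
    if burn_in_s > 0:
        drive = _protocol_drive(comp.net, Protocol(stimulations=(stimulation,)), 0.0)
        _run_chunk(
            comp,
            state,
            drive,
            burn_in_s * 1000.0,
            dt,
            np.full(comp.n, float(sigma_noise)),
            np.empty(0, dtype=np.int64),
            0,
            _kernel_seed(seed, 4),
        )
    diagrams = {"down": _branch_frame([])}
    plan = (("up", alphas), ("down", alphas[::-1]))
    if branches == "up":
        plan = plan[:1]
    for branch_no, (branch, branch_alphas) in enumerate(plan):
        rows = []
        for i, a in enumerate(branch_alphas):
            res = settle_at_alpha(
                comp,
                stimulation,
                float(a),
                state,
                chunk_s,
                max_s,
                dt,
                sigma_noise=sigma_noise,
                seed=_kernel_seed(seed, 5, branch_no, i),
            )
            state = res.state
            rows.append(
                (
                    res.alpha,
                    res.status,
                    res.frequency,
                    *res.phases,
                    max(res.phase_sd) if not np.all(np.isnan(res.phase_sd)) else np.nan,
                    res.gait,
                )
            )
            if progress is not None:
                progress(branch, res)
        diagrams[branch] = _branch_frame(rows)
    return BifurcationDiagram(up=diagrams["up"], down=diagrams["down"], stimulation=stimulation)


def noisy_sweep(
    net: Network,
    stimulation: Stimulation,
    alpha_step: float = 0.01,
    duration_per_step: float = 100.0,
    sigma_noise: float = 1.0,
    seed: int = 0,
    alpha_max: float = 1.05,
    dt: float = 0.1,
    windows: gait_analysis.GaitWindows | None = None,
) -> list[gait_analysis.CycleRecord]:
    """Long stochastic run over increasing alpha, pooling per-cycle records.

    Alpha increases from 0 to ``alpha_max`` in steps of ``alpha_step``; each
    step runs for ``duration_per_step`` seconds under Ornstein-Uhlenbeck
    noise of stationary SD ``sigma_noise`` (pA), warm-starting from the
    previous step.  Every detected reference-limb cycle yields one record.
    """
    if sigma_noise <= 0:
        raise InvalidParameterError("noisy_sweep requires sigma_noise > 0")
    comp = _Compiled(net)
    record_idx = np.array([comp.index[k] for k in RG_KEYS], dtype=np.int64)
    record_every = max(1, int(round(RECORD_DT / dt)))
    sigma = np.full(comp.n, float(sigma_noise))
    state = comp.initial_state()
    records: list[gait_analysis.CycleRecord] = []
    alphas = np.arange(0.0, alpha_max + alpha_step / 2, alpha_step)
    for step_no, a in enumerate(alphas):
        drive = _protocol_drive(
            comp.net, Protocol(stimulations=(stimulation,)), float(a)
        )
        out = _run_chunk(
            comp,
            state,
            drive,
            duration_per_step * 1000.0,
            dt,
            sigma,
            record_idx,
            record_every,
            _kernel_seed(seed, 2, step_no),
        )
        f = comp.activity(out, record_idx)
        time = (1 + np.arange(f.shape[0])) * RECORD_DT
        records.extend(
            gait_analysis.cycles_from_traces(
                time, f[:, 0], f[:, 1], f[:, 2], f[:, 3], windows=windows, alpha=float(a)
            )
        )
    return records


# ---------------------------------------------------------------------------
# Drive grids (inhibitory-stimulation experiments)
# ---------------------------------------------------------------------------


def drive_grid(
    net: Network,
    in_target: str,
    ex_values=None,
    in_values=None,
    chunk_s: float = 10.0,
    max_s: float = 40.0,
    dt: float | None = None,
    sigma_noise: float = BASELINE_SIGMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency/gait grid: bilateral CnF excitation x unilateral inhibition.

    For every excitatory drive ``D_CnF,ex`` (applied bilaterally to the
    glutamatergic CnF populations) the inhibitory drive is ramped over
    ``in_values`` applied unilaterally (left) to the inhibitory population of
    ``in_target`` (CnF, PPN or LPGi), warm-starting each cell from the
    previous one in the ramp.  Cells record the settled frequency and gait,
    or quiescence.
    """
    region_pops = {
        "CnF": "CnF-GABA/Gly",
        "PPN": "PPN-GABA/Gly",
        "LPGi": "LPGi-GABA/Gly",
    }
    if in_target in region_pops:
        in_pop = region_pops[in_target]
    elif in_target in region_pops.values():
        in_pop = in_target
    else:
        raise KeyError(
            f"unknown inhibitory target {in_target!r}; expected one of "
            f"{sorted(region_pops) + sorted(region_pops.values())}"
        )
    ex_values = (
        np.round(np.arange(2.78, 3.06 + 0.01, 0.02), 10) if ex_values is None else ex_values
    )
    in_values = (
        np.round(np.arange(1.15, 2.85 + 0.035, 0.07), 10) if in_values is None else in_values
    )
    comp = _Compiled(net)
    ex_stim = Stimulation(DriveLaw("CnF-Glu", "both", m=0.0, b=0.0))
    rows = []
    for j, d_ex in enumerate(ex_values):
        state = comp.initial_state()
        for i, d_in in enumerate(in_values):
            res = settle_at_alpha(
                comp,
                ex_stim,
                0.0,
                state,
                chunk_s,
                max_s,
                dt,
                sigma_noise=sigma_noise,
                seed=_kernel_seed(seed, 6, j, i),
                extra_drives={
                    "CnF-Glu:left": float(d_ex),
                    "CnF-Glu:right": float(d_ex),
                    f"{in_pop}:left": float(d_in),
                },
            )
            state = res.state
            rows.append(
                {
                    "d_ex": float(d_ex),
                    "d_in": float(d_in),
                    "status": res.status,
                    "frequency_hz": res.frequency,
                    "gait": res.gait,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Robustness to weight perturbation
# ---------------------------------------------------------------------------

ALL_GAITS = ("walk", "trot", "gallop", "bound")


@dataclass
class RobustnessReport:
    """Per-sigma_p classification of randomly perturbed models."""

    table: pd.DataFrame  # columns sigma_p, retains_all_gaits, loses_gaits, unstable
    n_models: int
    n_steps: int
    details: pd.DataFrame  # one row per model


#: Circular-SD threshold above which a non-converged step counts as non-periodic.
NONPERIODIC_SD = 0.1


def _classify_model(diagram: BifurcationDiagram) -> str:
    """Stability class of one (perturbed) model from its sweep.

    A step counts as failed when it neither converged nor went quiescent and
    its phase differences were non-periodic (circular SD above 0.1 over the
    last five cycles, or no measurable phases at all); a model is unstable
    when more than 5 % of its steps fail.  Timeouts with stationary phases
    are tolerated so that reduced settling caps do not masquerade as
    instability.
    """
    frames = pd.concat([diagram.up, diagram.down])
    n = len(frames)
    if n == 0:
        return "unstable"
    timeouts = frames[frames["status"] == "timeout"]
    bad = (
        timeouts["phase_sd_max"].isna() | (timeouts["phase_sd_max"] > NONPERIODIC_SD)
    ).sum()
    if bad / n > 0.05:
        return "unstable"
    gaits = set(diagram.gaits("up")) | set(diagram.gaits("down"))
    return "retains-all-gaits" if set(ALL_GAITS) <= gaits else "loses-gaits"


def robustness_suite(
    net: Network,
    sigma_p_values=None,
    n_models: int = 100,
    seed: int = 0,
    stimulation: Stimulation | None = None,
    n_steps: int = 50,
    chunk_s: float = 10.0,
    max_s: float = 40.0,
    dt: float | None = None,
    sigma_noise: float = BASELINE_SIGMA,
    progress=None,
) -> RobustnessReport:
    """Perturb all weights multiplicatively and re-run the CnF sweep.

    For each ``sigma_p``, ``n_models`` networks are drawn with every weight
    multiplied by an independent N(1, sigma_p) sample, and a (reduced
    resolution) CnF-Glu bifurcation sweep is run on each.  A model retains
    all gaits if walk, trot, gallop and bound all appear among its converged
    steps; it is unstable if integration fails or more than 5 % of its steps
    fail both convergence and quiescence classification; otherwise it has
    lost gaits.
    """
    sigma_p_values = (
        np.round(np.arange(0.02, 0.2 + 0.01, 0.02), 10)
        if sigma_p_values is None
        else sigma_p_values
    )
    stimulation = stimulation or Stimulation(DriveLaw("CnF-Glu", "left", m=1.35, b=3.95))
    detail_rows = []
    for sigma_p in sigma_p_values:
        for model_no in range(n_models):
            model_seed = _kernel_seed(seed, 3, int(round(sigma_p * 1000)), model_no)
            perturbed = perturb_weights(net, float(sigma_p), model_seed)
            try:
                diagram = bifurcation_sweep(
                    perturbed,
                    stimulation,
                    n_steps=n_steps,
                    chunk_s=chunk_s,
                    max_s=max_s,
                    dt=dt,
                    sigma_noise=sigma_noise,
                    seed=model_seed,
                )
                outcome = _classify_model(diagram)
            except IntegrationError:
                outcome = "unstable"
            detail_rows.append(
                {"sigma_p": float(sigma_p), "model": model_no, "outcome": outcome}
            )
            if progress is not None:
                progress(detail_rows[-1])
    details = pd.DataFrame(detail_rows)
    table = (
        details.assign(count=1)
        .pivot_table(
            index="sigma_p", columns="outcome", values="count", aggfunc="sum", fill_value=0
        )
        .reindex(columns=["retains-all-gaits", "loses-gaits", "unstable"], fill_value=0)
        .div(n_models)
        .reset_index()
    )
    return RobustnessReport(table=table, n_models=n_models, n_steps=n_steps, details=details)


# ---------------------------------------------------------------------------
# Rhythm-generator calibration
# ---------------------------------------------------------------------------


def build_isolated_center(
    nap: NaPParams | None = None, synapse: SynapseParams | None = None
) -> Network:
    """A single isolated flexor-centre population under direct drive."""
    from .connectome import RG_C, RG_E_L, RG_G_L

    spec = PopulationSpec(
        name="RG-F",
        side="left",
        compartment="spinal-hind",
        girdle="hind",
        dynamics_class="nap-oscillatory",
        C=RG_C,
        g_l=RG_G_L,
        e_l=RG_E_L,
        nap=nap or NaPParams(),
    )
    return Network(
        populations={spec.key: spec},
        connections=[],
        constant_drives={},
        stimulable=("RG-F",),
        synapse=synapse or SynapseParams(),
    )


def center_frequency(
    net: Network, drive: float, duration_s: float = 8.0, discard_s: float = 3.0,
    dt: float = 0.1,
) -> float:
    """Oscillation frequency (Hz) of an isolated centre at a drive; nan if none."""
    key = net.order[0]
    protocol = Protocol(
        stimulations=(),
        extra_drives={key: float(drive)},
        sigma_noise=0.0,
        duration=duration_s,
        dt=dt,
    )
    result = integrate(net, protocol)
    mask = result.time >= discard_s * 1000.0
    trace = result.f[mask, 0]
    if trace.max() - trace.min() < 0.05:
        return np.nan
    onsets = gait_analysis.detect_onsets(trace, dt=RECORD_DT)
    freqs = gait_analysis.cycle_frequency(onsets)
    if freqs.size < 3:
        return np.nan
    return float(np.mean(freqs[-3:]))


@dataclass
class CalibrationReport:
    """Outcome of the rhythm-generator frequency calibration."""

    nap: NaPParams | None
    feasible: bool
    frequency_curve: pd.DataFrame  # drive -> frequency for the chosen parameters
    message: str


def calibrate_rg_center(
    target_range: tuple[float, float] = (2.0, 12.0),
    drive_range: tuple[float, float] = (0.0, 1.2),
    g_nap_grid=None,
    tau_grid=None,
    n_drives: int = 13,
    base_nap: NaPParams | None = None,
    tolerance: float = 0.5,
) -> CalibrationReport:
    """Search g_NaP and tau_max so an isolated flexor centre spans the target band.

    Over a grid of (g_NaP, tau_max) candidates the isolated-centre
    frequency-drive curve is computed on ``n_drives`` points across
    ``drive_range``; a candidate is feasible when the curve is monotonically
    non-decreasing (0.1 Hz ripple allowed) and its end frequencies bracket
    the target range within ``tolerance`` Hz.  The feasible candidate with
    the smallest end-point mismatch wins.  Deterministic given the grids.
    """
    lo, hi = target_range
    if not (0.0 < lo < hi <= 20.0):
        raise InvalidParameterError("target range must lie within (0, 20] Hz")
    base = base_nap or NaPParams()
    g_nap_grid = [base.g_nap] if g_nap_grid is None else list(g_nap_grid)
    tau_grid = [base.tau_max] if tau_grid is None else list(tau_grid)
    drives = np.linspace(drive_range[0], drive_range[1], n_drives)
    best = None
    for g_nap in g_nap_grid:
        for tau_max in tau_grid:
            nap = replace(base, g_nap=float(g_nap), tau_max=float(tau_max))
            net = build_isolated_center(nap)
            freqs = np.array([center_frequency(net, d) for d in drives])
            osc = ~np.isnan(freqs)
            if osc.sum() < 3:
                continue
            f_osc = freqs[osc]
            if np.any(np.diff(f_osc) < -0.1):
                continue
            mismatch = abs(f_osc.min() - lo) + abs(f_osc.max() - hi)
            if best is None or mismatch < best[0]:
                best = (mismatch, nap, pd.DataFrame({"drive": drives, "frequency_hz": freqs}))
    if best is None:
        return CalibrationReport(
            nap=None,
            feasible=False,
            frequency_curve=pd.DataFrame(columns=["drive", "frequency_hz"]),
            message="no candidate produced a monotone oscillatory frequency-drive curve",
        )
    mismatch, nap, curve = best
    feasible = mismatch <= 2 * tolerance
    message = (
        f"calibrated g_NaP = {nap.g_nap} nS, tau_max = {nap.tau_max} ms "
        f"(end-point mismatch {mismatch:.2f} Hz)"
        if feasible
        else f"best candidate misses the target ends by {mismatch:.2f} Hz"
    )
    return CalibrationReport(nap=nap if feasible else None, feasible=feasible, frequency_curve=curve, message=message)
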