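"""Stochastic Euler integration of the coupled QIF network.

The membrane potential of neuron i obeys

    tau_m dV_i/dt = V_i^2 + eta_i + ge*Se_i + ghi*Shi_i + gai*Sai_i
                    + I_i(t) + xi_i(t)

with per-neuron excitabilities eta_i ~ N(0, (pi*tau0)^2), a Gaussian noise
term xi and three exponentially decaying synaptic drives, one per
pre-synaptic class, which jump by w_ij/N_q whenever pre-synaptic neuron j of
class q fires. A spike is registered when V crosses the numerical threshold
Vp; the firing time is corrected to t + tau_m/V (the residual time to reach
+infinity), the neuron is reset to Vr and held there for 2*tau_m/V (the time
to diverge from Vp and to return to Vr from -infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import CLASS_AI, CLASS_E, CLASS_HI, NetworkParams, STDPParams
from .plasticity import apply_spike_plasticity

__all__ = [
    "NetworkState",
    "WeightMatrix",
    "SimulationResult",
    "free_firing_rate",
    "init_network",
    "step",
    "update_synaptic_drive",
    "run_simulation",
]


@dataclass
class WeightMatrix:
    """Signed plastic coupling matrix with Dale-sign class bounds.

    ``w[i, j]`` is the coupling from pre-synaptic j to post-synaptic i.
    Excitatory columns live in [0, 1], inhibitory columns in [-1, 0];
    the diagonal and masked-out entries are exactly 0.
    """

    w: np.ndarray
    class_of: np.ndarray
    mask: np.ndarray

    def validate(self) -> None:
        N = self.w.shape[0]
        if self.w.shape != (N, N) or self.mask.shape != (N, N):
            raise ValueError("weight/mask shape mismatch")
        if self.class_of.shape != (N,):
            raise ValueError("class vector length mismatch")
        if np.any(np.diagonal(self.mask)):
            raise ValueError("mask must have zero diagonal (no autapses)")
        if np.any(self.w[~self.mask] != 0.0):
            raise ValueError("masked-out entries must be exactly 0")
        exc = self.class_of == CLASS_E
        if np.any(self.w[:, exc] < 0) or np.any(self.w[:, exc] > 1):
            raise ValueError("excitatory weights must lie in [0, 1]")
        if np.any(self.w[:, ~exc] > 0) or np.any(self.w[:, ~exc] < -1):
            raise ValueError("inhibitory weights must lie in [-1, 0]")

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy(), self.class_of.copy(), self.mask.copy())


@dataclass
class NetworkState:
    """Dynamical state of the network at time ``t``."""

    V: np.ndarray
    refractory_until: np.ndarray
    S_e: np.ndarray
    S_hi: np.ndarray
    S_ai: np.ndarray
    last_spike: np.ndarray
    eta: np.ndarray
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.V.copy(), self.refractory_until.copy(), self.S_e.copy(),
            self.S_hi.copy(), self.S_ai.copy(), self.last_spike.copy(),
            self.eta.copy(), self.t,
        )


@dataclass
class SimulationResult:
    """Raster, weight snapshots and final state of one simulation run."""

    spike_times: np.ndarray
    spike_ids: np.ndarray
    snapshots: dict[float, np.ndarray]
    state: NetworkState
    weights: WeightMatrix
    duration: float
    drive_times: np.ndarray | None = None
    drive_series: np.ndarray | None = None  # (n_rec, 3, N): S_e, S_hi, S_ai

    @property
    def raster(self) -> np.ndarray:
        """(n_spikes, 2) array of (time, neuron id), sorted by time."""
        return np.column_stack([self.spike_times, self.spike_ids.astype(float)])


def free_firing_rate(eta, I=0.0, tau_m: float = 0.02):
    """Firing rate (Hz) of an uncoupled noise-free QIF neuron.

    For total drive a = eta + I > 0 the neuron oscillates with period
    pi*tau_m/sqrt(a); for a <= 0 it is excitable and silent.
    """
    a = np.asarray(eta, dtype=float) + np.asarray(I, dtype=float)
    out = np.where(a > 0, np.sqrt(np.maximum(a, 0.0)) / (math.pi * tau_m), 0.0)
    return out if out.ndim else float(out)


def _build_mask(params: NetworkParams, rng: np.random.Generator) -> np.ndarray:
    N = params.N
    if params.connection_prob is None:
        mask = np.ones((N, N), dtype=bool)
    else:
        mask = rng.random((N, N)) < params.connection_prob
    np.fill_diagonal(mask, False)
    return mask


def init_network(
    params: NetworkParams,
    initial_weight_spec="small-random",
    seed=None,
    *,
    small_weight_scale: float = 0.1,
) -> tuple[NetworkState, WeightMatrix]:
    """Draw excitabilities, initial potentials, mask and initial weights.

    ``initial_weight_spec`` is either the string ``"small-random"`` (uniform
    weights in [0, scale] for excitatory and [-scale, 0] for inhibitory
    pre-synaptic neurons), the string ``"zero"``, or an explicit (N, N)
    matrix respecting the class bounds. ``seed`` may be an int or a
    ``numpy.random.Generator``; draw order is eta, V, mask, weights.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        params.seed if seed is None else seed
    )
    N = params.N
    eta = rng.normal(0.0, params.eta_sigma, N)
    V = rng.uniform(-1.0, 0.0, N)  # near the low-|V| rest/slow region
    mask = _build_mask(params, rng)
    class_of = params.class_of
    exc_col = class_of == CLASS_E

    if isinstance(initial_weight_spec, str):
        if initial_weight_spec == "small-random":
            w = rng.uniform(0.0, small_weight_scale, (N, N))
            w[:, ~exc_col] *= -1.0
        elif initial_weight_spec == "zero":
            w = np.zeros((N, N))
        else:
            raise ValueError(f"unknown weight spec {initial_weight_spec!r}")
    else:
        w = np.array(initial_weight_spec, dtype=float)
        if w.shape != (N, N):
            raise ValueError(f"weight matrix shape {w.shape} != ({N}, {N})")
        w = w.copy()
    w[~mask] = 0.0

    weights = WeightMatrix(w=w, class_of=class_of, mask=mask)
    weights.validate()
    state = NetworkState(
        V=V,
        refractory_until=np.full(N, -np.inf),
        S_e=np.zeros(N),
        S_hi=np.zeros(N),
        S_ai=np.zeros(N),
        last_spike=np.full(N, -np.inf),
        eta=eta,
    )
    return state, weights


def update_synaptic_drive(
    state: NetworkState,
    spikes: np.ndarray,
    weights: WeightMatrix,
    params: NetworkParams,
) -> None:
    """One Euler step of the synaptic drives: exponential decay plus the
    per-spike jumps w[:, j]/N_q from this step's pre-synaptic spikes."""
    state.S_e += -state.S_e * (params.dt / params.tau_de)
    state.S_hi += -state.S_hi * (params.dt / params.tau_di)
    state.S_ai += -state.S_ai * (params.dt / params.tau_di)
    _add_spike_increments(state, np.asarray(spikes, dtype=np.intp), weights, params)


def _add_spike_increments(
    state: NetworkState, spikes: np.ndarray, weights: WeightMatrix, params: NetworkParams
) -> None:
    if spikes.size == 0:
        return
    cls = weights.class_of[spikes]
    for cid, S, Nq in (
        (CLASS_E, state.S_e, params.Ne),
        (CLASS_HI, state.S_hi, params.Nhi),
        (CLASS_AI, state.S_ai, params.Nai),
    ):
        ids = spikes[cls == cid]
        if ids.size:
            S += weights.w[:, ids].sum(axis=1) / Nq


def step(
    state: NetworkState,
    weights: WeightMatrix,
    stimulus_current,
    params: NetworkParams,
    rng: np.random.Generator,
    stdp: dict[str, STDPParams] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the network by one Euler step of length ``params.dt``.

    Returns ``(spike_ids, spike_times)`` for the threshold crossings of this
    step, with times corrected by tau_m/V. Mutates ``state`` (and the
    weights, if ``stdp`` is given). ``stimulus_current`` is a scalar or
    per-neuron vector of DC input.
    """
    dt, tau_m = params.dt, params.tau_m
    t_new = state.t + dt
    xi = rng.normal(0.0, params.noise_step_sigma(), params.N)

    active = state.refractory_until <= state.t
    V = state.V
    V[~active] = params.Vr
    drive = (
        V * V
        + state.eta
        + params.ge * state.S_e
        + params.ghi * state.S_hi
        + params.gai * state.S_ai
        + stimulus_current
    )
    V[active] += (dt / tau_m) * drive[active] + xi[active]
    if not np.all(np.isfinite(V)):
        bad = np.nonzero(~np.isfinite(V))[0]
        raise FloatingPointError(
            f"membrane potential diverged at t={t_new:.4f}s for neurons {bad[:5]}"
        )

    crossed = active & (V >= params.Vp)
    spike_ids = np.nonzero(crossed)[0]
    if spike_ids.size:
        Vc = V[spike_ids]
        spike_times = t_new + tau_m / Vc
        state.refractory_until[spike_ids] = (
            t_new + params.refractory_scale * 2.0 * tau_m / Vc
        )
        V[spike_ids] = params.Vr
    else:
        spike_times = np.empty(0)

    update_synaptic_drive(state, spike_ids, weights, params)
    if stdp is not None and spike_ids.size:
        apply_spike_plasticity(
            weights.w, weights.mask, weights.class_of,
            state.last_spike, spike_ids, spike_times, stdp,
        )
    else:
        state.last_spike[spike_ids] = spike_times
    state.t = t_new
    return spike_ids, spike_times


def run_simulation(
    params: NetworkParams,
    weights: WeightMatrix,
    protocol=None,
    duration: float = 1.0,
    *,
    stdp: dict[str, STDPParams] | None = None,
    plasticity_on: bool = True,
    seed=None,
    state: NetworkState | None = None,
    snapshot_times=(),
    record_drives_every: float | None = None,
) -> SimulationResult:
    """Integrate the full network for ``duration`` seconds.

    ``protocol`` is None (resting dynamics) or an object with a
    ``stim_intervals()`` method / an iterable of ``(t_on, t_off, ids,
    amplitude)`` stimulation intervals; intervals must not overlap and must
    end within ``duration``. Weight snapshots (copies) are taken at the
    requested times; the run is bitwise reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        params.seed if seed is None else seed
    )
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if state is None:
        state, _ = init_network(params, "zero", rng)
        # weights come from the caller; only eta/V were needed here
    weights.validate()
    if not plasticity_on:
        stdp = None

    intervals = []
    if protocol is not None:
        it = protocol.stim_intervals() if hasattr(protocol, "stim_intervals") else protocol
        for t_on, t_off, ids, amp in it:
            if t_off > duration + 1e-9:
                raise ValueError(
                    f"stimulation interval ending at {t_off}s exceeds duration {duration}s"
                )
            intervals.append((float(t_on), float(t_off), np.asarray(ids, dtype=np.intp), float(amp)))
        intervals.sort(key=lambda iv: iv[0])

    n_steps = round(duration / params.dt)
    t0 = state.t
    snap_steps = {max(0, round((ts - t0) / params.dt)): float(ts) for ts in snapshot_times}
    rec_every = (
        max(1, round(record_drives_every / params.dt)) if record_drives_every else None
    )

    stim = np.zeros(params.N)
    next_iv = 0
    current_iv = None
    all_ids: list[np.ndarray] = []
    all_times: list[np.ndarray] = []
    snapshots: dict[float, np.ndarray] = {}
    drive_t: list[float] = []
    drive_s: list[np.ndarray] = []

    for k in range(n_steps):
        if k in snap_steps:
            snapshots[snap_steps[k]] = weights.w.copy()
        t = t0 + k * params.dt
        # piecewise-constant square-pulse stimulus
        if current_iv is not None and t >= current_iv[1] - 1e-12:
            stim[current_iv[2]] = 0.0
            current_iv = None
        if current_iv is None and next_iv < len(intervals) and t >= intervals[next_iv][0] - 1e-12:
            current_iv = intervals[next_iv]
            stim[current_iv[2]] = current_iv[3]
            next_iv += 1
        ids, times = step(state, weights, stim, params, rng, stdp=stdp)
        if ids.size:
            all_ids.append(ids)
            all_times.append(times)
        if rec_every is not None and k % rec_every == 0:
            drive_t.append(state.t)
            drive_s.append(np.stack([state.S_e, state.S_hi, state.S_ai]).copy())

    end_t = t0 + duration
    for k, ts in snap_steps.items():
        if k >= n_steps and ts not in snapshots:
            snapshots[ts] = weights.w.copy()

    if all_ids:
        spike_ids = np.concatenate(all_ids)
        spike_times = np.concatenate(all_times)
        order = np.argsort(spike_times, kind="stable")
        spike_ids, spike_times = spike_ids[order], spike_times[order]
    else:
        spike_ids = np.empty(0, dtype=np.intp)
        spike_times = np.empty(0)

    return SimulationResult(
        spike_times=spike_times,
        spike_ids=spike_ids,
        snapshots=snapshots,
        state=state,
        weights=weights,
        duration=end_t,
        drive_times=np.asarray(drive_t) if drive_t else None,
        drive_series=np.stack(drive_s) if drive_s else None,
    )
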