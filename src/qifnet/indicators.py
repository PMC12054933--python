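"""Microscopic and macroscopic observables of the network dynamics.

Implements windowed instantaneous firing rates, the coefficient of
variation of inter-spike intervals, interpolated spike phases and the
Kuramoto order parameter, the mean weight-change rate K(t), a sliding-window
detector of spontaneous memory recalls, the stable/unstable classification
used in capacity scans, block statistics of modular weight matrices, and a
Poisson-pair estimate of the time needed to forget one recall's
reinforcement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import STDPParams
from .plasticity import weight_delta

__all__ = [
    "RateSeries",
    "RecallEvent",
    "StabilityVerdict",
    "instantaneous_rate",
    "coefficient_of_variation",
    "spike_phases",
    "kuramoto",
    "kuramoto_series",
    "weight_change_rate",
    "detect_recalls",
    "classify_stability",
    "module_weight_stats",
    "forgetting_time_estimate",
]

#: default sliding-window length for recall detection [s]
RECALL_WINDOW = 0.2
#: default fraction of a module's excitatory neurons that must spike within
#: the window for a recall to be declared
RECALL_THRESHOLD = 0.5
#: asynchrony ceilings used by the stability classification
ASYNC_R_CEILING = 0.5
ASYNC_RATE_CEILING = 20.0


@dataclass
class RateSeries:
    """Per-neuron windowed firing rates on a regular grid of window starts."""

    times: np.ndarray            # (n_win,) window start times
    rates: np.ndarray            # (n_win, N) rates in Hz
    window: float

    def population_rate(self, ids=None) -> np.ndarray:
        """Mean rate over a neuron subset (all neurons by default)."""
        r = self.rates if ids is None else self.rates[:, np.asarray(ids, dtype=np.intp)]
        return r.mean(axis=1)


def _split_by_neuron(spike_times, spike_ids, N):
    trains = [np.empty(0)] * N
    if len(spike_times) == 0:
        return trains
    ids = np.asarray(spike_ids, dtype=np.intp)
    times = np.asarray(spike_times, dtype=float)
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    bounds = np.searchsorted(ids, np.arange(N + 1))
    for j in range(N):
        trains[j] = times[bounds[j]:bounds[j + 1]]
    return trains


def instantaneous_rate(
    spike_times, spike_ids, N: int,
    window: float = 0.05,
    t_start: float | None = None,
    t_end: float | None = None,
) -> RateSeries:
    """Windowed spike-count rates nu_j(t) = n_spikes[t, t+T] / T (Hz).

    Non-overlapping windows of length ``window`` (default 0.05 s) covering
    [t_start, t_end). An empty raster gives all-zero rates.
    """
    times = np.asarray(spike_times, dtype=float)
    ids = np.asarray(spike_ids, dtype=np.intp)
    if t_start is None:
        t_start = 0.0 if times.size == 0 else float(times.min())
    if t_end is None:
        t_end = t_start + window if times.size == 0 else float(times.max()) + 1e-9
    n_win = max(1, int(math.ceil((t_end - t_start) / window)))
    grid = t_start + window * np.arange(n_win)
    rates = np.zeros((n_win, N))
    if times.size:
        keep = (times >= t_start) & (times < t_start + n_win * window)
        wi = ((times[keep] - t_start) / window).astype(np.intp)
        np.add.at(rates, (wi, ids[keep]), 1.0 / window)
    return RateSeries(times=grid, rates=rates, window=window)


def coefficient_of_variation(spike_times, spike_ids, N: int, min_spikes: int = 3):
    """Per-neuron CV of inter-spike intervals: sigma_ISI / mean_ISI.

    Neurons with fewer than ``min_spikes`` spikes (default 3, i.e. fewer
    than two ISIs) get NaN ("undefined"). A perfectly periodic train has
    CV = 0; a Poisson process CV = 1.
    """
    out = np.full(N, np.nan)
    for j, train in enumerate(_split_by_neuron(spike_times, spike_ids, N)):
        if train.size >= max(min_spikes, 2):
            isi = np.diff(train)
            mu = isi.mean()
            if mu > 0:
                out[j] = isi.std() / mu
    return out


def spike_phases(spike_times, spike_ids, N: int, t_grid) -> np.ndarray:
    """Interpolated spike phases theta_j(t) on a grid of times.

    Between consecutive spikes t_n <= t <= t_{n+1} of neuron j the phase
    grows linearly from 0 to 2*pi. Outside a neuron's first/last spike the
    phase is undefined and returned as NaN; such neurons are excluded from
    the order parameter at those times.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    phases = np.full((t_grid.size, N), np.nan)
    for j, train in enumerate(_split_by_neuron(spike_times, spike_ids, N)):
        if train.size < 2:
            continue
        k = np.searchsorted(train, t_grid, side="right") - 1
        ok = (k >= 0) & (k < train.size - 1)
        kk = k[ok]
        phases[ok, j] = (
            2.0 * math.pi * (t_grid[ok] - train[kk]) / (train[kk + 1] - train[kk])
        )
    return phases


def kuramoto(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modulus R(t) and phase Phi(t) of the Kuramoto order parameter.

    ``phases`` is (n_times, N) with NaN for undefined entries; neurons with
    undefined phase are excluded at that time. Times with no valid neuron
    give NaN.
    """
    z = np.exp(1j * phases)
    valid = ~np.isnan(phases)
    n = valid.sum(axis=1)
    z = np.where(valid, z, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, z / np.maximum(n, 1), np.nan + 0j)
    return np.abs(mean), np.angle(mean)


def kuramoto_series(spike_times, spike_ids, N: int, t_grid, ids=None):
    """R(t) on a time grid, optionally restricted to a neuron subset."""
    phases = spike_phases(spike_times, spike_ids, N, t_grid)
    if ids is not None:
        phases = phases[:, np.asarray(ids, dtype=np.intp)]
    R, _ = kuramoto(phases)
    return R


def weight_change_rate(snapshots, mask: np.ndarray | None = None):
    """Mean weight-change rate K between consecutive weight snapshots.

    ``snapshots`` is a sequence of (time, matrix) pairs (or a dict keyed by
    time). K(t) = sum_{i != j} [w_ij(t+dt) - w_ij(t)] / dt / (N*(N-1));
    positive for net potentiation. Returns (pair start times, K values).
    """
    if isinstance(snapshots, dict):
        snapshots = sorted(snapshots.items())
    else:
        snapshots = sorted(snapshots, key=lambda p: p[0])
    if len(snapshots) < 2:
        return np.empty(0), np.empty(0)
    times, Ks = [], []
    for (t0, w0), (t1, w1) in zip(snapshots[:-1], snapshots[1:]):
        N = w0.shape[0]
        diff = (w1 - w0) if mask is None else np.where(mask, w1 - w0, 0.0)
        np.fill_diagonal(diff, 0.0)
        Ks.append(diff.sum() / (t1 - t0) / (N * (N - 1)))
        times.append(t0)
    return np.asarray(times), np.asarray(Ks)


@dataclass
class RecallEvent:
    """One detected transient-synchrony event."""

    start: float
    end: float
    module: int | str            # module index, "joint", or "hubs"
    participants: np.ndarray
    peak_fraction: float
    hubs_active: bool = False


def detect_recalls(
    spike_times, spike_ids, assignment,
    window: float = RECALL_WINDOW,
    threshold: float = RECALL_THRESHOLD,
    stride: float | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> list[RecallEvent]:
    """Sliding-window detection of spontaneous memory recalls.

    A window is attributed to module m when the fraction of m's (exclusive)
    excitatory neurons spiking inside it reaches ``threshold`` while every
    other module stays below; windows where two or more modules cross the
    threshold yield a single "joint" event. If the assignment declares an
    overlap (hub) set, windows where only the hubs cross the threshold are
    labelled "hubs", and attributed events carry a ``hubs_active`` flag.
    Overlapping windows with the same label are merged into one event.
    """
    times = np.asarray(spike_times, dtype=float)
    ids = np.asarray(spike_ids, dtype=np.intp)
    if stride is None:
        stride = window / 4.0
    if t_start is None:
        t_start = 0.0 if times.size == 0 else float(times.min())
    if t_end is None:
        t_end = t_start if times.size == 0 else float(times.max())
    if t_end <= t_start:
        return []

    hubs = np.asarray(getattr(assignment, "overlap", np.empty(0, dtype=np.intp)),
                      dtype=np.intp)
    hub_set = set(hubs.tolist())
    groups = []  # exclusive excitatory sets per module
    for exc in assignment.exc:
        excl = np.asarray([i for i in exc if i not in hub_set], dtype=np.intp)
        groups.append(excl)

    n_win = int(math.floor((t_end - t_start - window) / stride)) + 1
    n_win = max(n_win, 1)
    events: list[RecallEvent] = []
    current: RecallEvent | None = None

    order = np.argsort(times, kind="stable")
    times, ids = times[order], ids[order]

    for k in range(n_win):
        w0 = t_start + k * stride
        w1 = w0 + window
        lo, hi_ = np.searchsorted(times, (w0, w1))
        win_ids = ids[lo:hi_]
        uniq = np.unique(win_ids)
        uniq_set = set(uniq.tolist())
        fracs = np.array([
            (len(uniq_set & set(g.tolist())) / len(g)) if len(g) else 0.0
            for g in groups
        ])
        hub_frac = (len(uniq_set & hub_set) / len(hub_set)) if hub_set else 0.0
        above = np.nonzero(fracs >= threshold)[0]

        label: int | str | None = None
        peak = 0.0
        participants = np.empty(0, dtype=np.intp)
        hubs_active = hub_frac >= threshold
        if above.size == 1:
            label = int(above[0])
            peak = float(fracs[label])
            member = np.isin(uniq, np.concatenate([groups[label], hubs]) if hub_set
                             else groups[label])
            participants = uniq[member]
        elif above.size >= 2:
            label = "joint"
            peak = float(fracs.max())
            participants = uniq
        elif hubs_active:
            label = "hubs"
            peak = hub_frac
            participants = uniq[np.isin(uniq, hubs)]

        if label is None:
            current = None
            continue
        if current is not None and current.module == label and w0 <= current.end:
            current.end = w1
            current.peak_fraction = max(current.peak_fraction, peak)
            current.participants = np.union1d(current.participants, participants)
            current.hubs_active = current.hubs_active or hubs_active
        else:
            current = RecallEvent(
                start=w0, end=w1, module=label,
                participants=participants, peak_fraction=peak,
                hubs_active=hubs_active,
            )
            events.append(current)
    return events


@dataclass
class StabilityVerdict:
    """Stable/unstable classification of a stored-memory configuration."""

    stable: bool
    recall_counts: dict[int, int]
    asynchronous: bool
    median_R: float
    mean_rate: float
    participation_threshold: float = RECALL_THRESHOLD


def classify_stability(
    spike_times, spike_ids, N: int, assignment,
    recalls: list[RecallEvent] | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
    r_ceiling: float = ASYNC_R_CEILING,
    rate_ceiling: float = ASYNC_RATE_CEILING,
    threshold: float = RECALL_THRESHOLD,
) -> StabilityVerdict:
    """Stable iff every module shows >= 1 spontaneous recall and the
    background stays asynchronous (time-median network R below
    ``r_ceiling``, population mean rate below ``rate_ceiling`` Hz)."""
    times = np.asarray(spike_times, dtype=float)
    if t_start is None:
        t_start = 0.0 if times.size == 0 else float(times.min())
    if t_end is None:
        t_end = t_start if times.size == 0 else float(times.max())
    if recalls is None:
        recalls = detect_recalls(times, spike_ids, assignment,
                                 threshold=threshold, t_start=t_start, t_end=t_end)
    counts = {m: 0 for m in range(len(assignment.exc))}
    for ev in recalls:
        if isinstance(ev.module, int):
            counts[ev.module] += 1

    span = max(t_end - t_start, 1e-9)
    mean_rate = times.size / span / N
    grid = np.linspace(t_start, t_end, max(int(span / 0.05), 2))
    R = kuramoto_series(times, spike_ids, N, grid)
    median_R = float(np.nanmedian(R)) if np.any(~np.isnan(R)) else 0.0
    asynchronous = (median_R < r_ceiling) and (mean_rate < rate_ceiling)
    stable = asynchronous and all(c >= 1 for c in counts.values())
    return StabilityVerdict(
        stable=stable, recall_counts=counts, asynchronous=asynchronous,
        median_R=median_R, mean_rate=mean_rate, participation_threshold=threshold,
    )


def module_weight_stats(w: np.ndarray, assignment) -> dict[str, dict[str, float]]:
    """Mean intra- and inter-module weights per connection class.

    Classes are keyed by pre-group -> post-type: "E-E", "E-I", "H-E",
    "H-I", "A-E", "A-I" (H = Hebbian inhibitory, A = anti-Hebbian
    inhibitory; I pools Hebbian and anti-Hebbian post-synaptic neurons).
    The diagonal is excluded. Neurons not covered by the assignment are
    ignored.
    """
    M = len(assignment.exc)
    module_of = {}
    for m in range(M):
        for grp in (assignment.exc[m], assignment.hi[m], assignment.ai[m]):
            for i in np.asarray(grp, dtype=np.intp):
                module_of.setdefault(int(i), []).append(m)

    pre_groups = {
        "E": np.concatenate([np.asarray(g, dtype=np.intp) for g in assignment.exc])
        if M else np.empty(0, dtype=np.intp),
        "H": np.concatenate([np.asarray(g, dtype=np.intp) for g in assignment.hi])
        if M else np.empty(0, dtype=np.intp),
        "A": np.concatenate([np.asarray(g, dtype=np.intp) for g in assignment.ai])
        if M else np.empty(0, dtype=np.intp),
    }
    post_groups = {
        "E": np.unique(pre_groups["E"]),
        "I": np.unique(np.concatenate([pre_groups["H"], pre_groups["A"]])),
    }

    def same_module(i, j):
        return bool(set(module_of.get(int(i), ())) & set(module_of.get(int(j), ())))

    out: dict[str, dict[str, float]] = {}
    for pre_name, pre_ids in pre_groups.items():
        pre_ids = np.unique(pre_ids)
        for post_name, post_ids in post_groups.items():
            intra, inter = [], []
            for j in pre_ids:
                for i in post_ids:
                    if i == j:
                        continue
                    (intra if same_module(i, j) else inter).append(w[i, j])
            out[f"{pre_name}-{post_name}"] = {
                "intra": float(np.mean(intra)) if intra else 0.0,
                "inter": float(np.mean(inter)) if inter else 0.0,
            }
    return out


def forgetting_time_estimate(
    stdp_params: STDPParams,
    background_rate: float = 2.0,
    recall_boost: float | None = None,
    *,
    w0: float = 0.5,
    sim_time: float = 2000.0,
    n_recalls: int = 200,
    spikes_per_recall: int = 2,
    recall_window: float = RECALL_WINDOW,
    recall_jitter: float = 0.0025,
    seed: int = 12345,
) -> float:
    """Seconds of asynchronous background firing needed to erase the
    synaptic reinforcement contributed by one spontaneous recall.

    Both ingredients are measured by simulation of a single excitatory
    synapse held at ``w0`` (the drift and boost are evaluated at fixed
    weight so that the ratio is a rate comparison, not a trajectory):

    * the background drift is the mean weight change per second when pre-
      and post-synaptic neurons fire independent Poisson trains at
      ``background_rate`` Hz, applying the last-spike pairing rule at every
      spike of either neuron;
    * the recall boost (unless supplied) is the mean total weight change
      caused by one recall event, emulated as ``spikes_per_recall`` tightly
      synchronised volleys (cross-neuron jitter ``recall_jitter``) spread
      over ``recall_window`` seconds, on top of prior background firing.

    Returns boost / |drift|; infinite when the drift is non-negative.
    """
    rng = np.random.default_rng(seed)

    def pair_updates(pre, post, t_lo, t_hi):
        """Total gamma_l * Delta-w from last-spike pairing in [t_lo, t_hi)."""
        events = np.concatenate([pre, post])
        who = np.concatenate([np.zeros(pre.size, bool), np.ones(post.size, bool)])
        order = np.argsort(events, kind="stable")
        events, who = events[order], who[order]
        last = [-np.inf, -np.inf]  # pre, post
        total = 0.0
        for t, is_post in zip(events, who):
            partner = last[0] if is_post else last[1]
            if partner > -np.inf and t_lo <= t < t_hi:
                dt = (t - partner) if is_post else (partner - t)
                total += stdp_params.gamma_l * weight_delta(w0, dt, stdp_params)
            last[1 if is_post else 0] = t
        return total

    # background drift per second
    n_pre = rng.poisson(background_rate * sim_time)
    n_post = rng.poisson(background_rate * sim_time)
    pre = np.sort(rng.uniform(0.0, sim_time, n_pre))
    post = np.sort(rng.uniform(0.0, sim_time, n_post))
    drift = pair_updates(pre, post, 0.0, sim_time) / sim_time

    if recall_boost is None:
        boosts = []
        centers = (
            np.arange(spikes_per_recall) * recall_window / max(spikes_per_recall, 1)
        )
        for _ in range(n_recalls):
            # prior background spike for each neuron, then the volleys
            t0 = -rng.exponential(1.0 / background_rate, 2) - 1.0
            pre_r = np.sort(np.concatenate(
                [[t0[0]], centers + rng.normal(0.0, recall_jitter, centers.size)]))
            post_r = np.sort(np.concatenate(
                [[t0[1]], centers + rng.normal(0.0, recall_jitter, centers.size)]))
            boosts.append(pair_updates(pre_r, post_r, -0.5, recall_window + 0.5))
        recall_boost = float(np.mean(boosts))

    if drift >= 0:
        return math.inf
    return float(recall_boost / abs(drift))
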