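"""Experimental designs: stimulation schedules, template matrices,
perturbations, training/recovery runs, capacity scans and overlap (hub)
experiments.

The canonical training protocol is: 5 s of rest, then a learning phase of
one-second epochs (800 ms of DC stimulation of one memory's population
followed by 200 ms of relaxation, repeated 35 times with the stimulated
memory alternating randomly or strictly), then 20 s of free consolidation.
Plasticity stays on throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import NetworkParams, STDPParams, default_stdp_params
from .network import (NetworkState, SimulationResult, WeightMatrix,
                      init_network, run_simulation)
from . import indicators

__all__ = [
    "PopulationAssignment",
    "StimEpoch",
    "Protocol",
    "MatrixTemplate",
    "ExperimentConfig",
    "ExperimentResult",
    "make_assignment",
    "build_stimulus_schedule",
    "build_modular_matrix",
    "randomize_weight_subset",
    "training_experiment",
    "recovery_experiment",
    "capacity_scan",
    "max_feasible_memories",
    "overlap_experiment",
    "find_hubs",
]


@dataclass
class PopulationAssignment:
    """Per-memory neuron index sets (excitatory, Hebbian-I, anti-Hebbian-I).

    ``overlap`` lists excitatory neurons shared between all memories (hub
    candidates); inhibitory sets are disjoint.
    """

    exc: list[np.ndarray]
    hi: list[np.ndarray]
    ai: list[np.ndarray]
    overlap: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def M(self) -> int:
        return len(self.exc)

    def targets(self, m: int) -> np.ndarray:
        """All neurons targeted by the stimulus of memory ``m``."""
        return np.unique(np.concatenate([self.exc[m], self.hi[m], self.ai[m]]))


def make_assignment(
    params: NetworkParams, M: int,
    overlap: int = 0,
    untrained_fraction: float = 0.0,
    allow_empty: bool = False,
) -> PopulationAssignment:
    """Split the three class blocks into M contiguous per-memory pools.

    ``overlap`` shared excitatory neurons (taken from the top of the
    excitatory block) are added to every memory's target set. With
    ``untrained_fraction`` > 0, that fraction of each class block (from the
    top) is left out of every memory.
    """
    if M < 1:
        raise ValueError("M must be >= 1")

    def split(ids: np.ndarray) -> list[np.ndarray]:
        n_use = int(round(len(ids) * (1.0 - untrained_fraction)))
        return [np.asarray(part, dtype=np.intp)
                for part in np.array_split(ids[:n_use], M)]

    e_ids = np.arange(params.Ne, dtype=np.intp)
    if overlap:
        if overlap >= params.Ne:
            raise ValueError("overlap must be smaller than Ne")
        shared = e_ids[params.Ne - overlap:]
        exc = [np.concatenate([part, shared])
               for part in split(e_ids[: params.Ne - overlap])]
    else:
        shared = np.empty(0, dtype=np.intp)
        exc = split(e_ids)
    hi = split(np.arange(params.Ne, params.Ne + params.Nhi, dtype=np.intp))
    ai = split(np.arange(params.Ne + params.Nhi, params.N, dtype=np.intp))
    if not allow_empty:
        # each memory needs a pool from every class the network contains
        # (regimes with a single inhibitory kind have one class absent)
        for m in range(M):
            bad = (len(exc[m]) == 0
                   or (params.Nhi > 0 and len(hi[m]) == 0)
                   or (params.Nai > 0 and len(ai[m]) == 0))
            if bad:
                raise ValueError(
                    f"memory {m} has an empty pool; each memory needs at least "
                    "one neuron of every class present in the network"
                )
    return PopulationAssignment(exc=exc, hi=hi, ai=ai, overlap=shared)


@dataclass
class StimEpoch:
    """One 1 s stimulation epoch: DC on for ``stim_dur``, then relaxation."""

    memory: int
    onset: float
    stim_dur: float
    relax: float
    target_ids: np.ndarray
    amplitude: float

    @property
    def length(self) -> float:
        return self.stim_dur + self.relax


@dataclass
class Protocol:
    """Timed schedule of stimulation epochs over declared populations."""

    epochs: list[StimEpoch]

    def stim_intervals(self):
        for ep in self.epochs:
            yield ep.onset, ep.onset + ep.stim_dur, ep.target_ids, ep.amplitude

    @property
    def end(self) -> float:
        return max((ep.onset + ep.length for ep in self.epochs), default=0.0)


def build_stimulus_schedule(
    assignment: PopulationAssignment,
    mode: str = "random",
    n_epochs: int = 35,
    *,
    amplitude: float | None = None,
    params: NetworkParams | None = None,
    t_start: float = 0.0,
    stim_dur: float = 0.8,
    relax: float = 0.2,
    subset_fraction: float | None = None,
    amplitude_jitter: float = 0.0,
    seed=0,
) -> Protocol:
    """Build the epoch schedule for the learning phase.

    ``mode`` is "random" (uniform seeded choice of the stimulated memory,
    with the guarantee that every memory appears at least once) or "strict"
    (memories cycled in order). Options: ``subset_fraction`` stimulates a
    fresh random subset of the target population each epoch;
    ``amplitude_jitter`` multiplies the DC amplitude by U(1-j, 1+j) per
    epoch.
    """
    M = assignment.M
    if n_epochs < M:
        raise ValueError("n_epochs must be >= number of memories")
    if any(len(g) == 0 for g in assignment.exc):
        raise ValueError("empty memory set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if amplitude is None:
        amplitude = (params or NetworkParams()).stim_amplitude

    if mode == "strict":
        order = [m % M for m in range(n_epochs)]
    elif mode == "random":
        order = list(rng.integers(0, M, n_epochs))
        missing = [m for m in range(M) if m not in order]
        if missing:  # guarantee every memory is presented at least once
            slots = rng.choice(n_epochs, size=len(missing), replace=False)
            for m, s in zip(missing, slots):
                order[int(s)] = m
    else:
        raise ValueError(f"unknown alternation mode {mode!r}")

    epochs = []
    for k, m in enumerate(order):
        ids = assignment.targets(m)
        if subset_fraction is not None:
            n_sub = max(1, int(round(subset_fraction * ids.size)))
            ids = np.sort(rng.choice(ids, size=n_sub, replace=False))
        amp = amplitude
        if amplitude_jitter:
            amp *= rng.uniform(1.0 - amplitude_jitter, 1.0 + amplitude_jitter)
        epochs.append(StimEpoch(
            memory=int(m), onset=t_start + k * (stim_dur + relax),
            stim_dur=stim_dur, relax=relax, target_ids=ids, amplitude=amp,
        ))
    return Protocol(epochs=epochs)


@dataclass
class MatrixTemplate:
    """Pre-built modular weight matrix specification.

    ``style="imperfect"`` places every strong block intra-module (the
    imperfectly learned configuration: intra excitatory weights at
    ``intra_e``, intra inhibitory at ``intra_i``, all remaining entries
    drawn from a zero-mean Gaussian with sd ``inter_sigma`` truncated to the
    class sign). ``style="learned"`` mimics a post-training configuration:
    excitatory and Hebbian-inhibitory strong blocks are intra-module while
    the anti-Hebbian strong block is lateral (towards the other modules),
    matching the feedback/feed-forward architecture that training produces.
    """

    intra_e: float = 0.7
    intra_i: float = -0.7
    inter_sigma: float = 0.15
    style: str = "imperfect"

    def __post_init__(self) -> None:
        if self.style not in ("imperfect", "learned"):
            raise ValueError(f"unknown template style {self.style!r}")
        if not (0.0 <= self.intra_e <= 1.0) or not (-1.0 <= self.intra_i <= 0.0):
            raise ValueError("template weights must respect class bounds")

    @classmethod
    def trained(cls, intra: float = 0.95, inter_sigma: float = 0.05
                ) -> "MatrixTemplate":
        """Saturated post-training configuration (training drives the strong
        blocks to ~0.95-1.0 in magnitude and the rest towards 0)."""
        return cls(intra_e=intra, intra_i=-intra, inter_sigma=inter_sigma,
                   style="learned")


def build_modular_matrix(
    template: MatrixTemplate,
    params: NetworkParams,
    assignment: PopulationAssignment,
    seed=0,
    mask: np.ndarray | None = None,
) -> WeightMatrix:
    """Deterministically build a modular weight matrix from a template."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = params.N
    class_of = params.class_of
    exc_col = class_of == 0
    if mask is None:
        mask = np.ones((N, N), dtype=bool)
        np.fill_diagonal(mask, False)

    # background: truncated Gaussian of the correct sign everywhere
    w = np.abs(rng.normal(0.0, template.inter_sigma, (N, N)))
    w = np.clip(w, 0.0, 1.0)
    w[:, ~exc_col] *= -1.0

    members = [np.unique(np.concatenate([assignment.exc[m], assignment.hi[m],
                                         assignment.ai[m]]))
               for m in range(assignment.M)]
    all_members = (np.unique(np.concatenate(members)) if assignment.M
                   else np.empty(0, dtype=np.intp))
    for m in range(assignment.M):
        mem = members[m]
        sub = np.ix_(mem, mem)
        intra = np.zeros((mem.size, mem.size), dtype=bool)
        intra[:] = True
        block = w[sub]
        pre_cls = class_of[mem]
        block[:, pre_cls == 0] = template.intra_e
        block[:, pre_cls == 1] = template.intra_i
        if template.style == "imperfect":
            block[:, pre_cls == 2] = template.intra_i
        else:
            # learned: anti-Hebbian weights are lateral, weak intra-module
            block[:, pre_cls == 2] = -np.abs(
                rng.normal(0.0, template.inter_sigma, (mem.size, (pre_cls == 2).sum()))
            ).clip(0.0, 1.0)
            others = np.setdiff1d(all_members, mem)
            w[np.ix_(others, assignment.ai[m])] = template.intra_i
        w[sub] = block

    w[~mask] = 0.0
    np.fill_diagonal(w, 0.0)
    wm = WeightMatrix(w=w, class_of=class_of, mask=mask)
    wm.validate()
    return wm


_SUBSETS = ("E-out", "I-out", "all-but-EE", "none")


def randomize_weight_subset(weights: WeightMatrix, subset_spec: str, rng) -> WeightMatrix:
    """Return a copy with the selected synapse subset redrawn uniformly.

    ``"E-out"`` redraws every excitatory-presynaptic entry (wEE and wIE) in
    [0, 1]; ``"I-out"`` every inhibitory-presynaptic entry (wEI, wII) in
    [-1, 0]; ``"all-but-EE"`` everything except the E-to-E block; ``"none"``
    is the identity. Unselected entries are bit-identical to the input.
    """
    if subset_spec not in _SUBSETS:
        raise ValueError(f"unknown subset spec {subset_spec!r}; use one of {_SUBSETS}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = weights.copy()
    if subset_spec == "none":
        return out
    exc_col = weights.class_of == 0
    N = out.w.shape[0]
    if subset_spec == "E-out":
        sel = np.zeros((N, N), dtype=bool)
        sel[:, exc_col] = True
    elif subset_spec == "I-out":
        sel = np.zeros((N, N), dtype=bool)
        sel[:, ~exc_col] = True
    else:  # all-but-EE
        sel = np.ones((N, N), dtype=bool)
        sel[np.ix_(exc_col, exc_col)] = False
    sel &= out.mask
    draw = rng.uniform(0.0, 1.0, (N, N))
    draw[:, ~exc_col] -= 1.0
    out.w[sel] = draw[sel]
    out.validate()
    return out


@dataclass
class ExperimentConfig:
    """Resolved configuration of one training/rest experiment."""

    params: NetworkParams = field(default_factory=NetworkParams)
    M: int = 2
    regime: str = "mixed"            # mixed | hebbian | anti-hebbian
    rest: float = 5.0
    n_epochs: int = 35
    consolidation: float = 20.0
    alternation: str = "random"
    overlap: int = 0
    untrained_fraction: float = 0.0
    subset_fraction: float | None = None
    amplitude_jitter: float = 0.0
    f0: float = 0.2
    snapshot_times: tuple = (0.0, 20.0, 40.0)
    seed: int = 0

    def resolved_params(self) -> NetworkParams:
        """Network parameters with the inhibitory split of the regime."""
        p = self.params
        ni = p.Nhi + p.Nai
        if self.regime == "mixed":
            nhi = ni // 2
        elif self.regime == "hebbian":
            nhi = ni
        elif self.regime == "anti-hebbian":
            nhi = 0
        else:
            raise ValueError(f"unknown regime {self.regime!r}")
        return p.replace(Nhi=nhi, Nai=ni - nhi, seed=self.seed)

    def stdp(self) -> dict[str, STDPParams]:
        return default_stdp_params(M=self.M, f0=self.f0)


@dataclass
class ExperimentResult:
    """Simulation output plus the design that produced it."""

    result: SimulationResult
    assignment: PopulationAssignment
    protocol: Protocol | None
    config: ExperimentConfig
    hubs: np.ndarray | None = None

    @property
    def final_weights(self) -> np.ndarray:
        return self.result.weights.w


def training_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run rest -> learning -> consolidation with plasticity always on."""
    params = config.resolved_params()
    rng = np.random.default_rng(config.seed)
    state, weights = init_network(params, "small-random", rng)
    assignment = make_assignment(
        params, config.M, overlap=config.overlap,
        untrained_fraction=config.untrained_fraction,
    )
    protocol = build_stimulus_schedule(
        assignment, mode=config.alternation, n_epochs=config.n_epochs,
        params=params, t_start=config.rest,
        subset_fraction=config.subset_fraction,
        amplitude_jitter=config.amplitude_jitter,
        seed=rng,
    )
    duration = config.rest + config.n_epochs * 1.0 + config.consolidation
    snaps = tuple(config.snapshot_times) + (duration,)
    result = run_simulation(
        params, weights, protocol, duration,
        stdp=config.stdp(), seed=rng, state=state, snapshot_times=snaps,
    )
    return ExperimentResult(result=result, assignment=assignment,
                            protocol=protocol, config=config)


def recovery_experiment(
    weights0: WeightMatrix,
    duration: float,
    config: ExperimentConfig,
    *,
    snapshot_every: float = 10.0,
    plasticity_on: bool = True,
    noise_on: bool = True,
):
    """Spontaneous evolution from a (possibly damaged) weight matrix.

    Returns ``(ExperimentResult, times, stats)`` where ``stats`` is the
    trajectory of per-class intra/inter module weight means at the snapshot
    cadence, and the result carries the recall log in ``hubs=None`` runs via
    :func:`qifnet.indicators.detect_recalls` on the raster.
    """
    params = config.resolved_params()
    if not noise_on:
        params = params.replace(noise_sigma=0.0)
    rng = np.random.default_rng(config.seed)
    state, _ = init_network(params, "zero", rng)
    assignment = make_assignment(params, config.M, overlap=config.overlap)
    n_snap = int(math.floor(duration / snapshot_every))
    snap_times = tuple(k * snapshot_every for k in range(n_snap + 1)) + (duration,)
    result = run_simulation(
        params, weights0, None, duration,
        stdp=config.stdp(), plasticity_on=plasticity_on,
        seed=rng, state=state, snapshot_times=snap_times,
    )
    times = sorted(result.snapshots)
    stats = [indicators.module_weight_stats(result.snapshots[t], assignment)
             for t in times]
    exp = ExperimentResult(result=result, assignment=assignment,
                           protocol=None, config=config)
    return exp, np.asarray(times), stats


def max_feasible_memories(N: int) -> int:
    """Largest M satisfying the triplet rule at network size N.

    Each memory needs one excitatory, one Hebbian- and one anti-Hebbian-
    inhibitory neuron, and NI = 2M inhibitory neurons leave NE = N - 2M
    excitatory ones; the binding constraint is N - 2M >= M, i.e.
    M* = floor(N/3).
    """
    return N // 3


def feasible(N: int, M: int, NI: int) -> bool:
    """Triplet counting rule for one (M, NI) grid point."""
    NE = N - NI
    return M >= 1 and min(NE, NI // 2, NI - NI // 2) >= M


def capacity_scan(
    N: int,
    M_list,
    NI_list,
    run_config: ExperimentConfig | None = None,
    *,
    horizon: float = 120.0,
    template: MatrixTemplate | None = None,
    replicates: int = 1,
    simulate: bool = True,
) -> dict[tuple[int, int], str]:
    """Classify each (M, NI) grid point as stable / unstable / non-accessible.

    A point is non-accessible when the excitatory block cannot seed every
    memory (N - NI < M). Accessible points are simulated for ``horizon``
    seconds of resting dynamics starting from a learned modular template
    (modules below the NI = 2M line simply lack some inhibitory neurons)
    and classified with :func:`qifnet.indicators.classify_stability`; with
    ``simulate=False`` the triplet counting rule decides instead (stable
    iff min(NE, NI_H, NI_A) >= M). A point is stable if any replicate is
    classified stable.
    """
    base = run_config or ExperimentConfig()
    template = template or MatrixTemplate.trained()
    out: dict[tuple[int, int], str] = {}
    for M in M_list:
        for NI in NI_list:
            if M < 1 or N - NI < M:
                out[(M, NI)] = "non-accessible"
                continue
            if not simulate:
                out[(M, NI)] = "stable" if feasible(N, M, NI) else "unstable"
                continue
            verdicts = []
            for rep in range(replicates):
                cfg = replace(
                    base, M=M, seed=base.seed + rep,
                    params=base.params.replace(
                        N=N, Ne=N - NI, Nhi=NI // 2, Nai=NI - NI // 2),
                )
                params = cfg.params
                assignment = make_assignment(params, M, allow_empty=True)
                rng = np.random.default_rng(cfg.seed)
                weights = build_modular_matrix(template, params, assignment, rng)
                state, _ = init_network(params, "zero", rng)
                res = run_simulation(params, weights, None, horizon,
                                     stdp=cfg.stdp(), seed=rng, state=state)
                verdicts.append(indicators.classify_stability(
                    res.spike_times, res.spike_ids, params.N, assignment))
            out[(M, NI)] = "stable" if any(v.stable for v in verdicts) else "unstable"
    return out


def find_hubs(
    w: np.ndarray,
    assignment: PopulationAssignment,
    strength_threshold: float = 0.5,
) -> np.ndarray:
    """Excitatory neurons with strong outgoing weights to >= 2 modules.

    A neuron is a hub when the mean of its outgoing excitatory weights to
    the exclusive excitatory set of at least two modules exceeds the
    threshold.
    """
    hub_set = set(assignment.overlap.tolist())
    excl = [np.asarray([i for i in g if i not in hub_set], dtype=np.intp)
            for g in assignment.exc]
    all_e = np.unique(np.concatenate(assignment.exc))
    hubs = []
    for j in all_e:
        n_strong = 0
        for g in excl:
            tgt = g[g != j]
            if tgt.size and w[tgt, j].mean() >= strength_threshold:
                n_strong += 1
        if n_strong >= 2:
            hubs.append(j)
    return np.asarray(hubs, dtype=np.intp)


def overlap_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Training with overlapping stimuli; reports the emergent hub set."""
    if config.overlap <= 0:
        raise ValueError("overlap_experiment requires overlap > 0")
    cfg = replace(config, alternation="strict")
    exp = training_experiment(cfg)
    exp.hubs = find_hubs(exp.final_weights, exp.assignment)
    return exp
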