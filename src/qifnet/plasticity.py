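"""Spike-timing-dependent plasticity rules and soft-bounded weight updates.

Three STDP windows are implemented, keyed by the class of the pre-synaptic
neuron:

* excitatory -- asymmetric Hebbian: causal pairs (pre before post)
  potentiate, anti-causal pairs depress, with a double-exponential window;
* Hebbian inhibitory -- symmetric Ricker (Mexican-hat) window: coincident
  firing potentiates (drives the weight towards -1), uncorrelated firing
  depresses;
* anti-Hebbian inhibitory -- the reversed Ricker window: coincident firing
  depresses, uncorrelated firing potentiates.

Every window carries a constant forgetting offset ``f`` so that prolonged
uncorrelated firing slowly erodes the stored structure. Updates are pairwise
(last spike of the partner only) and pass through steep tanh soft bounds
that confine excitatory weights to [0, 1] and inhibitory weights to [-1, 0]
while keeping them plastic almost everywhere in that range.
"""

from __future__ import annotations

import numpy as np

from .params import CLASS_E, STDPParams

__all__ = [
    "lambda_e",
    "lambda_hi",
    "lambda_ai",
    "stdp_window",
    "split_plasticity",
    "weight_delta",
    "weight_update",
    "apply_spike_plasticity",
    "on_spike_plasticity",
]

#: absolute tolerance of the safety clamp absorbing floating-point overshoot
#: of the tanh soft bound
CLAMP_TOL = 1e-12


def lambda_e(dt_diff, params: STDPParams):
    """Asymmetric Hebbian window for excitatory pre-synaptic neurons.

    ``dt_diff`` is t_post - t_pre in seconds (scalar or array). The window
    is continuous at 0 where it equals A+ - A- - f.
    """
    dt = np.asarray(dt_diff, dtype=float)
    # evaluate each branch on |dt| so the inactive branch cannot overflow
    adt = np.abs(dt)
    pos = (
        params.A_plus * np.exp(-adt / params.tau_plus)
        - params.A_minus * np.exp(-4.0 * adt / params.tau_plus)
    )
    neg = (
        params.A_plus * np.exp(-4.0 * adt / params.tau_minus)
        - params.A_minus * np.exp(-adt / params.tau_minus)
    )
    out = np.where(dt >= 0, pos, neg) - params.f
    return out if out.ndim else float(out)


def _ricker(dt: np.ndarray, A: float, tau: float) -> np.ndarray:
    x2 = (dt / tau) ** 2
    return A * (1.0 - x2) * np.exp(-x2 / 2.0)


def lambda_hi(dt_diff, params: STDPParams):
    """Symmetric Hebbian (Ricker wavelet) window for inhibitory neurons."""
    dt = np.asarray(dt_diff, dtype=float)
    out = _ricker(dt, params.A, params.tau) - params.f
    return out if out.ndim else float(out)


def lambda_ai(dt_diff, params: STDPParams):
    """Symmetric anti-Hebbian (reversed Ricker) window; -lambda_hi up to f."""
    dt = np.asarray(dt_diff, dtype=float)
    out = -_ricker(dt, params.A, params.tau) + params.f
    return out if out.ndim else float(out)


_WINDOWS = {"e": lambda_e, "hi": lambda_hi, "ai": lambda_ai}


def stdp_window(dt_diff, params: STDPParams):
    """Evaluate the plasticity window selected by ``params.synapse_class``."""
    return _WINDOWS[params.synapse_class](dt_diff, params)


def split_plasticity(value):
    """Split a window value into its potentiation and depression parts."""
    v = np.asarray(value, dtype=float)
    pot, dep = np.maximum(v, 0.0), np.minimum(v, 0.0)
    if v.ndim:
        return pot, dep
    return float(pot), float(dep)


def weight_delta(w, dt_diff, params: STDPParams):
    """Raw weight change Delta-w (before the learning rate) for a pairing.

    For excitatory synapses the potentiation part is gated by
    tanh(lambda*(1 - w)) and the depression part by tanh(lambda*w); for
    inhibitory synapses the roles are exchanged and the sign flipped, so
    potentiation drives w towards -1 and depression towards 0.
    """
    w = np.asarray(w, dtype=float)
    pot, dep = split_plasticity(stdp_window(dt_diff, params))
    lam = params.lam
    if params.excitatory:
        out = np.tanh(lam * (1.0 - w)) * pot + np.tanh(lam * w) * dep
    else:
        out = -(np.tanh(lam * (0.0 - w)) * dep + np.tanh(lam * (w + 1.0)) * pot)
    return out if out.ndim else float(out)


def weight_update(w, dt_diff, params: STDPParams):
    """One pairwise soft-bounded update: w' = w + gamma_l * Delta-w.

    ``w`` must lie inside its class bounds on entry. The tanh soft bounds
    keep the update inside the bounds in exact arithmetic; a clamp with
    tolerance 1e-12 absorbs floating-point overshoot.
    """
    w_arr = np.asarray(w, dtype=float)
    lo, hi = (0.0, 1.0) if params.excitatory else (-1.0, 0.0)
    if np.any(w_arr < lo - CLAMP_TOL) or np.any(w_arr > hi + CLAMP_TOL):
        raise ValueError(f"weight outside class bounds [{lo}, {hi}]")
    out = np.clip(w_arr + params.gamma_l * weight_delta(w_arr, dt_diff, params), lo, hi)
    return out if out.ndim else float(out)


def apply_spike_plasticity(
    w: np.ndarray,
    mask: np.ndarray,
    class_of: np.ndarray,
    last_spike: np.ndarray,
    spiking: np.ndarray,
    spike_times: np.ndarray,
    stdp: dict[str, STDPParams],
) -> None:
    """Update, in place, every synapse incident to the neurons spiking now.

    For each spiking neuron ``s`` at (corrected) time ``t_s``:

    * all incoming synapses w[s, j] are updated with
      Delta-t = t_s - t_pre_last, using the window of pre-synaptic class j;
    * all outgoing synapses w[i, s] are updated with
      Delta-t = t_post_last - t_s, using the window of the class of s.

    Partners that have never fired are skipped (no defined Delta-t). When
    two coupled neurons spike in the same integration step, their pairwise
    synapses are updated exactly once, using both neurons' new spike times
    (Delta-t = 0 if the corrected times coincide). The last-spike ledger is
    advanced afterwards.
    """
    if spiking.size == 0:
        return
    exc = class_of == CLASS_E
    lo = np.where(exc, 0.0, -1.0)
    hi = np.where(exc, 1.0, 0.0)
    in_step = np.zeros(last_spike.shape, dtype=bool)
    in_step[spiking] = True
    # ledger with the new times already entered: co-spiking partners are
    # paired at their new spike times
    new_last = last_spike.copy()
    new_last[spiking] = spike_times

    order = np.argsort(spike_times, kind="stable")
    for k in order:
        s = int(spiking[k])
        ts = float(spike_times[k])
        # s as post-synaptic: incoming row w[s, :]
        valid = mask[s] & (new_last > -np.inf)
        if valid.any():
            ids = np.nonzero(valid)[0]
            dt = ts - new_last[ids]
            row = w[s, ids]
            delta = np.empty_like(row)
            for name, cid in (("e", 0), ("hi", 1), ("ai", 2)):
                sel = class_of[ids] == cid
                if sel.any():
                    p = stdp[name]
                    delta[sel] = p.gamma_l * weight_delta(row[sel], dt[sel], p)
            w[s, ids] = np.clip(row + delta, lo[ids], hi[ids])
        # s as pre-synaptic: outgoing column w[:, s]; posts spiking in the
        # same step are excluded (their row pass already covered the pair)
        valid = mask[:, s] & (last_spike > -np.inf) & ~in_step
        if valid.any():
            ids = np.nonzero(valid)[0]
            dt = last_spike[ids] - ts
            p = stdp[("e", "hi", "ai")[int(class_of[s])]]
            col = w[ids, s]
            w[ids, s] = np.clip(
                col + p.gamma_l * weight_delta(col, dt, p), lo[s], hi[s]
            )
    last_spike[spiking] = spike_times


def on_spike_plasticity(
    ledger: np.ndarray,
    weights,
    spiking_neurons,
    t,
    params_by_class: dict[str, STDPParams],
    mask: np.ndarray | None = None,
) -> None:
    """Convenience wrapper around :func:`apply_spike_plasticity`.

    ``weights`` may be a WeightMatrix-like object (attributes ``w``,
    ``class_of``, ``mask``) or a plain array (then ``mask`` and a class
    vector must be inferable). ``t`` may be a scalar (all spikes at the same
    time) or an array aligned with ``spiking_neurons``. Mutates the weight
    matrix and the ledger.
    """
    spiking = np.atleast_1d(np.asarray(spiking_neurons, dtype=np.intp))
    times = np.broadcast_to(np.asarray(t, dtype=float), spiking.shape).copy()
    w = weights.w if hasattr(weights, "w") else np.asarray(weights)
    class_of = weights.class_of if hasattr(weights, "class_of") else None
    if mask is None:
        mask = weights.mask if hasattr(weights, "mask") else ~np.eye(w.shape[0], dtype=bool)
    if class_of is None:
        raise ValueError("per-neuron synapse classes are required")
    apply_spike_plasticity(w, mask, class_of, ledger, spiking, times, params_by_class)
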