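"""Model parameters for the QIF network and its plasticity rules.

All defaults reproduce the reference parameter set of the model: a globally
coupled network of N = 100 quadratic integrate-and-fire neurons, 80%%
excitatory and 20%% inhibitory, the latter split evenly between symmetric
Hebbian and symmetric anti-Hebbian STDP. Times are in seconds; membrane
potentials, excitabilities and currents are dimensionless (the QIF equation
is written in normalised units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TAU0",
    "STIM_AMPLITUDE",
    "NetworkParams",
    "STDPParams",
    "default_stdp_params",
]

#: Dimensionless time scale entering the excitability, noise and stimulus
#: amplitudes: eta ~ N(0, (pi*tau0)^2), xi ~ N(0, (4*pi*tau0)^2) and the
#: stimulation DC current (50*pi*tau0)^2, which drives neurons at ~50 Hz.
TAU0 = 0.02

#: DC current applied to stimulated neurons; sqrt(I)/(pi*tau_m) = 50 Hz.
STIM_AMPLITUDE = (50.0 * math.pi * TAU0) ** 2

# Synapse classes, keyed by the pre-synaptic neuron:
#   "e"  excitatory, asymmetric Hebbian STDP
#   "hi" inhibitory, symmetric Hebbian STDP (Ricker / Mexican-hat window)
#   "ai" inhibitory, symmetric anti-Hebbian STDP (reversed Ricker window)
CLASS_E, CLASS_HI, CLASS_AI = 0, 1, 2
CLASS_NAMES = ("e", "hi", "ai")


@dataclass
class NetworkParams:
    """Parameters of the spiking network (membrane, synapses, integration).

    The per-neuron excitability vector ``eta`` is drawn at network
    initialisation from N(0, (pi*tau0)^2) unless given explicitly.
    """

    N: int = 100
    Ne: int = 80
    Nhi: int = 10
    Nai: int = 10
    tau_m: float = 0.02          # membrane time constant [s]
    tau0: float = TAU0           # dimensionless scale for eta/noise/stimulus
    tau_de: float = 0.002        # excitatory synaptic decay [s]
    tau_di: float = 0.005        # inhibitory synaptic decay [s]
    ge: float = 100.0
    ghi: float = 200.0
    gai: float = 400.0
    Vp: float = 10.0             # spike detection threshold
    Vr: float = -10.0            # reset potential
    dt: float = 0.001            # Euler time step [s]
    eta_sigma: float = math.pi * TAU0
    noise_sigma: float = 4.0 * math.pi * TAU0
    stim_amplitude: float = STIM_AMPLITUDE
    #: discretization of the white-noise term xi in the stochastic Euler
    #: scheme; sets the standard deviation of the per-step increment added
    #: to V:
    #:   "em_tau_m"  (default) -- sigma*sqrt(dt/tau_m): Euler-Maruyama for
    #:       the equation written in membrane-time units. Calibrated choice:
    #:       it reproduces the ~1 Hz coupled resting rate, the [0, 8] Hz
    #:       spontaneous range and the spontaneous recall ignition the model
    #:       is built around.
    #:   "per_step"  -- sigma*dt/tau_m: the draw enters the Euler update
    #:       like the deterministic terms (piecewise-constant over dt).
    #:   "em"        -- sigma*sqrt(dt)/tau_m: Euler-Maruyama for the
    #:       equation in physical time.
    noise_mode: str = "em_tau_m"
    #: multiplier for the refractory hold 2*tau_m/V after a threshold
    #: crossing at potential V; exposed because the printed expression for
    #: the hold is ambiguous in its source.
    refractory_scale: float = 1.0
    #: connection probability for a directed Erdos-Renyi mask; None means
    #: dense all-to-all (no autapses either way).
    connection_prob: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N, self.Ne, self.Nhi, self.Nai) < 0:
            raise ValueError("population counts must be non-negative")
        if self.Ne + self.Nhi + self.Nai != self.N:
            raise ValueError(
                f"Ne+Nhi+Nai = {self.Ne + self.Nhi + self.Nai} != N = {self.N}"
            )
        for name in ("tau_m", "tau_de", "tau_di", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.Vp > 0 > self.Vr):
            raise ValueError("require Vp > 0 > Vr")
        if self.connection_prob is not None and not (0.0 < self.connection_prob <= 1.0):
            raise ValueError("connection_prob must be in (0, 1]")
        if self.noise_mode not in ("em_tau_m", "per_step", "em"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    def noise_step_sigma(self) -> float:
        """Standard deviation of the per-step noise increment added to V."""
        if self.noise_mode == "em_tau_m":
            return self.noise_sigma * math.sqrt(self.dt / self.tau_m)
        if self.noise_mode == "per_step":
            return self.noise_sigma * self.dt / self.tau_m
        return self.noise_sigma * math.sqrt(self.dt) / self.tau_m

    # -- class bookkeeping -------------------------------------------------
    # Neurons are ordered [excitatory | Hebbian inhibitory | anti-Hebbian
    # inhibitory]; per-memory sub-populations are carved out of each block.

    @property
    def class_of(self) -> np.ndarray:
        """Per-neuron synapse class (0=e, 1=hi, 2=ai), by pre-synaptic id."""
        out = np.empty(self.N, dtype=np.int8)
        out[: self.Ne] = CLASS_E
        out[self.Ne : self.Ne + self.Nhi] = CLASS_HI
        out[self.Ne + self.Nhi :] = CLASS_AI
        return out

    @property
    def slice_e(self) -> slice:
        return slice(0, self.Ne)

    @property
    def slice_hi(self) -> slice:
        return slice(self.Ne, self.Ne + self.Nhi)

    @property
    def slice_ai(self) -> slice:
        return slice(self.Ne + self.Nhi, self.N)

    def replace(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass
class STDPParams:
    """Parameters of one STDP window and its soft-bounded weight update.

    ``synapse_class`` selects the window shape: "e" uses the asymmetric
    Hebbian double-exponential, "hi" the symmetric Ricker wavelet, "ai" the
    reversed Ricker wavelet. The forgetting term ``f`` produces a slow drift
    of the weights under uncorrelated firing and scales as f0/M with the
    number of stored memories M (f0 = 0.2, so f = 0.1 at M = 2).
    """

    synapse_class: str = "e"
    A_plus: float = 5.296
    A_minus: float = 2.949
    tau_plus: float = 0.02
    tau_minus: float = 0.05
    A: float = 3.0
    tau: float = 0.1
    f: float = 0.1
    gamma_l: float = 0.005       # learning rate
    lam: float = 100.0           # slope of the tanh soft bound

    def __post_init__(self) -> None:
        if self.synapse_class not in CLASS_NAMES:
            raise ValueError(f"unknown synapse class {self.synapse_class!r}")
        for name in ("tau_plus", "tau_minus", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.gamma_l < 0:
            raise ValueError("gamma_l must be >= 0")

    @property
    def excitatory(self) -> bool:
        return self.synapse_class == "e"

    def replace(self, **kwargs) -> "STDPParams":
        return replace(self, **kwargs)


def default_stdp_params(M: int = 2, f0: float = 0.2, *, gamma_l: float = 0.005,
                        ) -> dict[str, STDPParams]:
    """Reference STDP parameter set for all three synapse classes.

    The forgetting term is f0/M for every class (at the reference M = 2 this
    is the printed f = 0.1); pass explicit ``STDPParams`` to decouple them.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    f = f0 / M
    return {
        "e": STDPParams(synapse_class="e", f=f, gamma_l=gamma_l),
        "hi": STDPParams(synapse_class="hi", f=f, gamma_l=gamma_l),
        "ai": STDPParams(synapse_class="ai", f=f, gamma_l=gamma_l),
    }
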