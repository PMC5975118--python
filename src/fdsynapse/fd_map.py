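"""Deterministic calcium-dependent facilitation-depression map.

State per spike is the triple (C, P, R): dimensionless presynaptic calcium,
release probability, and the ready-to-release pool fraction.  Between
spikes, calcium decays exponentially (time constant ``tau_ca``) and the
pool recovers at a calcium-dependent rate; at each spike calcium jumps by
``delta``.  The normalized peak postsynaptic response at spike *n* is
``Pr_n = P_n * R_n``, with ``R_n`` the pool *before* release depletes it to
the fraction ``(1 - P_n) R_n``.

The pool update exponentiates the calcium-ratio factor by ``delta_k``
exactly as the source model prints it.  The closed-form solution of the
recovery ODE gives ``delta_k * tau_ca`` instead; that dimensionally
consistent variant is available via ``exponent="dimensional"`` but is not
the default, because the fitted constants belong to the printed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import FDParameters
from .spike_trains import ISISequence

__all__ = [
    "SynapseState",
    "PrSeries",
    "release_probability",
    "recovery_rate",
    "advance_state",
    "simulate_train",
    "deterministic_fixed_point",
    "fixed_point_R_limit",
    "DEFAULT_INITIAL_STATE",
    "DEFAULT_TRANSIENT",
]

#: Default number of initial spikes discarded as transient in stationary
#: analyses. The collapse to the attractor takes only a few iterations, so
#: 100 spikes is a conservative margin.
DEFAULT_TRANSIENT = 100


@dataclass(frozen=True)
class SynapseState:
    """Per-spike map state: calcium C, release probability P, pool R."""

    C: float
    P: float
    R: float

    def __post_init__(self):
        if self.C < 0:
            raise ValueError("calcium C must be >= 0")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("release probability P must lie in [0, 1]")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("pool fraction R must lie in [0, 1]")


#: Rest state: zero baseline calcium, empty release machinery, full pool.
DEFAULT_INITIAL_STATE = SynapseState(C=0.0, P=0.0, R=1.0)


@dataclass
class PrSeries:
    """Trajectory of the map driven by an ISI train, transient removed.

    Arrays are aligned: entry *i* is the state and the normalized peak
    response ``Pr = P * R`` at the spike terminating ``isi_ms[i]``.
    """

    isi_ms: np.ndarray
    C: np.ndarray
    P: np.ndarray
    R: np.ndarray
    pr: np.ndarray
    discarded: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spike_index": np.arange(len(self.pr)),
                "isi_ms": self.isi_ms,
                "C": self.C,
                "P": self.P,
                "R": self.R,
                "Pr": self.pr,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PrSeries":
        df = pd.read_csv(path)
        return cls(
            isi_ms=df["isi_ms"].to_numpy(),
            C=df["C"].to_numpy(),
            P=df["P"].to_numpy(),
            R=df["R"].to_numpy(),
            pr=df["Pr"].to_numpy(),
        )


def release_probability(C, params: FDParameters):
    """Release probability ``P = p_max * C^4 / (C^4 + K^4)``.

    Hill function of coefficient 4 in calcium, reflecting the cooperative
    calcium binding of synaptotagmin-1.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("calcium concentration must be >= 0")
    c4 = C**4
    out = params.p_max * c4 / (c4 + params.K**4)
    return out if out.ndim else float(out)


def recovery_rate(C, params: FDParameters):
    """Pool recovery rate ``k = k_min + delta_k * C / (C + K_r)`` (1/ms)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("calcium concentration must be >= 0")
    out = params.k_min + params.delta_k * C / (C + params.K_r)
    return out if out.ndim else float(out)


def _pool_exponent(params: FDParameters, exponent: str) -> float:
    if exponent == "printed":
        return params.delta_k
    if exponent == "dimensional":
        return params.delta_k * params.tau_ca
    raise ValueError("exponent must be 'printed' or 'dimensional'")


def advance_state(
    state: SynapseState,
    T: float,
    params: FDParameters,
    exponent: str = "printed",
) -> tuple[SynapseState, float]:
    """Advance the map by one inter-spike interval ``T`` (ms).

    Returns the state at the next spike and its peak response
    ``Pr = P_new * R_new``.  ``R_new`` is the pre-release pool; the update
    takes ``(1 - P_n) R_n`` (the pool left after the previous release) as
    the initial condition of the recovery dynamics.
    """
    if T <= 0:
        raise ValueError("inter-spike interval T must be > 0")
    dk = _pool_exponent(params, exponent)
    decay = math.exp(-T / params.tau_ca)
    C_new = state.C * decay + params.delta
    c4 = C_new**4
    P_new = params.p_max * c4 / (c4 + params.K**4)
    ratio = (state.C * decay + params.K_r) / (params.K_r + state.C)
    R_new = 1.0 - (1.0 - (1.0 - state.P) * state.R) * ratio**dk * math.exp(
        -params.k_min * T
    )
    new = SynapseState(C=C_new, P=P_new, R=R_new)
    return new, P_new * R_new


def simulate_train(
    params: FDParameters,
    isis: "ISISequence | np.ndarray",
    init: SynapseState = DEFAULT_INITIAL_STATE,
    discard: int = DEFAULT_TRANSIENT,
    exponent: str = "printed",
) -> PrSeries:
    """Iterate the map over an ISI train, discarding an initial transient.

    Deterministic given ``(params, isis, init)``.  The returned series has
    ``len(isis) - discard`` entries.
    """
    isi_arr = isis.isis if isinstance(isis, ISISequence) else np.asarray(isis, float)
    n = len(isi_arr)
    if n == 0:
        raise ValueError("ISI train is empty")
    if not 0 <= discard < n:
        raise ValueError(f"discard must lie in [0, {n}), got {discard}")
    if np.any(isi_arr <= 0):
        raise ValueError("all ISIs must be > 0")

    dk = _pool_exponent(params, exponent)
    tau = params.tau_ca
    K4 = params.K**4
    K_r = params.K_r
    k_min = params.k_min
    p_max = params.p_max
    delta = params.delta

    decay = np.exp(-isi_arr / tau)
    recov = np.exp(-k_min * isi_arr)

    C_out = np.empty(n)
    P_out = np.empty(n)
    R_out = np.empty(n)

    C, P, R = init.C, init.P, init.R
    for i in range(n):
        d = decay[i]
        Cd = C * d
        C_next = Cd + delta
        c4 = C_next**4
        P_next = p_max * c4 / (c4 + K4)
        R_next = 1.0 - (1.0 - (1.0 - P) * R) * ((Cd + K_r) / (K_r + C)) ** dk * recov[i]
        C, P, R = C_next, P_next, R_next
        C_out[i] = C
        P_out[i] = P
        R_out[i] = R

    sl = slice(discard, None)
    meta = {"discard": discard, "exponent": exponent}
    if isinstance(isis, ISISequence):
        meta.update(rate_hz=isis.rate_hz, seed=isis.seed, kind=isis.kind)
    return PrSeries(
        isi_ms=isi_arr[sl].copy(),
        C=C_out[sl],
        P=P_out[sl],
        R=R_out[sl],
        pr=P_out[sl] * R_out[sl],
        discarded=discard,
        meta=meta,
    )


def deterministic_fixed_point(
    params: FDParameters,
    T: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    exponent: str = "printed",
) -> SynapseState:
    """Attracting fixed point of the map under fixed-period stimulation.

    Iterates from the rest state until every component changes by less than
    ``tol``.  The calcium component has the closed form
    ``C* = delta / (1 - exp(-T / tau_ca))``; the convergence of (P, R) to
    the attractor is rapid for physiological parameters.
    """
    if T <= 0:
        raise ValueError("period T must be > 0")
    state = DEFAULT_INITIAL_STATE
    for _ in range(max_iter):
        new, _ = advance_state(state, T, params, exponent=exponent)
        if (
            abs(new.C - state.C) < tol
            and abs(new.P - state.P) < tol
            and abs(new.R - state.R) < tol
        ):
            return new
        state = new
    raise RuntimeError(f"fixed point not converged in {max_iter} iterations")


def fixed_point_R_limit(params: FDParameters, T) -> float | np.ndarray:
    """Closed-form pool fixed point for calcium decaying fully between spikes.

    For ``tau_ca`` much smaller than the period T, calcium relaxes to
    ``delta`` before each spike, the recovery rate sits at its baseline and
    the pool fixed point is

        R_bar(T) = (1 - e^(-k_min T)) / (1 - (1 - p_max) e^(-k_min T)).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("period T must be > 0")
    e = np.exp(-params.k_min * T)
    out = (1.0 - e) / (1.0 - (1.0 - params.p_max) * e)
    return out if out.ndim else float(out)
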