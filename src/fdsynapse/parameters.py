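"""Fitted parameters of the facilitation-depression (FD) synapse map.

The map describes short-term plasticity at a hippocampal PV basket-cell to
CA1 pyramidal-cell GABAergic synapse.  Two named parameter sets are shipped:
``control`` and ``muscarine``.  Muscarine (a cholinergic agonist acting on
presynaptic mAChRs) is modelled purely presynaptically, as a reduction of
the per-spike calcium influx ``delta`` and of the maximal release
probability ``p_max``; all other constants are shared between conditions.

Units: time in ms, rates in 1/ms.  Calcium is dimensionless — rescaled by
the control-condition influx, so ``delta = 1`` under control.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "FDParameters",
    "preset",
    "dynamics_parameters",
    "load_parameters",
    "dump_parameters",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class FDParameters:
    """Constants of the calcium-driven facilitation-depression map.

    Attributes
    ----------
    K : float
        Half-activation calcium of the release-probability Hill function
        (coefficient 4), dimensionless.
    k_min : float
        Baseline recovery rate of the releasable pool, 1/ms.
    k_max : float
        Maximal (calcium-saturated) recovery rate, 1/ms.
    K_r : float
        Half-activation calcium of the recovery-rate Hill function
        (coefficient 1), dimensionless.
    tau_ca : float
        Presynaptic calcium decay time constant, ms.
    p_max : float
        Maximal release probability, in (0, 1].
    delta : float
        Per-spike calcium influx, normalized to 1 under control.
    """

    K: float
    k_min: float
    k_max: float
    K_r: float
    tau_ca: float
    p_max: float
    delta: float

    @property
    def delta_k(self) -> float:
        """Dynamic range of the recovery rate, ``k_max - k_min`` (1/ms)."""
        return self.k_max - self.k_min

    def __post_init__(self) -> None:
        for name in ("K", "k_min", "k_max", "K_r", "tau_ca", "p_max", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.p_max > 1:
            raise ValueError("p_max must be <= 1")

    def replace(self, **kwargs) -> "FDParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_presets() -> dict:
    text = resources.files("fdsynapse").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


PRESET_NAMES = ("control", "muscarine")


def preset(name: str) -> FDParameters:
    """Return a named fitted parameter set (``control`` or ``muscarine``)."""
    presets = _load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return FDParameters(**presets[name])


def dynamics_parameters(params: FDParameters) -> FDParameters:
    """Map constants on the influx-normalized calcium axis.

    The Hill half-activation constants ``K`` and ``K_r`` were fitted on a
    calcium axis scaled by the per-spike influx: under both conditions the
    measured first-pulse response equals ``p_max`` (that is how ``p_max``
    was obtained by variance-mean analysis), which requires the release
    Hill function to saturate on the condition's own influx.  Dividing the
    calcium recurrence ``C_(n+1) = C_n e^(-T/tau) + delta`` by ``delta``
    therefore gives the dynamics actually exercised by the data: unit
    calcium jumps with the fitted ``K``, ``K_r`` unchanged.  Under control
    (``delta = 1``) this is the identity; under muscarine the condition
    enters the spike-to-spike dynamics through ``p_max`` alone, while
    ``delta`` records the absolute influx reduction (it still scales
    absolute calcium levels in the concentration analyses).

    All frequency sweeps use these dynamics; the literal fitted ``delta``
    stays available on the preset for calcium-scale computations.
    """
    return params.replace(delta=1.0)


def load_parameters(source) -> FDParameters:
    """Read an ``FDParameters`` from a YAML/JSON file path or file object."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    return FDParameters(**data)


def dump_parameters(params: FDParameters, target=None) -> str:
    """Write ``params`` to YAML; returns the YAML text."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if target is not None:
        if isinstance(target, (str, Path)):
            with open(target, "w") as fh:
                fh.write(text)
        else:
            target.write(text)
    return text
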