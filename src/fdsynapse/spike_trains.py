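"""Synthetic presynaptic spike trains.

Generates the stimulation protocols used throughout the analysis: Poisson
trains (i.i.d. exponential inter-spike intervals at a chosen mean rate,
the in-vivo-like drive) and fixed-frequency trains (the protocol of the
underlying paired-recording experiments).  Everything is seeded and
reproducible; per-frequency sub-streams for sweeps are derived from one
root seed with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ISISequence", "generate_poisson_isis", "generate_fixed_isis", "spawn_seeds"]


@dataclass
class ISISequence:
    """An ordered train of inter-spike intervals in ms.

    ``rate_hz`` is the nominal mean rate; ``seed`` is recorded for
    provenance (``None`` for deterministic fixed trains).
    """

    isis: np.ndarray
    rate_hz: float
    kind: str = "poisson"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.isis = np.asarray(self.isis, dtype=float)
        if self.isis.ndim != 1 or len(self.isis) == 0:
            raise ValueError("isis must be a nonempty 1-D array")
        if np.any(self.isis <= 0):
            raise ValueError("all inter-spike intervals must be > 0")

    def __len__(self) -> int:
        return len(self.isis)

    @property
    def rate_per_ms(self) -> float:
        return self.rate_hz / 1000.0

    @property
    def mean_isi_ms(self) -> float:
        return float(np.mean(self.isis))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"spike_index": np.arange(len(self.isis)), "isi_ms": self.isis}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate_hz: float | None = None, kind: str = "imported"):
        df = pd.read_csv(path)
        isis = df["isi_ms"].to_numpy()
        if rate_hz is None:
            rate_hz = 1000.0 / float(np.mean(isis))
        return cls(isis=isis, rate_hz=rate_hz, kind=kind)


def generate_poisson_isis(rate_hz: float, n: int, seed) -> ISISequence:
    """Draw ``n`` i.i.d. exponential ISIs with mean ``1000 / rate_hz`` ms.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``/``Generator``.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    isis = rng.exponential(scale=1000.0 / rate_hz, size=n)
    recorded = seed if isinstance(seed, (int, np.integer)) else None
    return ISISequence(isis=isis, rate_hz=rate_hz, kind="poisson", seed=recorded)


def generate_fixed_isis(period_ms: float, n: int) -> ISISequence:
    """A constant train: ``n`` intervals of ``period_ms`` each."""
    if period_ms <= 0:
        raise ValueError("period_ms must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return ISISequence(
        isis=np.full(n, float(period_ms)),
        rate_hz=1000.0 / period_ms,
        kind="fixed",
        seed=None,
    )


def spawn_seeds(root_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent reproducible sub-streams from one seed."""
    return np.random.SeedSequence(root_seed).spawn(n)
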