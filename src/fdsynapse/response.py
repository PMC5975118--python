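"""Katz-style stochastic model of the postsynaptic response.

Given a release probability ``Pr`` from the FD map, the number of vesicles
released across ``n_sites`` independent release sites is binomial
``K ~ B(n_sites, Pr)``.  Each released vesicle evokes a quantal response
drawn from a normal law with mean ``mu`` and s.d. ``sigma`` truncated to
(0, 2*mu); the total response is the sum of the K quantal amplitudes, and
exactly 0 when K = 0 (a failure).

The number of release sites is not constrained by the source data; the
default ``n_sites = 10`` is a typical count for a PV basket-cell
connection and is recorded in every experiment's metadata.

Quantal amplitudes are sampled exactly by the inverse-CDF transform on the
truncation interval.  Summing K truncated draws is the generative model;
the untruncated normal shortcut ``N(K mu, sqrt(K) sigma)`` is available
via ``quantal_mode="normal_sum"`` for comparison (the two differ slightly
in the tails).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fd_map import PrSeries

__all__ = ["ResponseModel", "PSRSeries", "generate_psr_series"]


@dataclass(frozen=True)
class ResponseModel:
    """Binomial release + truncated-normal quantal amplitude model.

    Attributes
    ----------
    n_sites : int
        Number of independent release sites N.
    mu : float
        Quantal mean amplitude (response units).
    sigma : float
        Quantal standard deviation.
    """

    n_sites: int = 10
    mu: float = 0.5
    sigma: float = 0.1

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be > 0")

    @property
    def truncation(self) -> tuple[float, float]:
        """Support of the quantal amplitude law, symmetric about ``mu``."""
        return (0.0, 2.0 * self.mu)

    @property
    def n_cts(self) -> float:
        """Mass of N(mu, sigma^2) inside (0, 2 mu) — the density normalizer."""
        z = self.mu / self.sigma
        return float(stats.norm.cdf(z) - stats.norm.cdf(-z))

    def quantal_pdf(self, s):
        """Density of a single quantal amplitude on (0, 2 mu)."""
        s = np.asarray(s, dtype=float)
        lo, hi = self.truncation
        inside = (s > lo) & (s < hi)
        out = np.where(
            inside, stats.norm.pdf(s, loc=self.mu, scale=self.sigma) / self.n_cts, 0.0
        )
        return out if out.ndim else float(out)

    def draw_release_count(self, pr, rng: np.random.Generator):
        """Vesicle count ``K ~ Binomial(n_sites, pr)``."""
        pr_arr = np.asarray(pr, dtype=float)
        if np.any((pr_arr < 0) | (pr_arr > 1)):
            raise ValueError("release probability must lie in [0, 1]")
        out = rng.binomial(self.n_sites, pr_arr)
        return out if np.ndim(pr) else int(out)

    def draw_quantal(self, rng: np.random.Generator, size=None):
        """Quantal amplitudes via inverse-CDF sampling on (0, 2 mu)."""
        z = self.mu / self.sigma
        lo = stats.norm.cdf(-z)
        hi = stats.norm.cdf(z)
        u = rng.uniform(lo, hi, size=size)
        out = self.mu + self.sigma * stats.norm.ppf(u)
        return out if size is not None else float(out)

    def draw_psr(self, pr: float, rng: np.random.Generator, quantal_mode: str = "sum"):
        """One postsynaptic amplitude for release probability ``pr``."""
        k = self.draw_release_count(pr, rng)
        if k == 0:
            return 0.0
        if quantal_mode == "sum":
            return float(np.sum(self.draw_quantal(rng, size=k)))
        if quantal_mode == "normal_sum":
            return float(rng.normal(k * self.mu, np.sqrt(k) * self.sigma))
        raise ValueError("quantal_mode must be 'sum' or 'normal_sum'")


@dataclass
class PSRSeries:
    """Stochastic response amplitudes aligned spike-by-spike to a PrSeries."""

    isi_ms: np.ndarray
    pr: np.ndarray
    k_released: np.ndarray
    amplitude: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.amplitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spike_index": np.arange(len(self.amplitude)),
                "isi_ms": self.isi_ms,
                "pr": self.pr,
                "k_released": self.k_released,
                "amplitude": self.amplitude,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_psr_series(
    pr_series: PrSeries,
    model: ResponseModel = ResponseModel(),
    seed=0,
    quantal_mode: str = "sum",
) -> PSRSeries:
    """Sample one stochastic response per spike of ``pr_series``.

    Vectorized: all release counts are drawn at once, then the total pool
    of quantal amplitudes is drawn and summed per spike.
    """
    rng = np.random.default_rng(seed)
    pr = np.asarray(pr_series.pr, dtype=float)
    k = rng.binomial(model.n_sites, np.clip(pr, 0.0, 1.0))
    total = int(k.sum())
    amplitudes = np.zeros(len(pr))
    if total > 0:
        if quantal_mode == "sum":
            quanta = model.draw_quantal(rng, size=total)
            spike_ids = np.repeat(np.arange(len(k)), k)
            amplitudes = np.bincount(spike_ids, weights=quanta, minlength=len(k))
        elif quantal_mode == "normal_sum":
            pos = k > 0
            amplitudes[pos] = rng.normal(
                k[pos] * model.mu, np.sqrt(k[pos]) * model.sigma
            )
        else:
            raise ValueError("quantal_mode must be 'sum' or 'normal_sum'")
    recorded = seed if isinstance(seed, (int, np.integer)) else None
    return PSRSeries(
        isi_ms=np.asarray(pr_series.isi_ms, float).copy(),
        pr=pr.copy(),
        k_released=k,
        amplitude=amplitudes,
        seed=recorded,
        meta={"n_sites": model.n_sites, "mu": model.mu, "sigma": model.sigma,
              "quantal_mode": quantal_mode},
    )
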