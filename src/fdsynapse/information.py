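"""Entropy and mutual-information estimators.

Two estimation routes are provided, matching how each quantity is used in
the analysis:

* **Histogram estimators** (log base 2, results in bits) for scalar
  variables: Shannon entropy, joint entropy and mutual information on
  binned data, with the Freedman-Diaconis rule choosing bin counts for
  response/ISI axes and a fixed 100-bin partition of [0, 1] for the
  normalized response Pr (held constant across conditions and rates so
  entropies are comparable).

* **k-nearest-neighbor estimators** (natural log, results in nats) for
  multivariate variables: the Kozachenko-Leonenko differential entropy
  estimator and the Kraskov-Stoegbauer-Grassberger (KSG, variant 1)
  mutual-information estimator, both under the max-norm.  These are used
  for the mutual information between a response and the ordered n-tuple of
  preceding ISIs, where histograms would be hopeless in n dimensions.

Failures (zero-amplitude responses) are part of the response law — the
mixture has an atom at 0 — and are included in histograms by default;
pass ``include_failures=False`` to drop them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import spatial, special

from .fd_map import PrSeries
from .response import PSRSeries

__all__ = [
    "BinnedDistribution",
    "KnnEstimatorConfig",
    "freedman_diaconis_nbins",
    "entropy_bits",
    "joint_entropy_bits",
    "mutual_information_hist",
    "fixed_partition_entropy",
    "mi_psr_vs_preceding_isi",
    "mi_vs_sum_history",
    "kl_knn_entropy",
    "ksg_mi",
    "mi_ntuple_history",
    "LN2",
]

LN2 = float(np.log(2.0))

#: Fixed partition of [0, 1] used for every Pr histogram.
PR_PARTITION_BINS = 100


@dataclass
class BinnedDistribution:
    """A normalized histogram: bin edges, relative frequencies, sample count."""

    edges: np.ndarray
    probs: np.ndarray
    n: int

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def from_samples(cls, samples, bins="fd") -> "BinnedDistribution":
        samples = np.asarray(samples, dtype=float)
        edges = _resolve_edges(samples, bins)
        counts, edges = np.histogram(samples, bins=edges)
        return cls(edges=edges, probs=counts / counts.sum(), n=len(samples))


def freedman_diaconis_nbins(samples) -> int:
    """Bin count by the Freedman-Diaconis rule.

    ``nbins = ceil( (max - min) / (2 * Iqr * n^(-1/3)) )``.  The
    interquartile range makes the rule robust to outliers.  A degenerate
    Iqr of zero falls back to the square-root rule with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples")
    q1, q3 = np.percentile(samples, [25, 75])
    iqr = q3 - q1
    span = samples.max() - samples.min()
    if span == 0:
        return 1
    if iqr == 0:
        warnings.warn(
            "zero interquartile range; falling back to square-root rule",
            stacklevel=2,
        )
        return int(np.ceil(np.sqrt(n)))
    return int(np.ceil(span / (2.0 * iqr * n ** (-1.0 / 3.0))))


def _resolve_edges(samples: np.ndarray, bins) -> np.ndarray:
    if isinstance(bins, str):
        if bins != "fd":
            raise ValueError(f"unknown binning rule {bins!r}")
        nbins = freedman_diaconis_nbins(samples)
        return np.histogram_bin_edges(samples, bins=nbins)
    if np.isscalar(bins):
        return np.histogram_bin_edges(samples, bins=int(bins))
    return np.asarray(bins, dtype=float)


def entropy_bits(dist: BinnedDistribution) -> float:
    """Shannon entropy ``H = -sum p log2 p`` in bits (0 log 0 := 0)."""
    p = dist.probs[dist.probs > 0]
    return float(-np.sum(p * np.log2(p)))


def _joint_probs(samples_x, samples_y, binning):
    x = np.asarray(samples_x, dtype=float)
    y = np.asarray(samples_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples_x and samples_y must have equal length")
    if isinstance(binning, tuple):
        bins_x, bins_y = binning
    else:
        bins_x = bins_y = binning
    edges_x = _resolve_edges(x, bins_x)
    edges_y = _resolve_edges(y, bins_y)
    counts, _, _ = np.histogram2d(x, y, bins=[edges_x, edges_y])
    return counts / counts.sum()


def joint_entropy_bits(samples_x, samples_y, binning="fd") -> float:
    """Joint entropy of two scalar samples on a product binning, in bits."""
    pxy = _joint_probs(samples_x, samples_y, binning)
    p = pxy[pxy > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information_hist(samples_x, samples_y, binning="fd") -> float:
    """Histogram mutual information ``I = H(X) + H(Y) - H(X, Y)`` in bits.

    The marginals are obtained by summing the joint table over rows and
    columns, which makes the estimate exactly symmetric and nonnegative
    (it is the KL divergence of the joint against the product of its own
    marginals on the same partition).
    """
    pxy = _joint_probs(samples_x, samples_y, binning)
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    outer = np.outer(px, py)
    mi = np.sum(pxy[mask] * np.log2(pxy[mask] / outer[mask]))
    return float(max(mi, 0.0))


def fixed_partition_entropy(pr_samples, n_bins: int = PR_PARTITION_BINS) -> float:
    """Entropy (bits) of Pr values on the fixed even partition of [0, 1]."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    dist = BinnedDistribution.from_samples(np.clip(pr_samples, 0.0, 1.0), bins=edges)
    return entropy_bits(dist)


def mi_psr_vs_preceding_isi(
    psr: PSRSeries,
    isis=None,
    binning="fd",
    include_failures: bool = True,
) -> float:
    """MI (bits) between response amplitudes and the ISI preceding each spike.

    ``psr`` is already aligned spike-by-spike to its driving train; an
    explicit ``isis`` array may be passed instead and must match in length.
    """
    s = np.asarray(psr.amplitude, dtype=float)
    t = np.asarray(psr.isi_ms if isis is None else isis, dtype=float)
    if len(s) != len(t):
        raise ValueError("response series and ISI train are misaligned")
    if not include_failures:
        keep = s > 0
        s, t = s[keep], t[keep]
    return mutual_information_hist(s, t, binning=binning)


def mi_vs_sum_history(
    psr: PSRSeries,
    isis=None,
    max_depth: int = 10,
    binning="fd",
    min_tail: int = 1000,
) -> np.ndarray:
    """MI (bits) between the response and the sum of its k preceding ISIs.

    Entry ``k-1`` of the result pairs each response ``S_n`` with
    ``t_k(n) = T_n + T_(n-1) + ... + T_(n-k+1)``.  Depth 1 reduces to
    :func:`mi_psr_vs_preceding_isi`.  The conditional-entropy form
    ``H(S) - H(S | t_k)`` is computed symmetrically as
    ``H(S) + H(t_k) - H(S, t_k)``.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    s = np.asarray(psr.amplitude, dtype=float)
    t = np.asarray(psr.isi_ms if isis is None else isis, dtype=float)
    if len(s) != len(t):
        raise ValueError("response series and ISI train are misaligned")
    if len(s) - max_depth < min_tail:
        raise ValueError(
            f"series too short: need at least {max_depth + min_tail} responses"
        )
    csum = np.concatenate(([0.0], np.cumsum(t)))
    out = np.empty(max_depth)
    for k in range(1, max_depth + 1):
        # window sums t_k(n) for n = k-1 .. end
        sums = csum[k:] - csum[:-k]
        out[k - 1] = mutual_information_hist(s[k - 1 :], sums, binning=binning)
    return out


@dataclass(frozen=True)
class KnnEstimatorConfig:
    """Settings for the k-nearest-neighbor estimators (max-norm metric)."""

    k: int = 4
    jitter: float = 1e-10
    jitter_seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _as_points(samples) -> np.ndarray:
    pts = np.asarray(samples, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def _standardized(pts: np.ndarray) -> np.ndarray:
    sd = np.std(pts, axis=0)
    sd[sd == 0] = 1.0
    return (pts - np.mean(pts, axis=0)) / sd


def _jittered(pts: np.ndarray, config: KnnEstimatorConfig) -> np.ndarray:
    if config.jitter <= 0:
        return pts
    rng = np.random.default_rng(config.jitter_seed)
    scale = np.std(pts, axis=0)
    scale[scale == 0] = 1.0
    return pts + rng.uniform(-config.jitter, config.jitter, size=pts.shape) * scale


def kl_knn_entropy(samples, config: KnnEstimatorConfig = KnnEstimatorConfig()) -> float:
    """Kozachenko-Leonenko differential entropy (nats), max-norm.

    ``H_hat = psi(N) - psi(k) + log(c_d) + (d / N) * sum_i log(eps_i)``
    with ``eps_i`` twice the distance from point i to its k-th neighbor
    and ``c_d = 1`` for the max-norm (unit "ball" = unit-edge cube on the
    eps scale).  Ties are broken by a tiny uniform jitter so that no
    nearest-neighbor distance is zero.
    """
    pts = _jittered(_as_points(samples), config)
    n, d = pts.shape
    if n <= config.k:
        raise ValueError("need more samples than neighbors k")
    tree = spatial.cKDTree(pts)
    dist, _ = tree.query(pts, k=config.k + 1, p=np.inf)
    eps = 2.0 * dist[:, -1]
    if np.any(eps == 0):
        raise FloatingPointError(
            "duplicate points give zero neighbor distance; increase jitter"
        )
    return float(
        special.digamma(n) - special.digamma(config.k) + d * np.mean(np.log(eps))
    )


def ksg_mi(
    samples_x,
    samples_y,
    k: int = 4,
    config: KnnEstimatorConfig | None = None,
) -> float:
    """KSG (variant 1) mutual information in nats, max-norm metric.

    ``I_hat = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) >`` where
    ``n_x(i)`` counts marginal points strictly within the joint-space
    distance to the k-th neighbor of point i.  Approximately zero for
    independent inputs and invariant under strictly monotone marginal
    transformations.

    Every coordinate is standardized to unit variance first: the true MI
    is unchanged, and comparable scales across the X and Y blocks keep
    the joint max-norm ball informative about both (the usual KSG
    preprocessing).
    """
    if config is None:
        config = KnnEstimatorConfig(k=k)
    x = _jittered(_standardized(_as_points(samples_x)), config)
    y = _jittered(
        _standardized(_as_points(samples_y)),
        KnnEstimatorConfig(config.k, config.jitter, config.jitter_seed + 1),
    )
    if len(x) != len(y):
        raise ValueError("samples_x and samples_y must have equal length")
    n = len(x)
    if n <= config.k:
        raise ValueError("need more samples than neighbors k")
    joint = np.hstack([x, y])
    tree_joint = spatial.cKDTree(joint)
    dist, _ = tree_joint.query(joint, k=config.k + 1, p=np.inf)
    radius = np.nextafter(dist[:, -1], 0.0)  # strict inequality
    tree_x = spatial.cKDTree(x)
    tree_y = spatial.cKDTree(y)
    n_x = tree_x.query_ball_point(x, radius, p=np.inf, return_length=True) - 1
    n_y = tree_y.query_ball_point(y, radius, p=np.inf, return_length=True) - 1
    mi = (
        special.digamma(config.k)
        + special.digamma(n)
        - np.mean(special.digamma(n_x + 1) + special.digamma(n_y + 1))
    )
    return float(mi)


def mi_ntuple_history(
    pr_series: PrSeries,
    depth: int,
    k: int = 4,
    max_depth_allowed: int = 8,
) -> float:
    """MI (nats) between the ordered n-tuple of preceding ISIs and Pr.

    Pairs each deterministic response ``Pr_n`` with the vector
    ``(T_(n-depth+1), ..., T_n)`` of the ``depth`` intervals preceding it
    (order preserved) and applies the KSG estimator with d_X = depth,
    d_Y = 1.  Depth is capped to avoid the curse of dimensionality at the
    2^14-sample scale.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > max_depth_allowed:
        raise ValueError(
            f"depth {depth} too large for k-NN estimation at this sample size; "
            f"use depth <= {max_depth_allowed} or increase the series length"
        )
    t = np.asarray(pr_series.isi_ms, dtype=float)
    pr = np.asarray(pr_series.pr, dtype=float)
    n = len(pr) - depth + 1
    if n <= k + 1:
        raise ValueError("series too short for this depth")
    idx = np.arange(depth)[None, :] + np.arange(n)[:, None]
    tuples = t[idx]
    return ksg_mi(tuples, pr[depth - 1 :], k=k)
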