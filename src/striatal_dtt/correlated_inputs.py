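"""Correlated cortical spike-train generation (two-layer MIP) and estimators.

Cortical input correlations are controlled with a two-layer
multiple-interaction process (MIP).  A mother Poisson train with rate
``r_in`` is thinned twice: the first layer copies each mother spike with
probability B' into one train per target neuron (the pool mothers), and the
second layer copies each pool-mother spike with probability W into the
``pool_size`` afferents converging on that neuron.  Each afferent then
fires at rate ``r_in * B' * W``; the pairwise count correlation within a
pool is ~W ("within" correlation) and between pools ~B = B'*W ("between" or
shared-input correlation), so B <= W by construction.

The MIP construction is exact thinning with synchronous copies (no jitter):
the copy probability equals the pairwise spike-count correlation for
sub-interspike-interval bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrelatedInputSpec",
    "SpikeTrainSet",
    "poisson_train",
    "mip_copy",
    "two_layer_mip",
    "count_correlation",
    "pooled_correlation_prediction",
    "mother_rate_for_afferent_rate",
]


@dataclass(frozen=True)
class CorrelatedInputSpec:
    """Parameters of the two-layer MIP generator.

    ``r_in`` is the mother rate in Hz; use
    :func:`mother_rate_for_afferent_rate` to hold the afferent rate constant
    while varying the correlations.
    """

    r_in: float
    b_prime: float
    w: float
    n_pools: int
    pool_size: int
    duration: float  # ms
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.b_prime <= 1.0 and 0.0 <= self.w <= 1.0):
            raise ValueError("copy probabilities must lie in [0, 1]")
        if self.r_in < 0 or self.duration <= 0:
            raise ValueError("r_in must be >= 0 and duration > 0")
        if self.n_pools < 1 or self.pool_size < 1:
            raise ValueError("n_pools and pool_size must be >= 1")

    @property
    def afferent_rate(self) -> float:
        """Expected single-afferent rate r_in * B' * W (Hz)."""
        return self.r_in * self.b_prime * self.w

    @property
    def b(self) -> float:
        """Effective between-pool correlation B = B' * W."""
        return self.b_prime * self.w


@dataclass(frozen=True)
class SpikeTrainSet:
    """Event-time arrays (ms, sorted) grouped by pool."""

    pools: list[list[np.ndarray]]
    spec: CorrelatedInputSpec
    pool_mothers: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def flat(self) -> list[np.ndarray]:
        return [train for pool in self.pools for train in pool]


def poisson_train(
    rate: float, duration: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration) ms, sorted.

    *rate* is in Hz, *duration* in ms.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, n))


def mip_copy(
    mother: np.ndarray,
    copy_prob: float,
    n_children: int,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Thin a mother train into *n_children* correlated copies.

    Each mother event is retained in each child independently with
    probability *copy_prob*; children therefore fire at ``copy_prob`` times
    the mother rate and have pairwise count correlation ~``copy_prob``.
    """
    if not 0.0 <= copy_prob <= 1.0:
        raise ValueError("copy_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mother = np.asarray(mother, dtype=float)
    if copy_prob == 1.0:
        return [mother.copy() for _ in range(n_children)]
    keep = rng.random((n_children, mother.size)) < copy_prob
    return [mother[k] for k in keep]


def two_layer_mip(spec: CorrelatedInputSpec) -> SpikeTrainSet:
    """Generate the full two-layer MIP ensemble for *spec*.

    Layer 1 thins the mother train (rate ``r_in``) with probability
    ``b_prime`` into one pool-mother per pool; layer 2 thins each
    pool-mother with probability ``w`` into ``pool_size`` afferent trains.
    """
    rng = np.random.default_rng(spec.seed)
    mother = poisson_train(spec.r_in, spec.duration, rng)
    pool_mothers = mip_copy(mother, spec.b_prime, spec.n_pools, rng)
    pools = [mip_copy(pm, spec.w, spec.pool_size, rng) for pm in pool_mothers]
    return SpikeTrainSet(pools=pools, spec=spec, pool_mothers=pool_mothers)


def _binned_counts(trains: list[np.ndarray], bin_ms: float, duration: float):
    n_bins = int(np.ceil(duration / bin_ms))
    out = np.zeros((len(trains), n_bins))
    for i, t in enumerate(trains):
        t = np.asarray(t)
        if t.size:
            out[i] = np.bincount(
                np.minimum((t / bin_ms).astype(int), n_bins - 1), minlength=n_bins
            )
    return out


def count_correlation(
    trains: list[np.ndarray],
    bin_ms: float = 5.0,
    duration: float | None = None,
    n_pairs: int | None = 2000,
    seed: int = 0,
) -> float:
    """Mean pairwise Pearson correlation of binned spike counts.

    Counts are binned at *bin_ms* (default 5 ms); *n_pairs* random distinct
    pairs are sampled (all pairs if None, or if fewer exist).  Zero-variance
    trains are excluded with a warning.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    if len(trains) < 2:
        raise ValueError("need at least 2 trains")
    if duration is None:
        duration = max((t[-1] if len(t) else 0.0) for t in trains) + bin_ms
    counts = _binned_counts(trains, bin_ms, duration)
    keep = counts.std(axis=1) > 0
    if not keep.all():
        import warnings

        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance train(s)", stacklevel=2
        )
    counts = counts[keep]
    m = len(counts)
    if m < 2:
        raise ValueError("fewer than 2 trains with non-zero variance")

    all_pairs = m * (m - 1) // 2
    rng = np.random.default_rng(seed)
    if n_pairs is None or n_pairs >= all_pairs:
        iu = np.triu_indices(m, k=1)
        pairs = np.column_stack(iu)
    else:
        pairs = np.empty((n_pairs, 2), dtype=int)
        for k in range(n_pairs):
            pairs[k] = rng.choice(m, 2, replace=False)

    z = (counts - counts.mean(axis=1, keepdims=True)) / counts.std(
        axis=1, keepdims=True
    )
    n_bins = counts.shape[1]
    vals = (z[pairs[:, 0]] * z[pairs[:, 1]]).sum(axis=1) / n_bins
    return float(vals.mean())


def pooled_correlation_prediction(b: float, w: float, n: int) -> float:
    """Predicted correlation between two pooled spike counts.

    For two pools of *n* trains each, with within-pool pairwise correlation
    *w* and between-pool pairwise correlation *b*, the pooled-count
    correlation is b / (w + (1 - w)/n) up to O(1/n); it tends to b/w for
    large pools, which is why b <= w is required for a valid correlation.
    """
    if not (0.0 <= b <= 1.0 and 0.0 <= w <= 1.0):
        raise ValueError("b and w must lie in [0, 1]")
    if b > w and not np.isclose(b, w):
        raise ValueError("requires b <= w")
    if n < 1:
        raise ValueError("n must be >= 1")
    if b == 0.0:
        return 0.0
    return b / (w + (1.0 - w) / n)


def mother_rate_for_afferent_rate(
    afferent_rate: float, b_prime: float, w: float
) -> float:
    """Mother rate that yields *afferent_rate* Hz per afferent after both layers."""
    if b_prime <= 0 or w <= 0:
        raise ValueError("b_prime and w must be > 0 to invert the rate")
    return afferent_rate / (b_prime * w)
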