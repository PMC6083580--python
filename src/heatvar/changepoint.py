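"""Bayesian change-point analysis of the daily risk-estimate series.

The series of daily log relative risks beta_1..beta_n is modeled as two
contiguous Gaussian blocks with a common standard deviation:

    beta_i ~ Gaussian(mu1, sigma)   i = 1..k
    beta_i ~ Gaussian(mu2, sigma)   i = k+1..n

A Gibbs sampler alternates the full conditionals — mu1 | . ~
Normal(block-1 mean, sigma^2/k), mu2 | . ~ Normal(block-2 mean,
sigma^2/(n-k)) under flat priors, sigma^2 | . from its inverse-gamma full
conditional under a Jeffreys prior, and k from the categorical distribution
proportional to the two-block likelihood, uniform over admissible k.  The
per-index posterior probability of being the change point is the relative
frequency of k draws after burn-in (default 11,000 iterations, first 1,000
discarded).

Significance is judged against a simulation envelope: many (default 1,000)
iid Gaussian series with the observed series' mean and variance are run
through the same sampler; per index, the 97.5% quantile of their posterior
probabilities, smoothed with a centered moving average, is the threshold an
observed posterior must exceed.  Indices above the envelope, merged into
runs and summarized by the run's modal index, are the detected change
points.

With sigma known the marginal likelihood of each k is available in closed
form under flat priors on the means, so the posterior over k can be
computed by direct enumeration; :func:`exact_posterior` provides that
independent oracle for validating the sampler.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("heatvar")

__all__ = [
    "BCPConfig",
    "ChangePointResult",
    "bcp_posterior",
    "exact_posterior",
    "null_envelope",
    "detect_changepoints",
    "run_bcp",
]

_VAR_FLOOR = 1e-12


@dataclass
class BCPConfig:
    """Sampler and envelope settings.

    ``envelope_rank`` defaults to ceil(0.975 * n_null): the order statistic
    (ascending) of the null posteriors used as the per-index threshold,
    i.e. the 97.5% null quantile.  ``null_n_iter``/``null_burn_in`` let the
    chains run on the null series be shorter than the observed-series
    chain; by default they mirror it.
    """

    n_iter: int = 11_000
    burn_in: int = 1_000
    min_block: int = 5
    n_null: int = 1_000
    envelope_rank: int | None = None
    smooth_window: int = 31
    null_n_iter: int | None = None
    null_burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.min_block < 2:
            raise ValueError("min_block must be >= 2")
        if self.envelope_rank is None:
            self.envelope_rank = math.ceil(0.975 * self.n_null)
        if not 1 <= self.envelope_rank <= self.n_null:
            raise ValueError("envelope_rank must lie in [1, n_null]")
        if self.null_n_iter is None:
            self.null_n_iter = self.n_iter
        if self.null_burn_in is None:
            self.null_burn_in = self.burn_in
        if not self.null_burn_in < self.null_n_iter:
            raise ValueError("null burn-in must be smaller than null n_iter")


@dataclass
class ChangePointResult:
    """Posterior change probabilities and, once computed, the null envelope.

    ``posterior[i]`` is the posterior probability that the boundary between
    the two blocks falls after index i (0-based: block 1 is 0..i); it sums
    to one over admissible indices.
    """

    posterior: np.ndarray
    mu1_mean: float
    mu2_mean: float
    sigma_mean: float
    envelope: np.ndarray | None = None
    detected: list[int] = field(default_factory=list)


def _block_stats(s1: np.ndarray, s2: np.ndarray, k: int, n: int,
                 ) -> tuple[float, float, float, float]:
    """Means and sums of squares of blocks 0..k-1 and k..n-1 from cumsums."""
    m1 = s1[k - 1] / k
    m2 = (s1[n - 1] - s1[k - 1]) / (n - k)
    ss1 = s2[k - 1] - k * m1 * m1
    ss2 = (s2[n - 1] - s2[k - 1]) - (n - k) * m2 * m2
    return m1, m2, ss1, ss2


def bcp_posterior(series, config: BCPConfig, sigma: float | None = None,
                  rng: np.random.Generator | None = None) -> ChangePointResult:
    """Gibbs-sample the two-block change-point model on ``series``.

    ``sigma`` fixes the common standard deviation instead of sampling it
    (used when validating against the closed-form enumeration).  The result
    is reproducible given ``config.seed`` (or an explicit ``rng``).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    d = config.min_block
    if n < 2 * d:
        raise ValueError(f"series length {n} < 2*min_block={2 * d}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    var0 = float(np.var(x))
    if var0 < _VAR_FLOOR:
        logger.warning("near-constant series; variance floored at %g", _VAR_FLOOR)
        var0 = _VAR_FLOOR

    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    # Admissible block-1 sizes k in [d, n-d]; boundary index = k-1 (0-based).
    ks = np.arange(d, n - d + 1)
    s1k = s1[ks - 1]
    s2k = s2[ks - 1]
    tot1, tot2 = s1[-1], s2[-1]

    k = int(n // 2)
    k = min(max(k, d), n - d)
    sig2 = sigma ** 2 if sigma is not None else var0

    counts = np.zeros(n, dtype=np.int64)
    mu1_acc = mu2_acc = sig_acc = 0.0
    kept = 0

    for it in range(config.n_iter):
        m1, m2, _, _ = _block_stats(s1, s2, k, n)
        mu1 = rng.normal(m1, math.sqrt(sig2 / k))
        mu2 = rng.normal(m2, math.sqrt(sig2 / (n - k)))

        if sigma is None:
            # sigma^2 | mu, k ~ InvGamma(n/2, SSR/2) under a Jeffreys prior.
            ssr = (s2[k - 1] - 2 * mu1 * s1[k - 1] + k * mu1 * mu1
                   + (tot2 - s2[k - 1]) - 2 * mu2 * (tot1 - s1[k - 1])
                   + (n - k) * mu2 * mu2)
            ssr = max(ssr, _VAR_FLOOR)
            sig2 = ssr / (2.0 * rng.gamma(n / 2.0))
            sig2 = max(sig2, _VAR_FLOOR)

        # k | mu1, mu2, sigma: categorical over admissible splits.
        ll = -0.5 / sig2 * (
            (s2k - 2 * mu1 * s1k + ks * mu1 * mu1)
            + ((tot2 - s2k) - 2 * mu2 * (tot1 - s1k) + (n - ks) * mu2 * mu2))
        ll -= ll.max()
        w = np.exp(ll)
        w_sum = w.sum()
        u = rng.random() * w_sum
        idx = min(int(np.searchsorted(np.cumsum(w), u)), len(ks) - 1)
        k = int(ks[idx])
        k = min(max(k, d), n - d)

        if it >= config.burn_in:
            counts[k - 1] += 1
            mu1_acc += mu1
            mu2_acc += mu2
            sig_acc += math.sqrt(sig2)
            kept += 1

    posterior = counts / kept
    return ChangePointResult(posterior=posterior,
                             mu1_mean=mu1_acc / kept,
                             mu2_mean=mu2_acc / kept,
                             sigma_mean=sig_acc / kept)


def exact_posterior(series, sigma: float, min_block: int = 5) -> np.ndarray:
    """Closed-form posterior over the change index for known sigma.

    With flat priors on mu1 and mu2 each block's mean integrates out
    analytically; the marginal likelihood of a split with block-1 size k is
    proportional to k^{-1/2} (n-k)^{-1/2} exp(-(SS1_k + SS2_k)/(2 sigma^2))
    with SS the within-block sums of squares about the block means.  The
    normalized posterior over every admissible boundary index is returned
    on the same indexing as :func:`bcp_posterior` (entry i = boundary after
    index i).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(series, dtype=float)
    n = len(x)
    d = min_block
    if n < 2 * d:
        raise ValueError(f"series length {n} < 2*min_block={2 * d}")
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    ks = np.arange(d, n - d + 1)
    m1 = s1[ks - 1] / ks
    m2 = (s1[-1] - s1[ks - 1]) / (n - ks)
    ss1 = s2[ks - 1] - ks * m1 * m1
    ss2 = (s2[-1] - s2[ks - 1]) - (n - ks) * m2 * m2
    logm = (-(ss1 + ss2) / (2.0 * sigma * sigma)
            - 0.5 * np.log(ks) - 0.5 * np.log(n - ks))
    logm -= logm.max()
    w = np.exp(logm)
    post = np.zeros(n)
    post[ks - 1] = w / w.sum()
    return post


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, edges truncated to the available window."""
    if window <= 1:
        return values.copy()
    return (pd.Series(values)
            .rolling(window=window, center=True, min_periods=1)
            .mean().to_numpy())


def null_envelope(series, config: BCPConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-index significance threshold from matched Gaussian null series.

    ``config.n_null`` iid Gaussian series with the observed series' mean and
    variance are run through the sampler; per index the
    ``config.envelope_rank``-th ascending order statistic of the null
    posterior probabilities (the 97.5% null quantile by default) is taken
    and smoothed with a centered moving average of ``smooth_window`` days.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    sd = max(sd, math.sqrt(_VAR_FLOOR))

    null_cfg_iter = config.null_n_iter
    null_cfg_burn = config.null_burn_in
    null_cfg = BCPConfig(n_iter=null_cfg_iter, burn_in=null_cfg_burn,
                         min_block=config.min_block, n_null=config.n_null,
                         envelope_rank=config.envelope_rank,
                         smooth_window=config.smooth_window, seed=config.seed)

    posteriors = np.empty((config.n_null, n))
    for j in range(config.n_null):
        z = rng.normal(mean, sd, size=n)
        posteriors[j] = bcp_posterior(z, null_cfg, rng=rng).posterior

    posteriors.sort(axis=0)
    raw = posteriors[config.envelope_rank - 1]
    env = _smooth(raw, config.smooth_window)
    return np.clip(env, 0.0, 1.0)


def detect_changepoints(posterior: np.ndarray, envelope: np.ndarray) -> list[int]:
    """Indices where the posterior exceeds the envelope, one per run.

    Contiguous exceedance runs are merged and each run is reported by its
    modal (highest-posterior) index.
    """
    if len(posterior) != len(envelope):
        raise ValueError("posterior and envelope lengths differ")
    above = posterior > envelope
    detections = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = np.arange(i, j + 1)
            detections.append(int(run[np.argmax(posterior[run])]))
            i = j + 1
        else:
            i += 1
    return detections


def run_bcp(series, config: BCPConfig) -> ChangePointResult:
    """Posterior, envelope and detections for one daily risk series."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    result = bcp_posterior(series, config, rng=rng)
    env_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    result.envelope = null_envelope(series, config, rng=env_rng)
    result.detected = detect_changepoints(result.posterior, result.envelope)
    return result
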