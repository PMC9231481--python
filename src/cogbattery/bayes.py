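"""Posterior estimation for accuracy and reaction-time parameters.

Accuracy uses a binomial likelihood with a uniform prior on [0, 1], whose
posterior is the exact conjugate Beta(1+k, 1+n-k); reaction time uses a
normal likelihood for the mean with a flat prior truncated to [0, U]
(default U = 1000 ms) and a plug-in sample standard deviation.  Draws are
sampled exactly from these posteriors (default 10,000 retained draws), so
no warm-up or convergence bookkeeping is needed; a generic random-walk
Metropolis sampler targeting the same accuracy posterior is provided as an
independent cross-check.

Group-level estimates average the per-participant draws draw-wise, and
cross-day contrasts are draw-wise differences with the sign convention
that positive means better second-day performance (day 2 - day 1 for
accuracy, day 1 - day 2 for RT).  Interval summaries are the 2.5/97.5
percentile interval for single-day estimates and the 95% highest-density
interval for difference distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 10_000
DEFAULT_RT_PRIOR_UPPER = 1000.0


@dataclass
class PosteriorEstimate:
    draws: np.ndarray
    mean: float
    ci_low: float  # 2.5th percentile
    ci_high: float  # 97.5th percentile
    kind: str  # "accuracy" | "rt"
    scope: str = "participant"  # "participant" | "group"

    @classmethod
    def from_draws(cls, draws: np.ndarray, kind: str, scope: str = "participant"):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim != 1 or draws.size < 1:
            raise EstimationError("draws must be a non-empty 1-d vector")
        if not np.all(np.isfinite(draws)):
            raise EstimationError("non-finite posterior draws")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return cls(draws=draws, mean=float(draws.mean()), ci_low=float(lo),
                   ci_high=float(hi), kind=kind, scope=scope)


@dataclass
class DifferenceDistribution:
    condition: str
    kind: str
    draws: np.ndarray
    mean_diff: float
    hdi_low: float
    hdi_high: float

    @property
    def contains_zero(self) -> bool:
        return self.hdi_low <= 0.0 <= self.hdi_high


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval by shortest-interval search on sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n == 0:
        raise EstimationError("cannot compute an HDI of zero draws")
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def posterior_accuracy(
    k: int, n: int, draws: int = DEFAULT_DRAWS, seed: int = 0
) -> PosteriorEstimate:
    """Posterior over a success probability from k successes in n trials.

    Binomial likelihood with a Uniform(0, 1) prior; draws come from the
    exact conjugate posterior Beta(1+k, 1+n-k).  With n = 0 the posterior
    equals the prior.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if draws < 1000:
        raise ValueError(f"draws must be >= 1000, got {draws}")
    rng = np.random.default_rng(seed)
    samples = rng.beta(1 + k, 1 + n - k, size=draws)
    return PosteriorEstimate.from_draws(samples, kind="accuracy")


def posterior_rt(
    rts,
    draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    prior_upper: float = DEFAULT_RT_PRIOR_UPPER,
) -> PosteriorEstimate:
    """Posterior over the mean RT (ms) from correct-trial reaction times.

    Normal likelihood with known sigma set to the sample standard
    deviation, flat prior truncated to [0, prior_upper]; the truncated
    posterior is renormalized and sampled exactly.
    """
    x = np.asarray(rts, dtype=float)
    if x.size < 2:
        raise EstimationError(f"need at least 2 RTs, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise EstimationError("non-finite RT values")
    mean = float(x.mean())
    se = float(x.std(ddof=1)) / math.sqrt(x.size)
    if mean > 0.9 * prior_upper:
        logger.warning(
            "sample mean RT %.1f ms is within 10%% of the prior upper bound "
            "%.0f ms; the truncated prior will pull the estimate down",
            mean, prior_upper,
        )
    rng = np.random.default_rng(seed)
    if se == 0.0:
        samples = np.full(draws, min(max(mean, 0.0), prior_upper))
    else:
        a, b = (0.0 - mean) / se, (prior_upper - mean) / se
        samples = stats.truncnorm.rvs(a, b, loc=mean, scale=se, size=draws, random_state=rng)
    return PosteriorEstimate.from_draws(samples, kind="rt")


def metropolis_accuracy(
    k: int,
    n: int,
    draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    step: float = 0.1,
    burn_in: int = 2000,
    thin: int = 5,
) -> PosteriorEstimate:
    """Generic random-walk Metropolis sampler for the accuracy posterior.

    Targets the same binomial-likelihood / uniform-prior model as
    :func:`posterior_accuracy` without using conjugacy; retained for use as
    an independent oracle against the conjugate path.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)

    def log_post(p: float) -> float:
        if p <= 0.0 or p >= 1.0:
            return -math.inf
        return k * math.log(p) + (n - k) * math.log1p(-p)

    p = 0.5
    lp = log_post(p)
    kept = np.empty(draws)
    total = burn_in + draws * thin
    i_keep = 0
    for i in range(total):
        prop = p + rng.normal(0.0, step)
        lp_prop = log_post(prop)
        if math.log(rng.uniform()) < lp_prop - lp:
            p, lp = prop, lp_prop
        if i >= burn_in and (i - burn_in) % thin == 0:
            kept[i_keep] = p
            i_keep += 1
    return PosteriorEstimate.from_draws(kept[:i_keep], kind="accuracy")


def group_average(per_participant: list[PosteriorEstimate]) -> PosteriorEstimate:
    """Draw-wise mean across participants (the group posterior is the
    average of the individual posteriors, draw by draw)."""
    if not per_participant:
        raise ValueError("empty estimate list")
    kinds = {e.kind for e in per_participant}
    if len(kinds) != 1:
        raise ValueError(f"mixed metric kinds {kinds}")
    sizes = {e.draws.size for e in per_participant}
    if len(sizes) != 1:
        raise ValueError(f"mismatched draw counts {sizes}")
    stacked = np.vstack([e.draws for e in per_participant])
    return PosteriorEstimate.from_draws(stacked.mean(axis=0), kind=kinds.pop(), scope="group")


def crossday_difference(
    day1: PosteriorEstimate,
    day2: PosteriorEstimate,
    condition: str = "",
) -> DifferenceDistribution:
    """Cross-day contrast with positive = second-day improvement:
    day2 - day1 for accuracy, day1 - day2 for RT."""
    if day1.kind != day2.kind:
        raise ValueError(f"metric kind mismatch: {day1.kind} vs {day2.kind}")
    if day1.draws.size != day2.draws.size:
        raise ValueError("mismatched draw counts")
    if day1.kind == "accuracy":
        diff = day2.draws - day1.draws
    else:
        diff = day1.draws - day2.draws
    lo, hi = hdi(diff, 0.95)
    return DifferenceDistribution(
        condition=condition,
        kind=day1.kind,
        draws=diff,
        mean_diff=float(diff.mean()),
        hdi_low=lo,
        hdi_high=hi,
    )
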