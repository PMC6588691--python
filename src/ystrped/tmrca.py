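"""Bayesian TMRCA inference for haplotype pairs (Walsh procedure).

For a pair separated by tau meioses in total, each locus mutates as a
Poisson process of rate mu per meiosis.  Two mutation models give the
per-locus likelihood of the observed difference:

IAM (infinite alleles)
    a locus is either identical or different; any mutation on the tau
    transmissions destroys identity and no back-mutation restores it, so
    with k of n loci differing
    L(tau) = (1 - e^{-mu tau})^k (e^{-mu tau})^{n-k}.

SMM (strict stepwise)
    every mutation shifts the repeat count by +-1 with equal probability;
    the net displacement d of a rate-(mu tau) symmetric walk follows
    P(D = d) = e^{-mu tau} I_{|d|}(mu tau) with I the modified Bessel
    function of the first kind, so
    L(tau) = prod_i e^{-mu tau} I_{|d_i|}(mu tau).

The posterior over a discrete tau grid (default uniform prior on
1..600 meioses) is normalised likelihood x prior; summaries are reported
in generations (tau / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import special

DEFAULT_TAU_GRID = np.arange(1, 601)


@dataclass
class TMRCAObservation:
    """Pairwise data consumed by the TMRCA machinery.

    ``n_loci`` loci were compared (ambiguous ones excluded), ``k_differing``
    of them differ (the IAM datum) and ``step_differences`` holds the
    per-locus minimal step counts (the SMM datum).  ``mu`` is the pooled
    per-locus per-meiosis rate of the panel used.
    """

    pair_id: str
    panel: str
    n_loci: int
    k_differing: int
    step_differences: list[int]
    mu: float

    def __post_init__(self):
        if not 0 <= self.k_differing <= self.n_loci:
            raise ValueError("need 0 <= k <= n")
        if self.k_differing != sum(1 for d in self.step_differences if d):
            raise ValueError("k must equal the count of nonzero steps")


@dataclass
class TMRCAPosterior:
    tau_grid: np.ndarray                 # total meioses
    probabilities: np.ndarray
    model: str
    prior: str = "uniform"

    def __post_init__(self):
        total = self.probabilities.sum()
        if not np.isclose(total, 1.0, atol=1e-12, rtol=1e-12):
            raise ValueError(f"posterior not normalised: sums to {total}")


@dataclass
class TMRCAEstimate:
    pair_id: str
    model: str
    mean: float                          # generations
    median: float
    mode: float
    ci: tuple[float, float]
    observed: float | None = None        # documented meioses / 2
    within_ci: bool | None = None


def iam_likelihood(k: int, n: int, mu: float, tau) -> np.ndarray:
    """IAM likelihood of k differing loci out of n after tau meioses."""
    if k > n:
        raise ValueError("k cannot exceed n")
    tau = np.asarray(tau, dtype=float)
    q = np.exp(-mu * tau)                # per-locus identity probability
    return (1 - q) ** k * q ** (n - k)


def smm_likelihood(step_differences, mu: float, tau) -> np.ndarray:
    """SMM likelihood of the per-locus net step differences after tau meioses.

    Uses the exponentially scaled Bessel function ive(d, x) = e^{-x} I_d(x)
    for numerical stability.
    """
    d = np.asarray(step_differences)
    if not np.issubdtype(d.dtype, np.integer):
        if not np.allclose(d, np.round(d)):
            raise ValueError("step differences must be integers")
        d = np.round(d).astype(int)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    x = mu * tau
    like = np.ones_like(x)
    for di in np.abs(d):
        like = like * special.ive(int(di), x)
    return like


def geometric_prior(tau_grid: np.ndarray, pop_size: float) -> np.ndarray:
    """Walsh-style population prior: P(tau) ~ (1 - 1/(2N))^(tau) / (2N)."""
    return (1 - 1 / (2 * pop_size)) ** tau_grid


def compute_posterior(obs: TMRCAObservation,
                      model: str = "IAM",
                      prior: str | np.ndarray = "uniform",
                      tau_grid: np.ndarray = DEFAULT_TAU_GRID,
                      pop_size: float = 5000.0) -> TMRCAPosterior:
    """Discrete posterior over the tau grid: prior(tau) x likelihood(tau)."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if model.upper() == "IAM":
        like = iam_likelihood(obs.k_differing, obs.n_loci, obs.mu, tau_grid)
    elif model.upper() == "SMM":
        like = smm_likelihood(obs.step_differences, obs.mu, tau_grid)
    else:
        raise ValueError(f"unknown model {model!r}")
    if isinstance(prior, str):
        prior_label = prior
        if prior == "uniform":
            weights = np.ones_like(tau_grid)
        elif prior == "geometric":
            weights = geometric_prior(tau_grid, pop_size)
        else:
            raise ValueError(f"unknown prior {prior!r}")
    else:
        prior_label = "custom"
        weights = np.asarray(prior, dtype=float)
    post = like * weights
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate posterior: zero likelihood on the grid")
    return TMRCAPosterior(tau_grid, post / total, model.upper(), prior_label)


def summarize_posterior(post: TMRCAPosterior,
                        pair_id: str = "",
                        observed: float | None = None) -> TMRCAEstimate:
    """Mean / median / mode and central 95% band, in generations.

    Median and band bounds are the smallest grid values whose CDF reaches
    0.5 / 0.025 / 0.975; the mode resolves ties to the smallest tau.
    """
    tau, p = post.tau_grid, post.probabilities
    mean = float((tau * p).sum()) / 2
    cdf = np.cumsum(p)

    def q(level: float) -> float:
        return float(tau[np.searchsorted(cdf, level)]) / 2

    mode = float(tau[int(np.argmax(p))]) / 2
    lo, med, hi = q(0.025), q(0.5), q(0.975)
    within = None if observed is None else bool(lo <= observed <= hi)
    return TMRCAEstimate(pair_id, post.model, mean, med, mode, (lo, hi),
                         observed, within)


def coverage_fraction(estimates: list[TMRCAEstimate]) -> float:
    """Percentage of documented TMRCAs inside their estimated 95% bands."""
    if not estimates:
        raise ValueError("no estimates")
    inside = sum(1 for e in estimates
                 if e.ci[0] <= e.observed <= e.ci[1])
    return 100.0 * inside / len(estimates)


def deviation_statistic(estimates: list[TMRCAEstimate],
                        statistic: str = "mean") -> float:
    """Signed total deviation of a posterior summary from the documented
    values, normalised by N - 1 (positive = overestimation)."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates")
    vals = [getattr(e, statistic) - e.observed for e in estimates]
    return float(sum(vals) / (len(vals) - 1))


def regress_observed_on_expected(estimates: list[TMRCAEstimate],
                                 statistic: str = "mean",
                                 through_origin: bool = False):
    """OLS of documented TMRCA (y) on the estimated summary (x).

    Returns a dict with slope, its 95% CI and (with intercept) p-value and
    R-squared statistics.
    """
    if len(estimates) < 3:
        raise ValueError("need at least 3 estimates")
    x = np.array([getattr(e, statistic) for e in estimates], dtype=float)
    y = np.array([e.observed for e in estimates], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate estimates: zero variance")
    design = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    i = 0 if through_origin else 1
    ci = fit.conf_int()[i]
    out = {"slope": float(fit.params[i]),
           "slope_ci": (float(ci[0]), float(ci[1])),
           "through_origin": through_origin}
    if not through_origin:
        out.update(intercept=float(fit.params[0]),
                   p_slope=float(fit.pvalues[1]),
                   r2_multiple=float(fit.rsquared),
                   r2_adjusted=float(fit.rsquared_adj))
    return out


def flag_nonpaternity_tmrca(estimate: TMRCAEstimate) -> bool:
    """True when the documented depth lies below the posterior band, i.e.
    the genetic TMRCA is significantly higher than the archival one."""
    if estimate.observed is None:
        raise ValueError("estimate carries no documented value")
    return estimate.observed < estimate.ci[0]


# -- cohort driver ---------------------------------------------------------

def pool_mu(stats_by_locus, panel_loci, mode: str = "multi") -> float:
    """Panel-average per-locus per-meiosis rate: pooled counts of the
    panel's loci, in the requested counting mode (multi by default, since
    the SMM treats every single step as an event)."""
    loci = [l for l in panel_loci if l in stats_by_locus]
    if not loci:
        raise ValueError("no rate stats for any panel locus")
    attr = "mutations_multi" if mode == "multi" else "mutations_single"
    k = sum(getattr(stats_by_locus[l], attr) for l in loci)
    n = sum(stats_by_locus[l].meioses for l in loci)
    return k / n

def observation_from_pair(pair_id, panel, observations, mu) -> TMRCAObservation:
    """Build a TMRCAObservation from per-locus pair observations
    (:class:`ystrped.counting.PairLocusObservation`), skipping ambiguous loci."""
    usable = [o for o in observations if not o.ambiguous]
    steps = [abs(o.step_difference) for o in usable]
    k = sum(1 for s in steps if s)
    return TMRCAObservation(pair_id, panel, len(usable), k, steps, mu)
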