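"""Likelihood, MCMC fitting and cross-level statistics.

The likelihood treats the scored marker-class counts of each generation as a
multinomial draw around the deterministic trajectory propagated from the
seeded composition: generations are conditionally independent given the
mean-field recursion, and replicates enter as independent factors (pooled in
one likelihood by default).  Parameters are estimated by adaptive
random-walk Metropolis-Hastings on logit-transformed coordinates with
uniform [0, 1] priors, reporting the maximum a posteriori (MAP) draw,
central 95% credible intervals and split-Rhat convergence diagnostics.

Also included are the single-cross statistics used alongside the cage fits:
a chi-square goodness-of-fit against Mendelian 50:50 transmission, the
Mann-Whitney rank-sum U for comparing per-vial inheritance between sexes,
and the wildtype-normalised viability ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cage_simulator import CageProtocol, CageTrajectory
from .deterministic_dynamics import (
    MARKER_CLASSES,
    ExtinctionError,
    GenotypeFrequencies,
    seed_frequencies,
    trajectory_marker_expectations,
)
from .genetics_core import (
    FEMALE,
    MALE,
    DriveParams,
    ModelConfig,
    individual,
    trans_het,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "log_likelihood",
    "fit_mcmc",
    "credible_interval",
    "chisq_mendelian",
    "rank_sum_u",
    "normalize_viability",
]

#: DriveParams fields that may be declared free in a fit.
_FREE_FIELDS = tuple(DriveParams().__dataclass_fields__)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _seed_freqs_from_g0(counts: Mapping[str, int], config: ModelConfig) -> GenotypeFrequencies:
    """Interpret a G_0 scored row as the seeded adult composition.

    sGD+Cas9+ adults are taken to be double heterozygotes (D/W; Cas9/+),
    sGD+-only adults D/W without Cas9, Cas9+-only adults W/W; Cas9/+, the
    rest wildtype, split equally between the sexes.
    """
    def geno(cls, sex):
        if cls == "sgd_cas9":
            return trans_het(config, sex)
        a1, a2 = ("D", "W") if cls == "sgd_only" else ("W", "W")
        return individual(a1, a2, cas9=1 if cls == "cas9_only" else 0, sex=sex, config=config)

    females: Dict = {}
    males: Dict = {}
    for cls in ("sgd_cas9", "sgd_only", "cas9_only", "neither"):
        c = counts.get(cls, 0)
        if c <= 0:
            continue
        females[geno(cls, FEMALE)] = c / 2
        males[geno(cls, MALE)] = c / 2
    return seed_frequencies(females, males)


def log_likelihood(
    params: DriveParams,
    observed: CageTrajectory,
    config: ModelConfig,
    pool_replicates: bool = True,
    replicate: Optional[int] = None,
    drift_adjusted: bool = True,
) -> float:
    """Multinomial log-likelihood of observed cage counts under the
    deterministic trajectory.

    For each replicate the recursion is propagated from its G_0 composition;
    each scored generation g >= 1 contributes the multinomial log-probability
    of its four marker-class counts given the expected class proportions.
    Returns ``-inf`` when an observed class has zero expected probability or
    the modelled population goes extinct before the data do.

    By default the per-generation contribution is tempered to an effective
    sample size ``n_eff = 1/(1/n + 3g/N)`` (``N`` = passage census, taken
    equal to the scored census): genotype drift through g census bottlenecks
    adds variance of order ``3 g p(1-p)/N`` on top of the scoring noise
    ``p(1-p)/n`` — one part census sampling and roughly two parts
    family-size variance from monogamous mating at ~N/2 mated females,
    consistent with the simulator's measured replicate dispersion.  A plain
    multinomial treating generations as independent would be overconfident;
    ``drift_adjusted=False`` gives it anyway.
    """
    reps = observed.replicates() if replicate is None else [replicate]
    if not pool_replicates and replicate is None:
        raise ValueError("set pool_replicates=True or select a replicate")
    total = 0.0
    for rep in reps:
        sub = observed.data[observed.data["replicate"] == rep]
        gens = sorted(sub["generation"].tolist())
        if not gens or gens[0] != 0:
            raise ValueError(f"replicate {rep} lacks a generation-0 row")
        n_gen = int(max(gens))
        seed = _seed_freqs_from_g0(observed.class_counts(rep, 0), config)
        try:
            expect = trajectory_marker_expectations(seed, params, config, n_gen)
        except ExtinctionError:
            return -math.inf
        for g in gens:
            if g == 0:
                continue
            cts = observed.class_counts(rep, int(g))
            x = np.array([cts[c] for c in MARKER_CLASSES], dtype=float)
            p = expect[int(g)]
            if np.any((x > 0) & (p <= 0.0)):
                return -math.inf
            n = x.sum()
            if n == 0:
                continue
            lp = stats.multinomial.logpmf(x, int(n), p / p.sum())
            if not np.isfinite(lp):
                return -math.inf
            if drift_adjusted:
                lp *= 1.0 / (1.0 + 3.0 * g)  # n_eff/n with N = n
            total += float(lp)
    if math.isnan(total):
        raise ValueError("log-likelihood evaluated to NaN")
    return total


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSpec:
    """MCMC run specification.

    ``free`` lists the DriveParams fields to estimate (uniform [0, 1] priors
    on each); all other fields are fixed at their ``base`` value, e.g. at
    sex-specific cleavage/HDR rates initialised from single-cross data.
    """

    free: Tuple[str, ...]
    base: DriveParams
    chain_length: int = 4000
    burn_in: int = 1000
    thin: int = 1
    proposal_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name in self.free:
            if name not in _FREE_FIELDS:
                raise ValueError(f"unknown parameter {name!r}")
        if self.chain_length <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior draws, MAP point and 95% credible intervals."""

    draws: pd.DataFrame            # one column per free parameter + log_post
    map_estimate: Dict[str, float]
    credible_intervals: Dict[str, Tuple[float, float]]
    acceptance_rate: float
    rhat: Dict[str, float]
    converged: bool
    spec: Optional[FitSpec] = None

    def params_at_map(self) -> DriveParams:
        return replace(self.spec.base, **self.map_estimate)


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def split_rhat(x: np.ndarray, n_segments: int = 4) -> float:
    """Gelman-Rubin potential scale reduction computed on a single chain
    split into equal segments."""
    n = (len(x) // n_segments) * n_segments
    if n < 2 * n_segments:
        return math.nan
    segs = x[:n].reshape(n_segments, -1)
    m = segs.shape[1]
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean()
    B = m * means.var(ddof=1)
    if W <= 0.0:
        return 1.0
    var_plus = (m - 1) / m * W + B / m
    return float(math.sqrt(var_plus / W))


def fit_mcmc(
    spec: FitSpec,
    observed: CageTrajectory,
    config: ModelConfig,
    log_likelihood_fn=None,
) -> FitResult:
    """Adaptive random-walk Metropolis-Hastings on logit-transformed
    parameters.

    The target density on the logit scale is the likelihood times the
    uniform-prior Jacobian ``prod theta (1 - theta)``.  Per-parameter
    proposal scales adapt toward a 0.2-0.4 acceptance rate during burn-in
    only.  The MAP is the highest-posterior retained draw.  Non-convergence
    (split-Rhat > 1.1) is flagged via ``converged``, not fatal.
    """
    loglik = log_likelihood_fn or (
        lambda p: log_likelihood(p, observed, config)
    )
    k = len(spec.free)
    rng = np.random.default_rng(spec.seed)

    def log_post(theta: np.ndarray) -> float:
        if np.any(theta <= 0.0) or np.any(theta >= 1.0):
            return -math.inf
        params = replace(spec.base, **dict(zip(spec.free, theta.tolist())))
        ll = loglik(params)
        if not np.isfinite(ll):
            return -math.inf
        return ll + float(np.sum(np.log(theta) + np.log1p(-theta)))

    theta = np.array(
        [min(max(getattr(spec.base, n), 0.02), 0.98) for n in spec.free]
    )
    z = _logit(theta)
    lp = log_post(theta)
    if not np.isfinite(lp):
        theta = np.full(k, 0.5)
        z = _logit(theta)
        lp = log_post(theta)

    scales = np.full(k, spec.proposal_scale)
    kept: List[np.ndarray] = []
    kept_lp: List[float] = []
    n_accept = 0
    n_post = 0
    window_acc = np.zeros(k)
    window_n = 0

    for it in range(spec.chain_length):
        # one component-at-a-time sweep keeps acceptance well-behaved in
        # correlated posteriors without a covariance estimate
        for j in range(k):
            z_prop = z.copy()
            z_prop[j] += rng.normal(0.0, scales[j])
            theta_prop = _expit(z_prop)
            lp_prop = log_post(theta_prop)
            if math.log(rng.uniform()) < lp_prop - lp:
                z, lp = z_prop, lp_prop
                window_acc[j] += 1
                if it >= spec.burn_in:
                    n_accept += 1
        window_n += 1
        if it < spec.burn_in and window_n == 50:
            rate = window_acc / window_n
            scales *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            window_acc[:] = 0.0
            window_n = 0
        if it >= spec.burn_in:
            n_post += k
            if (it - spec.burn_in) % spec.thin == 0:
                kept.append(_expit(z))
                kept_lp.append(lp)

    draws = pd.DataFrame(np.array(kept), columns=list(spec.free))
    draws["log_post"] = kept_lp
    i_map = int(np.argmax(kept_lp))
    map_est = {n: float(draws[n].iloc[i_map]) for n in spec.free}
    cri = {n: credible_interval(draws[n].to_numpy()) for n in spec.free}
    rhat = {n: split_rhat(draws[n].to_numpy()) for n in spec.free}
    converged = all((not math.isnan(v)) and v <= 1.1 for v in rhat.values())
    return FitResult(
        draws=draws,
        map_estimate=map_est,
        credible_intervals=cri,
        acceptance_rate=n_accept / max(n_post, 1),
        rhat=rhat,
        converged=converged,
        spec=spec,
    )


def credible_interval(
    draws: Sequence[float], level: float = 0.95
) -> Tuple[float, float]:
    """Central quantile interval of posterior draws (>=100 draws required)."""
    x = np.asarray(draws, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    if level == 1.0:
        return (float(x.min()), float(x.max()))
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [a, 1.0 - a])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# single-cross statistics
# ---------------------------------------------------------------------------

class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chisq_mendelian(counts: Tuple[int, int]) -> ChiSquareResult:
    """Pearson chi-square goodness-of-fit of two inheritance counts against
    the Mendelian 50:50 expectation (df = 1)."""
    a, b = counts
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise ValueError("total count must be positive")
    e = n / 2.0
    stat = (a - e) ** 2 / e + (b - e) ** 2 / e
    return ChiSquareResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))


class RankSumResult(NamedTuple):
    U: float    # min-convention statistic, as conventionally printed
    U1: float   # one-sided U for group A
    U2: float   # one-sided U for group B
    pvalue: float


def rank_sum_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankSumResult:
    """Mann-Whitney U with midrank tie handling.

    ``U`` follows the min(U1, U2) reporting convention; the two-sided
    normal-approximation p-value comes from scipy's implementation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[: a.size].sum()
    u1 = r1 - a.size * (a.size + 1) / 2.0
    u2 = a.size * b.size - u1
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(min(u1, u2)), float(u1), float(u2), float(res.pvalue))


class ViabilityResult(NamedTuple):
    hatch_pct: float
    egg_to_adult_pct: float


def normalize_viability(
    hatched: float,
    laid: float,
    adults: float,
    wt_hatched: float,
    wt_laid: float,
    wt_adults: float,
) -> ViabilityResult:
    """Hatchability and egg-to-adult survival normalised to the proportions
    observed in parallel wildtype crosses (x100; values may exceed 100)."""
    if wt_laid <= 0 or laid <= 0:
        raise ValueError("egg counts must be positive")
    wt_hatch = wt_hatched / wt_laid
    wt_adult = wt_adults / wt_laid
    if wt_hatch <= 0 or wt_adult <= 0:
        raise ValueError("wildtype denominators must be positive")
    hatch = (hatched / laid) / wt_hatch * 100.0
    adult = (adults / laid) / wt_adult * 100.0
    return ViabilityResult(float(hatch), float(adult))
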