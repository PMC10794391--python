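"""Screening strategies: data-quality estimation and sample-size planning.

Three strategies are supported for assembling a sample of target-device
(by default headphone) users in an Internet study:

* **FWR** (Filter Without Request) — screen without disclosing the required
  device; keep test-positive participants.
* **FAR** (Filter After Request) — request the device first, then screen for
  compliance.
* **SCC** (Split–Convince–Compare) — split by unbiased self-report, prompt
  the non-target group to switch, screen only the prompted group; the final
  sample is the self-reported users plus the test-positive prompted users.

The number of true target-device users H in an accepted sample of size n is
modelled as Binomial(n, p), where p is the PPV of the screening procedure at
the relevant base rate (FWR/FAR) or the SCC success probability p̃.  From
that, sample sizes for a target count k at certainty ϑ follow from a normal
approximation with continuity correction, with an exact binomial search as
fallback, and post-hoc data-quality bounds follow from the binomial
quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binom, norm

from .combiner import Procedure
from .metrics import InputError, UndefinedQuantityError, UtilityWeights, overall_utility, ppv

__all__ = [
    "StrategyPlan",
    "PlanResult",
    "Candidate",
    "PosthocQuality",
    "prob_at_least",
    "data_quality_quantile",
    "required_n",
    "required_n_exact",
    "scc_success_prob",
    "plan",
    "posthoc_quality",
]

STRATEGIES = ("FWR", "FAR", "SCC")


@dataclass(frozen=True)
class StrategyPlan:
    """Planning inputs for one screening strategy.

    pi_hat is the prevalence estimate of the target device in the relevant
    population (for FAR: after the request); sigma_hat is the switching
    prevalence ς̂ and is required only for SCC; k is the desired number of
    true target-device users and theta the certainty with which at least k
    must be reached.
    """

    strategy: str
    pi_hat: float
    k: int
    theta: float
    sigma_hat: float | None = None
    utilities: UtilityWeights = field(default_factory=UtilityWeights)
    target_device: str = "headphones"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise InputError(f"strategy must be one of {STRATEGIES}")
        if not 0.0 <= self.pi_hat <= 1.0:
            raise InputError("pi_hat must lie in [0, 1]")
        if self.k < 1:
            raise InputError("k must be ≥ 1")
        if not 0.0 < self.theta < 1.0:
            raise InputError("theta must lie in (0, 1)")
        if self.strategy == "SCC":
            if self.sigma_hat is None:
                raise InputError("SCC requires a switching-prevalence estimate")
            if not 0.0 <= self.sigma_hat <= 1.0:
                raise InputError("sigma_hat must lie in [0, 1]")


@dataclass(frozen=True)
class Candidate:
    """A candidate screening procedure with its (combined) characteristics."""

    procedure: Procedure
    sen: float
    spe: float
    source: str = "user"  # provenance: fixture / user / independent-product / empirical


@dataclass(frozen=True)
class PlanResult:
    """One ranked planning outcome: procedure, success probability, n, utility."""

    procedure: Procedure
    success_prob: float
    n_required: int
    n_source: str  # "normal-approximation" or "exact-binomial"
    utility: float


def prob_at_least(k: int, n: int, p: float) -> float:
    """Exact binomial upper tail ϑ = P(H ≥ k) with H ~ Binomial(n, p)."""
    if k > n or k < 0 or n < 0:
        raise InputError(f"need 0 ≤ k ≤ n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise InputError("p must lie in [0, 1]")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


def data_quality_quantile(theta: float, n: int, p: float) -> int:
    """Largest k with P(H ≥ k) ≥ ϑ; k/n is the data-quality lower bound.

    With probability at least ϑ, an accepted sample of size n contains at
    least k true target-device users.
    """
    if not 0.0 < theta < 1.0:
        raise InputError("theta must lie in (0, 1)")
    # P(H ≥ k) is non-increasing in k; scan from above
    for k in range(n, -1, -1):
        if prob_at_least(k, n, p) >= theta:
            return k
    return 0


def required_n_exact(k: int, theta: float, p: float) -> int:
    """Smallest n with P(H ≥ k | n, p) ≥ ϑ by exact binomial search."""
    if not 0.0 < p <= 1.0:
        raise InputError("p must lie in (0, 1]")
    lo = k
    if prob_at_least(k, lo, p) >= theta:
        return lo
    hi = lo + 1
    while prob_at_least(k, hi, p) < theta:
        lo = hi
        hi *= 2
    while hi - lo > 1:  # tail prob is non-decreasing in n
        mid = (lo + hi) // 2
        if prob_at_least(k, mid, p) >= theta:
            hi = mid
        else:
            lo = mid
    return hi


def _required_n(k: int, theta: float, p: float) -> tuple[int, str]:
    if k < 1:
        raise InputError("k must be ≥ 1")
    if not 0.0 < theta < 1.0:
        raise InputError("theta must lie in (0, 1)")
    if not 0.0 < p <= 1.0:
        raise InputError("success probability must lie in (0, 1]")
    if p == 1.0:
        return k, "exact-binomial"
    if theta <= 0.5:
        # outside the stated domain of the normal approximation
        return required_n_exact(k, theta, p), "exact-binomial"
    z = norm.ppf(1.0 - theta)
    a = -(1.0 / p) * (2 * k - 1 + (1.0 - p) * z**2)
    b = (k - 0.5) ** 2 / p**2
    disc = (a / 2.0) ** 2 - b
    if disc < 0.0:
        return required_n_exact(k, theta, p), "exact-binomial"
    n = math.ceil(-a / 2.0 + math.sqrt(disc))
    return max(n, k), "normal-approximation"


def required_n(k: int, theta: float, p: float) -> int:
    """Sample size n such that P(H ≥ k | n, p) ≥ ϑ.

    Uses the De Moivre–Laplace normal approximation with continuity
    correction, n = −a/2 + √((a/2)² − b) with
    a = −p⁻¹(2k − 1 + (1−p)·Φ⁻¹(1−ϑ)²) and b = p⁻²(k − ½)², rounded up and
    floored at k.  For ϑ ≤ 0.5 or a negative discriminant the exact
    binomial search is used instead.
    """
    n, _ = _required_n(k, theta, p)
    return n


def scc_success_prob(pi_hat: float, sigma_hat: float, sen: float, spe: float) -> float:
    """SCC success probability p̃ = P(target device | D1 or D0⁺).

    Given unbiased self-report, a member of the final SCC sample is a
    self-reported user (probability π̂) or a prompted participant who
    switched and tested positive ((1−π̂)·ς̂·Sen) or failed to switch but
    false-alarmed ((1−π̂)·(1−ς̂)·(1−Spe)); p̃ is the fraction of the first
    two among all three.
    """
    for name, v in (("pi_hat", pi_hat), ("sigma_hat", sigma_hat), ("sen", sen), ("spe", spe)):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{name} must lie in [0, 1]")
    num = pi_hat + (1.0 - pi_hat) * sigma_hat * sen
    denom = pi_hat + (1.0 - pi_hat) * (
        sigma_hat * sen + (1.0 - sigma_hat) * (1.0 - spe)
    )
    if denom <= 0.0:
        raise UndefinedQuantityError("SCC success probability undefined: empty sample")
    return num / denom


def _success_prob(sp: StrategyPlan, sen: float, spe: float) -> float:
    if sp.target_device == "loudspeakers":
        # detecting loudspeakers swaps the roles of the two error rates
        sen, spe = spe, sen
    if sp.strategy == "SCC":
        return scc_success_prob(sp.pi_hat, sp.sigma_hat, sen, spe)
    return ppv(sen, spe, sp.pi_hat)


def _utility(sp: StrategyPlan, sen: float, spe: float) -> float:
    if sp.target_device == "loudspeakers":
        sen, spe = spe, sen
    # for SCC the screening test only operates in the prompted group, where
    # the base rate is the switching prevalence
    base = sp.sigma_hat if sp.strategy == "SCC" else sp.pi_hat
    return overall_utility(sen, spe, base, sp.utilities)


def plan(
    strategy_plan: StrategyPlan,
    candidates: list[Candidate],
    criterion: str = "min_n",
) -> list[PlanResult]:
    """Rank candidate procedures for a strategy.

    ``criterion="min_n"`` ranks ascending by the sample size required to
    reach k true users at certainty ϑ (the paper-style selection maximizing
    data quality); ``criterion="utility"`` ranks descending by overall
    utility, with the base rate replaced by ς̂ under SCC.  Ties break
    deterministically by fewer involved tests, then by procedure spec.
    """
    if not candidates:
        raise InputError("empty candidate list")
    if criterion not in ("min_n", "utility"):
        raise InputError("criterion must be 'min_n' or 'utility'")
    results = []
    for cand in candidates:
        p = _success_prob(strategy_plan, cand.sen, cand.spe)
        n, source = _required_n(strategy_plan.k, strategy_plan.theta, p) if p > 0 else (
            None,
            None,
        )
        if n is None:
            continue  # zero success probability: no finite n exists
        results.append(
            PlanResult(
                procedure=cand.procedure,
                success_prob=p,
                n_required=n,
                n_source=source,
                utility=_utility(strategy_plan, cand.sen, cand.spe),
            )
        )
    if not results:
        raise InputError("no candidate has a positive success probability")
    if criterion == "min_n":
        key = lambda r: (r.n_required, r.procedure.n_tests, r.procedure.spec)
    else:
        key = lambda r: (-r.utility, r.procedure.n_tests, r.procedure.spec)
    return sorted(results, key=key)


@dataclass(frozen=True)
class PosthocQuality:
    """Post-hoc data-quality lower bound at certainty ϑ."""

    quality: float
    k: int
    n: int
    theta: float


def posthoc_quality(
    strategy: str,
    group_sizes: int | tuple[int, int],
    p_or_ppv: float,
    theta: float,
) -> PosthocQuality:
    """Post-hoc data-quality lower bound for a conducted study.

    FWR/FAR: ``group_sizes`` is the accepted sample size n and ``p_or_ppv``
    the procedure's PPV; with probability ϑ the sample holds at least k true
    users, quality ≥ k/n.  SCC: ``group_sizes`` is (|D1|, |D0⁺|) and
    ``p_or_ppv`` the PPV within the prompted group (base rate ς̂); D1 is
    taken at face value (quality 1 under unbiased self-report), so the
    pooled bound is (|D1| + k_{D0⁺}) / (|D1| + |D0⁺|).
    """
    if strategy not in STRATEGIES:
        raise InputError(f"strategy must be one of {STRATEGIES}")
    if strategy == "SCC":
        n_d1, n_d0pos = group_sizes
        if n_d1 < 0 or n_d0pos < 0 or n_d1 + n_d0pos == 0:
            raise InputError("invalid SCC group sizes")
        k0 = data_quality_quantile(theta, n_d0pos, p_or_ppv) if n_d0pos else 0
        n = n_d1 + n_d0pos
        return PosthocQuality(quality=(n_d1 + k0) / n, k=n_d1 + k0, n=n, theta=theta)
    n = int(group_sizes)
    if n <= 0:
        raise InputError("sample size must be positive")
    k = data_quality_quantile(theta, n, p_or_ppv)
    return PosthocQuality(quality=k / n, k=k, n=n, theta=theta)
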