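"""Synthetic cohorts with the statistical structure the framework assumes.

Each participant starts on headphones with probability π (the device
prevalence) and, when the study requests headphones, switches to them with
probability ς if not already using them.  Every screening test then yields
``trials_per_test`` binary trial responses; a response is
headphone-indicating with per-trial probability q_pos on headphones and
q_neg on loudspeakers.  With the dependence parameter d > 0 a participant
is, with probability d, an "all-or-nothing" responder whose trials within a
test repeat one latent draw — this keeps the per-trial marginals while
inducing within-participant correlation, the minimal mechanism for
exercising the empirical-combination path.

Defaults emulate the main-study conditions: prevalence π = 0.1767,
switching prevalence ς = 0.55, six trials per test, and per-trial response
probabilities moment-matched to the published per-threshold characteristics
of the three tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .combiner import Procedure, combine_empirical
from .metrics import (
    DEVICE_COLUMN,
    NEGATIVE_DEVICE,
    POSITIVE_DEVICE,
    InputError,
    positive_calls,
)
from .strategy import StrategyPlan

__all__ = [
    "TestSpec",
    "CohortSpec",
    "CohortResponses",
    "DEFAULT_TESTS",
    "simulate_cohort",
    "theoretical_accuracy",
    "run_strategy_sim",
    "StrategySimSummary",
]


@dataclass(frozen=True)
class TestSpec:
    """Per-trial response probabilities of one screening test.

    q_pos / q_neg: probability of a headphone-indicating trial response
    given the participant actually uses headphones / loudspeakers.
    """

    q_pos: float
    q_neg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_pos <= 1.0 and 0.0 <= self.q_neg <= 1.0):
            raise InputError("trial probabilities must lie in [0, 1]")


# moment-matched to the main-study per-threshold tables: mean sensitivity
# (resp. false-alarm rate) over thresholds 1..6 equals the expected fraction
# of headphone-indicating trials
DEFAULT_TESTS: dict[str, TestSpec] = {
    "A": TestSpec(q_pos=0.848, q_neg=0.509),
    "B": TestSpec(q_pos=0.842, q_neg=0.311),
    "C": TestSpec(q_pos=0.940, q_neg=0.515),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic screening cohort."""

    n_participants: int
    pi: float = 0.1767
    sigma: float = 0.55
    tests: dict[str, TestSpec] = field(default_factory=lambda: dict(DEFAULT_TESTS))
    trials_per_test: int = 6
    dependence: float = 0.0
    misreport: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InputError("n_participants must be ≥ 1")
        for name in ("pi", "sigma", "dependence", "misreport"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        if self.trials_per_test < 1:
            raise InputError("trials_per_test must be ≥ 1")


@dataclass(frozen=True)
class CohortResponses:
    """Item-level outcomes of a (simulated or observed) cohort.

    ``frame`` holds one row per participant: ``initial_device`` (before any
    request), ``self_report`` of the initial device, ``switched``, the
    actual ``device`` at test time, and trial columns ``test<X>_<i>`` with
    1 for a headphone-indicating response.
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


def simulate_cohort(
    spec: CohortSpec, request: bool = False, seed: int | None = None
) -> CohortResponses:
    """Draw one cohort; fully reproducible from the seed.

    With ``request=True`` (the FAR/SCC flow) every participant not on the
    target device switches to it with probability ς before testing; trial
    outcomes are generated under the device actually in use at test time.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_participants
    on_target = rng.random(n) < spec.pi
    report = on_target.copy()
    flip = rng.random(n) < spec.misreport
    report[flip] = ~report[flip]
    if request:
        switched = (~on_target) & (rng.random(n) < spec.sigma)
    else:
        switched = np.zeros(n, dtype=bool)
    using = on_target | switched
    data: dict[str, np.ndarray | list[str]] = {
        "participant_id": [f"p{i:06d}" for i in range(n)],
        "initial_device": np.where(on_target, POSITIVE_DEVICE, NEGATIVE_DEVICE),
        "self_report": np.where(report, POSITIVE_DEVICE, NEGATIVE_DEVICE),
        "switched": switched,
        DEVICE_COLUMN: np.where(using, POSITIVE_DEVICE, NEGATIVE_DEVICE),
    }
    latent_responder = rng.random(n) < spec.dependence
    t = spec.trials_per_test
    for test_id, ts in spec.tests.items():
        q = np.where(using, ts.q_pos, ts.q_neg)
        independent = rng.random((n, t)) < q[:, None]
        shared = (rng.random(n) < q)[:, None] & np.ones((1, t), dtype=bool)
        trials = np.where(latent_responder[:, None], shared, independent)
        for i in range(t):
            data[f"test{test_id}_{i + 1}"] = trials[:, i].astype(int)
    return CohortResponses(frame=pd.DataFrame(data))


def theoretical_accuracy(q: float, trials: int, threshold: int) -> float:
    """P(Binomial(trials, q) ≥ threshold): the exact per-threshold call rate
    implied by independent trials with per-trial probability q."""
    if not 1 <= threshold <= trials:
        raise InputError("threshold must lie in 1..trials")
    return float(binom.sf(threshold - 1, trials, q))


@dataclass(frozen=True)
class StrategySimSummary:
    """Monte-Carlo summary of one strategy executed on simulated cohorts.

    ``success_prob`` is the pooled fraction of accepted participants who
    truly used the target device at test time (the empirical PPV or p̃);
    ``mean_quality`` averages the per-replicate fraction; ``prob_k_reached``
    is the fraction of replicates whose final sample of size ``n_final``
    held at least k true users.
    """

    strategy: str
    n_final: int
    replicates: int
    success_prob: float
    mean_quality: float
    prob_k_reached: float
    k: int


def _accept(frame: pd.DataFrame, strategy: str, procedure: Procedure) -> np.ndarray:
    comb = procedure.combiner
    weighted = np.zeros(len(frame))
    for t in comb.involved:
        w = comb.weights[("A", "B", "C").index(t)]
        weighted += float(w) * positive_calls(frame, t, procedure.thresholds[t]).to_numpy()
    positive = weighted >= 1.0 - 1.0 / 24.0
    if strategy in ("FWR", "FAR"):
        return positive
    reported = (frame["self_report"] == POSITIVE_DEVICE).to_numpy()
    return reported | (~reported & positive)  # D1 plus D0+


def run_strategy_sim(
    spec: CohortSpec,
    strategy_plan: StrategyPlan,
    procedure: Procedure,
    replicates: int = 200,
    n_final: int | None = None,
    seed: int | None = None,
) -> StrategySimSummary:
    """Execute a screening strategy on simulated cohorts.

    Each replicate recruits participants until the strategy's final sample
    reaches ``n_final`` accepted members (default: the plan's k), mirroring
    a study that stops at its planned sample size.  Replicate r uses seed
    ``seed + r``.
    """
    strategy = strategy_plan.strategy
    k = strategy_plan.k
    n_final = k if n_final is None else n_final
    base_seed = spec.seed if seed is None else seed
    request = strategy in ("FAR", "SCC")
    true_counts = np.empty(replicates, dtype=int)
    for r in range(replicates):
        accepted_true = 0
        accepted = 0
        chunk_seed = base_seed + r
        # recruit in chunks until n_final accepted
        batch = max(64, int(n_final * 2))
        guard = 0
        while accepted < n_final:
            cohort = simulate_cohort(
                replace(spec, n_participants=batch),
                request=request,
                seed=(chunk_seed * 1_000_003 + guard) % 2**31,
            )
            frame = cohort.frame
            acc = _accept(frame, strategy, procedure)
            truth = (frame[DEVICE_COLUMN] == POSITIVE_DEVICE).to_numpy()
            if strategy_plan.target_device == NEGATIVE_DEVICE:
                truth = ~truth
            take = np.flatnonzero(acc)[: n_final - accepted]
            accepted += len(take)
            accepted_true += int(truth[take].sum())
            guard += 1
            if guard > 10_000:
                raise InputError("acceptance probability too small to fill the sample")
        true_counts[r] = accepted_true
    pooled = true_counts.sum() / (replicates * n_final)
    return StrategySimSummary(
        strategy=strategy,
        n_final=n_final,
        replicates=replicates,
        success_prob=pooled,
        mean_quality=float(np.mean(true_counts / n_final)),
        prob_k_reached=float(np.mean(true_counts >= k)),
        k=k,
    )


def empirical_combined(
    spec: CohortSpec, procedure: Procedure, request: bool = False, seed: int | None = None
):
    """Convenience: simulate one cohort and score a procedure empirically."""
    cohort = simulate_cohort(spec, request=request, seed=seed)
    return combine_empirical(cohort.frame, procedure)
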