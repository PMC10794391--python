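"""Diagnostic-accuracy quantities for a single binary screening rule.

A screening test for playback devices classifies each participant as a
headphone user (positive) or a loudspeaker user (negative).  Against the
true device this yields the usual confusion cells (hit / miss / correct
rejection / false alarm), from which sensitivity, specificity and the
prevalence-dependent predictive values follow.  Interval estimates use the
Wilson score interval for binomial proportions, the interval recommended by
Agresti & Coull.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "UndefinedQuantityError",
    "InputError",
    "ConfusionCounts",
    "Accuracy",
    "PrevalenceEstimate",
    "UtilityWeights",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "overall_utility",
    "score_ci",
    "accuracy_from_responses",
    "format_percent",
]


class UndefinedQuantityError(ValueError):
    """A requested quantity is mathematically undefined for the given input."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def format_percent(p: float, decimals: int = 1) -> str:
    """Format a proportion as a percentage, rounding halves up.

    Tables in this field print one-decimal percentages with half-up
    rounding (96.25 % prints as 96.3), which differs from Python's
    banker's rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(repr(float(p))) * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cell counts of one screening rule against truth.

    tp: true headphone users with a positive result (hits)
    fn: true headphone users with a negative result (misses)
    tn: true loudspeaker users with a negative result (correct rejections)
    fp: true loudspeaker users with a positive result (false alarms)
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class Accuracy:
    """Point estimates of a rule's sensitivity and specificity with group sizes."""

    sen: float
    spe: float
    n_pos: int
    n_neg: int
    sen_ci: tuple[float, float] | None = None
    spe_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sen <= 1.0 and 0.0 <= self.spe <= 1.0):
            raise InputError("sen and spe must lie in [0, 1]")
        for est, ci in ((self.sen, self.sen_ci), (self.spe, self.spe_ci)):
            if ci is None:
                continue
            lo, hi = ci
            if not (0.0 <= lo <= hi <= 1.0):
                raise InputError(f"CI bounds {ci} must be ordered within [0, 1]")
            if not (lo - 1e-12 <= est <= hi + 1e-12):
                raise InputError(f"point estimate {est} outside its CI {ci}")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Estimated base rate of the target device with its score CI."""

    n_success: int
    n_total: int
    level: float = 0.95
    pi_hat: float = field(init=False)
    ci: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= self.n_total or self.n_total <= 0:
            raise InputError("need 0 <= n_success <= n_total, n_total > 0")
        object.__setattr__(self, "pi_hat", self.n_success / self.n_total)
        object.__setattr__(self, "ci", score_ci(self.n_success, self.n_total, self.level))


@dataclass(frozen=True)
class UtilityWeights:
    """Desirabilities of the four classification outcomes, each in [0, 1].

    The default (1, 0, 1, 0) rewards correct classifications only, so the
    overall utility reduces to the probability of a correct classification.
    """

    u_tp: float = 1.0
    u_fn: float = 0.0
    u_tn: float = 1.0
    u_fp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_tp", "u_fn", "u_tn", "u_fp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v!r}")


def sensitivity(counts: ConfusionCounts) -> float:
    """Hit rate: P(test positive | headphones) = TP / (TP + FN)."""
    if counts.n_pos == 0:
        raise UndefinedQuantityError("sensitivity undefined: no true headphone users")
    return counts.tp / counts.n_pos


def specificity(counts: ConfusionCounts) -> float:
    """Correct-rejection rate: P(test negative | loudspeakers) = TN / (TN + FP)."""
    if counts.n_neg == 0:
        raise UndefinedQuantityError("specificity undefined: no true loudspeaker users")
    return counts.tn / counts.n_neg


def ppv(sen: float, spe: float, pi: float) -> float:
    """Positive predictive value P(headphones | test positive).

    Depends on the base rate ``pi`` of headphone users; unlike sensitivity
    and specificity it is not intrinsic to the test.
    """
    denom = sen * pi + (1.0 - spe) * (1.0 - pi)
    if denom <= 0.0:
        raise UndefinedQuantityError("PPV undefined: P(test positive) is zero")
    return sen * pi / denom


def npv(sen: float, spe: float, pi: float) -> float:
    """Negative predictive value P(loudspeakers | test negative)."""
    denom = (1.0 - sen) * pi + spe * (1.0 - pi)
    if denom <= 0.0:
        raise UndefinedQuantityError("NPV undefined: P(test negative) is zero")
    return spe * (1.0 - pi) / denom


def overall_utility(
    sen: float, spe: float, pi: float, weights: UtilityWeights = UtilityWeights()
) -> float:
    """Utility-weighted sum of the probabilities of the four outcomes.

    U = π·Sen·U_TP + π·(1−Sen)·U_FN + (1−π)·Spe·U_TN + (1−π)·(1−Spe)·U_FP
    """
    return (
        pi * sen * weights.u_tp
        + pi * (1.0 - sen) * weights.u_fn
        + (1.0 - pi) * spe * weights.u_tn
        + (1.0 - pi) * (1.0 - spe) * weights.u_fp
    )


def score_ci(successes: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    Uses the exact normal quantile z = Φ⁻¹(1 − α/2); bounds are clamped
    to [0, 1].
    """
    if total <= 0 or not 0 <= successes <= total:
        raise InputError(f"invalid counts {successes}/{total}")
    if not 0.0 < level < 1.0:
        raise InputError(f"confidence level must lie in (0, 1), got {level}")
    lo, hi = proportion_confint(successes, total, alpha=1.0 - level, method="wilson")
    # the Wilson bound is exactly 0 (resp. 1) at the boundary counts; snap
    # floating-point residue so downstream equality checks hold
    lo = 0.0 if successes == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if successes == total else float(np.clip(hi, 0.0, 1.0))
    return (lo, hi)


# item-level schema: one row per participant, trial outcome columns
# <test>_1.. <test>_T holding 1 for a headphone-indicating response
DEVICE_COLUMN = "device"
POSITIVE_DEVICE = "headphones"
NEGATIVE_DEVICE = "loudspeakers"


def trial_columns(frame: pd.DataFrame, test_id: str) -> list[str]:
    """Ordered trial-outcome columns of one test, e.g. testA_1..testA_6."""
    prefix = f"test{test_id}_"
    cols = [c for c in frame.columns if c.startswith(prefix)]
    return sorted(cols, key=lambda c: int(c.removeprefix(prefix)))


def positive_calls(frame: pd.DataFrame, test_id: str, threshold: int) -> pd.Series:
    """Dichotomize one test: positive iff ≥ threshold headphone-indicating trials."""
    cols = trial_columns(frame, test_id)
    if not cols:
        raise InputError(f"no trial columns for test {test_id!r}")
    if not 1 <= threshold <= len(cols):
        raise InputError(
            f"threshold {threshold} outside 1..{len(cols)} for test {test_id!r}"
        )
    block = frame[cols]
    if block.isna().any().any():
        raise InputError(f"missing trial data for test {test_id!r}")
    return block.sum(axis=1) >= threshold


def accuracy_from_responses(
    responses: pd.DataFrame, test_id: str, threshold: int, level: float = 0.95
) -> Accuracy:
    """Sensitivity/specificity of a threshold rule evaluated on item-level data.

    A participant is classified positive iff at least ``threshold`` of the
    test's trials got a headphone-indicating response; the classification is
    compared against the true device column.  Score CIs are attached.
    """
    pos = positive_calls(responses, test_id, threshold)
    device = responses[DEVICE_COLUMN]
    is_hp = device == POSITIVE_DEVICE
    is_ls = device == NEGATIVE_DEVICE
    counts = ConfusionCounts(
        tp=int((pos & is_hp).sum()),
        fn=int((~pos & is_hp).sum()),
        tn=int((~pos & is_ls).sum()),
        fp=int((pos & is_ls).sum()),
    )
    sen = sensitivity(counts)
    spe = specificity(counts)
    return Accuracy(
        sen=sen,
        spe=spe,
        n_pos=counts.n_pos,
        n_neg=counts.n_neg,
        sen_ci=score_ci(counts.tp, counts.n_pos, level),
        spe_ci=score_ci(counts.tn, counts.n_neg, level),
    )
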