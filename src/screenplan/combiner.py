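"""Voting combiners for parallel screening tests.

Up to three screening tests run in parallel; their binary outcomes are fused
by a weighted vote: the ensemble is positive (headphones) iff
ω_A·A + ω_B·B + ω_C·C ≥ 1.  Weights are exact rationals so the threshold
comparison never suffers floating-point ties.  Eighteen logically distinct
rules are catalogued — 3 singles, 6 pairwise (AND/OR per pair) and 9
three-way rules — each under an *evaluation key* (EK).

Characteristics of a combination are obtained either by the product rule
(valid only under conditional independence of the tests given the true
device, which :func:`conditional_independence_test` checks) or empirically,
by treating the combination as one test on item-level data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency

from .metrics import (
    DEVICE_COLUMN,
    NEGATIVE_DEVICE,
    POSITIVE_DEVICE,
    Accuracy,
    ConfusionCounts,
    InputError,
    positive_calls,
    score_ci,
    sensitivity,
    specificity,
)

__all__ = [
    "TESTS",
    "Combiner",
    "Procedure",
    "CombinedAccuracy",
    "IndependenceResult",
    "DependenceError",
    "enumerate_combiners",
    "get_combiner",
    "vote",
    "enumerate_procedures",
    "combine_independent",
    "combine_empirical",
    "conditional_independence_test",
    "combine",
]

TESTS = ("A", "B", "C")

F = Fraction


@dataclass(frozen=True)
class Combiner:
    """A weighted voting rule over up to three test outcomes.

    The ensemble result G(A, B, C) is 1 (headphones) iff
    ω_A·A + ω_B·B + ω_C·C ≥ 1.  ``ek`` is the rule's evaluation key in the
    catalogue; ``label`` describes the equivalent logical statement.
    """

    ek: int
    weights: tuple[Fraction, Fraction, Fraction]
    label: str

    def __post_init__(self) -> None:
        if not all(0 <= w <= 1 for w in self.weights):
            raise InputError("combiner weights must lie in [0, 1]")
        if sum(self.weights) < 1:
            raise InputError("weights must allow a positive vote (sum ≥ 1)")

    @property
    def involved(self) -> tuple[str, ...]:
        """Tests with nonzero weight, in A/B/C order."""
        return tuple(t for t, w in zip(TESTS, self.weights) if w > 0)

    def truth_table(self) -> dict[tuple[int, int, int], int]:
        """Global result for each of the 8 outcome triples."""
        return {o: vote(self, o) for o in itertools.product((0, 1), repeat=3)}


def vote(combiner: Combiner, outcomes: tuple[int, int, int]) -> int:
    """Apply the weighted vote: 1 iff ω·outcomes ≥ 1 (exact arithmetic)."""
    if any(o not in (0, 1) for o in outcomes):
        raise InputError(f"outcomes must be binary, got {outcomes!r}")
    total = sum(w for w, o in zip(combiner.weights, outcomes) if o)
    return int(total >= 1)


def _catalogue() -> list[Combiner]:
    """The 18 canonical voting rules.

    Singles, then AND pairs, OR pairs, three-way OR, majority, three-way
    AND, the (X OR Y) AND Z family, and the (X AND Y) OR Z family.  The
    numbering places the anchored rules at EK 6 (B AND C), EK 11
    (majority), EK 12 (all three) and EK 13 ((A OR B) AND C).
    """
    h, q3, q1, th = F(1, 2), F(3, 4), F(1, 4), F(1, 3)
    rows: list[tuple[tuple[Fraction, Fraction, Fraction], str]] = [
        ((F(1), F(0), F(0)), "Test A"),
        ((F(0), F(1), F(0)), "Test B"),
        ((F(0), F(0), F(1)), "Test C"),
        ((h, h, F(0)), "Test A AND Test B"),
        ((h, F(0), h), "Test A AND Test C"),
        ((F(0), h, h), "Test B AND Test C"),
        ((F(1), F(1), F(0)), "Test A OR Test B"),
        ((F(1), F(0), F(1)), "Test A OR Test C"),
        ((F(0), F(1), F(1)), "Test B OR Test C"),
        ((F(1), F(1), F(1)), "Test A OR Test B OR Test C"),
        ((h, h, h), "at least two times headphones"),
        ((th, th, th), "Test A AND Test B AND Test C"),
        ((q1, q1, q3), "(Test A OR Test B) AND Test C"),
        ((q1, q3, q1), "(Test A OR Test C) AND Test B"),
        ((q3, q1, q1), "(Test B OR Test C) AND Test A"),
        ((h, h, F(1)), "(Test A AND Test B) OR Test C"),
        ((h, F(1), h), "(Test A AND Test C) OR Test B"),
        ((F(1), h, h), "(Test B AND Test C) OR Test A"),
    ]
    return [Combiner(ek=i, weights=w, label=lab) for i, (w, lab) in enumerate(rows, 1)]


def enumerate_combiners(ek_map: dict[int, int] | None = None) -> list[Combiner]:
    """All 18 voting combiners, optionally renumbered.

    ``ek_map`` maps default EK numbers to alternative ones (the published
    catalogue's full numbering is configurable; the anchored rules keep
    their default keys when no map is given).
    """
    combiners = _catalogue()
    if ek_map is None:
        return combiners
    if sorted(ek_map.values()) != sorted(set(ek_map.values())):
        raise InputError("ek_map must be injective")
    return [
        Combiner(ek=ek_map.get(c.ek, c.ek), weights=c.weights, label=c.label)
        for c in combiners
    ]


def get_combiner(ek: int) -> Combiner:
    """Look up one combiner by its (default) evaluation key."""
    for c in _catalogue():
        if c.ek == ek:
            return c
    raise InputError(f"unknown evaluation key {ek}")


@dataclass(frozen=True)
class Procedure:
    """A fully specified screening method: a combiner plus per-test thresholds."""

    combiner: Combiner
    thresholds: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(self.combiner.involved):
            raise InputError(
                "thresholds must be given exactly for the tests with nonzero weight"
            )
        if any(t < 1 for t in self.thresholds.values()):
            raise InputError("thresholds must be ≥ 1")

    def __hash__(self) -> int:
        return hash((self.combiner, tuple(sorted(self.thresholds.items()))))

    @property
    def spec(self) -> str:
        """Compact string form, e.g. ``EK11:A5,B5,C6``."""
        parts = ",".join(f"{t}{self.thresholds[t]}" for t in self.combiner.involved)
        return f"EK{self.combiner.ek}:{parts}"

    @property
    def n_tests(self) -> int:
        return len(self.combiner.involved)


def enumerate_procedures(
    max_threshold: int = 6, ek_map: dict[int, int] | None = None
) -> list[Procedure]:
    """Every combiner crossed with every threshold assignment.

    For T thresholds per test this yields 3T + 6T² + 9T³ procedures
    (2,178 at the canonical T = 6).
    """
    if max_threshold < 1:
        raise InputError("max_threshold must be ≥ 1")
    out = []
    for comb in enumerate_combiners(ek_map):
        for thresholds in itertools.product(
            range(1, max_threshold + 1), repeat=len(comb.involved)
        ):
            out.append(Procedure(comb, dict(zip(comb.involved, thresholds))))
    return out


@dataclass(frozen=True)
class CombinedAccuracy:
    """Sensitivity/specificity of a test combination.

    ``method`` records how the values were obtained: ``independent-product``
    (product rule under conditional independence) or ``empirical``
    (combination treated as a single test on item-level data).
    ``outcome_probs`` maps each outcome tuple of the involved tests to its
    probability within each device stratum.
    """

    sen: float
    spe: float
    method: str
    outcome_probs: dict[str, dict[tuple[int, ...], float]] | None = None
    sen_ci: tuple[float, float] | None = None
    spe_ci: tuple[float, float] | None = None


def combine_independent(
    chars: dict[str, Accuracy], combiner: Combiner
) -> CombinedAccuracy:
    """Product-rule combination of per-test characteristics.

    Valid when the involved tests are conditionally independent given the
    true device: within each stratum the probability of an outcome tuple is
    the product of per-test marginals (Sen or 1−Sen given headphones,
    1−Spe or Spe given loudspeakers).  Combined Sen sums the headphone-
    stratum probabilities over tuples the vote calls positive; combined Spe
    sums the loudspeaker-stratum probabilities over tuples called negative.
    """
    involved = combiner.involved
    missing = [t for t in involved if t not in chars]
    if missing:
        raise InputError(f"missing characteristics for tests {missing}")
    sen = spe = 0.0
    probs: dict[str, dict[tuple[int, ...], float]] = {
        POSITIVE_DEVICE: {},
        NEGATIVE_DEVICE: {},
    }
    for tup in itertools.product((0, 1), repeat=len(involved)):
        p_hp = math.prod(
            chars[t].sen if o else 1.0 - chars[t].sen for t, o in zip(involved, tup)
        )
        p_ls = math.prod(
            1.0 - chars[t].spe if o else chars[t].spe for t, o in zip(involved, tup)
        )
        probs[POSITIVE_DEVICE][tup] = p_hp
        probs[NEGATIVE_DEVICE][tup] = p_ls
        full = tuple(
            tup[involved.index(t)] if t in involved else 0 for t in TESTS
        )
        if vote(combiner, full):
            sen += p_hp
        else:
            spe += p_ls
    return CombinedAccuracy(
        sen=sen, spe=spe, method="independent-product", outcome_probs=probs
    )


def combine_empirical(
    responses: pd.DataFrame, procedure: Procedure, level: float = 0.95
) -> CombinedAccuracy:
    """Empirical combination: the ensemble is scored as one screening test.

    Each involved test is dichotomized at its threshold, the vote rule is
    applied per participant, and sensitivity/specificity are computed on the
    resulting classification.  This is the fallback when conditional
    independence fails.
    """
    comb = procedure.combiner
    calls = {
        t: positive_calls(responses, t, procedure.thresholds[t]).to_numpy()
        for t in comb.involved
    }
    n = len(responses)
    weighted = np.zeros(n)
    for t, w in zip(TESTS, comb.weights):
        if w > 0:
            weighted += float(w) * calls[t]
    # weights are exact rationals with denominators 2, 3 or 4; a margin of
    # 1/24 is safely below the smallest possible gap to the threshold 1
    pos = weighted >= 1.0 - 1.0 / 24.0
    device = responses[DEVICE_COLUMN].to_numpy()
    is_hp = device == POSITIVE_DEVICE
    is_ls = device == NEGATIVE_DEVICE
    counts = ConfusionCounts(
        tp=int((pos & is_hp).sum()),
        fn=int((~pos & is_hp).sum()),
        tn=int((~pos & is_ls).sum()),
        fp=int((pos & is_ls).sum()),
    )
    tuples = list(zip(*(calls[t].astype(int) for t in comb.involved)))
    probs: dict[str, dict[tuple[int, ...], float]] = {}
    for name, mask in ((POSITIVE_DEVICE, is_hp), (NEGATIVE_DEVICE, is_ls)):
        group = [tup for tup, m in zip(tuples, mask) if m]
        probs[name] = {
            tup: sum(g == tup for g in group) / len(group)
            for tup in itertools.product((0, 1), repeat=len(comb.involved))
        } if group else {}
    return CombinedAccuracy(
        sen=sensitivity(counts),
        spe=specificity(counts),
        method="empirical",
        outcome_probs=probs,
        sen_ci=score_ci(counts.tp, counts.n_pos, level),
        spe_ci=score_ci(counts.tn, counts.n_neg, level),
    )


@dataclass(frozen=True)
class IndependenceResult:
    """Outcome of a conditional-independence check within one device stratum."""

    p_value: float
    method: str  # "chi2", "exact-multinomial" or "degenerate"
    table: tuple[tuple[int, int], tuple[int, int]]
    alpha: float
    degenerate: bool = False

    @property
    def rejected(self) -> bool:
        """True when independence is rejected at the configured α."""
        return (not self.degenerate) and self.p_value < self.alpha


def _multinomial_logpmf(counts: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """Log-pmf of Multinomial(n, p) for rows of 4-cell count vectors."""
    logcoef = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.where(p > 0, p, 1.0)), 0.0)
        terms = np.where((counts > 0) & (p == 0), -np.inf, terms)
    return logcoef + terms.sum(axis=-1)


# above this total, full enumeration of the O(n³) table space is replaced by
# a seeded Monte-Carlo estimate of the exact p-value
_EXACT_ENUM_LIMIT = 200
_MC_TABLES = 200_000


def _exact_multinomial_p(table: np.ndarray) -> float:
    """Exact multinomial independence test on a 2×2 table.

    Null cell probabilities are the products of the observed margins; the
    p-value sums the multinomial probabilities of every table with the same
    total whose probability does not exceed the observed table's.  For
    totals beyond a few hundred the full table space is too large to
    enumerate and the p-value is estimated by drawing tables from the null
    (seeded, hence reproducible).
    """
    n = int(table.sum())
    if n > _EXACT_ENUM_LIMIT:
        row = table.sum(axis=1) / n
        col = table.sum(axis=0) / n
        p = np.outer(row, col).ravel()
        log_obs = float(_multinomial_logpmf(table.ravel(), n, p))
        rng = np.random.default_rng(87131)
        draws = rng.multinomial(n, p, size=_MC_TABLES)
        logs = _multinomial_logpmf(draws, n, p)
        return float(np.mean(logs <= log_obs + 1e-9))
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p = np.outer(row, col).ravel()
    # enumerate all (a, b, c, d) with a+b+c+d = n
    a, b, c = np.meshgrid(
        np.arange(n + 1), np.arange(n + 1), np.arange(n + 1), indexing="ij", sparse=True
    )
    d = n - a - b - c
    valid = d >= 0
    logp = np.full(valid.shape, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        logcoef = (
            gammaln(n + 1)
            - gammaln(a + 1)
            - gammaln(b + 1)
            - gammaln(c + 1)
            - gammaln(np.where(valid, d, 0) + 1)
        )
        logcells = sum(
            np.where(k > 0, k * np.log(np.where(p_i > 0, p_i, 1.0)), 0.0)
            + np.where((k > 0) & (p_i == 0), -np.inf, 0.0)
            for k, p_i in zip((a, b, c, np.where(valid, d, 0)), p)
        )
    logp = np.where(valid, logcoef + logcells, -np.inf)
    obs = table.ravel()
    log_obs = (
        gammaln(n + 1)
        - sum(gammaln(k + 1) for k in obs)
        + sum(
            k * np.log(p_i) if k > 0 else 0.0
            for k, p_i in zip(obs, p)
            if not (k > 0 and p_i == 0)
        )
    )
    # tolerance absorbs log-space round-off when ranking equiprobable tables
    mask = logp <= log_obs + 1e-9
    return float(np.exp(logp[mask]).sum().clip(0.0, 1.0))


def conditional_independence_test(
    responses: pd.DataFrame,
    test_x: str,
    test_y: str,
    thresholds: dict[str, int],
    device_group: str,
    alpha: float = 0.10,
    continuity_correction: bool = False,
) -> IndependenceResult:
    """Test conditional independence of two dichotomized tests in one stratum.

    Within the participants whose true device is ``device_group``, the 2×2
    table of the two tests' threshold calls is tested for independence with
    a chi-square test, or with an exact multinomial test when any expected
    cell count falls below 5.  The null hypothesis (independence) is the
    hypothesis of interest, so a comparatively high α (default .10) guards
    against the type-II error.
    """
    stratum = responses[responses[DEVICE_COLUMN] == device_group]
    if len(stratum) == 0:
        raise InputError(f"device stratum {device_group!r} is empty")
    x = positive_calls(stratum, test_x, thresholds[test_x]).to_numpy()
    y = positive_calls(stratum, test_y, thresholds[test_y]).to_numpy()
    table = np.array(
        [
            [int((x & y).sum()), int((x & ~y).sum())],
            [int((~x & y).sum()), int((~x & ~y).sum())],
        ]
    )
    tup = tuple(map(tuple, table.tolist()))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # a constant margin cannot show dependence; flag rather than reject
        return IndependenceResult(1.0, "degenerate", tup, alpha, degenerate=True)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return IndependenceResult(_exact_multinomial_p(table), "exact-multinomial", tup, alpha)
    res = chi2_contingency(table, correction=continuity_correction)
    return IndependenceResult(float(res.pvalue), "chi2", tup, alpha)


class DependenceError(ValueError):
    """Product-rule combination refused because conditional independence failed."""


def combine(
    procedure: Procedure,
    chars: dict[str, Accuracy] | None = None,
    responses: pd.DataFrame | None = None,
    alpha: float = 0.10,
    on_dependence: str = "empirical",
) -> CombinedAccuracy:
    """Combine a procedure's tests, guarding the product rule.

    With item-level ``responses``, conditional independence is checked for
    every involved pair in both device strata; on any rejection the
    combination falls back to the empirical route (or raises
    :class:`DependenceError` with ``on_dependence="raise"``).  With
    characteristics only, the product rule is applied on the caller's
    assertion of independence (the published-characteristics workflow when
    only Sen/Spe are available); if ``responses`` are absent and ``chars``
    are too, that is an error.
    """
    if on_dependence not in ("empirical", "raise"):
        raise InputError("on_dependence must be 'empirical' or 'raise'")
    comb = procedure.combiner
    if responses is not None:
        if len(comb.involved) >= 2:
            for tx, ty in itertools.combinations(comb.involved, 2):
                for device in (POSITIVE_DEVICE, NEGATIVE_DEVICE):
                    res = conditional_independence_test(
                        responses, tx, ty, procedure.thresholds, device, alpha=alpha
                    )
                    if res.rejected:
                        if on_dependence == "raise":
                            raise DependenceError(
                                f"tests {tx}/{ty} are conditionally dependent in the "
                                f"{device} stratum (p = {res.p_value:.4f} < {alpha})"
                            )
                        return combine_empirical(responses, procedure)
        if chars is None:
            return combine_empirical(responses, procedure)
    if chars is None:
        raise InputError("need characteristics or item-level responses")
    if len(comb.involved) == 1:
        t = comb.involved[0]
        return CombinedAccuracy(
            sen=chars[t].sen, spe=chars[t].spe, method="independent-product"
        )
    return combine_independent(chars, comb)
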