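"""Packaged characteristics tables of the three playback-device tests.

Two published per-threshold tables ship with the package: the laboratory
pre-study (tests A and B, four trials each, 80 observations per device
group) and the Internet main study (tests A, B and C, six trials each, 80
headphone and 131 loudspeaker users), plus two headphone-prevalence
estimates (A: 80/211 among valid cases; B: 211/1194 among all participants
reaching the device filter).

Values are stored as the published one-decimal percentages; loading
reconstructs the underlying cell counts (round(pct/100 × group size)) and
verifies the count re-prints to the stored percentage, so downstream
arithmetic (ROC, AUC, combination) runs on exact proportions.
"""

from __future__ import annotations

import pandas as pd

from .metrics import InputError, PrevalenceEstimate, format_percent

__all__ = ["load_fixture", "FIXTURE_NAMES", "characteristics_frame"]

# columns: threshold, sen%, sen CI lo/hi %, spe%, spe CI lo/hi %
_PRESTUDY = {
    "A": [
        (1, 96.3, 89.6, 98.7, 16.3, 9.80, 25.9),
        (2, 96.3, 89.6, 98.7, 22.5, 14.7, 32.8),
        (3, 93.8, 86.3, 97.3, 28.8, 20.0, 39.5),
        (4, 83.8, 74.2, 90.3, 42.5, 32.3, 53.4),
    ],
    "B": [
        (1, 57.5, 46.6, 67.7, 81.3, 71.4, 88.3),
        (2, 51.3, 40.5, 61.9, 91.3, 83.1, 95.7),
        (3, 43.8, 33.4, 54.7, 98.8, 93.3, 99.8),
        (4, 41.3, 31.2, 52.2, 100.0, 95.4, 100.0),
    ],
}
_MAINSTUDY = {
    "A": [
        (1, 92.5, 84.6, 96.5, 17.6, 12.0, 25.0),
        (2, 90.0, 81.5, 94.8, 29.0, 21.9, 37.3),
        (3, 87.5, 78.5, 93.1, 43.5, 35.3, 52.1),
        (4, 82.5, 72.7, 89.3, 58.0, 49.4, 66.1),
        (5, 80.0, 70.0, 87.3, 68.7, 60.3, 76.0),
        (6, 76.3, 65.9, 84.3, 77.9, 70.1, 84.2),
    ],
    "B": [
        (1, 93.8, 86.3, 97.3, 41.2, 33.1, 49.8),
        (2, 88.8, 80.0, 94.0, 54.2, 45.7, 62.5),
        (3, 88.8, 80.0, 94.0, 67.9, 59.5, 75.3),
        (4, 81.3, 71.4, 88.3, 80.2, 72.6, 86.1),
        (5, 80.0, 70.0, 87.3, 83.2, 75.9, 88.6),
        (6, 72.5, 61.9, 81.1, 87.0, 80.2, 91.7),
    ],
    "C": [
        (1, 98.8, 93.3, 99.8, 25.2, 18.5, 33.3),
        (2, 98.8, 93.3, 99.8, 36.6, 28.8, 45.1),
        (3, 95.0, 87.8, 98.0, 47.3, 38.9, 55.8),
        (4, 95.0, 87.8, 98.0, 51.9, 43.4, 60.3),
        (5, 92.5, 84.6, 96.5, 58.0, 49.4, 66.1),
        (6, 83.8, 74.2, 90.3, 71.8, 63.6, 78.8),
    ],
}
_STUDIES = {
    "prestudy": (_PRESTUDY, 80, 80, 4),
    "mainstudy": (_MAINSTUDY, 80, 131, 6),
}
_PREVALENCE = {"prevalenceA": (80, 211), "prevalenceB": (211, 1194)}

FIXTURE_NAMES = tuple(
    list(_STUDIES)
    + [f"{s}:{t}" for s, (tbl, *_), in _STUDIES.items() for t in tbl]
    + list(_PREVALENCE)
)


def _reconstruct(pct: float, group_n: int) -> tuple[int, float]:
    """Count implied by a printed percentage, verified to re-print identically."""
    count = round(pct / 100.0 * group_n)
    if format_percent(count / group_n) != format_percent(pct / 100.0):
        raise InputError(
            f"percentage {pct} is inconsistent with group size {group_n}"
        )
    return count, count / group_n


def characteristics_frame(study: str, tests: list[str] | None = None) -> pd.DataFrame:
    """Characteristics table of one study as exact proportions.

    Columns: test_id, threshold, sen, spe (count-based proportions),
    tp, tn, n_pos, n_neg, and the published CI bounds as proportions.
    """
    if study not in _STUDIES:
        raise KeyError(f"unknown study {study!r}; expected one of {list(_STUDIES)}")
    table, n_pos, n_neg, trials = _STUDIES[study]
    tests = list(table) if tests is None else tests
    rows = []
    for t in tests:
        if t not in table:
            raise KeyError(f"study {study!r} has no test {t!r}")
        for thr, sen, slo, shi, spe, plo, phi in table[t]:
            tp, sen_p = _reconstruct(sen, n_pos)
            tn, spe_p = _reconstruct(spe, n_neg)
            rows.append(
                {
                    "test_id": t,
                    "threshold": thr,
                    "sen": sen_p,
                    "spe": spe_p,
                    "tp": tp,
                    "tn": tn,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "trials": trials,
                    "sen_ci_lo": slo / 100.0,
                    "sen_ci_hi": shi / 100.0,
                    "spe_ci_lo": plo / 100.0,
                    "spe_ci_hi": phi / 100.0,
                }
            )
    return pd.DataFrame(rows)


def load_fixture(name: str) -> pd.DataFrame | PrevalenceEstimate:
    """Load a packaged fixture by name.

    ``"prestudy"`` / ``"mainstudy"`` return the full characteristics table;
    ``"mainstudy:C"`` restricts to one test; ``"prevalenceA"`` /
    ``"prevalenceB"`` return :class:`PrevalenceEstimate` objects.
    """
    if name in _PREVALENCE:
        s, n = _PREVALENCE[name]
        return PrevalenceEstimate(n_success=s, n_total=n)
    study, _, test = name.partition(":")
    if study not in _STUDIES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    return characteristics_frame(study, [test] if test else None)
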