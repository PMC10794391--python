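"""Empirical ROC curves and trapezoidal AUC from per-threshold characteristics.

Each threshold of a multi-trial test contributes one operating point
(false-alarm rate, hit rate) = (1 − Spe, Sen).  The curve is anchored at
(0, 0) and (1, 1) — the degenerate always-negative / always-positive rules —
and the AUC is the trapezoidal area over the sorted points.  The AUC is the
probability that a randomly drawn headphone/loudspeaker user pair is ordered
correctly by the test score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import InputError

__all__ = ["ROCCurve", "roc_points", "auc_trapezoid", "plot_roc"]


@dataclass(frozen=True)
class ROCCurve:
    """Ordered empirical ROC points, anchored at (0,0) and (1,1)."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = self.points
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise InputError("ROC curve must be anchored at (0,0) and (1,1)")
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if (x1, y1) < (x0, y0):
                raise InputError("ROC points must be sorted ascending")
        arr = np.asarray(pts)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise InputError("ROC coordinates must lie in [0, 1]")

    @property
    def auc(self) -> float:
        return auc_trapezoid(self)

    @property
    def far(self) -> np.ndarray:
        """False-alarm rates (x coordinates)."""
        return np.asarray(self.points)[:, 0]

    @property
    def hit(self) -> np.ndarray:
        """Hit rates (y coordinates)."""
        return np.asarray(self.points)[:, 1]


def roc_points(table: pd.DataFrame) -> ROCCurve:
    """Build the anchored empirical ROC curve of one test.

    ``table`` holds one row per threshold with ``sen`` and ``spe`` as
    proportions (the characteristics-table schema).  Duplicate operating
    points are collapsed; points are sorted by false-alarm rate with hit
    rate as tie-break.
    """
    if len(table) == 0:
        raise InputError("empty characteristics table")
    sen = np.asarray(table["sen"], dtype=float)
    spe = np.asarray(table["spe"], dtype=float)
    if np.isnan(sen).any() or np.isnan(spe).any():
        raise InputError("characteristics table contains missing sen/spe")
    pts = {(float(1.0 - s), float(h)) for s, h in zip(spe, sen)}
    pts.update({(0.0, 0.0), (1.0, 1.0)})
    return ROCCurve(points=tuple(sorted(pts)))


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the anchored empirical ROC curve."""
    return float(np.trapezoid(curve.hit, curve.far))


def plot_roc(curves: dict[str, ROCCurve], path: str | None = None, ax=None):
    """Plot one or more ROC curves (hit rate against false-alarm rate).

    With ``path`` the figure is written to file; otherwise the axes object
    is returned for further styling.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, curve in curves.items():
        ax.plot(curve.far, curve.hit, marker="o", label=f"{label} (AUC = {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("False-alarm rate (1 − specificity)")
    ax.set_ylabel("Hit rate (sensitivity)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
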