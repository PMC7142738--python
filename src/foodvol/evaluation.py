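"""Agreement statistics for method-comparison of meal estimates.

Implements the study's endpoint statistics: signed bias (estimate minus
reference), absolute error and its relative (percent-of-reference) form,
95% limits of agreement as mean bias +- 2*SD (sample SD, n-1 denominator),
Bland-Altman difference-vs-mean points, and a stratified report over meal
types and capture angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "bias",
    "absolute_error",
    "relative_absolute_error",
    "relative_bias",
    "limits_of_agreement",
    "bland_altman_points",
    "bland_altman_plot",
    "stratified_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "quantity",
    "stratum",
    "abs_err_mean",
    "abs_err_sd",
    "rel_abs_err_mean_pct",
    "rel_abs_err_sd_pct",
    "bias_mean",
    "bias_sd",
    "rel_bias_mean_pct",
    "rel_bias_sd_pct",
    "loa_lower",
    "loa_upper",
    "n",
]


def _paired(est, ref) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ConfigurationError("estimate and reference lengths differ")
    return est, ref


def bias(est, ref) -> np.ndarray:
    """Signed error, estimate minus reference, elementwise."""
    est, ref = _paired(est, ref)
    return est - ref


def absolute_error(est, ref) -> np.ndarray:
    """Unsigned error |estimate - reference|, elementwise."""
    return np.abs(bias(est, ref))


def _relative(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Percent-of-reference form; pairs with ref <= 0 are excluded."""
    ok = ref > 0
    n_dropped = int(np.count_nonzero(~ok))
    if n_dropped:
        logger.warning(
            "relative metric: %d pair(s) with non-positive reference excluded",
            n_dropped,
        )
    return 100.0 * values[ok] / ref[ok]


def relative_absolute_error(est, ref) -> np.ndarray:
    """100 * |estimate - reference| / reference (percent), per pair."""
    est, ref = _paired(est, ref)
    return _relative(np.abs(est - ref), ref)


def relative_bias(est, ref) -> np.ndarray:
    """100 * (estimate - reference) / reference (percent), per pair."""
    est, ref = _paired(est, ref)
    return _relative(est - ref, ref)


def limits_of_agreement(biases) -> tuple[float, float]:
    """95% limits of agreement: mean(bias) +- 2*SD(bias), sample SD."""
    b = np.asarray(biases, dtype=float)
    if b.size < 2:
        raise ConfigurationError("limits of agreement need at least 2 biases")
    m = float(b.mean())
    sd = float(b.std(ddof=1))
    return m - 2.0 * sd, m + 2.0 * sd


def bland_altman_points(est, ref) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Difference-vs-mean pairs for a Bland-Altman plot.

    Returns an (n, 2) array of ((est+ref)/2, est-ref) points, the mean
    bias, and the limits of agreement (for the plot's reference lines).
    """
    est, ref = _paired(est, ref)
    points = np.column_stack([(est + ref) / 2.0, est - ref])
    b = est - ref
    return points, float(b.mean()), limits_of_agreement(b)


def bland_altman_plot(est, ref, quantity: str, path, unit: str = "g") -> None:
    """Save a Bland-Altman scatter with mean-bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points, mean_bias, (lo, hi) = bland_altman_points(est, ref)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(points[:, 0], points[:, 1], s=18, alpha=0.8)
    ax.axhline(mean_bias, color="k", lw=1, label=f"bias {mean_bias:.1f} {unit}")
    for y, name in ((lo, "-2SD"), (hi, "+2SD")):
        ax.axhline(y, color="r", ls="--", lw=1)
        ax.annotate(f"{name} {y:.1f}", (points[:, 0].max(), y), fontsize=8)
    ax.set_xlabel(f"mean of estimate and reference ({unit})")
    ax.set_ylabel(f"estimate - reference ({unit})")
    ax.set_title(quantity)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PairedMeasurements:
    """Per-meal (estimate, reference) pairs for one quantity, with the
    stratification variables."""

    quantity: str
    est: np.ndarray
    ref: np.ndarray
    meal_type: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self) -> None:
        self.est, self.ref = _paired(self.est, self.ref)
        self.meal_type = np.asarray(self.meal_type)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if not (len(self.est) == len(self.meal_type) == len(self.angle_deg)):
            raise ConfigurationError("stratification variables length mismatch")

    def subset(self, mask: np.ndarray) -> "PairedMeasurements":
        return PairedMeasurements(
            self.quantity,
            self.est[mask],
            self.ref[mask],
            self.meal_type[mask],
            self.angle_deg[mask],
        )


def _row(quantity: str, stratum: str, pm: PairedMeasurements) -> dict:
    b = bias(pm.est, pm.ref)
    ae = np.abs(b)
    rae = relative_absolute_error(pm.est, pm.ref)
    rb = relative_bias(pm.est, pm.ref)
    lo, hi = limits_of_agreement(b) if len(b) >= 2 else (float("nan"), float("nan"))

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")

    return {
        "quantity": quantity,
        "stratum": stratum,
        "abs_err_mean": float(ae.mean()),
        "abs_err_sd": _sd(ae),
        "rel_abs_err_mean_pct": float(rae.mean()) if rae.size else float("nan"),
        "rel_abs_err_sd_pct": _sd(rae),
        "bias_mean": float(b.mean()),
        "bias_sd": _sd(b),
        "rel_bias_mean_pct": float(rb.mean()) if rb.size else float("nan"),
        "rel_bias_sd_pct": _sd(rb),
        "loa_lower": lo,
        "loa_upper": hi,
        "n": len(b),
    }


@dataclass
class AgreementReport:
    """Stratified agreement table (one row per quantity x stratum)."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def row(self, quantity: str, stratum: str) -> pd.Series:
        sel = self.frame[
            (self.frame.quantity == quantity) & (self.frame.stratum == stratum)
        ]
        if sel.empty:
            raise KeyError((quantity, stratum))
        return sel.iloc[0]

    def __str__(self) -> str:
        with pd.option_context("display.width", 200, "display.max_columns", 99):
            return str(self.frame.round(2))


def stratified_report(
    data: dict[str, PairedMeasurements],
    meal_type_order: tuple[str, ...] = ("breakfast", "cooked", "snack"),
) -> AgreementReport:
    """All error metrics for all meals and per stratum (meal type, angle).

    Empty strata are omitted with a warning; strata counts partition the
    total meal count.
    """
    rows = []
    for quantity, pm in data.items():
        rows.append(_row(quantity, "all", pm))
        for mt in meal_type_order:
            sub = pm.subset(pm.meal_type == mt)
            if len(sub.est) == 0:
                logger.warning("stratum %s empty for %s; omitted", mt, quantity)
                continue
            rows.append(_row(quantity, mt, sub))
        for ang in (45.0, 90.0):
            sub = pm.subset(pm.angle_deg == ang)
            if len(sub.est) == 0:
                logger.warning("angle stratum %g empty for %s; omitted", ang, quantity)
                continue
            rows.append(_row(quantity, f"angle_{ang:.0f}", sub))
    return AgreementReport(frame=pd.DataFrame(rows, columns=REPORT_COLUMNS))
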