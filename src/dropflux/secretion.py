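"""Secretion-rate estimation and detection criteria for droplet traces.

Detection statistics are robust: the noise model of every rule is the
median/MAD of droplets that received no cell ("empty droplets"), with
``sigma_hat = 1.4826 * MAD`` as a consistent estimator of the Gaussian SD.
A droplet counts as secreting its analyte when its relocation series

I.   reaches the LoD (``median_empty + 1.645 * 2 * sigma_hat``) at least once,
II.  increases over time (positive least-squares slope), and
III. varies more than blank noise: ``max - min > 1.645 * 2 * sigma_hat``.

Rates are interval averages: the per-time-point signal is inverted through
the calibration curve into a concentration (lactate, amol/nL) or a molecule
count (antibodies), differenced between consecutive frames and divided by
the frame interval; the mean over intervals is the cell's secretion rate.
Lactate rates are expressed in amol/s by multiplying the concentration
change by the droplet volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .calibration import (
    ExponentialRelocationModel,
    FourPLModel,
    QuantitativeRange,
    invert_relocation,
    molecules_from_concentration,
)

__all__ = [
    "EmptyDropletStats",
    "CriteriaResult",
    "SecretionEstimate",
    "empty_droplet_stats",
    "relocation_lod",
    "passes_secretion_criteria",
    "lactate_secretion_rate",
    "ig_secretion_rate",
    "classify_secretors",
    "LACTATE_QUANT_RANGE",
    "IGG_QUANT_RANGE",
    "IGM_QUANT_RANGE",
    "IGG_SC_THRESHOLD",
    "IGM_SC_THRESHOLD",
]

MAD_TO_SD = 1.4826

# Assay quantitative ranges are configuration, not derived quantities: the
# working lactate range reflects instrument limits beyond the raw LoD/cutoff.
LACTATE_QUANT_RANGE = QuantitativeRange(0.10, 0.80, "amol/s")
IGG_QUANT_RANGE = QuantitativeRange(3.0, 375.0, "IgG/s")
IGM_QUANT_RANGE = QuantitativeRange(7.0, 150.0, "IgM/s")
IGG_SC_THRESHOLD = 3.0  # IgG/s; at or above => IgG-secreting cell
IGM_SC_THRESHOLD = 7.0  # IgM/s


@dataclass(frozen=True)
class EmptyDropletStats:
    """Robust blank statistics pooled over all time points of empty droplets."""

    median_empty: float
    mad_empty: float
    n_empty: int
    k: float = MAD_TO_SD

    @property
    def sigma_hat(self) -> float:
        return self.k * self.mad_empty


@dataclass(frozen=True)
class CriteriaResult:
    """Per-criterion audit flags for one droplet's relocation series."""

    above_lod: bool  # I: any time point >= LoD
    increasing: bool  # II: positive least-squares slope vs time
    varies: bool  # III: max - min > 1.645 * 2 * sigma_hat

    @property
    def passed(self) -> bool:
        return self.above_lod and self.increasing and self.varies


@dataclass(frozen=True)
class SecretionEstimate:
    """Calibrated secretion rate of one droplet/cell with range flags."""

    droplet_id: int
    analyte: str  # "lactate", "IgG" or "IgM"
    rate: float
    passed_criteria: bool
    in_quant_range: bool
    above_range: bool
    n_intervals_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if self.above_range and self.in_quant_range:
            raise ValueError("above_range implies not in_quant_range")


def empty_droplet_stats(
    traces: pd.DataFrame, channel: str, min_empty: int = 30
) -> EmptyDropletStats:
    """Median/MAD of a channel over all time points of all empty droplets.

    Statistics are pooled within one experiment (LoDs are per-experiment
    quantities). ``min_empty`` is a configurable floor on the number of empty
    droplets required for a stable noise estimate.
    """
    empty = traces.loc[traces["n_cells"] == 0, channel]
    n_empty = int(traces.loc[traces["n_cells"] == 0, "droplet_id"].nunique())
    if n_empty == 0:
        raise ValueError("no empty droplets in the trace set")
    if n_empty < min_empty:
        raise ValueError(
            f"only {n_empty} empty droplets; need >= {min_empty} for noise stats"
        )
    values = empty.to_numpy(dtype=float)
    return EmptyDropletStats(
        median_empty=float(np.median(values)),
        mad_empty=float(sp_stats.median_abs_deviation(values, scale=1.0)),
        n_empty=n_empty,
    )


def relocation_lod(stats: EmptyDropletStats) -> float:
    """Relocation detection limit: ``median_empty + 1.645 * 2 * sigma_hat``."""
    return stats.median_empty + 1.645 * 2.0 * stats.sigma_hat


def passes_secretion_criteria(
    time_s: Sequence[float],
    signals: Sequence[float],
    lod: float,
    stats: EmptyDropletStats,
) -> CriteriaResult:
    """Evaluate detection criteria I-III on one droplet's relocation series."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(t) < 2 or len(t) != len(y):
        raise ValueError("need >= 2 matching time points")
    above_lod = bool(np.any(y >= lod))
    # covariance form: exactly zero for a constant series
    tc = t - t.mean()
    slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    varies = bool((y.max() - y.min()) > 1.645 * 2.0 * stats.sigma_hat)
    return CriteriaResult(above_lod=above_lod, increasing=slope > 0.0, varies=varies)


def _safe_lactate_concentrations(
    signals: np.ndarray, model: FourPLModel
) -> tuple[np.ndarray, bool]:
    """Invert lactate signals, clamping out-of-range values.

    Signals at or below the curve's bottom carry no concentration information
    and clamp to 0; signals at or above the plateau are saturated and clamp
    just inside it (the returned flag marks the trace as above range).
    """
    eps = 1e-9 * (model.plateau - model.bottom)
    clamped_high = bool(np.any(signals >= model.plateau - eps))
    conc = np.empty_like(signals)
    for i, y in enumerate(signals):
        if y <= model.bottom + eps:
            conc[i] = 0.0
        else:
            y_eff = min(y, model.plateau - eps)
            frac = (model.plateau - model.bottom) / (y_eff - model.bottom) - 1.0
            conc[i] = model.ec50 / frac ** (1.0 / model.hill)
    return conc, clamped_high


def lactate_secretion_rate(
    trace: pd.DataFrame,
    model: FourPLModel,
    droplet_volume_pl: float,
    quant_range: QuantitativeRange = LACTATE_QUANT_RANGE,
    *,
    signal_column: str = "lactate_signal",
) -> SecretionEstimate:
    """Lactate secretion rate (amol/s) of one droplet.

    ``trace`` holds one droplet's rows (time_s and the lactate signal). Per
    interval the rate is ``(C(t+1) - C(t)) * V / dt``; the estimate is the
    mean over intervals, with negative intervals retained for unbiasedness.
    """
    t = trace["time_s"].to_numpy(dtype=float)
    y = trace[signal_column].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points for a rate")
    conc, saturated = _safe_lactate_concentrations(y, model)
    vol_nl = droplet_volume_pl * 1e-3
    interval_rates = np.diff(conc) * vol_nl / np.diff(t)  # amol/s
    rate = float(np.mean(interval_rates))
    above = saturated or rate > quant_range.high
    droplet_id = int(trace["droplet_id"].iloc[0]) if "droplet_id" in trace else -1
    return SecretionEstimate(
        droplet_id=droplet_id,
        analyte="lactate",
        rate=rate,
        passed_criteria=True,
        in_quant_range=(not above) and quant_range.contains(rate),
        above_range=above,
        n_intervals_used=len(interval_rates),
    )


def ig_secretion_rate(
    trace: pd.DataFrame,
    model: ExponentialRelocationModel,
    droplet_volume_pl: float,
    analyte: str = "IgG",
    quant_range: Optional[QuantitativeRange] = None,
    criteria: Optional[CriteriaResult] = None,
    *,
    signal_column: str = "ig_relocation",
) -> SecretionEstimate:
    """Antibody secretion rate (molecules/s) of one droplet.

    Relocation signals are inverted to concentrations, converted to molecule
    counts, differenced between frames and averaged. Saturated time points
    (at or above the fitted plateau) are excluded; if fewer than two points
    remain the trace is reported at the cutoff-equivalent bound with
    ``above_range=True``.
    """
    if quant_range is None:
        quant_range = IGG_QUANT_RANGE if analyte == "IgG" else IGM_QUANT_RANGE
    t = trace["time_s"].to_numpy(dtype=float)
    y = trace[signal_column].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points for a rate")
    droplet_id = int(trace["droplet_id"].iloc[0]) if "droplet_id" in trace else -1
    usable = y < model.y_plateau
    saturated = bool(np.any(~usable))
    if usable.sum() < 2:
        # fully saturated trace: report the largest quantifiable rate
        y_top = model.y_plateau - model.prediction_halfwidth_90
        if not y_top < model.y_plateau:
            y_top = model.y_plateau - 1e-9 * (model.y_plateau - model.y_blank)
        conc_top = max(invert_relocation(max(y_top, model.y_blank), model), 0.0)
        rate = molecules_from_concentration(conc_top, droplet_volume_pl) / (
            t[-1] - t[0]
        )
        return SecretionEstimate(
            droplet_id=droplet_id,
            analyte=analyte,
            rate=float(rate),
            passed_criteria=bool(criteria.passed) if criteria else True,
            in_quant_range=False,
            above_range=True,
            n_intervals_used=0,
        )
    tt, yy = t[usable], y[usable]
    with np.errstate(invalid="ignore"):
        conc = np.array(
            [invert_relocation(v, model) if v >= model.y_blank else 0.0 for v in yy]
        )
    molecules = np.array(
        [molecules_from_concentration(c, droplet_volume_pl) for c in conc]
    )
    interval_rates = np.diff(molecules) / np.diff(tt)
    rate = float(np.mean(interval_rates))
    above = saturated or rate > quant_range.high
    return SecretionEstimate(
        droplet_id=droplet_id,
        analyte=analyte,
        rate=rate,
        passed_criteria=bool(criteria.passed) if criteria else True,
        in_quant_range=(not above) and quant_range.contains(rate),
        above_range=above,
        n_intervals_used=len(interval_rates),
    )


def classify_secretors(estimates: Sequence[SecretionEstimate]) -> pd.DataFrame:
    """Label secretion estimates from single-cell droplets.

    IgG-SC: rate >= 3 IgG/s with criteria passed; IgM-SC: rate >= 7 IgM/s
    with criteria passed; lactate estimates get an in/below/above flag for
    the 0.10-0.80 amol/s range. Multi-cell droplets must be excluded before
    estimation (upstream).
    """
    rows = []
    for est in estimates:
        if est.analyte not in ("lactate", "IgG", "IgM"):
            raise ValueError(f"unknown analyte {est.analyte!r}")
        label = None
        range_status = None
        if est.analyte == "IgG":
            label = est.passed_criteria and est.rate >= IGG_SC_THRESHOLD
        elif est.analyte == "IgM":
            label = est.passed_criteria and est.rate >= IGM_SC_THRESHOLD
        else:
            if est.above_range or est.rate > LACTATE_QUANT_RANGE.high:
                range_status = "above"
            elif est.rate < LACTATE_QUANT_RANGE.low:
                range_status = "below"
            else:
                range_status = "in"
        rows.append(
            {
                "droplet_id": est.droplet_id,
                "analyte": est.analyte,
                "rate": est.rate,
                "passed_criteria": est.passed_criteria,
                "in_quant_range": est.in_quant_range,
                "above_range": est.above_range,
                "is_secretor": label,
                "lactate_range_status": range_status,
            }
        )
    return pd.DataFrame(rows)
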