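"""Affinity slopes, antigen-specificity calls, and cell-state classifiers.

Affinity of a secreted antibody is read out indirectly: antigen relocation
is regressed on antibody-probe relocation over the time points at which the
probe signal lies inside the assay's quantitative window ([LoD, cutoff]),
and the regression slope indicates binding strength (steeper = more antigen
captured per unit antibody = higher affinity).

Cell-state calls are threshold classifiers whose thresholds are pure
functions of a reference set:

* ROS: increase in cell signal up to its maximum; threshold = mean + 2 SD of
  a reference-day distribution of increases.
* intracellular pH: first-frame dye signal normalized to the cohort median;
  threshold = average of per-replicate calibration means at pH 5.5 plus
  their SEM; the dye signal rises with acidity, so "acidic" means a
  normalized signal at or above the threshold.
* caspase-3/7: active when the per-droplet SD of the whole-droplet signal
  (SD_WDF) reaches median + 3 SD of empty-droplet SD_WDF at the first frame
  at any time point.

All comparisons treat ties as positive calls (>= on the activated side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .secretion import MAD_TO_SD, EmptyDropletStats

__all__ = [
    "AffinityEstimate",
    "affinity_slope",
    "is_antigen_specific",
    "ros_signal_increase",
    "ros_classify",
    "ph_classify",
    "caspase_active",
]


@dataclass(frozen=True)
class AffinityEstimate:
    """Affinity slope of one droplet, or the reason none could be fitted."""

    droplet_id: int
    slope: Optional[float]
    n_points_used: int
    antigen_specific: bool
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.slope is not None:
            if self.n_points_used < 2:
                raise ValueError("slope requires >= 2 points")
            if not np.isfinite(self.slope):
                raise ValueError("slope must be finite")


def affinity_slope(
    ig_trace: Sequence[float],
    antigen_trace: Sequence[float],
    lod: float,
    cutoff: float,
    *,
    droplet_id: int = -1,
    antigen_specific: bool = True,
) -> AffinityEstimate:
    """Regress antigen relocation on antibody relocation within [LoD, cutoff].

    Only time points with antibody relocation inside the quantitative window
    contribute; the intercept is fitted. With fewer than two eligible points
    a no-slope estimate is returned carrying the reason.
    """
    ig = np.asarray(ig_trace, dtype=float)
    ag = np.asarray(antigen_trace, dtype=float)
    if len(ig) != len(ag):
        raise ValueError("traces must share the time grid")
    if not lod < cutoff:
        raise ValueError("require lod < cutoff")
    eligible = (ig >= lod) & (ig <= cutoff)
    n = int(eligible.sum())
    if n < 2:
        return AffinityEstimate(
            droplet_id=droplet_id,
            slope=None,
            n_points_used=n,
            antigen_specific=antigen_specific,
            reason=f"only {n} time points with Ig relocation in [LoD, cutoff]",
        )
    x, y = ig[eligible], ag[eligible]
    if np.ptp(x) == 0:
        return AffinityEstimate(
            droplet_id=droplet_id,
            slope=None,
            n_points_used=n,
            antigen_specific=antigen_specific,
            reason="no variation in Ig relocation among eligible points",
        )
    slope = float(np.polyfit(x, y, 1)[0])
    return AffinityEstimate(
        droplet_id=droplet_id,
        slope=slope,
        n_points_used=n,
        antigen_specific=antigen_specific,
    )


def is_antigen_specific(
    antigen_trace: Sequence[float], empty_stats_antigen: EmptyDropletStats
) -> bool:
    """True when antigen relocation reaches its LoD at least once.

    The antigen LoD is ``median_empty + 1.645 * 2 * k * MAD_empty`` with
    k = 1.4826, computed per experiment from droplets without a cell.
    """
    trace = np.asarray(antigen_trace, dtype=float)
    lod = (
        empty_stats_antigen.median_empty
        + 1.645 * 2.0 * MAD_TO_SD * empty_stats_antigen.mad_empty
    )
    return bool(np.any(trace >= lod))


def ros_signal_increase(cell_trace: Sequence[float]) -> float:
    """Signal increase up to the cell's maximum: max - first value.

    The rise is measured over the prefix ending at the argmax; any decay
    after the maximum is ignored.
    """
    y = np.asarray(cell_trace, dtype=float)
    if len(y) < 2:
        raise ValueError("need >= 2 time points")
    peak = int(np.argmax(y))
    return float(y[peak] - y[0])


def ros_classify(
    increases: Sequence[float], day14_increases: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Label signal increases ROS_low/ROS_high against a reference day.

    Threshold = mean + 2 * SD (sample SD, ddof=1) of the reference-day
    increases; an increase at or above the threshold is ROS_high. Returns
    (labels, threshold).
    """
    ref = np.asarray(day14_increases, dtype=float)
    if len(ref) == 0:
        raise ValueError("reference (day-14) increases must be nonempty")
    sd = float(np.std(ref, ddof=1)) if len(ref) > 1 else 0.0
    threshold = float(np.mean(ref)) + 2.0 * sd
    inc = np.asarray(increases, dtype=float)
    labels = np.where(inc >= threshold, "ROS_high", "ROS_low")
    return labels, threshold


def ph_classify(
    cell_signals_t1: Sequence[float],
    calibration_5p5_means: Sequence[float],
) -> tuple[np.ndarray, float, np.ndarray]:
    """Label cells acidic/physiological from first-frame pH-dye signals.

    Each cell's first-time-point signal is normalized to the cohort median
    (assumed near physiological pH). The threshold is the average of the
    per-replicate calibration means at pH 5.5 plus their SEM, applied in
    normalized-signal space; because the dye signal rises with acidity, a
    normalized signal at or above the threshold is called acidic. Returns
    (labels, threshold, normalized_signals).
    """
    sig = np.asarray(cell_signals_t1, dtype=float)
    if len(sig) == 0:
        raise ValueError("need >= 1 cell signal")
    cal = np.asarray(calibration_5p5_means, dtype=float)
    if len(cal) == 0:
        raise ValueError("pH 5.5 calibration means must be nonempty")
    cohort_median = float(np.median(sig))
    if cohort_median == 0:
        raise ValueError("cohort median signal is zero; cannot normalize")
    normalized = sig / cohort_median
    sem = float(np.std(cal, ddof=1) / np.sqrt(len(cal))) if len(cal) > 1 else 0.0
    threshold = float(np.mean(cal)) + sem
    labels = np.where(normalized >= threshold, "acidic", "physiological")
    return labels, threshold, normalized


def caspase_active(
    sd_wdf_trace: Sequence[float], empty_sd_wdf_t1: Sequence[float]
) -> tuple[bool, float]:
    """Caspase-3/7 activity call from the SD_WDF series of one droplet.

    Threshold = median + 3 * SD (sample SD, ddof=1) of empty-droplet SD_WDF
    values at the first time point, computed per experiment; the droplet is
    active when any time point's SD_WDF reaches the threshold. Returns
    (active, threshold).
    """
    ref = np.asarray(empty_sd_wdf_t1, dtype=float)
    if len(ref) == 0:
        raise ValueError("empty-droplet SD_WDF reference must be nonempty")
    sd = float(np.std(ref, ddof=1)) if len(ref) > 1 else 0.0
    threshold = float(np.median(ref)) + 3.0 * sd
    trace = np.asarray(sd_wdf_trace, dtype=float)
    return bool(np.any(trace >= threshold)), threshold
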