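"""Seeded synthetic droplet experiments and calibration standards.

The generator emulates the statistical structure of a droplet-microfluidics
single-B-cell assay: cells are Poisson-encapsulated into 50 pL droplets at a
mean occupancy λ of 0.25–0.50 and imaged six times at 10-minute intervals.
Per droplet and time point it produces

* a whole-droplet lactate channel, the truth 4PL image of the in-droplet
  lactate concentration ``C(t) = rate * t / V`` (amol/nL),
* an antibody relocation channel, the truth saturating-exponential image of
  the cumulative secreted antibody concentration,
* an antigen relocation channel, linear in the (noise-free) antibody
  relocation above blank with the cell's true affinity slope,
* ROS (monotone ramp with state-dependent amplitude), pH-dye level, and
  caspase SD_WDF channels for cell-state classification,

each plus additive Gaussian noise whose standard deviation is tied to the
blank MAD through sigma = 1.4826 * MAD, matching the normality assumption the
downstream robust detection statistics make for empty droplets. Empty
droplets carry blank noise in every channel. All randomness flows through a
single integer seed; identical (config, seed) pairs reproduce outputs
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    AVOGADRO,
    ExponentialRelocationModel,
    FourPLModel,
)

__all__ = [
    "MAD_TO_SD",
    "SimulationConfig",
    "GroundTruthCell",
    "default_lactate_truth",
    "default_relocation_truth",
    "simulate_encapsulation",
    "sample_cells",
    "simulate_experiment",
    "simulate_cohort",
    "simulate_calibration_standards",
    "simulate_ph_calibration",
    "TRACE_COLUMNS",
]

MAD_TO_SD = 1.4826  # consistency constant for Gaussian data

TRACE_COLUMNS = [
    "droplet_id",
    "time_index",
    "time_s",
    "n_cells",
    "lactate_signal",
    "ig_relocation",
    "antigen_relocation",
    "ros_cell_signal",
    "ph_cell_signal",
    "sd_wdf",
]


def default_lactate_truth() -> FourPLModel:
    """Ground-truth lactate 4PL curve used by the generator defaults.

    The curve spans the standard ladder (2 to 200,000 amol/nL) with its
    half-maximal point at 10,000 amol/nL, so that secretion at the assay's
    quantitative rates (0.10-0.80 amol/s over 50 min in 50 pL, i.e. final
    concentrations of 6,000-48,000 amol/nL) stays on the informative flank.
    """
    return FourPLModel(
        bottom=200.0,
        plateau=10_000.0,
        ec50=10_000.0,
        hill=1.0,
        plateau_ci_low=10_000.0,
        plateau_ci_high=10_000.0,
        n_points=12,
        residual_sd=0.0,
    )


def default_relocation_truth() -> ExponentialRelocationModel:
    """Ground-truth antibody relocation curve used by the generator defaults.

    With K = 0.02 /nM the 100 nM top standard reaches ~86% of saturation and
    a 375 IgG/s secretor (~37 nM after 50 min in 50 pL) stays invertible.
    """
    return ExponentialRelocationModel(
        y_blank=1.0,
        y_plateau=3.0,
        K=0.02,
        residual_sd=0.0,
        prediction_halfwidth_90=0.0,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic droplet experiment.

    Defaults mirror the assay's acquisition settings: 50 pL droplets, six
    images at 600 s intervals, encapsulation λ = 0.3. Noise scales are blank
    MADs; the additive Gaussian noise on each channel has standard deviation
    1.4826 x MAD. ``blank_drift_per_s`` adds an optional linear blank drift
    to the lactate channel (default 0: no photoactivation drift).
    """

    n_droplets: int = 2000
    lambda_: float = 0.3
    n_timepoints: int = 6
    interval_s: float = 600.0
    droplet_volume_pl: float = 50.0
    blank_median: float = 200.0
    blank_mad: float = 10.0
    relocation_blank_median: float = 1.0
    relocation_blank_mad: float = 0.002
    forward_lactate_model: FourPLModel = field(default_factory=default_lactate_truth)
    forward_relocation_model: ExponentialRelocationModel = field(
        default_factory=default_relocation_truth
    )
    ig_analyte: str = "IgG"
    blank_drift_per_s: float = 0.0
    # ROS ramp: amplitude ~ N(mean, sd) per state, on a baseline level
    ros_baseline: float = 100.0
    ros_low_mean: float = 50.0
    ros_low_sd: float = 10.0
    ros_high_mean: float = 100.0
    ros_high_sd: float = 10.0
    ros_point_noise_sd: float = 2.0
    # pH dye level: signal increases with acidity (pHrodo-type response)
    ph_physiological_mean: float = 100.0
    ph_physiological_sd: float = 5.0
    ph_acidic_mean: float = 250.0
    ph_acidic_sd: float = 15.0
    # caspase channel: per-droplet SD of the whole-droplet fluorescence
    sd_wdf_empty_median: float = 10.0
    sd_wdf_empty_sd: float = 1.0
    sd_wdf_active_elevation: float = 5.0  # in units of sd_wdf_empty_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if self.droplet_volume_pl <= 0:
            raise ValueError("droplet_volume_pl must be positive")
        for name in ("blank_mad", "relocation_blank_mad", "ros_point_noise_sd",
                     "sd_wdf_empty_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ig_analyte not in ("IgG", "IgM"):
            raise ValueError("ig_analyte must be 'IgG' or 'IgM'")

    @property
    def time_grid_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.interval_s


@dataclass(frozen=True)
class GroundTruthCell:
    """Ground-truth state of one simulated cell (for recovery tests)."""

    cell_id: int
    lactate_rate: float  # amol/s
    ig_rate: float  # molecules/s
    isotype: str  # "IgG", "IgM" or "none"
    true_affinity_slope: float
    ros_state: str  # "low" or "high"
    ph_state: str  # "physiological" or "acidic"
    caspase_active: bool

    def __post_init__(self) -> None:
        if self.lactate_rate < 0 or self.ig_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.isotype not in ("IgG", "IgM", "none"):
            raise ValueError("isotype must be IgG, IgM or none")
        if self.isotype == "none" and self.ig_rate != 0:
            raise ValueError("isotype 'none' implies ig_rate == 0")
        if self.ros_state not in ("low", "high"):
            raise ValueError("ros_state must be 'low' or 'high'")
        if self.ph_state not in ("physiological", "acidic"):
            raise ValueError("ph_state must be 'physiological' or 'acidic'")


def simulate_encapsulation(
    n_droplets: int, lambda_: float, seed: int
) -> np.ndarray:
    """Draw per-droplet cell counts as independent Poisson(λ) variates."""
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(lambda_, size=n_droplets)


def sample_cells(
    n_cells: int,
    seed: int,
    *,
    frac_igg: float = 0.35,
    frac_igm: float = 0.15,
    frac_specific: float = 0.8,
    lactate_rate_range: tuple[float, float] = (0.05, 1.0),
    igg_rate_range: tuple[float, float] = (3.0, 375.0),
    igm_rate_range: tuple[float, float] = (7.0, 150.0),
    affinity_slope_range: tuple[float, float] = (0.3, 3.0),
    frac_ros_high: float = 0.3,
    frac_acidic: float = 0.2,
    frac_caspase_active: float = 0.15,
) -> list[GroundTruthCell]:
    """Sample a ground-truth cell population.

    Secretion rates are log-uniform across (and slightly beyond) the assays'
    quantitative ranges so that in-range recovery and out-of-range flagging
    are both exercised; isotype, affinity and cell-state fractions follow the
    keyword defaults.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        u = rng.random()
        if u < frac_igg:
            isotype = "IgG"
            lo, hi = igg_rate_range
        elif u < frac_igg + frac_igm:
            isotype = "IgM"
            lo, hi = igm_rate_range
        else:
            isotype = "none"
        if isotype == "none":
            ig_rate = 0.0
            slope = 0.0
        else:
            ig_rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            if rng.random() < frac_specific:
                slope = float(
                    np.exp(
                        rng.uniform(
                            np.log(affinity_slope_range[0]),
                            np.log(affinity_slope_range[1]),
                        )
                    )
                )
            else:
                slope = 0.0
        lac_lo, lac_hi = lactate_rate_range
        cells.append(
            GroundTruthCell(
                cell_id=i,
                lactate_rate=float(np.exp(rng.uniform(np.log(lac_lo), np.log(lac_hi)))),
                ig_rate=ig_rate,
                isotype=isotype,
                true_affinity_slope=slope,
                ros_state="high" if rng.random() < frac_ros_high else "low",
                ph_state="acidic" if rng.random() < frac_acidic else "physiological",
                caspase_active=bool(rng.random() < frac_caspase_active),
            )
        )
    return cells


def simulate_experiment(
    config: SimulationConfig,
    cells: Sequence[GroundTruthCell],
    seed: int,
    counts: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate one droplet experiment.

    ``counts`` (per-droplet occupancy) is drawn from Poisson(λ) when not
    given. The provided cells fill the occupancy slots in order; passing a
    different number of cells than there are slots raises a ``ValueError``
    (assignment error). Returns the droplet trace table (one row per droplet
    and time point, columns :data:`TRACE_COLUMNS`) and the cell-to-droplet
    assignment (cell_id, droplet_id).
    """
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = rng.poisson(config.lambda_, size=config.n_droplets)
    else:
        counts = np.asarray(counts)
        if len(counts) != config.n_droplets:
            raise ValueError("counts length must equal config.n_droplets")
    n_slots = int(counts.sum())
    if len(cells) != n_slots:
        raise ValueError(
            f"assignment error: {len(cells)} cells for {n_slots} occupancy slots"
        )

    t = config.time_grid_s
    nt = len(t)
    nd = len(counts)
    lac_truth = config.forward_lactate_model
    rel_truth = config.forward_relocation_model
    vol_nl = config.droplet_volume_pl * 1e-3

    # per-droplet aggregated ground truth
    lac_rate = np.zeros(nd)
    ig_rate = np.zeros(nd)
    slope = np.zeros(nd)
    ros_state_high = np.zeros(nd, dtype=bool)
    ph_acidic = np.zeros(nd, dtype=bool)
    casp_active = np.zeros(nd, dtype=bool)
    assignment_rows = []
    k = 0
    for d in range(nd):
        for _ in range(int(counts[d])):
            cell = cells[k]
            assignment_rows.append((cell.cell_id, d))
            lac_rate[d] += cell.lactate_rate
            if cell.isotype == config.ig_analyte:
                ig_rate[d] += cell.ig_rate
                # one specific cell suffices for antigen relocation
                slope[d] = max(slope[d], cell.true_affinity_slope)
            ros_state_high[d] |= cell.ros_state == "high"
            ph_acidic[d] |= cell.ph_state == "acidic"
            casp_active[d] |= cell.caspase_active
            k += 1
    occupied = counts > 0

    # lactate channel: blank + truth-curve rise above its own blank + drift
    conc = lac_rate[:, None] * t[None, :] / vol_nl  # amol/nL
    lac_clean = (
        config.blank_median
        + lac_truth.forward(conc)
        - lac_truth.forward(0.0)
        + config.blank_drift_per_s * t[None, :]
    )
    lac_sigma = MAD_TO_SD * config.blank_mad
    lactate_signal = lac_clean + rng.normal(0.0, lac_sigma, size=(nd, nt))

    # antibody relocation channel
    molecules = ig_rate[:, None] * t[None, :]
    conc_nm = molecules / (1e-9 * config.droplet_volume_pl * 1e-12 * AVOGADRO)
    rel_clean = (
        config.relocation_blank_median
        + rel_truth.forward(conc_nm)
        - rel_truth.y_blank
    )
    rel_sigma = MAD_TO_SD * config.relocation_blank_mad
    ig_relocation = rel_clean + rng.normal(0.0, rel_sigma, size=(nd, nt))

    # antigen relocation: linear in the clean Ig relocation above blank
    ag_clean = (
        config.relocation_blank_median
        + slope[:, None] * (rel_clean - config.relocation_blank_median)
    )
    antigen_relocation = ag_clean + rng.normal(0.0, rel_sigma, size=(nd, nt))

    # ROS: monotone linear ramp to a state-dependent amplitude
    amp = np.where(
        ros_state_high,
        rng.normal(config.ros_high_mean, config.ros_high_sd, size=nd),
        rng.normal(config.ros_low_mean, config.ros_low_sd, size=nd),
    )
    amp = np.where(occupied, amp, 0.0)
    ramp = t / t[-1] if t[-1] > 0 else np.zeros_like(t)
    ros_cell_signal = (
        config.ros_baseline
        + amp[:, None] * ramp[None, :]
        + rng.normal(0.0, config.ros_point_noise_sd, size=(nd, nt))
    )

    # pH dye level (higher signal = more acidic)
    ph_level = np.where(
        ph_acidic,
        rng.normal(config.ph_acidic_mean, config.ph_acidic_sd, size=nd),
        rng.normal(config.ph_physiological_mean, config.ph_physiological_sd, size=nd),
    )
    ph_level = np.where(
        occupied, ph_level, rng.normal(
            config.ph_physiological_mean, config.ph_physiological_sd, size=nd
        )
    )
    ph_cell_signal = ph_level[:, None] + rng.normal(
        0.0, config.ph_physiological_sd * 0.2, size=(nd, nt)
    )

    # caspase SD_WDF: elevated for droplets holding a caspase-active cell
    elevation = np.where(
        casp_active, config.sd_wdf_active_elevation * config.sd_wdf_empty_sd, 0.0
    )
    sd_wdf = (
        config.sd_wdf_empty_median
        + elevation[:, None]
        + rng.normal(0.0, config.sd_wdf_empty_sd, size=(nd, nt))
    )

    traces = pd.DataFrame(
        {
            "droplet_id": np.repeat(np.arange(nd), nt),
            "time_index": np.tile(np.arange(nt), nd),
            "time_s": np.tile(t, nd),
            "n_cells": np.repeat(counts, nt),
            "lactate_signal": lactate_signal.ravel(),
            "ig_relocation": ig_relocation.ravel(),
            "antigen_relocation": antigen_relocation.ravel(),
            "ros_cell_signal": ros_cell_signal.ravel(),
            "ph_cell_signal": ph_cell_signal.ravel(),
            "sd_wdf": sd_wdf.ravel(),
        }
    )
    assignment = pd.DataFrame(assignment_rows, columns=["cell_id", "droplet_id"])
    return traces, assignment


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None, **cell_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame, list[GroundTruthCell]]:
    """Encapsulate a freshly sampled cell population under ``config``.

    Convenience wrapper: draws the Poisson occupancy, samples exactly the
    required number of ground-truth cells and forward-simulates the traces.
    Returns (traces, assignment, cells).
    """
    if seed is None:
        seed = config.seed
    counts = simulate_encapsulation(config.n_droplets, config.lambda_, seed)
    cells = sample_cells(int(counts.sum()), seed + 1, **cell_kwargs)
    traces, assignment = simulate_experiment(config, cells, seed + 2, counts=counts)
    return traces, assignment, cells


LACTATE_LADDER = (0.0, 2.0, 20.0, 200.0, 500.0, 1_000.0, 2_000.0, 5_000.0,
                  10_000.0, 20_000.0, 50_000.0, 100_000.0, 200_000.0)


def simulate_calibration_standards(
    kind: str,
    noise_scale: float,
    replicates: int,
    seed: int,
    *,
    lactate_model: Optional[FourPLModel] = None,
    relocation_model: Optional[ExponentialRelocationModel] = None,
) -> pd.DataFrame:
    """Generate a calibration-standard table for one assay.

    ``kind='lactate'`` produces the concentration ladder 2-200,000 amol/nL
    (plus blank), whose two lowest nonzero points (2 and 20 amol/nL) feed the
    LoD formula; ``kind='IgG'``/``'IgM'`` produce a blank plus 100 nM and
    eight twofold serial dilutions. Signals are the truth forward curve plus
    additive Gaussian noise of standard deviation ``noise_scale``.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if kind == "lactate":
        model = lactate_model or default_lactate_truth()
        concentrations = np.array(LACTATE_LADDER)
        clean = model.forward(concentrations)
    elif kind in ("IgG", "IgM"):
        model = relocation_model or default_relocation_truth()
        concentrations = np.concatenate([[0.0], 100.0 / 2.0 ** np.arange(8, -1, -1)])
        clean = model.forward(concentrations)
    else:
        raise ValueError(f"unknown standard kind: {kind!r}")
    rows = []
    for conc, mu in zip(concentrations, clean):
        sig = mu + rng.normal(0.0, noise_scale, size=replicates)
        for r, s in enumerate(sig):
            rows.append((conc, r, s))
    return pd.DataFrame(rows, columns=["concentration", "replicate_id", "signal"])


def simulate_ph_calibration(
    n_replicates: int = 3,
    mean_5p5: float = 2.0,
    sd_5p5: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-replicate normalized mean signals at pH 5.5.

    Emulates the dye calibration in which cell signals are normalized to the
    median signal at pH 7.5 and the per-replicate means at pH 5.5 define the
    acidic threshold (their average plus SEM).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(mean_5p5, sd_5p5, size=n_replicates)
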