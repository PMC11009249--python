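"""Calibration-curve fitting and signal/concentration conversion.

Two calibration models are used by droplet secretion assays:

* a four-parameter logistic (4PL) curve for the enzymatic lactate assay,
  where the whole-droplet fluorescence rises sigmoidally with lactate
  concentration (amol/nL), and
* a saturating exponential for the antibody relocation sandwich assay,
  ``y = y_plateau - (y_plateau - y_blank) * exp(-K * x)``, where ``y`` is the
  fluorescence relocation ratio and ``x`` the antibody concentration in nM.

From the fitted curves this module derives the assay's working limits:

* the lactate limit of detection, ``median(low) + 1.646 * (SD_low + SD_low+1)``
  computed from the two lowest nonzero standards,
* the lactate upper cutoff, ``plateau - 2 * (sqrt(N) * CI_width / 3.92)`` where
  the width is that of the plateau's 95% confidence interval and N the number
  of distinct standard concentrations, and
* the relocation cutoff, the fitted plateau minus the half-width of a 90%
  prediction interval.

Both curves expose exact algebraic inverses, which downstream rate estimation
uses to convert per-time-point fluorescence into concentrations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AVOGADRO",
    "FourPLModel",
    "ExponentialRelocationModel",
    "QuantitativeRange",
    "CalibrationFitError",
    "SignalOutOfRangeError",
    "SaturationError",
    "fit_four_pl",
    "lactate_lod",
    "lactate_cutoff",
    "invert_four_pl",
    "fit_relocation_model",
    "invert_relocation",
    "relocation_cutoff",
    "molecules_from_concentration",
    "concentration_from_molecules",
]

AVOGADRO = 6.02214076e23  # molecules per mole


class CalibrationFitError(RuntimeError):
    """Nonlinear calibration fit failed or the input is degenerate."""


class SignalOutOfRangeError(ValueError):
    """Signal lies outside the invertible range of the calibration curve."""


class SaturationError(SignalOutOfRangeError):
    """Signal at or above the fitted plateau; concentration is unbounded."""


@dataclass(frozen=True)
class FourPLModel:
    """Fitted four-parameter logistic calibration curve.

    ``signal = bottom + (plateau - bottom) / (1 + (ec50 / x) ** hill)`` with
    ``hill > 0`` so the signal increases with concentration. ``plateau_ci_low``
    and ``plateau_ci_high`` bound the plateau's 95% confidence interval, and
    ``n_points`` is the number of distinct standard concentrations used.
    """

    bottom: float
    plateau: float
    ec50: float
    hill: float
    plateau_ci_low: float
    plateau_ci_high: float
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if not self.plateau > self.bottom:
            raise ValueError("plateau must exceed bottom")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if not self.plateau_ci_low <= self.plateau <= self.plateau_ci_high:
            raise ValueError("plateau must lie inside its confidence interval")

    def forward(self, concentration):
        """Predicted signal (AU) at the given concentration(s)."""
        return four_pl(concentration, self.bottom, self.plateau, self.ec50, self.hill)

    def inverse(self, signal: float) -> float:
        """Concentration at the given signal; see :func:`invert_four_pl`."""
        return invert_four_pl(signal, self)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "FourPLModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ExponentialRelocationModel:
    """Fitted saturating-exponential relocation calibration curve.

    ``y = y_plateau - (y_plateau - y_blank) * exp(-K * x)`` with ``x`` in nM.
    ``prediction_halfwidth_90`` is the half-width of a 90% prediction interval
    near saturation, used to place the assay's upper cutoff.
    """

    y_blank: float
    y_plateau: float
    K: float
    residual_sd: float
    prediction_halfwidth_90: float

    def __post_init__(self) -> None:
        if not self.y_plateau > self.y_blank:
            raise ValueError("y_plateau must exceed y_blank")
        if not self.K > 0:
            raise ValueError("K must be positive")

    def forward(self, concentration):
        concentration = np.asarray(concentration, dtype=float)
        out = self.y_plateau - (self.y_plateau - self.y_blank) * np.exp(
            -self.K * concentration
        )
        return out if out.ndim else float(out)

    def inverse(self, y: float) -> float:
        return invert_relocation(y, self)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ExponentialRelocationModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class QuantitativeRange:
    """Closed quantitative range of an assay, in rate units (e.g. amol/s)."""

    low: float
    high: float
    units: str

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("require 0 < low < high")

    def contains(self, rate: float) -> bool:
        return self.low <= rate <= self.high


def four_pl(x, bottom: float, plateau: float, ec50: float, hill: float):
    """Increasing 4PL response; maps x=0 to ``bottom`` exactly."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (ec50 / np.where(x > 0, x, 1.0)) ** hill, np.inf)
        out = bottom + (plateau - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


def _distinct_levels(table: pd.DataFrame) -> np.ndarray:
    return np.sort(table["concentration"].unique())


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = {"concentration", "signal"} - set(table.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    if table[["concentration", "signal"]].isna().any().any():
        raise ValueError("calibration table contains NaN")
    return table


def fit_four_pl(table: pd.DataFrame) -> FourPLModel:
    """Least-squares 4PL fit of signal vs concentration.

    Expects a tidy table with ``concentration`` (amol/nL) and ``signal`` (AU)
    columns; replicate rows per concentration are used as-is. The plateau's
    95% CI comes from the asymptotic covariance of the fit.
    """
    table = _check_table(table)
    levels = _distinct_levels(table)
    if len(levels) < 4:
        raise CalibrationFitError(
            f"need >= 4 distinct concentrations, got {len(levels)}"
        )
    x = table["concentration"].to_numpy(dtype=float)
    y = table["signal"].to_numpy(dtype=float)
    span = y.max() - y.min()
    if span <= 0 or span < 1e-9 * max(1.0, abs(y.mean())):
        raise CalibrationFitError("signal shows no transition (constant table)")

    # initial guesses: extremes for the asymptotes, the concentration whose
    # mean signal is closest to the midpoint for ec50
    mid = (y.min() + y.max()) / 2.0
    means = table.groupby("concentration")["signal"].mean()
    pos = means.index[means.index > 0]
    ec50_0 = float(pos[np.argmin(np.abs(means.loc[pos] - mid))]) if len(pos) else 1.0
    p0 = [y.min(), y.max(), ec50_0, 1.0]
    try:
        popt, pcov = optimize.curve_fit(
            four_pl,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 50.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise CalibrationFitError(f"4PL fit did not converge: {exc}") from exc
    bottom, plateau, ec50, hill = (float(v) for v in popt)
    if not np.all(np.isfinite(popt)) or plateau <= bottom:
        raise CalibrationFitError(
            f"degenerate 4PL fit: bottom={bottom:g} plateau={plateau:g}"
        )
    resid = y - four_pl(x, *popt)
    dof = max(len(y) - 4, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    se_plateau = float(np.sqrt(max(pcov[1, 1], 0.0)))
    tcrit = float(stats.t.ppf(0.975, dof))
    return FourPLModel(
        bottom=bottom,
        plateau=plateau,
        ec50=ec50,
        hill=hill,
        plateau_ci_low=plateau - tcrit * se_plateau,
        plateau_ci_high=plateau + tcrit * se_plateau,
        n_points=int(len(levels)),
        residual_sd=residual_sd,
    )


def lactate_lod(table: pd.DataFrame, model: FourPLModel) -> tuple[float, float]:
    """Detection limit from the two lowest nonzero standards.

    Signal LoD = median(lowest level) + 1.646 * (SD(lowest) + SD(next)); the
    concentration LoD is the inverse-4PL image of the signal LoD (0 if the
    signal LoD does not exceed the curve's bottom).
    """
    table = _check_table(table)
    levels = _distinct_levels(table)
    levels = levels[levels > 0]
    if len(levels) < 2:
        raise ValueError("need at least two nonzero concentration levels")
    low, low1 = levels[0], levels[1]
    sig_low = table.loc[table["concentration"] == low, "signal"]
    sig_low1 = table.loc[table["concentration"] == low1, "signal"]
    if len(sig_low) < 2 or len(sig_low1) < 2:
        raise ValueError("need >= 2 replicates at the two lowest levels")
    signal_lod = float(
        sig_low.median() + 1.646 * (sig_low.std(ddof=1) + sig_low1.std(ddof=1))
    )
    if signal_lod <= model.bottom:
        conc_lod = 0.0
    elif signal_lod >= model.plateau:
        raise SignalOutOfRangeError("signal LoD at or above the plateau")
    else:
        conc_lod = invert_four_pl(signal_lod, model)
    return signal_lod, conc_lod


def lactate_cutoff(model: FourPLModel) -> float:
    """Upper signal cutoff: plateau - 2 * (sqrt(N) * CI width / 3.92)."""
    if model.n_points <= 0:
        raise ValueError("model fitted on zero concentrations")
    sd = math.sqrt(model.n_points) * (model.plateau_ci_high - model.plateau_ci_low) / 3.92
    return model.plateau - 2.0 * sd


def invert_four_pl(signal: float, model: FourPLModel) -> float:
    """Exact algebraic inverse of the 4PL curve.

    Valid for ``bottom < signal < plateau``; outside that open interval the
    concentration is undefined (0 or infinity) and an error is raised, with a
    clamping suggestion for callers that can tolerate it.
    """
    if signal >= model.plateau:
        raise SaturationError(
            f"signal {signal:g} >= plateau {model.plateau:g}; concentration is "
            "unbounded (consider clamping to the assay cutoff)"
        )
    if signal <= model.bottom:
        raise SignalOutOfRangeError(
            f"signal {signal:g} <= bottom {model.bottom:g}; concentration is "
            "not resolvable (consider clamping to 0)"
        )
    frac = (model.plateau - model.bottom) / (signal - model.bottom) - 1.0
    return model.ec50 / frac ** (1.0 / model.hill)


def _relocation_curve(x, y_blank, y_plateau, K):
    return y_plateau - (y_plateau - y_blank) * np.exp(-K * np.asarray(x, dtype=float))


def fit_relocation_model(table: pd.DataFrame) -> ExponentialRelocationModel:
    """Least-squares fit of the saturating-exponential relocation curve.

    The table must include a blank (0 nM) level and at least four nonzero
    levels. ``y_blank`` is initialised at the median blank relocation. The 90%
    prediction half-width is ``t(0.95, dof) * residual_sd * sqrt(1 + h)`` with
    ``h`` the leverage of the highest-concentration design point.
    """
    table = _check_table(table)
    levels = _distinct_levels(table)
    if levels[0] != 0:
        raise CalibrationFitError("relocation table must include a 0 nM blank level")
    if len(levels[levels > 0]) < 4:
        raise CalibrationFitError("need >= 4 nonzero concentration levels")
    x = table["concentration"].to_numpy(dtype=float)
    y = table["signal"].to_numpy(dtype=float)
    y_blank0 = float(table.loc[table["concentration"] == 0, "signal"].median())
    y_plateau0 = float(y.max())
    if y_plateau0 <= y_blank0:
        raise CalibrationFitError("no relocation increase over blank")
    # half-saturation concentration seeds K
    means = table.groupby("concentration")["signal"].mean()
    mid = y_blank0 + 0.5 * (y_plateau0 - y_blank0)
    pos = means.index[means.index > 0]
    x_half = float(pos[np.argmin(np.abs(means.loc[pos] - mid))])
    p0 = [y_blank0, y_plateau0, math.log(2.0) / max(x_half, 1e-9)]
    try:
        popt, _ = optimize.curve_fit(
            _relocation_curve,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise CalibrationFitError(f"relocation fit did not converge: {exc}") from exc
    y_blank, y_plateau, K = (float(v) for v in popt)
    if y_plateau <= y_blank:
        raise CalibrationFitError("fitted plateau does not exceed fitted blank")
    resid = y - _relocation_curve(x, *popt)
    dof = max(len(y) - 3, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    halfwidth = _prediction_halfwidth_90(x, popt, residual_sd, dof)
    return ExponentialRelocationModel(
        y_blank=y_blank,
        y_plateau=y_plateau,
        K=K,
        residual_sd=residual_sd,
        prediction_halfwidth_90=halfwidth,
    )


def _prediction_halfwidth_90(x, popt, residual_sd: float, dof: int) -> float:
    """90% prediction half-width at the highest-concentration design point."""
    y_blank, y_plateau, K = popt
    e = np.exp(-K * x)
    jac = np.column_stack([e, 1.0 - e, (y_plateau - y_blank) * x * e])
    jtj = jac.T @ jac
    try:
        jtj_inv = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        jtj_inv = np.linalg.pinv(jtj)
    j_top = jac[int(np.argmax(x))]
    leverage = float(j_top @ jtj_inv @ j_top)
    tcrit = float(stats.t.ppf(0.95, dof))
    return tcrit * residual_sd * math.sqrt(1.0 + max(leverage, 0.0))


def invert_relocation(y: float, model: ExponentialRelocationModel) -> float:
    """Exact inverse ``x = -ln((y_plateau - y)/(y_plateau - y_blank)) / K``.

    Signals at or above the plateau raise :class:`SaturationError`; signals
    below the blank clamp to 0 nM with a warning (they carry no concentration
    information beyond "blank").
    """
    if y >= model.y_plateau:
        raise SaturationError(
            f"relocation {y:g} >= plateau {model.y_plateau:g}; saturated"
        )
    if y < model.y_blank:
        warnings.warn(
            f"relocation {y:g} below blank {model.y_blank:g}; clamped to 0 nM",
            stacklevel=2,
        )
        return 0.0
    return float(
        -math.log((model.y_plateau - y) / (model.y_plateau - model.y_blank)) / model.K
    )


def relocation_cutoff(model: ExponentialRelocationModel) -> float:
    """Upper relocation cutoff: fitted plateau minus the 90% prediction half-width."""
    return model.y_plateau - model.prediction_halfwidth_90


def molecules_from_concentration(conc_nm: float, droplet_volume_pl: float) -> float:
    """Molecule count in a droplet at the given concentration.

    ``molecules = conc[nM] * 1e-9 mol/L * volume[L] * N_A``; 1 nM in a 50 pL
    droplet is about 30,111 molecules.
    """
    if conc_nm < 0:
        raise ValueError("concentration must be >= 0")
    if droplet_volume_pl <= 0:
        raise ValueError("droplet volume must be positive")
    return conc_nm * 1e-9 * droplet_volume_pl * 1e-12 * AVOGADRO


def concentration_from_molecules(molecules: float, droplet_volume_pl: float) -> float:
    """Inverse of :func:`molecules_from_concentration`, in nM."""
    if molecules < 0:
        raise ValueError("molecule count must be >= 0")
    if droplet_volume_pl <= 0:
        raise ValueError("droplet volume must be positive")
    return molecules / (1e-9 * droplet_volume_pl * 1e-12 * AVOGADRO)
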