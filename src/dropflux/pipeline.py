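"""End-to-end orchestration: simulate -> calibrate -> quantify -> phenotype.

``run_pipeline`` executes the full analysis on a synthetic experiment:

1. generate calibration-standard tables and fit both calibration curves;
2. forward-simulate a droplet cohort under the configured conditions;
3. pool empty-droplet noise statistics per channel;
4. for every single-cell droplet (multi-cell droplets are excluded),
   estimate the lactate secretion rate, evaluate the antibody detection
   criteria and rate, fit the affinity slope and call antigen specificity,
   and classify ROS, intracellular pH and caspase-3/7 state;
5. summarise cohort statistics (λ estimate, class counts, a comparison of
   lactate rates between pH classes).

Every run emits a manifest (config snapshot, seeds, stage row counts,
warnings) sufficient to re-execute identically; reruns with the same config
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    fit_four_pl,
    fit_relocation_model,
    lactate_cutoff,
    lactate_lod,
    relocation_cutoff,
)
from .cohort import compare_distributions, estimate_lambda
from .phenotype import (
    affinity_slope,
    caspase_active,
    is_antigen_specific,
    ph_classify,
    ros_classify,
    ros_signal_increase,
)
from .secretion import (
    IGG_QUANT_RANGE,
    IGG_SC_THRESHOLD,
    IGM_QUANT_RANGE,
    IGM_SC_THRESHOLD,
    LACTATE_QUANT_RANGE,
    empty_droplet_stats,
    ig_secretion_rate,
    lactate_secretion_rate,
    passes_secretion_criteria,
    relocation_lod,
)
from .synthetic import (
    SimulationConfig,
    simulate_calibration_standards,
    simulate_cohort,
    simulate_ph_calibration,
)

__all__ = ["PipelineConfig", "run_pipeline", "write_results"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run.

    Assay constants (quantitative ranges, secretor thresholds, significance
    level) are configuration, never hard-coded in computation paths; the
    defaults are the assay's working values.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calibration_replicates: int = 16
    lactate_standard_noise: float = 15.0
    relocation_standard_noise: float = 0.003
    lactate_range: tuple[float, float] = (LACTATE_QUANT_RANGE.low,
                                          LACTATE_QUANT_RANGE.high)
    igg_range: tuple[float, float] = (IGG_QUANT_RANGE.low, IGG_QUANT_RANGE.high)
    igm_range: tuple[float, float] = (IGM_QUANT_RANGE.low, IGM_QUANT_RANGE.high)
    igg_sc_threshold: float = IGG_SC_THRESHOLD
    igm_sc_threshold: float = IGM_SC_THRESHOLD
    alpha: float = 0.05
    ros_reference_n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lactate_range", "igg_range", "igm_range"):
            low, high = getattr(self, name)
            if not 0 < low < high:
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if self.calibration_replicates < 2:
            raise ValueError("calibration_replicates must be >= 2")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("lactate_range", "igg_range", "igm_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle maps stage names to their outputs: ``calibration`` (fitted
    models and limits), ``traces``/``cells``, ``secretion`` and
    ``phenotype`` DataFrames, ``stats`` and ``manifest`` dicts.
    """
    warnings_log: list[str] = []
    seed = config.seed
    sim = dataclasses.replace(config.simulation, seed=seed)

    # 1. calibration
    lac_table = simulate_calibration_standards(
        "lactate", config.lactate_standard_noise, config.calibration_replicates,
        seed + 10, lactate_model=sim.forward_lactate_model,
    )
    ig_table = simulate_calibration_standards(
        sim.ig_analyte, config.relocation_standard_noise,
        config.calibration_replicates, seed + 11,
        relocation_model=sim.forward_relocation_model,
    )
    lac_model = fit_four_pl(lac_table)
    rel_model = fit_relocation_model(ig_table)
    lac_lod_signal, lac_lod_conc = lactate_lod(lac_table, lac_model)
    lac_cut = lactate_cutoff(lac_model)
    rel_cut = relocation_cutoff(rel_model)

    # 2. cohort simulation
    traces, assignment, cells = simulate_cohort(sim, seed=seed)
    counts = (
        traces.loc[traces["time_index"] == 0]
        .set_index("droplet_id")["n_cells"]
        .sort_index()
    )

    # 3. empty-droplet noise statistics per channel
    stats_ig = empty_droplet_stats(traces, "ig_relocation")
    stats_ag = empty_droplet_stats(traces, "antigen_relocation")
    rel_lod = relocation_lod(stats_ig)
    empty_ids = counts.index[counts == 0]
    first_frame = traces.loc[traces["time_index"] == 0].set_index("droplet_id")
    empty_sd_wdf_t1 = first_frame.loc[empty_ids, "sd_wdf"].to_numpy()

    # reference distributions for the cell-state thresholds
    ref_rng = np.random.default_rng(seed + 20)
    ros_reference = ref_rng.normal(
        sim.ros_low_mean, sim.ros_low_sd, size=config.ros_reference_n
    )
    ph_calibration = simulate_ph_calibration(seed=seed + 21)

    single_ids = counts.index[counts == 1]
    n_multi = int((counts > 1).sum())
    if n_multi:
        warnings_log.append(f"excluded {n_multi} multi-cell droplets")

    # 4. per single-cell droplet quantification and phenotyping
    by_droplet = dict(tuple(traces.groupby("droplet_id")))
    ig_range = (config.igg_range if sim.ig_analyte == "IgG" else config.igm_range)
    from .calibration import QuantitativeRange

    lac_qr = QuantitativeRange(*config.lactate_range, "amol/s")
    ig_qr = QuantitativeRange(*ig_range, f"{sim.ig_analyte}/s")
    sc_threshold = (config.igg_sc_threshold if sim.ig_analyte == "IgG"
                    else config.igm_sc_threshold)

    secretion_rows = []
    ros_increases = []
    ph_signals_t1 = []
    phenotype_rows = []
    for did in single_ids:
        trace = by_droplet[did]
        lac_est = lactate_secretion_rate(
            trace, lac_model, sim.droplet_volume_pl, quant_range=lac_qr
        )
        crit = passes_secretion_criteria(
            trace["time_s"], trace["ig_relocation"], rel_lod, stats_ig
        )
        ig_est = ig_secretion_rate(
            trace, rel_model, sim.droplet_volume_pl, analyte=sim.ig_analyte,
            quant_range=ig_qr, criteria=crit,
        )
        secretion_rows.append(
            {
                "droplet_id": did,
                "lactate_rate_amol_s": lac_est.rate,
                "lactate_in_range": lac_est.in_quant_range,
                "lactate_above_range": lac_est.above_range,
                "ig_rate_molecules_s": ig_est.rate,
                "ig_criteria_passed": crit.passed,
                "ig_above_range": ig_est.above_range,
                "is_secretor": crit.passed and ig_est.rate >= sc_threshold,
            }
        )
        aff = affinity_slope(
            trace["ig_relocation"], trace["antigen_relocation"], rel_lod, rel_cut,
            droplet_id=did,
            antigen_specific=is_antigen_specific(
                trace["antigen_relocation"], stats_ag
            ),
        )
        casp, casp_thr = caspase_active(trace["sd_wdf"], empty_sd_wdf_t1)
        ros_increases.append(ros_signal_increase(trace["ros_cell_signal"]))
        ph_signals_t1.append(float(trace["ph_cell_signal"].iloc[0]))
        phenotype_rows.append(
            {
                "droplet_id": did,
                "affinity_slope": aff.slope,
                "affinity_n_points": aff.n_points_used,
                "antigen_specific": aff.antigen_specific,
                "caspase_active": casp,
            }
        )

    ros_labels, ros_thr = ros_classify(ros_increases, ros_reference)
    ph_labels, ph_thr, ph_norm = ph_classify(ph_signals_t1, ph_calibration)
    phenotype = pd.DataFrame(phenotype_rows)
    phenotype["ros_increase"] = ros_increases
    phenotype["ros_class"] = ros_labels
    phenotype["ph_normalized"] = ph_norm
    phenotype["ph_class"] = ph_labels
    secretion = pd.DataFrame(secretion_rows)

    # 5. cohort statistics
    lam = estimate_lambda(counts.to_numpy())
    stats_out = {
        "lambda_hat": lam.lambda_hat,
        "lambda_se": lam.standard_error,
        "n_droplets": lam.n_droplets,
        "n_single_cell": int(len(single_ids)),
        "n_multi_cell_excluded": n_multi,
        "n_secretors": int(secretion["is_secretor"].sum()),
        "lactate_lod_signal": lac_lod_signal,
        "lactate_lod_conc": lac_lod_conc,
        "lactate_cutoff_signal": lac_cut,
        "relocation_lod": rel_lod,
        "relocation_cutoff": rel_cut,
        "ros_threshold": ros_thr,
        "ph_threshold": ph_thr,
    }
    acidic = secretion.loc[phenotype["ph_class"].values == "acidic",
                           "lactate_rate_amol_s"]
    phys = secretion.loc[phenotype["ph_class"].values == "physiological",
                         "lactate_rate_amol_s"]
    if len(acidic) >= 2 and len(phys) >= 2:
        stats_out["lsr_by_ph_ks"] = compare_distributions(
            acidic, phys, method="kolmogorov_smirnov"
        )

    manifest = {
        "software": f"dropflux {__version__}",
        "seed": seed,
        "config": _config_snapshot(config),
        "row_counts": {
            "traces": int(len(traces)),
            "cells": int(len(cells)),
            "secretion": int(len(secretion)),
            "phenotype": int(len(phenotype)),
        },
        "warnings": warnings_log,
    }
    return {
        "calibration": {
            "lactate_model": lac_model,
            "relocation_model": rel_model,
            "lactate_lod_signal": lac_lod_signal,
            "lactate_cutoff_signal": lac_cut,
            "relocation_lod": rel_lod,
            "relocation_cutoff": rel_cut,
        },
        "traces": traces,
        "assignment": assignment,
        "cells": cells,
        "secretion": secretion,
        "phenotype": phenotype,
        "stats": stats_out,
        "manifest": manifest,
    }


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    return json.loads(json.dumps(snap, default=str))


def write_results(bundle: dict, out_dir: Union[str, Path]) -> list[Path]:
    """Write the result bundle (CSV tables + JSON stats/manifest) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("secretion", "phenotype", "traces", "assignment"):
        path = out / f"{name}.csv"
        bundle[name].to_csv(path, index=False)
        written.append(path)
    cal = bundle["calibration"]
    cal_json = {
        "lactate_model": json.loads(cal["lactate_model"].to_json()),
        "relocation_model": json.loads(cal["relocation_model"].to_json()),
        "lactate_lod_signal": cal["lactate_lod_signal"],
        "lactate_cutoff_signal": cal["lactate_cutoff_signal"],
        "relocation_lod": cal["relocation_lod"],
        "relocation_cutoff": cal["relocation_cutoff"],
    }
    for name, payload in (
        ("calibration", cal_json),
        ("stats", bundle["stats"]),
        ("manifest", bundle["manifest"]),
    ):
        path = out / f"{name}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written
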