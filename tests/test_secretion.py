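"""Empty-droplet noise statistics, detection criteria, and rate estimation."""

import numpy as np
import pandas as pd
import pytest

from dropflux.calibration import fit_four_pl, fit_relocation_model
from dropflux.secretion import (
    EmptyDropletStats,
    classify_secretors,
    empty_droplet_stats,
    ig_secretion_rate,
    lactate_secretion_rate,
    passes_secretion_criteria,
    relocation_lod,
    SecretionEstimate,
)
from dropflux.synthetic import (
    GroundTruthCell,
    SimulationConfig,
    simulate_experiment,
)

from conftest import make_trace


def empty_traces(values, n_droplets=40):
    """Trace set whose empty droplets carry the given pooled channel values."""
    reps = int(np.ceil(n_droplets * 6 / len(values)))
    vals = np.tile(np.asarray(values, dtype=float), reps)[: n_droplets * 6]
    return pd.DataFrame(
        {
            "droplet_id": np.repeat(np.arange(n_droplets), 6),
            "time_index": np.tile(np.arange(6), n_droplets),
            "time_s": np.tile(np.arange(6) * 600.0, n_droplets),
            "n_cells": 0,
            "ig_relocation": vals,
        }
    )


class TestEmptyDropletStats:
    def test_constant_signal(self):
        stats = empty_droplet_stats(empty_traces([3.0]), "ig_relocation")
        assert (stats.median_empty, stats.mad_empty, stats.sigma_hat) == (
            3.0, 0.0, 0.0,
        )

    def test_hand_computed_mad(self):
        stats = empty_droplet_stats(
            empty_traces([0.0, 1.0, 2.0, 3.0, 4.0], n_droplets=30),
            "ig_relocation",
        )
        assert stats.median_empty == 2.0
        assert stats.mad_empty == 1.0
        assert stats.sigma_hat == pytest.approx(1.4826)

    def test_sigma_hat_consistent_for_gaussian(self):
        rng = np.random.default_rng(0)
        values = rng.normal(5.0, 2.0, size=60_000)
        stats = empty_droplet_stats(empty_traces(values, 10_000),
                                    "ig_relocation")
        assert stats.sigma_hat == pytest.approx(2.0, rel=0.05)

    def test_requires_empty_droplets(self):
        traces = empty_traces([1.0])
        traces["n_cells"] = 1
        with pytest.raises(ValueError):
            empty_droplet_stats(traces, "ig_relocation")


class TestRelocationLoD:
    def test_hand_arithmetic(self):
        stats = EmptyDropletStats(median_empty=0.5, mad_empty=0.1 / 1.4826,
                                  n_empty=100)
        assert relocation_lod(stats) == pytest.approx(0.5 + 1.645 * 2 * 0.1)

    def test_zero_noise_lod_is_median(self):
        stats = EmptyDropletStats(median_empty=0.5, mad_empty=0.0, n_empty=100)
        assert relocation_lod(stats) == 0.5

    def test_monotone_in_sigma(self):
        lods = [
            relocation_lod(EmptyDropletStats(0.5, mad, 100))
            for mad in [0.0, 0.01, 0.05, 0.2]
        ]
        assert np.all(np.diff(lods) > 0)


class TestSecretionCriteria:
    stats = EmptyDropletStats(median_empty=1.0, mad_empty=0.01 / 1.4826,
                              n_empty=100)
    lod = relocation_lod(stats)  # 1.0329
    t = np.arange(6) * 600.0

    def test_blank_droplet_fails_all(self):
        res = passes_secretion_criteria(self.t, np.full(6, 1.0), self.lod,
                                        self.stats)
        assert not (res.above_lod or res.increasing or res.varies)
        assert not res.passed

    def test_strong_secretor_passes(self):
        y = 1.0 + np.arange(6) * 0.05  # crosses LoD, range 0.25 = 25 sigma_hat
        res = passes_secretion_criteria(self.t, y, self.lod, self.stats)
        assert res.above_lod and res.increasing and res.varies and res.passed

    def test_decreasing_series_fails_criterion_two_only(self):
        y = 1.3 - np.arange(6) * 0.05
        res = passes_secretion_criteria(self.t, y, self.lod, self.stats)
        assert res.above_lod and res.varies and not res.increasing
        assert not res.passed

    def test_matches_brute_force_evaluation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            y = 1.0 + rng.normal(0, 0.02, size=6) + rng.uniform(-0.01, 0.05) * (
                self.t / 600.0
            )
            res = passes_secretion_criteria(self.t, y, self.lod, self.stats)
            assert res.above_lod == bool((y >= self.lod).any())
            assert res.increasing == (np.polyfit(self.t, y, 1)[0] > 0)
            assert res.varies == (
                y.max() - y.min() > 1.645 * 2 * self.stats.sigma_hat
            )

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            passes_secretion_criteria([0.0], [1.0], self.lod, self.stats)


class TestLactateRate:
    def test_noiseless_round_trip(self, noiseless_lactate_standards):
        """A 0.4 amol/s ground-truth cell is recovered exactly."""
        model = fit_four_pl(noiseless_lactate_standards)
        t = np.arange(6) * 600.0
        conc = 0.4 * t / 0.05  # amol/nL in 50 pL
        trace = make_trace(t, lactate_signal=model.forward(conc))
        est = lactate_secretion_rate(trace, model, 50.0)
        assert est.rate == pytest.approx(0.4, abs=1e-6)
        assert est.in_quant_range and not est.above_range

    def test_unit_arithmetic_oracle(self, noiseless_lactate_standards):
        """1200 amol/nL gained per 600 s interval at 50 pL is 0.10 amol/s."""
        model = fit_four_pl(noiseless_lactate_standards)
        t = np.arange(6) * 600.0
        trace = make_trace(t, lactate_signal=model.forward(1200.0 * np.arange(6)))
        est = lactate_secretion_rate(trace, model, 50.0)
        assert est.rate == pytest.approx(0.10, rel=1e-9)

    def test_constant_concentration_is_below_range(self,
                                                   noiseless_lactate_standards):
        model = fit_four_pl(noiseless_lactate_standards)
        t = np.arange(6) * 600.0
        trace = make_trace(t, lactate_signal=np.full(6, model.forward(500.0)))
        est = lactate_secretion_rate(trace, model, 50.0)
        assert est.rate == 0.0
        assert not est.in_quant_range and not est.above_range

    def test_monotone_in_true_rate(self, noiseless_lactate_standards):
        model = fit_four_pl(noiseless_lactate_standards)
        t = np.arange(6) * 600.0
        rates = [
            lactate_secretion_rate(
                make_trace(t, lactate_signal=model.forward(r * t / 0.05)),
                model, 50.0,
            ).rate
            for r in [0.1, 0.2, 0.4, 0.6, 0.8]
        ]
        assert np.all(np.diff(rates) > 0)

    def test_time_origin_invariance(self, noiseless_lactate_standards):
        model = fit_four_pl(noiseless_lactate_standards)
        t = np.arange(6) * 600.0
        sig = model.forward(0.3 * t / 0.05)
        r0 = lactate_secretion_rate(make_trace(t, lactate_signal=sig), model,
                                    50.0).rate
        r1 = lactate_secretion_rate(make_trace(t + 7200.0, lactate_signal=sig),
                                    model, 50.0).rate
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_single_time_point_rejected(self, noiseless_lactate_standards):
        model = fit_four_pl(noiseless_lactate_standards)
        with pytest.raises(ValueError):
            lactate_secretion_rate(
                make_trace([0.0], lactate_signal=[300.0]), model, 50.0
            )


class TestIgRate:
    def test_noiseless_round_trip(self, noiseless_ig_standards, relocation_truth):
        """A 50 IgG/s ground-truth cell is recovered exactly."""
        from dropflux.calibration import concentration_from_molecules

        model = fit_relocation_model(noiseless_ig_standards)
        t = np.arange(6) * 600.0
        conc = np.array(
            [concentration_from_molecules(50.0 * ti, 50.0) for ti in t]
        )
        trace = make_trace(t, ig_relocation=relocation_truth.forward(conc))
        est = ig_secretion_rate(trace, model, 50.0, analyte="IgG")
        assert est.rate == pytest.approx(50.0, rel=1e-6)
        assert est.in_quant_range

    def test_avogadro_arithmetic_oracle(self, relocation_truth):
        """0.1 nM gained per 600 s interval at 50 pL is ~5.0 molecules/s."""
        t = np.arange(6) * 600.0
        conc = 0.1 * np.arange(6)
        trace = make_trace(t, ig_relocation=relocation_truth.forward(conc))
        est = ig_secretion_rate(trace, relocation_truth, 50.0, analyte="IgG")
        assert est.rate == pytest.approx(5.018, rel=1e-3)

    def test_blank_trace_near_zero_rate(self, relocation_truth):
        t = np.arange(6) * 600.0
        trace = make_trace(t, ig_relocation=np.full(6, relocation_truth.y_blank))
        est = ig_secretion_rate(trace, relocation_truth, 50.0, analyte="IgG")
        assert est.rate == pytest.approx(0.0, abs=1e-9)
        assert not est.in_quant_range

    def test_saturated_points_excluded(self, relocation_truth):
        t = np.arange(6) * 600.0
        y = relocation_truth.forward(0.5 * np.arange(6))
        y[-1] = relocation_truth.y_plateau + 0.1
        trace = make_trace(t, ig_relocation=y)
        est = ig_secretion_rate(trace, relocation_truth, 50.0, analyte="IgG")
        assert est.above_range
        assert not est.in_quant_range
        assert est.n_intervals_used == 4

    def test_fully_saturated_reports_upper_bound(self):
        from dropflux.calibration import ExponentialRelocationModel

        model = ExponentialRelocationModel(
            y_blank=1.0, y_plateau=3.0, K=0.02, residual_sd=0.01,
            prediction_halfwidth_90=0.05,
        )
        t = np.arange(6) * 600.0
        trace = make_trace(t, ig_relocation=np.full(6, 3.5))
        est = ig_secretion_rate(trace, model, 50.0, analyte="IgG")
        assert est.above_range and not est.in_quant_range
        assert np.isfinite(est.rate) and est.rate > 0


class TestClassifySecretors:
    def _est(self, analyte, rate, passed=True, above=False):
        return SecretionEstimate(
            droplet_id=0, analyte=analyte, rate=rate, passed_criteria=passed,
            in_quant_range=not above, above_range=above, n_intervals_used=5,
        )

    def test_igg_threshold_boundary(self):
        table = classify_secretors(
            [self._est("IgG", 2.9), self._est("IgG", 3.0)]
        )
        assert list(table["is_secretor"]) == [False, True]

    def test_igm_threshold_boundary(self):
        table = classify_secretors(
            [self._est("IgM", 7.0), self._est("IgM", 6.99)]
        )
        assert list(table["is_secretor"]) == [True, False]

    def test_criteria_gate_the_call(self):
        table = classify_secretors([self._est("IgG", 100.0, passed=False)])
        assert not table["is_secretor"].iloc[0]

    def test_lactate_range_flags(self):
        table = classify_secretors(
            [
                self._est("lactate", 0.05),
                self._est("lactate", 0.5),
                self._est("lactate", 0.85, above=True),
            ]
        )
        assert list(table["lactate_range_status"]) == ["below", "in", "above"]


class TestRecoveryFromSimulation:
    def test_noiseless_pipeline_recovers_rates_exactly(
        self, noiseless_config, noiseless_lactate_standards, noiseless_ig_standards
    ):
        """Noiseless forward simulation + quantification is a 1e-6 round trip."""
        lac_model = fit_four_pl(noiseless_lactate_standards)
        rel_model = fit_relocation_model(noiseless_ig_standards)
        cells = [
            GroundTruthCell(0, 0.25, 40.0, "IgG", 1.0, "low", "physiological",
                            False),
            GroundTruthCell(1, 0.60, 200.0, "IgG", 2.0, "low", "physiological",
                            False),
        ]
        counts = np.zeros(noiseless_config.n_droplets, dtype=int)
        counts[:2] = 1
        traces, _ = simulate_experiment(noiseless_config, cells, seed=0,
                                        counts=counts)
        for cell in cells:
            trace = traces[traces["droplet_id"] == cell.cell_id]
            lac = lactate_secretion_rate(trace, lac_model,
                                         noiseless_config.droplet_volume_pl)
            ig = ig_secretion_rate(trace, rel_model,
                                   noiseless_config.droplet_volume_pl)
            assert lac.rate == pytest.approx(cell.lactate_rate, rel=1e-6)
            assert ig.rate == pytest.approx(cell.ig_rate, rel=1e-6)
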