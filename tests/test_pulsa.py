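"""Pulse physics, expression gating, and PulSA tail gates."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsa_screen.pulsa import (
    GateSpec,
    OpticalModel,
    acquire_population,
    apply_gates,
    binned_aggregation_fraction,
    calibrate_pulsa_gates,
    gate_expression,
    read_pulses_tsv,
    simulate_pulse,
    write_pulses_tsv,
)
from pulsa_screen.benchmarks import (
    _constant_diameter,
    area_conservation_check,
    gate_capture_check,
    height_ratio_check,
    monotonicity_check,
)


def quiet_model(**kw):
    defaults = dict(noise_sd=0.0, cell_diameter_sampler=_constant_diameter(15.0))
    defaults.update(kw)
    return OpticalModel(**defaults)


class TestPulsePhysics:
    def test_zero_fluorescence_gives_zero_pulse(self):
        p = simulate_pulse({"total_fluorescence": 0.0, "punctate_fraction": 0.0}, quiet_model())
        assert (p["height"], p["width"], p["area"]) == (0.0, 0.0, 0.0)

    def test_punctate_taller_and_narrower_than_diffuse(self):
        m = quiet_model()
        punc = simulate_pulse({"total_fluorescence": 500.0, "punctate_fraction": 1.0}, m)
        diff = simulate_pulse({"total_fluorescence": 500.0, "punctate_fraction": 0.0}, m)
        assert punc["height"] > diff["height"]
        assert punc["width"] < diff["width"]
        assert punc["area"] == diff["area"]

    def test_closed_form_height_ratio_sqrt5(self):
        r = height_ratio_check()
        assert r["dev_closed_form"] < 1e-9
        assert r["dev_quadrature"] < 1e-6

    def test_height_and_area_linear_in_fluorescence(self):
        m = quiet_model()
        p1 = simulate_pulse({"total_fluorescence": 300.0, "punctate_fraction": 0.4}, m)
        p2 = simulate_pulse({"total_fluorescence": 600.0, "punctate_fraction": 0.4}, m)
        assert p2["height"] == pytest.approx(2 * p1["height"], rel=1e-12)
        assert p2["area"] == pytest.approx(2 * p1["area"], rel=1e-12)
        assert p2["width"] >= p1["width"]

    def test_monotonicity_in_punctate_fraction(self):
        r = monotonicity_check(n_grid=21)
        assert r["height_strictly_increasing"]
        assert r["width_non_increasing"]

    def test_area_conservation_across_population(self):
        assert area_conservation_check(seed=3)["max_rel_dev"] < 1e-9

    def test_subthreshold_pulse_has_zero_width(self):
        m = quiet_model(trigger_threshold=1e9)
        p = simulate_pulse({"total_fluorescence": 100.0, "punctate_fraction": 0.0}, m)
        assert p["width"] == 0.0
        assert p["height"] > 0.0


class TestAcquirePopulation:
    def test_empty_population(self):
        empty = pd.DataFrame(
            columns=["cell_id", "total_fluorescence", "punctate_fraction", "aggregated"]
        )
        out = acquire_population(empty, OpticalModel(), seed=0)
        assert len(out) == 0

    def test_one_record_per_cell_order_preserved(self, null_population):
        out = acquire_population(null_population, OpticalModel(), seed=1)
        assert len(out) == len(null_population)
        assert (out["cell_id"].to_numpy() == null_population["cell_id"].to_numpy()).all()

    def test_seeded_determinism(self, null_population):
        a = acquire_population(null_population, OpticalModel(), seed=2)
        b = acquire_population(null_population, OpticalModel(), seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestGateExpression:
    def test_full_range_keeps_everything(self):
        rec = pd.DataFrame({"area": np.arange(1.0, 101.0)})
        assert len(gate_expression(rec, 0.0, 1.0)) == 100

    def test_order_statistic_convention(self):
        rec = pd.DataFrame({"area": np.arange(1.0, 1001.0)})
        kept = gate_expression(rec, 0.25, 0.75)
        assert len(kept) == 501
        assert kept["area"].min() == 250.0
        assert kept["area"].max() == 750.0

    def test_empty_input_passes_through(self):
        rec = pd.DataFrame({"area": []})
        assert len(gate_expression(rec, 0.1, 0.9)) == 0

    def test_bad_quantiles_rejected(self):
        rec = pd.DataFrame({"area": [1.0]})
        with pytest.raises(ValueError):
            gate_expression(rec, 0.9, 0.1)


def _two_cluster_records(n=1000, seed=0):
    """Synthetic clusters separated >10x in r = height/width."""
    rng = np.random.default_rng(seed)
    n_hi = n // 10
    height = np.concatenate([rng.uniform(9, 11, n - n_hi), rng.uniform(190, 210, n_hi)])
    width = np.concatenate([rng.uniform(0.9, 1.1, n - n_hi), rng.uniform(0.4, 0.6, n_hi)])
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "height": height,
            "width": width,
            "area": rng.uniform(50, 150, n),
            "truth_aggregated": np.arange(n) >= n - n_hi,
        }
    )


class TestPulsaGates:
    def test_capture_counts_at_10k(self):
        r = gate_capture_check(seed=5)
        assert abs(r["aggregate_fraction"] - 0.05) <= 0.002
        assert abs(r["diffuse_fraction"] - 0.05) <= 0.002

    def test_default_config_aggregate_gate_purity(self):
        r = gate_capture_check(seed=5, q_lo=0.1, q_hi=0.9)
        assert r["aggregate_purity"] > 0.9

    def test_constructed_separation_gives_pure_gate(self):
        rec = _two_cluster_records()
        gates = calibrate_pulsa_gates(rec, 0.05)
        agg, dif = apply_gates(rec, gates)
        assert agg["truth_aggregated"].all()
        assert not dif["truth_aggregated"].any()

    def test_round_to_zero_gives_empty_gates(self):
        rec = _two_cluster_records(n=100)
        gates = calibrate_pulsa_gates(rec, 0.004)  # round(0.4) == 0
        agg, dif = apply_gates(rec, gates)
        assert len(agg) == 0 and len(dif) == 0

    def test_gate_sizes_within_one_of_target(self):
        rec = _two_cluster_records(n=10_000, seed=3)
        gates = calibrate_pulsa_gates(rec, 0.05)
        agg, dif = apply_gates(rec, gates)
        assert abs(len(agg) - 500) <= 1
        assert abs(len(dif) - 500) <= 1

    def test_boundary_record_belongs_to_gate(self):
        rec = pd.DataFrame(
            {
                "cell_id": range(4),
                "height": [1.0, 2.0, 3.0, 4.0],
                "width": [1.0, 1.0, 1.0, 1.0],
                "area": [1.0, 1.0, 1.0, 1.0],
                "truth_aggregated": [False] * 4,
            }
        )
        gates = GateSpec(0, 1, 0.25, aggregate_threshold=4.0, diffuse_threshold=1.0)
        agg, dif = apply_gates(rec, gates)
        assert list(agg["height"]) == [4.0]
        assert list(dif["height"]) == [1.0]

    def test_zero_width_records_excluded_and_counted(self):
        rec = _two_cluster_records(n=200)
        rec.loc[:4, "width"] = 0.0
        gates = calibrate_pulsa_gates(rec, 0.1)
        assert gates.n_width_zero == 5
        agg, dif = apply_gates(rec, gates)
        assert not set(range(5)) & set(agg["cell_id"]) | set(range(5)) & set(dif["cell_id"])

    def test_union_never_exceeds_input(self):
        rec = _two_cluster_records(n=500, seed=9)
        gates = calibrate_pulsa_gates(rec, 0.3)
        agg, dif = apply_gates(rec, gates)
        assert len(agg) + len(dif) <= len(rec)
        assert not set(agg.index) & set(dif.index)


class TestBinnedAggregation:
    def test_counts_and_fractions(self):
        rec = pd.DataFrame(
            {
                "area": [1.0, 1.5, 1.8, 1.9, 5.0],
                "truth_aggregated": [True, False, False, False, True],
            }
        )
        out = binned_aggregation_fraction(rec, "truth_aggregated", [0, 2, 4, 6])
        assert list(out["n_cells"]) == [4, 0, 1]
        assert out["fraction_aggregated"].iloc[0] == 0.25
        assert np.isnan(out["fraction_aggregated"].iloc[1])  # empty bin undefined, not 0
        assert out["fraction_aggregated"].iloc[2] == 1.0

    def test_all_aggregated_gives_fraction_one(self):
        rec = pd.DataFrame({"area": np.linspace(0.5, 9.5, 50), "truth_aggregated": True})
        out = binned_aggregation_fraction(rec, "truth_aggregated", [0, 5, 10])
        assert (out.loc[out["n_cells"] > 0, "fraction_aggregated"] == 1.0).all()

    def test_label_array_and_unsorted_edges_rejected(self):
        rec = pd.DataFrame({"area": [1.0, 2.0]})
        out = binned_aggregation_fraction(rec, np.array([True, False]), [0, 3])
        assert out["fraction_aggregated"].iloc[0] == 0.5
        with pytest.raises(ValueError):
            binned_aggregation_fraction(rec, np.array([True, False]), [3, 0])


def test_pulses_tsv_round_trip(tmp_path, null_population):
    pulses = acquire_population(null_population.head(100), OpticalModel(), seed=7)
    path = tmp_path / "pulses.tsv"
    write_pulses_tsv(pulses, path)
    again = read_pulses_tsv(path)
    np.testing.assert_allclose(
        pulses["height"].to_numpy(), again["height"].to_numpy(), rtol=1e-9
    )
    assert (pulses["truth_aggregated"].to_numpy() == again["truth_aggregated"].to_numpy()).all()
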