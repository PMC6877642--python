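"""Airway tree construction and the three-step breath cycle."""

import numpy as np
import pytest
from scipy import stats

from inhaledose.aerosol import SizeDistributionSpec, deposition_fraction, sample_ensemble
from inhaledose.airway import (
    DFCurveSet,
    alveolar_removal,
    build_airway_tree,
    default_curves,
    place_deposited,
    simulate_breath_cycle,
)


def flat_curves(mt=0.0, gen=0.0, alv=0.0, per_gen=None):
    """Constant-probability curve set for controlled filtration tests."""
    d = np.geomspace(1e-3, 100, 16)
    q = np.array([7.5, 15.0, 60.0])
    tables = {"MT": np.full((16, 3), mt)}
    for g in range(10):
        p = per_gen[g] if per_gen is not None else gen
        tables[f"G{g}"] = np.full((16, 3), p)
    return DFCurveSet(d, q, tables, np.full(16, alv))


class TestAirwayTree:
    def test_default_outlet_count(self):
        assert build_airway_tree().n_outlets == 115

    def test_symmetric_full_tree(self):
        assert build_airway_tree(n_outlets=512).n_outlets == 512

    def test_single_generation(self):
        assert build_airway_tree(generations=1, n_outlets=2).n_outlets == 2

    def test_impossible_outlet_count(self):
        with pytest.raises(ValueError, match="cannot realise"):
            build_airway_tree(generations=3, n_outlets=9)

    def test_tree_is_acyclic_and_connected(self):
        tree = build_airway_tree()
        for seg in range(1, len(tree.radius)):
            # walking parents always reaches the mouth-throat root
            cur, steps = seg, 0
            while tree.parent[cur] >= 0:
                cur = tree.parent[cur]
                steps += 1
                assert steps < 20
            assert cur == 0

    def test_outlet_flow_weights_normalised(self):
        tree = build_airway_tree()
        assert tree.outlet_weight.sum() == pytest.approx(1.0)

    def test_vtk_export(self, tmp_path):
        tree = build_airway_tree(generations=3, n_outlets=8)
        out = tmp_path / "tree.vtk"
        tree.to_vtk_polylines(out)
        assert "POLYDATA" in out.read_text()


class TestBreathCycle:
    def test_zero_curves_everything_exhaled(self):
        ens = sample_ensemble(SizeDistributionSpec(1.0, 2.0), 500, 0)
        final, _ = simulate_breath_cycle(ens, flat_curves(), build_airway_tree(), seed=1)
        assert final.counts_by_status()["exhaled"] == 500

    def test_certain_mt_capture_of_large_particles(self):
        # MT probability 1 above 10 µm: every 15 µm particle lands in MT
        d = np.geomspace(1e-3, 100, 16)
        q = np.array([7.5, 15.0, 60.0])
        tables = {"MT": np.where(d >= 10.0, 1.0, 0.0)[:, None] * np.ones((1, 3))}
        for g in range(10):
            tables[f"G{g}"] = np.zeros((16, 3))
        curves = DFCurveSet(d, q, tables, np.zeros(16))
        ens = sample_ensemble(SizeDistributionSpec(15.0, 1.0), 200, 0)
        final, rec = simulate_breath_cycle(ens, curves, build_airway_tree(), seed=1)
        assert (final.table["region"] == "MT").all()
        assert (final.table["status"] == "deposited").all()

    def test_serial_filtration_closed_form(self):
        # monodisperse, constant per-region probabilities: expected counts
        # follow n·p_r·Π(1−p_j, j<r) for the inhalation pass
        n = 40_000
        p_mt, p_gen = 0.1, 0.05
        tree = build_airway_tree(n_outlets=512)  # uniform depth 9 for all paths
        curves = flat_curves(mt=p_mt, gen=p_gen)
        ens = sample_ensemble(SizeDistributionSpec(1.0, 1.0), n, 0)
        final, rec = simulate_breath_cycle(ens, curves, tree, seed=5)
        inhale = rec[rec["phase"] == "inhale"]
        surv = 1.0
        for region, p in [("MT", p_mt)] + [(f"G{g}", p_gen) for g in range(10)]:
            expect = n * surv * p
            got = (inhale["region"] == region).sum()
            sigma = np.sqrt(n * surv * p * (1 - surv * p))
            assert abs(got - expect) < 4 * sigma, region
            surv *= 1 - p

    def test_count_conservation(self):
        ens = sample_ensemble(SizeDistributionSpec(0.42, 3.5), 5000, 0)
        final, _ = simulate_breath_cycle(ens, default_curves(), build_airway_tree(), seed=2)
        counts = final.counts_by_status()
        assert sum(counts.values()) == 5000
        assert counts["airborne"] == 0

    def test_requires_airborne_input(self):
        ens = sample_ensemble(SizeDistributionSpec(1.0, 2.0), 10, 0)
        final, _ = simulate_breath_cycle(ens, flat_curves(), build_airway_tree(), seed=1)
        with pytest.raises(ValueError, match="airborne"):
            simulate_breath_cycle(final, flat_curves(), build_airway_tree(), seed=1)

    def test_missing_region_curve_rejected(self):
        d = np.geomspace(1e-3, 100, 8)
        q = np.array([7.5, 60.0])
        curves = DFCurveSet(d, q, {"MT": np.zeros((8, 2))}, np.zeros(8))
        ens = sample_ensemble(SizeDistributionSpec(1.0, 2.0), 10, 0)
        with pytest.raises(ValueError, match="missing regions"):
            simulate_breath_cycle(ens, curves, build_airway_tree(), seed=1)

    def test_mass_df_exceeds_count_df_for_impaction_curves(self):
        # default curves deposit large particles preferentially
        ens = sample_ensemble(SizeDistributionSpec(0.42, 3.5), 20_000, 0)
        final, _ = simulate_breath_cycle(ens, default_curves(), build_airway_tree(), seed=3)
        assert deposition_fraction(final, "mass") >= deposition_fraction(final, "count")


class TestAlveolarRemoval:
    def test_zero_df_retains_nothing(self, rng):
        d = rng.lognormal(0, 0.3, 1000)
        keep, flagged = alveolar_removal(d, d, flat_curves(alv=0.0), np.geomspace(0.1, 10, 31), rng)
        assert keep.sum() == 0

    def test_unit_df_retains_everything(self, rng):
        d = rng.lognormal(0, 0.3, 1000)
        keep, _ = alveolar_removal(d, d, flat_curves(alv=1.0), np.geomspace(0.1, 10, 31), rng)
        assert keep.all()

    def test_binomial_oracle(self, rng):
        d = np.full(1000, 1.0)
        keep, _ = alveolar_removal(d, d, flat_curves(alv=0.5), np.geomspace(0.5, 2, 4), rng)
        assert abs(keep.sum() - 500) < 3 * np.sqrt(250)

    def test_injected_only_bins_flagged(self, rng):
        exiting = np.full(50, 1.0)
        inhaled = np.concatenate([exiting, np.full(50, 8.0)])  # large ones never exit
        edges = np.array([0.5, 2.0, 16.0])
        _, flagged = alveolar_removal(exiting, inhaled, flat_curves(alv=0.1), edges, rng)
        assert flagged == [1]

    def test_ratio_clipped_to_one(self, rng):
        # 10x more injected than exiting with DF 0.5: p clips at 1
        exiting = np.full(200, 1.0)
        inhaled = np.full(2000, 1.0)
        keep, _ = alveolar_removal(exiting, inhaled, flat_curves(alv=0.5), np.array([0.5, 2.0]), rng)
        assert keep.all()


class TestPlacement:
    def test_axial_uniform_without_hotspots(self, rng):
        tree = build_airway_tree()
        segs = np.full(2000, 1)  # trachea
        pos = place_deposited(segs, tree, hotspot_weight=0.0, rng=rng)
        axis = tree.end[1] - tree.start[1]
        t = (pos - tree.start[1]) @ axis / (axis @ axis)
        assert stats.kstest(t, "uniform").pvalue > 1e-3

    def test_positions_on_tube_surface(self, rng):
        tree = build_airway_tree()
        segs = np.full(500, 1)
        pos = place_deposited(segs, tree, hotspot_weight=0.5, rng=rng)
        axis = tree.end[1] - tree.start[1]
        u = axis / np.linalg.norm(axis)
        radial = (pos - tree.start[1]) - np.outer((pos - tree.start[1]) @ u, u)
        assert np.allclose(np.linalg.norm(radial, axis=1), tree.radius[1], atol=1e-9)

    def test_seeded_reproducibility(self):
        tree = build_airway_tree()
        a = place_deposited(np.arange(1, 20), tree, 0.3, np.random.default_rng(9))
        b = place_deposited(np.arange(1, 20), tree, 0.3, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_unplaced_region_rejected(self, rng):
        with pytest.raises(ValueError, match="segment"):
            place_deposited(np.array([-1]), build_airway_tree(), 0.0, rng)


def test_curve_csv_round_trip(tmp_path):
    curves = default_curves()
    p = tmp_path / "curves.csv"
    curves.to_csv(p)
    back = DFCurveSet.read_csv(p)
    d = np.array([0.1, 1.0, 10.0])
    for region in ("MT", "G0", "G5"):
        assert np.allclose(
            back.probability(region, d, 15.0), curves.probability(region, d, 15.0)
        )
    assert np.allclose(back.alveolar_df(d), curves.alveolar_df(d))
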