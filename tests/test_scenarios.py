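"""Experiment protocols: ECM patterns, anneal, spreading, indentation,
migration — structural and invariant checks on scaled systems.

The quantitative phenotype checks (purity bound, three-phase force curve,
adhesion ordering, NSI passage sequence) live in the acceptance suite.
"""

import numpy as np
import pytest

import semcell as sc
from semcell import scenarios
from semcell.model import CYT, ECM, GLA, NUC, InvalidParameterError, ParticleKind


class TestEcmPatterns:
    def test_square_count_matches_loop_oracle(self):
        pattern = scenarios.EcmPattern("square", 10.0, spacing=1.0,
                                       centered=True)
        ecm = scenarios.build_ecm(pattern)
        count = 0
        # independent brute-force enumeration of centered lattice sites
        for i in range(-20, 20):
            for j in range(-20, 20):
                x, y = (i + 0.5) * 1.0, (j + 0.5) * 1.0
                if abs(x) <= 5.0 and abs(y) <= 5.0:
                    count += 1
        assert ecm.n == count == 100

    def test_circle_count_matches_loop_oracle(self):
        r, s = 7.3, 1.7
        ecm = scenarios.build_ecm(scenarios.EcmPattern("circle", r,
                                                       spacing=s))
        count = sum(1 for i in range(-10, 11) for j in range(-10, 11)
                    if (i * s) ** 2 + (j * s) ** 2 <= r**2)
        assert ecm.n == count

    def test_zero_margin_means_no_glass(self):
        ecm = scenarios.build_ecm(scenarios.EcmPattern("circle", 5.0,
                                                       spacing=1.0))
        assert ecm.count(ParticleKind.GLASS) == 0
        assert ecm.count(ParticleKind.ECM) > 0

    def test_glass_ring_outside_shape(self):
        ecm = scenarios.build_ecm(scenarios.EcmPattern(
            "circle", 5.0, spacing=1.0, margin=3.0))
        glass = ecm.positions[ecm.kinds == GLA]
        inside = ecm.positions[ecm.kinds == ECM]
        assert np.all(np.linalg.norm(glass[:, :2], axis=1) > 5.0)
        assert np.all(np.linalg.norm(inside[:, :2], axis=1) <= 5.0)
        assert not ecm.mobile.any()

    def test_triangle_contains_barycentric_oracle(self):
        side = 9.0
        pattern = scenarios.EcmPattern("triangle", side, spacing=1.0)
        rc = side / np.sqrt(3.0)
        verts = np.array([[rc * np.cos(np.deg2rad(a)),
                           rc * np.sin(np.deg2rad(a))]
                          for a in (90, 210, 330)])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-rc, rc, (500, 2))

        def bary_inside(p):
            a, b, c = verts
            v0, v1, v2 = b - a, c - a, p - a
            den = v0[0] * v1[1] - v1[0] * v0[1]
            u = (v2[0] * v1[1] - v1[0] * v2[1]) / den
            v = (v0[0] * v2[1] - v2[0] * v0[1]) / den
            return u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12

        got = pattern.contains(pts[:, 0], pts[:, 1])
        want = np.array([bary_inside(p) for p in pts])
        np.testing.assert_array_equal(got, want)

    def test_degenerate_pattern_rejected(self):
        with pytest.raises(InvalidParameterError):
            scenarios.build_ecm(scenarios.EcmPattern("circle", 0.0,
                                                     spacing=1.0))
        with pytest.raises(InvalidParameterError):
            scenarios.build_ecm(scenarios.EcmPattern("square", 10.0,
                                                     spacing=-1.0))


class TestEquilibration:
    def test_pre_separated_input_stops_immediately(self, test_config,
                                                   test_params, test_table):
        rng = np.random.default_rng(0)
        nuc = rng.uniform(-1.5, 1.5, (20, 3))
        cyt = rng.uniform(-3, 3, (180, 3)) + np.array([12.0, 0, 0])
        cell = sc.ParticleSystem(
            np.vstack([nuc, cyt]),
            np.array([NUC] * 20 + [CYT] * 180),
            np.ones(200, bool), np.zeros(200, np.int64))
        drag = sc.drag_array(cell, test_params,
                             sc.nuclear_drag(test_config, test_params))
        out, trace, reached = scenarios.equilibrate_nucleus(
            cell, test_table, test_params, drag, seed=0)
        assert reached and trace == [0.0]
        np.testing.assert_array_equal(out.positions, cell.positions)

    def test_purity_trace_decreases_across_seeds(self, test_config,
                                                 test_params, test_table):
        """The anneal monotonically improves the demixing in the large
        majority of runs (allowing small stochastic upticks)."""
        improved = 0
        runs = 3
        for seed in range(runs):
            cell = sc.init_cell(200, 0.1, radius=10, height=10,
                                min_spacing=0.5 * test_params.deq,
                                seed=seed)
            drag = sc.drag_array(cell, test_params,
                                 sc.nuclear_drag(test_config, test_params))
            _, trace, _ = scenarios.equilibrate_nucleus(
                cell, test_table, test_params, drag, seed=seed)
            steps_ok = sum(1 for a, b in zip(trace, trace[1:])
                           if b <= a + 1.0)
            if steps_ok >= 0.8 * (len(trace) - 1):
                improved += 1
            assert trace[-1] < trace[0]
        assert improved >= 0.8 * runs

    def test_separated_cell_properties(self, separated_cell, test_params):
        assert sc.nuclear_purity(separated_cell) <= 8.0
        nuc = separated_cell.positions[
            separated_cell.kind_mask(ParticleKind.NUCLEUS)]
        rg = np.sqrt(((nuc - nuc.mean(0)) ** 2).sum(1).mean())
        # the nucleus is a compact cluster, much smaller than the cell
        assert rg < 0.5 * test_params.Rcell


class TestSpreadCellAndSpreading:
    def test_spread_cell_geometry(self, spread_cell, test_params,
                                  test_config):
        sigma = test_config["ecm"]["sigma"]
        z = spread_cell.positions[:, 2]
        assert z.min() == pytest.approx(2 ** (1 / 6) * sigma, abs=1.0)
        assert spread_cell.count(ParticleKind.NUCLEUS) == 20
        nuc_z = spread_cell.positions[
            spread_cell.kind_mask(ParticleKind.NUCLEUS), 2]
        assert nuc_z.mean() > z.mean()    # nucleus parked near the top
        d2 = np.sum((spread_cell.positions[:, None]
                     - spread_cell.positions[None]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 0.5 * test_params.deq

    def test_detachment_flag(self, test_config, test_params, test_table):
        """A cell far above the substrate with no adhesion range is
        reported as detached."""
        cell = sc.init_cell(40, 0.1, radius=6, height=6,
                            center=(0, 0, 40.0),
                            min_spacing=0.6 * test_params.deq, seed=1)
        ecm = scenarios.build_ecm(scenarios.EcmPattern(
            "square", 20.0, spacing=5.0))
        drag = sc.drag_array(cell, test_params,
                             sc.nuclear_drag(test_config, test_params))
        with pytest.warns(UserWarning, match="detached"):
            res = scenarios.run_spreading(
                cell, ecm, test_table, test_params, drag, n_steps=200,
                output_every=100, seed=1)
        assert res.detached

    def test_metrics_schema(self, test_config, test_params, test_table):
        cell = sc.init_cell(60, 0.1, radius=5, height=5, center=(0, 0, 9),
                            min_spacing=0.6 * test_params.deq, seed=2)
        ecm = scenarios.build_ecm(scenarios.EcmPattern(
            "square", 30.0, spacing=2.5))
        drag = sc.drag_array(cell, test_params,
                             sc.nuclear_drag(test_config, test_params))
        res = scenarios.run_spreading(cell, ecm, test_table, test_params,
                                      drag, n_steps=300, output_every=150,
                                      seed=2)
        assert list(res.metrics.columns) == [
            "time", "csi", "nsi", "area", "basal_area", "ellipticity",
            "purity"]
        assert len(res.metrics) == 3
        assert res.metrics["time"].is_monotonic_increasing


class TestIndentation:
    def test_invalid_protocols_rejected(self):
        with pytest.raises(InvalidParameterError):
            scenarios.IndentationProtocol(approach_speed=0.0)
        with pytest.raises(InvalidParameterError):
            scenarios.IndentationProtocol(depth=-1.0)

    def test_tip_below_plane_rejected(self, spread_cell, test_config,
                                      test_params, test_table):
        system = spread_cell.copy()
        drag = np.full(system.n, test_params.eta_p)
        deep = scenarios.IndentationProtocol(depth=100.0)
        with pytest.raises(scenarios.ProtocolError):
            scenarios.run_indentation(system, test_table, test_params,
                                      drag, deep, kT_eff=0.0)

    def test_force_zero_without_contact(self, spread_cell, test_config,
                                        test_params, test_table):
        """Zero indentation depth never brings the tip into contact, so
        the recorded force is identically zero in every phase."""
        system = spread_cell.copy()
        drag = np.full(system.n, test_params.eta_p)
        protocol = scenarios.IndentationProtocol(depth=0.0,
                                                 hold_duration=0.5,
                                                 sampling_interval=0.2)
        res = scenarios.run_indentation(system, test_table, test_params,
                                        drag, protocol, kT_eff=0.0)
        np.testing.assert_allclose(res.force_curve["force"], 0.0,
                                   atol=1e-12)
        assert set(res.force_curve["phase"]) == {"load", "hold", "unload"}


class TestMigration:
    @pytest.fixture(scope="class")
    def migration_result(self, test_config, test_params, test_table,
                         separated_cell):
        cfg = test_config
        cell = separated_cell.copy()
        sigma = cfg["ecm"]["sigma"]
        cell.positions[:, 0] -= cell.positions[:, 0].mean() + 12.0
        scenarios.place_on_substrate(cell, sigma)
        ecm = scenarios.build_ecm(scenarios.EcmPattern(
            "rectangle", (100.0, 20.0), spacing=sigma / 2,
            margin=2 * sigma))
        protocol = scenarios.MigrationProtocol(
            gap=5.0, obstacle_radius=10.0, obstacle_x=0.0, period=50,
            slab_height=13.0)

        def drag_fn(system):
            return sc.drag_array(system, test_params,
                                 sc.nuclear_drag(cfg, test_params))

        return scenarios.run_constricted_migration(
            cell, ecm, test_table, test_params, drag_fn, protocol,
            n_steps=12000, output_every=400, settle_steps=500, seed=3)

    def test_particle_count_conserved(self, migration_result):
        assert migration_result.metrics["n_particles"].nunique() == 1

    def test_substrate_static(self, migration_result, test_config):
        sigma = test_config["ecm"]["sigma"]
        system = migration_result.system
        sub = system.positions[system.cell_id < 0]
        ref = scenarios.build_ecm(scenarios.EcmPattern(
            "rectangle", (100.0, 20.0), spacing=sigma / 2,
            margin=2 * sigma)).positions
        np.testing.assert_array_equal(np.sort(sub, axis=0),
                                      np.sort(ref, axis=0))

    def test_nucleus_advances_in_trend(self, migration_result):
        x = migration_result.metrics["nucleus_x"].to_numpy()
        smoothed = np.convolve(x, np.ones(3) / 3, mode="valid")
        assert smoothed[-1] > smoothed[0]
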