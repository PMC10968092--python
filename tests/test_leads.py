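import numpy as np
import pytest

import ecgforge as ef
from ecgforge.leads import GridSpec, GridError, LeadPair, _project_to_surface
from ecgforge.sources import build_path
from ecgforge.study import symmetric_torso
from ecgforge.tissues import MYOCARDIUM


class TestGrid:
    def test_grid_symmetric_on_symmetric_phantom(self):
        vol = symmetric_torso(8.0)
        grid = ef.place_grid(vol, GridSpec(center_x_mm=0.0))
        pts = grid.points_mm
        flipped = pts[:, ::-1].copy()
        flipped[..., 0] *= -1
        # projected depths agree within one voxel on mirrored columns
        assert np.abs(pts[..., 1] - flipped[..., 1]).max() <= vol.spacing[1]

    def test_row_pitch_sets_vertical_extent(self, torso8):
        grid = ef.place_grid(torso8, GridSpec(rows=7, row_pitch_mm=30.0))
        z = grid.points_mm[..., 2]
        assert z.max() - z.min() == pytest.approx(180.0)  # (7-1) x 30 mm
        # projection along -y preserves the nominal lattice x and z
        assert np.allclose(z, z[:, :1])

    def test_thirty_five_lead_pairs_materialize(self, torso8):
        grid = ef.place_grid(torso8)
        pairs = ef.lead_pairs(grid)
        assert len(pairs) == 35
        slots = {(p.upper_rc, p.lower_rc) for p in pairs}
        assert ((2, 3), (3, 4)) in slots
        assert all(2 <= r <= 6 and 3 <= c <= 9 for (r, c), _ in slots)
        assert all(low == (up[0] + 1, up[1] + 1) for up, low in slots)

    def test_pair_distance_near_six_cm(self, torso8):
        for p in ef.lead_pairs(ef.place_grid(torso8)):
            assert 45.0 <= p.distance_mm <= 75.0

    def test_projection_missing_body_raises(self, torso8):
        with pytest.raises(GridError):
            ef.place_grid(torso8, GridSpec(cols=30, col_pitch_mm=60.0))

    def test_deterministic(self, torso8):
        g1 = ef.place_grid(torso8)
        g2 = ef.place_grid(torso8)
        assert np.array_equal(g1.points_mm, g2.points_mm)


class TestMisalignment:
    def test_zero_displacement_is_identity(self, torso8, torso8_solution):
        pair = torso8_solution["pairs"][17]
        mis = ef.Misalignment("upper", 3, 0.0)
        assert ef.apply_misalignment(pair, mis, torso8) == pair

    def test_exactly_one_electrode_moves(self, torso8, torso8_solution):
        pair = torso8_solution["pairs"][17]
        for target in ("upper", "lower"):
            moved = ef.apply_misalignment(pair, ef.Misalignment(target, 1, 20.0), torso8)
            if target == "upper":
                assert moved.lower_mm == pair.lower_mm and moved.upper_mm != pair.upper_mm
            else:
                assert moved.upper_mm == pair.upper_mm and moved.lower_mm != pair.lower_mm

    def test_opposite_directions_are_symmetric(self, torso8, torso8_solution):
        pair = torso8_solution["pairs"][17]
        ref = np.array(pair.upper_mm)
        for k in (1, 2, 3, 4):
            a = np.array(
                ef.apply_misalignment(pair, ef.Misalignment("upper", k, 20.0), torso8).upper_mm
            )
            b = np.array(
                ef.apply_misalignment(pair, ef.Misalignment("upper", k + 4, 20.0), torso8).upper_mm
            )
            # in the lattice plane (x, z) the displacements cancel exactly
            assert (a + b)[[0, 2]] == pytest.approx(2 * ref[[0, 2]], abs=1e-9)

    def test_sixteen_variants_per_pair(self, torso8, torso8_solution):
        pair = torso8_solution["pairs"][0]
        variants = ef.misalignment_variants(pair, 20.0, torso8)
        assert len(variants) == 16
        keys = {(m.target, m.direction) for m, _ in variants}
        assert len(keys) == 16

    def test_invalid_misalignment_rejected(self):
        with pytest.raises(ValueError):
            ef.Misalignment("middle", 1, 10.0)
        with pytest.raises(ValueError):
            ef.Misalignment("upper", 9, 10.0)


def _manual_pair(vol, dx_mm=30.0, dz_mm=10.0):
    c = vol.heart_centroid_mm()
    upper = _project_to_surface(vol, c[0] - dx_mm, c[2] + dz_mm)
    lower = _project_to_surface(vol, c[0] + dx_mm, c[2] - dz_mm)
    return LeadPair("manual", (0, 0), (1, 1), tuple(upper), tuple(lower))


class TestWaveform:
    def test_single_dipole_constant_waveform(self, heart_block, mg_cfg):
        c = heart_block.heart_centroid_mm()
        spec = {"His_branches": np.array([c, c + [0.0, 0.0, -2.0]])}
        seq = build_path(heart_block, spec, step_mm=2.0)
        assert len(seq) == 1
        sys = ef.assemble(heart_block, ef.default_tissue_table())
        pair = _manual_pair(heart_block, dx_mm=8.0)
        w = ef.build_waveform(sys, seq, pair, mg_cfg)
        assert np.allclose(w.v_volts, w.v_volts[0])
        assert ef.signal_amplitude(w) == 0.0

    def test_swapping_electrodes_negates_waveform(self, torso8_solution):
        fields = torso8_solution["fields"]
        pair = torso8_solution["pairs"][17]
        swapped = LeadPair("swap", pair.lower_rc, pair.upper_rc, pair.lower_mm, pair.upper_mm)
        w = ef.assemble_waveform(fields, pair)
        ws = ef.assemble_waveform(fields, swapped)
        assert np.allclose(ws.v_volts, -w.v_volts)
        assert ws.sa == pytest.approx(w.sa)

    def test_two_dipole_toy_matches_direct_solver_oracle(self, heart_block):
        # hand-checkable toy: two dipoles, direct sparse solve as the oracle
        c = heart_block.heart_centroid_mm()
        spec = {"His_branches": np.array([c + [0, 0, 2.0], c + [0.0, 0.0, -2.0]])}
        seq = build_path(heart_block, spec, step_mm=2.0)
        assert len(seq) == 2
        sys = ef.assemble(heart_block, ef.default_tissue_table())
        pair = _manual_pair(heart_block, dx_mm=8.0)
        cfg = ef.SolverConfig(method="direct")
        fields = ef.solve_sequence(sys, seq, cfg)
        b = fields.electrode_potentials(pair.upper_mm) - fields.electrode_potentials(
            pair.lower_mm
        )
        # oracle: independent direct solves + explicit correction + difference
        corr = seq.correction_factors()
        for i in range(2):
            f = ef.solve(sys, (int(seq.node_neg[i]), int(seq.node_pos[i]), seq.current_A), cfg)
            vu = ef.surface_potential(sys, f, pair.upper_mm)
            vl = ef.surface_potential(sys, f, pair.lower_mm)
            assert b[i] == pytest.approx((vu - vl) * corr[i], rel=1e-9)
        # and the assembled waveform peaks at exactly these bipolar samples
        w = ef.build_waveform(sys, seq, pair, cfg, fields=fields)
        assert w.v_volts.min() == pytest.approx(min(b.min(), 0.0), rel=1e-9)
        assert w.v_volts.max() == pytest.approx(max(b.max(), 0.0), rel=1e-9)

    def test_linearity_in_source_magnitude(self, torso8, mg_cfg, torso8_solution):
        spec = ef.default_path_spec(torso8.heart_centroid_mm())
        seq2 = build_path(torso8, spec, moment_A_m=2 * ef.sources.DEFAULT_MOMENT_A_M)
        sys = torso8_solution["sys"]
        pair = torso8_solution["pairs"][17]
        w1 = ef.assemble_waveform(torso8_solution["fields"], pair)
        fields2 = ef.solve_sequence(sys, seq2, mg_cfg)
        w2 = ef.assemble_waveform(fields2, pair)
        assert np.allclose(w2.v_volts, 2 * w1.v_volts, rtol=1e-4)
        assert w2.sa == pytest.approx(2 * w1.sa, rel=1e-4)
        # shape metrics are scale-free
        assert np.allclose(w2.normalized(), w1.normalized(), atol=1e-4)
        assert ef.normalized_dtw(w1, w2) == pytest.approx(0.0, abs=1e-2)

    def test_qrs_width_is_activation_span(self, torso8_solution):
        seq = torso8_solution["seq"]
        pair = torso8_solution["pairs"][0]
        w = ef.assemble_waveform(torso8_solution["fields"], pair)
        assert w.qrs_width_s == pytest.approx(seq.t.max(), abs=1e-3)

    def test_amplitude_largest_at_smallest_heart_distance(
        self, torso8, mg_cfg, homogeneous_tissues
    ):
        # far-field monotonicity: on a homogeneous torso the SA-maximal pair
        # is the pair with the smallest mean heart-electrode distance
        seq = build_path(torso8, ef.default_path_spec(torso8.heart_centroid_mm()))
        sys = ef.assemble(torso8, homogeneous_tissues)
        fields = ef.solve_sequence(sys, seq, mg_cfg)
        pairs = ef.lead_pairs(ef.place_grid(torso8))
        sa = {p.pair_id: ef.assemble_waveform(fields, p).sa for p in pairs}
        d = {p.pair_id: ef.pair_geometry(torso8, seq, p).d_mm for p in pairs}
        assert max(sa, key=sa.get) == min(d, key=d.get)
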