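import numpy as np
import pytest

import ecgforge as ef
from ecgforge.spfd import AssemblyError, PlacementError, SolverError
from ecgforge.study import symmetric_torso
from ecgforge.tissues import AIR, MUSCLE, TissueTable

from _oracles import dipole_potential_infinite_medium


def _unit_sigma_table():
    return TissueTable(sigma={AIR: 0.0, MUSCLE: 1.0})


def _center_z_dipole(sys, spacing_mm, current=1e-4):
    a = sys.nearest_node([0, 0, -spacing_mm])
    b = sys.nearest_node([0, 0, +spacing_mm])
    return (a, b, current)


class TestAssemble:
    def test_uniform_block_interior_edge_conductance(self):
        h = 2.0
        vol = ef.homogeneous_block(16, h)
        sys = ef.assemble(vol, _unit_sigma_table())
        for axis in range(3):
            S = sys.edge_conductance[axis]
            interior = S[5:-5, 5:-5, 5:-5]
            # sigma * area / length = 1 S/m * h (in meters)
            assert np.allclose(interior, h / 1000.0)

    def test_edge_shared_by_half_air_voxels(self):
        # two conductive voxels and two air voxels around one x-edge
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        labels[:, 0, :] = MUSCLE  # conductive at y=0, air at y=1
        vol = ef.LabeledVolume(labels, spacing=[2.0, 2.0, 2.0], origin=[0, 0, 0])
        sys = ef.assemble(vol, _unit_sigma_table())
        Sx = sys.edge_conductance[0]
        # the edge at (i=0, node j=1, k=1) sees sigma {1, 1, 0, 0}
        assert Sx[0, 1, 1] == pytest.approx(0.5 * 2.0 / 1000.0)

    def test_random_volume_symmetry_and_interior_row_sums(self, rng):
        labels = rng.integers(0, 8, size=(10, 9, 11)).astype(np.uint8)
        labels[0] = labels[-1] = 0
        labels[:, 0] = labels[:, -1] = 0
        labels[:, :, 0] = labels[:, :, -1] = 0
        vol = ef.LabeledVolume(labels, spacing=[3.0, 4.0, 5.0], origin=[0, 0, 0])
        sys = ef.assemble(vol, ef.default_tissue_table())
        A = sys.laplacian
        assert (A - A.T).nnz == 0
        assert np.allclose(np.asarray(A.sum(axis=1)).ravel(), 0.0)
        assert np.all(np.asarray(A.diagonal()) >= 0)

    def test_all_air_volume_rejected(self):
        vol = ef.LabeledVolume(
            np.zeros((8, 8, 8), dtype=np.uint8), spacing=[1, 1, 1], origin=[0, 0, 0]
        )
        with pytest.raises(AssemblyError):
            ef.assemble(vol, ef.default_tissue_table())


class TestSolve:
    def test_polarity_swap_negates_potential(self, block24, mg_cfg):
        _, sys = block24
        a, b, i = _center_z_dipole(sys, 4.0)
        f1 = ef.solve(sys, (a, b, i), ef.SolverConfig(method="direct"))
        f2 = ef.solve(sys, (b, a, i), ef.SolverConfig(method="direct"))
        assert np.allclose(f1.phi, -f2.phi, atol=1e-12)

    def test_multigrid_matches_direct(self, block24):
        _, sys = block24
        src = _center_z_dipole(sys, 4.0)
        fd = ef.solve(sys, src, ef.SolverConfig(method="direct"))
        fm = ef.solve(
            sys, src, ef.SolverConfig(method="multigrid_preconditioned", tolerance=1e-10)
        )
        assert np.abs(fm.phi - fd.phi).max() <= 1e-6 * np.abs(fd.phi).max()

    def test_sor_matches_direct(self, block24):
        _, sys = block24
        src = _center_z_dipole(sys, 4.0)
        fd = ef.solve(sys, src, ef.SolverConfig(method="direct"))
        fs = ef.solve(
            sys, src, ef.SolverConfig(method="sor", tolerance=1e-8, max_iterations=3000)
        )
        assert np.abs(fs.phi - fd.phi).max() <= 1e-5 * np.abs(fd.phi).max()

    def test_nonconvergence_reports_history(self, block24):
        _, sys = block24
        src = _center_z_dipole(sys, 4.0)
        with pytest.raises(SolverError) as exc:
            ef.solve(sys, src, ef.SolverConfig(method="sor", tolerance=1e-9, max_iterations=3))
        assert len(exc.value.residual_history) == 3

    def test_potential_matches_analytic_dipole_small_grid(self):
        # compact version of the analytic oracle: 48^3 conductor, radii 4-7
        # (mid-range: inside this band both the near-source discretization
        # and the insulating-boundary images stay below the tolerance)
        h, sigma, current = 2.0, 0.2, 1e-4
        vol = ef.homogeneous_block(52, h, shell=2)
        sys = ef.assemble(vol, ef.default_tissue_table())
        src = _center_z_dipole(sys, h)
        f = ef.solve(sys, src, ef.SolverConfig(method="multigrid_preconditioned", tolerance=1e-8))
        p = current * 2 * h / 1000.0
        coords = sys.node_world_mm(np.arange(sys.n_nodes))
        r = np.linalg.norm(coords, axis=1)
        cos = np.divide(coords[:, 2], r, out=np.zeros(len(r)), where=r > 0)
        for rv in (4, 5, 6, 7):
            band = (np.abs(r - rv * h) < 0.4 * h) & (np.abs(cos) > 0.3)
            ana = dipole_potential_infinite_medium(coords[band], p, sigma)
            rel = np.abs(f.phi[band] - ana) / np.abs(ana)
            assert np.median(rel) < 0.05

    def test_reciprocity_in_homogeneous_block(self, block24):
        # potential at B from a dipole at A equals potential at A from the
        # same dipole at B (symmetric operator)
        _, sys = block24
        h = 4.0
        a1, a2 = sys.nearest_node([-12, 0, -h]), sys.nearest_node([-12, 0, h])
        b1, b2 = sys.nearest_node([16, 8, -h]), sys.nearest_node([16, 8, h])
        fA = ef.solve(sys, (a1, a2, 1e-4), ef.SolverConfig(method="direct"))
        fB = ef.solve(sys, (b1, b2, 1e-4), ef.SolverConfig(method="direct"))
        vAB = fA.phi[b2] - fA.phi[b1]
        vBA = fB.phi[a2] - fB.phi[a1]
        assert vAB == pytest.approx(vBA, rel=1e-8)

    def test_discrete_current_conservation(self, block24, mg_cfg):
        # net current out of any source-free region is residual-small
        _, sys = block24
        src = _center_z_dipole(sys, 4.0)
        f = ef.solve(sys, src, mg_cfg)
        div = sys.laplacian @ f.phi  # nodal net outflow
        nodes = sys.node_world_mm(np.arange(sys.n_nodes))
        region = np.linalg.norm(nodes, axis=1) > 16.0  # excludes the dipole
        assert abs(div[region].sum()) < mg_cfg.tolerance * src[2]

    def test_coincident_endpoints_rejected(self, block24):
        _, sys = block24
        n = sys.nearest_node([0, 0, 0])
        with pytest.raises(ValueError):
            ef.solve(sys, (n, n, 1e-4), ef.SolverConfig(method="direct"))


class TestSurfacePotential:
    def test_surface_node_identity(self, block24, mg_cfg):
        vol, sys = block24
        f = ef.solve(sys, _center_z_dipole(sys, 4.0), mg_cfg)
        node = sys.surface_node_idx[0]
        point = sys.node_world_mm(node)[0]
        assert ef.surface_potential(sys, f, point) == f.phi[node]

    def test_gauge_shift_leaves_bipolar_difference(self, block24, mg_cfg):
        vol, sys = block24
        f = ef.solve(sys, _center_z_dipole(sys, 4.0), mg_cfg)
        e1, e2 = [0, 0, 44.0], [0, 44.0, 0]
        v0 = ef.surface_potential(sys, f, e1) - ef.surface_potential(sys, f, e2)
        shifted = ef.PotentialField(f.phi + 0.37, f.residual, f.iterations, f.method)
        v1 = ef.surface_potential(sys, shifted, e1) - ef.surface_potential(sys, shifted, e2)
        assert v1 == pytest.approx(v0, abs=1e-15)

    def test_mirrored_electrodes_on_symmetric_phantom(self):
        vol = symmetric_torso(8.0)
        sys = ef.assemble(vol, ef.default_tissue_table())
        c = vol.heart_centroid_mm()
        a = sys.nearest_node(c + [0, 0, -8])
        b = sys.nearest_node(c + [0, 0, 8])
        cfg = ef.SolverConfig(method="multigrid_preconditioned", tolerance=1e-8)
        f = ef.solve(sys, (a, b, 1e-4), cfg)
        # midline z-dipole: the potential field is mirror-symmetric in x, so
        # every surface node and its x-mirror carry equal values
        nx = sys.nodes_shape[0]
        ijk = np.stack(np.unravel_index(sys.surface_node_idx, sys.nodes_shape), axis=-1)
        anterior = ijk[(ijk[:, 0] > nx // 2) & (ijk[:, 1] > sys.nodes_shape[1] // 2)]
        assert len(anterior) > 100
        mirrored = anterior.copy()
        mirrored[:, 0] = nx - 1 - anterior[:, 0]
        vL = f.phi[np.ravel_multi_index(tuple(anterior.T), sys.nodes_shape)]
        vR = f.phi[np.ravel_multi_index(tuple(mirrored.T), sys.nodes_shape)]
        # agreement limited by the iterative solve, not the geometry
        assert np.abs(vL - vR).max() <= 1e-6 * np.abs(f.phi).max()

    def test_far_electrode_rejected(self, block24, mg_cfg):
        vol, sys = block24
        f = ef.solve(sys, _center_z_dipole(sys, 4.0), mg_cfg)
        with pytest.raises(PlacementError):
            ef.surface_potential(sys, f, [500.0, 500.0, 500.0])
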