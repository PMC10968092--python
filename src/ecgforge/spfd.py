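"""Scalar-potential finite-difference (SPFD) volume-conductor solver.

The quasi-static potential phi in a voxel conductor obeys the Poisson problem

    div(sigma grad phi) = -div J   inside the body,
    (sigma grad phi) . n = 0       on the body surface,

discretized on voxel vertices: the edge between two adjacent nodes carries a
conductance equal to the arithmetic mean of the conductivities of the (up to
four) voxels sharing that edge, times the edge cross-section over its length.
Kirchhoff's current law at every node yields a symmetric singular M-matrix;
the insulating boundary appears naturally because edges surrounded by air
have zero conductance. At ECG frequencies (~1 Hz) displacement current is
negligible, so a current dipole enters as an equal-and-opposite nodal
injection pair and the solve is real-valued.

Three solution methods are provided: a direct sparse factorization, plain
successive over-relaxation (SOR), and conjugate gradients preconditioned by
a geometric multigrid V-cycle (Galerkin-coarsened trilinear hierarchy,
damped-Jacobi smoothing). The potential is only defined up to a constant;
the gauge is fixed to zero mean over body-surface nodes, which leaves all
bipolar (two-electrode) differences unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import LabeledVolume
from .tissues import AIR, TissueTable


class AssemblyError(ValueError):
    """The volume cannot be assembled into a conductor system."""


class PlacementError(ValueError):
    """An electrode lies too far from the body surface."""


class SolverError(RuntimeError):
    """Iterative solve failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


@dataclass
class SolverConfig:
    """Numerical settings for the potential solve.

    ``method`` is one of ``multigrid_preconditioned`` (CG with a geometric
    V-cycle preconditioner — the default), ``sor`` or ``direct``. ``tolerance``
    is the relative residual ||A phi - b|| / ||b|| demanded of iterative
    methods. ``levels`` caps the multigrid hierarchy depth (further capped by
    the grid size). ``sor_omega`` is the SOR relaxation factor.
    """

    method: str = "multigrid_preconditioned"
    tolerance: float = 1e-6
    levels: int = 6
    sor_omega: float = 1.8
    max_iterations: int = 500
    jacobi_omega: float = 0.7
    smooth_steps: int = 2

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.levels < 1:
            raise ValueError("need at least one multigrid level")
        if not 0 < self.sor_omega < 2:
            raise ValueError("SOR relaxation factor must lie in (0, 2)")


@dataclass
class SPFDSystem:
    """Assembled node system for one labeled volume."""

    laplacian: sp.csr_matrix          # pure Neumann operator; air rows exactly zero
    nodes_shape: tuple[int, int, int]
    spacing: np.ndarray               # mm
    origin: np.ndarray                # mm
    edge_conductance: dict            # axis -> S_n array (siemens)
    air_node: np.ndarray              # True where the node touches no conductive voxel
    surface_node_idx: np.ndarray      # flat indices of body-surface nodes
    omega_rad: float = 2.0 * np.pi * 1.0   # nominal angular frequency (rad/s)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.nodes_shape))

    def node_world_mm(self, flat_idx) -> np.ndarray:
        ijk = np.stack(np.unravel_index(np.atleast_1d(flat_idx), self.nodes_shape), axis=-1)
        return self.origin + ijk * self.spacing

    def nearest_node(self, point_mm) -> int:
        ijk = np.rint((np.asarray(point_mm, dtype=float) - self.origin) / self.spacing)
        ijk = np.clip(ijk, 0, np.array(self.nodes_shape) - 1).astype(int)
        return int(np.ravel_multi_index(tuple(ijk), self.nodes_shape))

    def operator(self) -> sp.csr_matrix:
        """Nonsingular solve operator: identity on air nodes plus one grounding shift."""
        if "A_solve" not in self._cache:
            diag = self.laplacian.diagonal()
            body = diag > 0
            if not body.any():
                raise AssemblyError("system has no conductive nodes")
            g = int(np.flatnonzero(body)[0])
            shift = np.where(self.air_node, 1.0, 0.0)
            # Small grounding penalty: fixes the Neumann nullspace without
            # perturbing the physical residual (the gauge is re-fixed after).
            shift[g] += 1e-6 * float(diag[body].mean())
            self._cache["A_solve"] = (self.laplacian + sp.diags(shift)).tocsr()
        return self._cache["A_solve"]


@dataclass
class PotentialField:
    """Node potentials (V) with solver diagnostics; zero-mean gauge on the surface."""

    phi: np.ndarray
    residual: float
    iterations: int
    method: str


def assemble(vol: LabeledVolume, tissues: TissueTable) -> SPFDSystem:
    """Build edge conductances and the nodal Kirchhoff system for a volume.

    The edge conductance uses the arithmetic mean of the four adjoining voxel
    conductivities (voxels outside the grid count as air), scaled by the edge
    cross-section area over the edge length.
    """
    labels = vol.labels
    if not np.any(labels != AIR):
        raise AssemblyError("volume is entirely air")
    sigma = tissues.sigma_array(int(labels.max()) + 1)[labels]
    hx, hy, hz = vol.spacing
    nodes_shape = tuple(np.array(labels.shape) + 1)

    def edge_cond(axis: int) -> np.ndarray:
        # Average sigma over the 4 voxel positions around each edge of this axis;
        # out-of-grid positions contribute air (zero).
        pads = [(1, 1)] * 3
        pads[axis] = (0, 0)
        sp_ = np.pad(sigma, pads)
        sl = [slice(None)] * 3
        acc = None
        other = [a for a in range(3) if a != axis]
        for da in (0, 1):
            for db in (0, 1):
                s = list(sl)
                s[other[0]] = slice(da, sp_.shape[other[0]] - 1 + da)
                s[other[1]] = slice(db, sp_.shape[other[1]] - 1 + db)
                term = sp_[tuple(s)]
                acc = term if acc is None else acc + term
        h = (hx, hy, hz)
        area = h[other[0]] * h[other[1]]
        return (acc / 4.0) * (area / h[axis]) / 1000.0  # mm -> m gives siemens

    S = {axis: edge_cond(axis) for axis in range(3)}

    node_idx = np.arange(np.prod(nodes_shape)).reshape(nodes_shape)
    rows, cols, vals = [], [], []
    for axis in range(3):
        w = S[axis]
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = node_idx[tuple(sl_a)].ravel()
        b = node_idx[tuple(sl_b)].ravel()
        wf = w.ravel()
        keep = wf > 0
        a, b, wf = a[keep], b[keep], wf[keep]
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-wf, -wf, wf, wf]
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(node_idx.size, node_idx.size),
    ).tocsr()
    A.sum_duplicates()

    air_node = A.diagonal() == 0

    # Surface nodes: touch at least one body voxel and at least one air voxel
    # among the <=8 voxels around the node (outside-grid counts as air).
    body_pad = np.pad(labels != AIR, 1)
    any_body = np.zeros(nodes_shape, dtype=bool)
    any_air = np.zeros(nodes_shape, dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                blk = body_pad[
                    dx : dx + nodes_shape[0],
                    dy : dy + nodes_shape[1],
                    dz : dz + nodes_shape[2],
                ]
                any_body |= blk
                any_air |= ~blk
    surface = (any_body & any_air).ravel()

    return SPFDSystem(
        laplacian=A,
        nodes_shape=nodes_shape,
        spacing=vol.spacing.copy(),
        origin=vol.origin.copy(),
        edge_conductance=S,
        air_node=air_node,
        surface_node_idx=np.flatnonzero(surface),
    )


# ---------------------------------------------------------------------------
# geometric multigrid


def _interp_1d(n_fine: int) -> sp.csr_matrix:
    """1-D trilinear prolongation from coarse nodes (even fine indices)."""
    n_coarse = (n_fine + 1) // 2
    rows, cols, vals = [], [], []
    for f in range(n_fine):
        c, r = divmod(f, 2)
        if r == 0:
            rows.append(f); cols.append(c); vals.append(1.0)
        else:
            rows.append(f); cols.append(c); vals.append(0.5)
            if c + 1 < n_coarse:
                rows.append(f); cols.append(c + 1); vals.append(0.5)
            else:
                vals[-1] = 1.0
    return sp.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))


class _Multigrid:
    """Galerkin-coarsened V-cycle usable as a symmetric preconditioner."""

    def __init__(self, A: sp.csr_matrix, nodes_shape, cfg: SolverConfig):
        self.cfg = cfg
        self.As = [A]
        self.Ps = []
        self.shapes = [tuple(nodes_shape)]
        shape = tuple(nodes_shape)
        max_levels = min(cfg.levels, int(np.log2(max(min(shape) - 1, 2))))
        while (
            len(self.As) < max_levels
            and min(shape) >= 5
            and self.As[-1].shape[0] > 500
        ):
            P = reduce(sp.kron, [_interp_1d(n) for n in shape]).tocsr()
            Ac = (P.T @ self.As[-1] @ P).tocsr()
            shape = tuple((n + 1) // 2 for n in shape)
            self.Ps.append(P)
            self.As.append(Ac)
            self.shapes.append(shape)
        self.coarse_lu = spla.splu(self.As[-1].tocsc())
        self.diags = [np.asarray(Al.diagonal()) for Al in self.As]

    def _smooth(self, level: int, x: np.ndarray, b: np.ndarray) -> np.ndarray:
        A, d = self.As[level], self.diags[level]
        for _ in range(self.cfg.smooth_steps):
            x = x + self.cfg.jacobi_omega * (b - A @ x) / d
        return x

    def vcycle(self, b: np.ndarray, level: int = 0) -> np.ndarray:
        if level == len(self.As) - 1:
            return self.coarse_lu.solve(b)
        x = self._smooth(level, np.zeros_like(b), b)
        r = b - self.As[level] @ x
        x = x + self.Ps[level] @ self.vcycle(self.Ps[level].T @ r, level + 1)
        return self._smooth(level, x, b)


# ---------------------------------------------------------------------------
# solve


def _source_vector(sys: SPFDSystem, node_neg: int, node_pos: int, current_A: float) -> np.ndarray:
    diag = sys.laplacian.diagonal()
    if node_neg == node_pos:
        raise ValueError("dipole endpoints snapped to the same node")
    for node in (node_neg, node_pos):
        if not 0 <= node < sys.n_nodes or diag[node] <= 0:
            raise ValueError(f"source node {node} is not a body node")
    b = np.zeros(sys.n_nodes)
    b[node_pos] += current_A
    b[node_neg] -= current_A
    return b


def solve(
    sys: SPFDSystem,
    source,
    cfg: SolverConfig | None = None,
) -> PotentialField:
    """Solve for the potential of one current-dipole source.

    ``source`` is ``(node_neg, node_pos, current_A)`` with flat node indices
    (see :meth:`SPFDSystem.nearest_node`), or an object with attributes
    ``node_neg``, ``node_pos`` and ``current_A`` (a dipole-sequence element).
    """
    cfg = cfg or SolverConfig()
    if hasattr(source, "node_neg"):
        node_neg, node_pos, current = source.node_neg, source.node_pos, source.current_A
    else:
        node_neg, node_pos, current = source
    b = _source_vector(sys, int(node_neg), int(node_pos), float(current))
    A_solve = sys.operator()

    history: list[float] = []
    b_norm = float(np.linalg.norm(b))

    if cfg.method == "direct":
        if "lu" not in sys._cache:
            sys._cache["lu"] = spla.splu(A_solve.tocsc())
        phi = sys._cache["lu"].solve(b)
        iterations = 1
    elif cfg.method == "multigrid_preconditioned":
        if "mg" not in sys._cache:
            sys._cache["mg"] = _Multigrid(A_solve, sys.nodes_shape, cfg)
        mg = sys._cache["mg"]
        M = spla.LinearOperator(A_solve.shape, matvec=mg.vcycle)
        count = {"n": 0}

        def cb(xk):
            count["n"] += 1
            history.append(float(np.linalg.norm(b - A_solve @ xk)) / b_norm)

        phi, info = spla.cg(
            A_solve, b, M=M, rtol=cfg.tolerance, atol=0.0,
            maxiter=cfg.max_iterations, callback=cb,
        )
        iterations = count["n"]
        if info != 0:
            raise SolverError(
                f"CG failed to reach tolerance {cfg.tolerance} in "
                f"{cfg.max_iterations} iterations", history,
            )
    elif cfg.method == "sor":
        if "sor_M" not in sys._cache:
            d = A_solve.diagonal()
            M_sor = sp.tril(A_solve, k=-1) + sp.diags(d / cfg.sor_omega)
            sys._cache["sor_M"] = spla.splu(M_sor.tocsc())
        M_lu = sys._cache["sor_M"]
        phi = np.zeros_like(b)
        iterations = 0
        for iterations in range(1, cfg.max_iterations + 1):
            r = b - A_solve @ phi
            rel = float(np.linalg.norm(r)) / b_norm
            history.append(rel)
            if rel < cfg.tolerance:
                break
            phi = phi + M_lu.solve(r)
        else:
            raise SolverError(
                f"SOR failed to reach tolerance {cfg.tolerance} in "
                f"{cfg.max_iterations} iterations", history,
            )
    else:
        raise ValueError(f"unknown solver method {cfg.method!r}")

    # Physical residual of the pure Neumann operator (gauge-invariant).
    residual = float(np.linalg.norm(sys.laplacian @ phi - b)) / b_norm
    if not np.all(np.isfinite(phi)):
        raise SolverError("non-finite potential", history)
    # Zero-mean gauge over surface nodes, applied to body nodes only; air
    # nodes carry no physics and are pinned to exactly zero.
    phi = phi.copy()
    phi[~sys.air_node] -= phi[sys.surface_node_idx].mean()
    phi[sys.air_node] = 0.0
    return PotentialField(phi=phi, residual=residual, iterations=iterations, method=cfg.method)


def surface_potential(sys: SPFDSystem, field: PotentialField, electrode_mm) -> float:
    """Potential at the body-surface node nearest to an electrode point (V).

    The electrode must lie within two voxels of the surface; nearest-node ties
    are broken by the lowest (z, y, x) node index.
    """
    coords = sys._cache.get("surface_coords")
    if coords is None:
        coords = sys.node_world_mm(sys.surface_node_idx)
        sys._cache["surface_coords"] = coords
    d2 = np.sum((coords - np.asarray(electrode_mm, dtype=float)) ** 2, axis=1)
    dmin = float(d2.min())
    if np.sqrt(dmin) > 2.0 * float(sys.spacing.max()):
        raise PlacementError(
            f"electrode {electrode_mm} is {np.sqrt(dmin):.1f} mm from the surface"
        )
    ties = np.flatnonzero(d2 <= dmin + 1e-9)
    tie_nodes = sys.surface_node_idx[ties]
    ijk = np.stack(np.unravel_index(tie_nodes, sys.nodes_shape), axis=-1)
    order = np.lexsort((ijk[:, 0], ijk[:, 1], ijk[:, 2]))  # lowest (z, y, x)
    return float(field.phi[tie_nodes[order[0]]])
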