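"""Cardiac conduction-system dipole sequence.

Ventricular depolarization (the QRS complex) is modelled by marching a single
current dipole along the conduction system: A–V node to the bundle of His,
His to the bundle branches, the branches themselves, then left and right
Purkinje trees activated in parallel. Each step of nominal length 2 mm
becomes one dipole; activation times accumulate step length over the
segment's conduction velocity (His and branches 1.25 m/s, Purkinje fibers
3.25 m/s). On a voxel grid the dipole endpoints snap to voxel vertices, so
individual dipole lengths l_dn vary; potentials computed from a fixed
injection current are rescaled by l_mean / l_dn (the mean over the segment)
to restore a uniform effective dipole moment.

Only the QRS is modelled: no atrial (P) or repolarization (T) activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import LabeledVolume
from .tissues import HEART_LABELS


class PathError(ValueError):
    """A conduction-path control point lies outside the heart."""


class ConfigurationError(ValueError):
    """Invalid source configuration (e.g. zero conduction velocity)."""


SEGMENT_ORDER = ("AV_His", "His_branches", "branches", "purkinje_L", "purkinje_R")
#: Segments activated in parallel after the serial trunk completes.
PARALLEL_SEGMENTS = ("purkinje_L", "purkinje_R")

#: Conduction velocities, m/s. The A-V node to His segment inherits the His
#: bundle velocity; both Purkinje trees share the Purkinje fiber velocity.
DEFAULT_VELOCITIES = {
    "AV_His": 1.25,
    "His_branches": 1.25,
    "branches": 1.25,
    "purkinje_L": 3.25,
    "purkinje_R": 3.25,
}

NOMINAL_DIPOLE_LENGTH_MM = 2.0
#: Default dipole moment, A*m: the effective moment of the ventricular
#: activation wavefront (~20 mA*mm), giving millivolt-scale surface ECG.
#: Absolute amplitudes scale linearly with it; every robustness metric except
#: raw amplitude is invariant to the choice.
DEFAULT_MOMENT_A_M = 2e-5

#: Control points of the default conduction path, mm relative to the heart
#: centroid (x toward subject left, y anterior, z superior). The serial trunk
#: (A-V node -> His -> branches) descends along a frontal-plane cardiac axis
#: tilted ~30 degrees from vertical toward the subject's left, the normal
#: electrical axis; the Purkinje trees fan toward the apex and the right
#: ventricular wall.
DEFAULT_PATH_OFFSETS_MM = {
    "AV_His": [(-18.0, 0.0, 44.0), (-12.0, -2.0, 28.0)],
    "His_branches": [(-12.0, -2.0, 28.0), (-2.0, -6.0, 8.0)],
    "branches": [(-2.0, -6.0, 8.0), (12.0, -10.0, -18.0)],
    "purkinje_L": [(12.0, -10.0, -18.0), (26.0, -8.0, -30.0), (36.0, -5.0, -36.0)],
    "purkinje_R": [(12.0, -10.0, -18.0), (-10.0, -9.0, -28.0), (-26.0, -8.0, -34.0)],
}


def default_path_spec(heart_center_mm) -> dict[str, np.ndarray]:
    c = np.asarray(heart_center_mm, dtype=float)
    return {
        seg: c + np.asarray(pts, dtype=float)
        for seg, pts in DEFAULT_PATH_OFFSETS_MM.items()
    }


def transform_path_spec(
    spec: dict[str, np.ndarray],
    center_mm,
    volumetric_scale: float = 1.0,
    rotate_z_deg: float = 0.0,
) -> dict[str, np.ndarray]:
    """Apply the heart morph affine (scale about / rotate around the centroid)."""
    c = np.asarray(center_mm, dtype=float)
    lin = float(volumetric_scale) ** (1.0 / 3.0)
    th = np.deg2rad(rotate_z_deg)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    out = {}
    for seg, pts in spec.items():
        rel = (np.asarray(pts, dtype=float) - c) * lin
        out[seg] = c + rel @ R.T
    return out


@dataclass
class DipoleSequence:
    """Ordered dipole records along the conduction system.

    ``position`` holds the step endpoints r_i (mm); ``start`` the step start
    points r_{i-1}; ``l_dn`` the realized dipole lengths; ``t`` the activation
    times (s); ``track`` groups dipoles into serially-connected chains (the
    trunk plus left Purkinje is track 0, the right Purkinje track 1).
    """

    position: np.ndarray
    start: np.ndarray
    segment: np.ndarray
    l_dn: np.ndarray
    t: np.ndarray
    dt: np.ndarray
    track: np.ndarray
    velocities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VELOCITIES))
    nominal_length_mm: float = NOMINAL_DIPOLE_LENGTH_MM
    moment_A_m: float = DEFAULT_MOMENT_A_M
    node_neg: np.ndarray | None = None   # flat node index of the step start
    node_pos: np.ndarray | None = None   # flat node index of the step end

    def __len__(self) -> int:
        return len(self.position)

    @property
    def current_A(self) -> float:
        """Injection current giving the nominal moment at the nominal length."""
        return self.moment_A_m / (self.nominal_length_mm / 1000.0)

    def l_mean_by_segment(self) -> dict[str, float]:
        return {
            seg: float(self.l_dn[self.segment == seg].mean())
            for seg in np.unique(self.segment)
        }

    def correction_factors(self) -> np.ndarray:
        """Per-dipole multiplier l_mean / l_dn restoring a uniform moment."""
        l_mean = self.l_mean_by_segment()
        return np.array([l_mean[s] for s in self.segment]) / self.l_dn

    @property
    def duration_s(self) -> float:
        return float(self.t.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": np.arange(len(self)),
                "segment": self.segment,
                "x_mm": self.position[:, 0],
                "y_mm": self.position[:, 1],
                "z_mm": self.position[:, 2],
                "l_dn_mm": self.l_dn,
                "t_s": self.t,
            }
        )


def _discretize_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Points along a polyline at arc-length multiples of ``step_mm`` (origin excluded,
    endpoint included)."""
    pts = np.asarray(points, dtype=float)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        raise PathError("degenerate (zero-length) path segment")
    n_steps = int(np.ceil(total / step_mm - 1e-9))
    s_targets = np.minimum(np.arange(1, n_steps + 1) * step_mm, total)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((n_steps, 3))
    for k, s in enumerate(s_targets):
        j = min(int(np.searchsorted(cum, s, side="right")) - 1, len(seg_len) - 1)
        frac = (s - cum[j]) / seg_len[j]
        out[k] = pts[j] + frac * (pts[j + 1] - pts[j])
    return out


def build_path(
    vol: LabeledVolume | None,
    path_spec: dict[str, np.ndarray],
    step_mm: float = NOMINAL_DIPOLE_LENGTH_MM,
    velocities: dict[str, float] | None = None,
    moment_A_m: float = DEFAULT_MOMENT_A_M,
) -> DipoleSequence:
    """Discretize a conduction-path spec into a dipole sequence.

    With a volume the step points snap to voxel vertices (duplicate nodes are
    merged, so realized l_dn can exceed the nominal step on coarse grids);
    without one the exact 2 mm geometry is kept. Control points must lie
    inside the heart when a volume is given. Deterministic.
    """
    vel = dict(DEFAULT_VELOCITIES)
    if velocities:
        vel.update(velocities)
    for seg in SEGMENT_ORDER:
        if seg in path_spec and vel.get(seg, 0.0) <= 0.0:
            raise ConfigurationError(f"non-positive velocity for segment {seg}")

    nodes_shape = None
    if vol is not None:
        nodes_shape = tuple(np.array(vol.shape) + 1)
        heart = vol.heart_mask()
        for seg, pts in path_spec.items():
            idx = vol.world_to_index(pts)
            oob = np.any((idx < 0) | (idx >= np.array(vol.shape)), axis=1)
            if oob.any() or not np.all(heart[idx[:, 0], idx[:, 1], idx[:, 2]]):
                raise PathError(f"control point of segment {seg!r} is outside the heart")

    def snap(p: np.ndarray) -> np.ndarray:
        if vol is None:
            return p
        ijk = np.rint((p - vol.origin) / vol.spacing)
        return vol.origin + ijk * vol.spacing

    def node_index(p: np.ndarray) -> int:
        ijk = np.rint((p - vol.origin) / vol.spacing).astype(int)
        return int(np.ravel_multi_index(tuple(ijk), nodes_shape))

    records: list[tuple] = []  # (segment, start, end, track)
    trunk_end: np.ndarray | None = None
    cursor: np.ndarray | None = None
    for seg in SEGMENT_ORDER:
        if seg not in path_spec:
            continue
        pts = np.asarray(path_spec[seg], dtype=float)
        if seg in PARALLEL_SEGMENTS and trunk_end is not None:
            seg_start = trunk_end
        elif cursor is not None:
            seg_start = cursor
        else:
            seg_start = snap(pts[0])
        raw = _discretize_polyline(pts, step_mm)
        prev = seg_start
        for p in raw:
            q = snap(p)
            if np.allclose(q, prev):
                continue  # merged zero-length step on a coarse grid
            records.append((seg, prev, q, None))
            prev = q
        if seg not in PARALLEL_SEGMENTS:
            cursor = prev
            trunk_end = prev  # parallel branches start where the trunk so far ends
    if not records:
        raise PathError("path discretization produced no dipoles")
    if trunk_end is None:
        trunk_end = records[-1][2]

    segs = np.array([r[0] for r in records])
    starts = np.array([r[1] for r in records])
    ends = np.array([r[2] for r in records])
    track = np.where(segs == "purkinje_R", 1, 0)

    seq = DipoleSequence(
        position=ends,
        start=starts,
        segment=segs,
        l_dn=np.linalg.norm(ends - starts, axis=1),
        t=np.zeros(len(records)),
        dt=np.zeros(len(records)),
        track=track,
        velocities=vel,
        nominal_length_mm=step_mm,
        moment_A_m=moment_A_m,
    )
    if vol is not None:
        seq.node_neg = np.array([node_index(s) for s in starts])
        seq.node_pos = np.array([node_index(e) for e in ends])
    return activation_times(seq)


def activation_times(seq: DipoleSequence) -> DipoleSequence:
    """Fill dt_i = |r_i - r_{i-1}| / v_part and cumulative t_i (in place).

    Each track accumulates serially; parallel tracks start when the serial
    trunk (everything before the Purkinje trees) has completed.
    """
    for seg in np.unique(seq.segment):
        if seq.velocities.get(seg, 0.0) <= 0.0:
            raise ConfigurationError(f"non-positive velocity for segment {seg}")
    v = np.array([seq.velocities[s] for s in seq.segment])  # m/s
    seq.dt = (seq.l_dn / 1000.0) / v
    seq.t = np.empty_like(seq.dt)
    trunk = ~np.isin(seq.segment, PARALLEL_SEGMENTS)
    t_cursor = 0.0
    for i in np.flatnonzero(trunk):
        t_cursor += seq.dt[i]
        seq.t[i] = t_cursor
    trunk_end_t = t_cursor
    for track_id in np.unique(seq.track[~trunk] if (~trunk).any() else []):
        for seg in PARALLEL_SEGMENTS:
            sel = np.flatnonzero((seq.segment == seg) & (seq.track == track_id))
            t_cursor = trunk_end_t
            for i in sel:
                t_cursor += seq.dt[i]
                seq.t[i] = t_cursor
    return seq


def correct_potential(phi: float, l_mean_mm: float, l_dn_mm: float) -> float:
    """Dipole-length correction: rescale a potential by l_mean / l_dn."""
    if l_dn_mm <= 0:
        raise ValueError("realized dipole length must be positive")
    return phi * (l_mean_mm / l_dn_mm)
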