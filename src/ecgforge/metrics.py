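"""Waveform and geometry metrics: signal amplitude, DTW, heart-electrode geometry.

DTW here is the classical unconstrained dynamic-programming alignment with
absolute-difference ground cost, steps {(1,0), (0,1), (1,1)} and full
boundary matching; the dissimilarity is the unweighted sum of per-step
costs. Applied to raw waveforms it measures amplitude-plus-shape variation;
applied after min-max normalization of each signal ("normalized DTW") it is
a shape-only dissimilarity, invariant to positive affine rescaling.

The geometric predictors are d, the mean distance from an electrode to the
conduction-path dipole positions, and theta, the angle subtended at the
electrode by the uppermost and lowermost myocardial points (a planar
stand-in for the solid angle under which the heart is seen). For a bipolar
pair both are averaged over the two electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leads import LeadPair, LeadWaveform
from .phantom import LabeledVolume
from .sources import DipoleSequence


class NormalizationError(ValueError):
    """A constant waveform (SA = 0) cannot be min-max normalized."""


@dataclass
class DTWResult:
    """Optimal alignment: cumulative cost, warping path, per-step costs.

    ``path`` is 0-based; it starts at (0, 0) and ends at (n-1, m-1) with
    non-decreasing unit steps.
    """

    value: float
    path: list[tuple[int, int]]
    step_costs: np.ndarray


@dataclass(frozen=True)
class GeometryMetrics:
    d_mm: float
    theta_deg: float


def signal_amplitude(w) -> float:
    """SA = |V_max - V_min| of a waveform (V). Accepts a LeadWaveform or array."""
    v = w.v_volts if isinstance(w, LeadWaveform) else np.asarray(w, dtype=float)
    if v.size == 0:
        raise ValueError("empty waveform")
    return float(np.abs(v.max() - v.min()))


def normalize(w) -> np.ndarray:
    """Min-max normalization V' = (V - V_min)/|V_max - V_min| onto [0, 1]."""
    v = w.v_volts if isinstance(w, LeadWaveform) else np.asarray(w, dtype=float)
    sa = signal_amplitude(v)
    if sa == 0:
        raise NormalizationError("SA = 0: constant signal cannot be normalized")
    return (v - v.min()) / sa


def dtw(S, T) -> DTWResult:
    """Dynamic-time-warping dissimilarity between two series (lengths may differ).

    Ties in the backtracking are broken by preferring the diagonal step, then
    the vertical one.
    """
    s = np.asarray(S, dtype=float).ravel()
    t = np.asarray(T, dtype=float).ravel()
    if s.size == 0 or t.size == 0:
        raise ValueError("both series must be non-empty")
    if np.isnan(s).any() or np.isnan(t).any():
        raise ValueError("NaN in DTW input")
    n, m = s.size, t.size
    cost = np.abs(s[:, None] - t[None, :])
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    D[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    D[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    for i in range(1, n):
        Dm1 = D[i - 1]
        row = D[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(Dm1[j - 1], Dm1[j], row[j - 1])
    # Backtrack; preference order diagonal > vertical > horizontal on ties.
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            i, j = 0, j - 1
        elif j == 0:
            i, j = i - 1, 0
        else:
            candidates = ((D[i - 1, j - 1], (i - 1, j - 1)),
                          (D[i - 1, j], (i - 1, j)),
                          (D[i, j - 1], (i, j - 1)))
            best = min(c[0] for c in candidates)
            for val, nxt in candidates:
                if val == best:
                    i, j = nxt
                    break
        path.append((i, j))
    path.reverse()
    steps = np.array([cost[a, b] for a, b in path])
    return DTWResult(value=float(D[n - 1, m - 1]), path=path, step_costs=steps)


def normalized_dtw(w1, w2) -> float:
    """DTW between the min-max normalized versions of two waveforms."""
    return dtw(normalize(w1), normalize(w2)).value


def geometry(vol: LabeledVolume, seq: DipoleSequence, electrode_mm) -> GeometryMetrics:
    """Heart-electrode distance d and subtended angle theta for one electrode.

    d is the mean Euclidean distance from the electrode to the conduction-path
    dipole positions. theta is the angle between the rays to the uppermost and
    lowermost myocardial points AS SEEN from the electrode — the span of the
    elevation angles of all myocardial voxel directions. (For a sphere of
    radius R viewed from distance D this is the visual extent 2 asin(R/D);
    rays to the literal max-z / min-z voxels would under-read it, because the
    silhouette extremes are tangent points, not the poles.)
    """
    from .tissues import MYOCARDIUM

    if len(seq) == 0:
        raise ValueError("empty dipole sequence")
    e = np.asarray(electrode_mm, dtype=float)
    d = float(np.linalg.norm(seq.position - e, axis=1).mean())
    idx = np.argwhere(vol.labels == MYOCARDIUM)
    if idx.size == 0:
        raise ValueError("phantom has no myocardium")
    u = vol.voxel_centers_mm(idx) - e
    elev = np.arcsin(np.clip(u[:, 2] / np.linalg.norm(u, axis=1), -1.0, 1.0))
    theta = float(np.degrees(elev.max() - elev.min()))
    return GeometryMetrics(d_mm=d, theta_deg=theta)


def pair_geometry(vol: LabeledVolume, seq: DipoleSequence, pair: LeadPair) -> GeometryMetrics:
    """Per-pair geometry: mean of the two electrodes' d and theta."""
    gu = geometry(vol, seq, pair.upper_mm)
    gl = geometry(vol, seq, pair.lower_mm)
    return GeometryMetrics(
        d_mm=0.5 * (gu.d_mm + gl.d_mm), theta_deg=0.5 * (gu.theta_deg + gl.theta_deg)
    )


def solid_angle_steradian(vol: LabeledVolume, electrode_mm) -> float:
    """True solid angle (sr) of the myocardial convex hull seen from a point.

    Optional alternative to the planar two-ray angle: sums the Van Oosterom-
    Strackee solid angles of the hull triangles facing the viewpoint.
    """
    from scipy.spatial import ConvexHull

    from .tissues import MYOCARDIUM

    pts = np.argwhere(vol.labels == MYOCARDIUM)
    pts = vol.voxel_centers_mm(pts)
    hull = ConvexHull(pts)
    e = np.asarray(electrode_mm, dtype=float)
    centroid = pts[hull.vertices].mean(axis=0)
    total = 0.0
    for simplex in hull.simplices:
        tri = pts[simplex]
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        if np.dot(n, tri[0] - centroid) < 0:
            n = -n
        if np.dot(n, e - tri[0]) <= 0:
            continue  # back-facing triangle: hidden side of the hull
        r = tri - e
        r0, r1, r2 = r
        l0, l1, l2 = (np.linalg.norm(v) for v in r)
        num = np.dot(r0, np.cross(r1, r2))
        den = (
            l0 * l1 * l2
            + np.dot(r0, r1) * l2
            + np.dot(r1, r2) * l0
            + np.dot(r0, r2) * l1
        )
        total += abs(2.0 * np.arctan2(num, den))
    return float(total)
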