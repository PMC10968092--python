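"""Synthetic labeled voxel torso phantoms and their morphs.

The phantom is a stacked-superellipse torso with concentric skin/fat/muscle
shells, two lateral lung ellipsoids, an optional ribcage, and a heart
ellipsoid (myocardial shell around a blood pool) in the mediastinum. It is a
topological stand-in for a CT-derived anatomical voxel model: layer order,
heart-between-lungs placement and tissue set are realistic, individual organ
shapes are not.

Morphs emulate inter-individual geometric variability:

* ``morph_physique`` — rescales the torso cross-section and fat layer so the
  computed body-mass index hits a target, organs staying put;
* ``morph_heart`` — uniform volumetric scaling or rotation about the vertical
  axis through the heart centroid, nearest-neighbour resampled, with vacated
  voxels refilled as lung.

Axes convention: x = subject right→left, y = posterior→anterior,
z = inferior→superior. Voxel centers sit at ``origin + (index + 0.5)*spacing``.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .tissues import AIR, BLOOD, BONE, FAT, HEART_LABELS, LUNG, MUSCLE, MYOCARDIUM, SKIN


class GeometryError(ValueError):
    """Phantom geometry parameters are inconsistent (layers too thick, organs don't fit)."""


class MorphError(ValueError):
    """A morph target is unreachable or would break phantom invariants."""


#: Uniform soft-tissue density used for body-mass computation, g/cm^3.
BODY_DENSITY_G_PER_CM3 = 1.05
#: Fraction of whole-body mass contained in the modelled torso section.
TORSO_MASS_FRACTION = 0.5
#: Standing height used for BMI, m (fixed across physique morphs).
BODY_HEIGHT_M = 1.752

#: Physique morph targets (kg/m^2): underweight, normal, pre-obese, obese.
PHYSIQUE_BMI_TARGETS = (17.2, 23.2, 28.5, 34.2)
#: Heart volumetric scale factors (fractions of original volume).
HEART_SCALE_FACTORS = (0.90, 0.95, 0.98, 1.00, 1.02, 1.05, 1.10)
#: Heart rotation angles about the vertical axis, degrees.
HEART_ROTATION_DEG = (-8.0, -5.0, -3.0, 0.0, 3.0, 5.0, 8.0)


@dataclass
class LabeledVolume:
    """Voxel grid of integer tissue labels with physical spacing/origin (mm)."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3 vectors")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            self.labels.copy(), self.spacing.copy(), self.origin.copy(),
            _copy.deepcopy(self.meta),
        )

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centers for an (N, 3) index array."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (mm); not bounds-checked."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(int)

    def body_mask(self) -> np.ndarray:
        return self.labels != AIR

    def heart_mask(self) -> np.ndarray:
        return np.isin(self.labels, HEART_LABELS)

    def heart_centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.heart_mask())
        if idx.size == 0:
            raise ValueError("phantom has no heart voxels")
        return self.voxel_centers_mm(idx).mean(axis=0)


@dataclass(frozen=True)
class MorphSpec:
    """One geometric-variability scenario member.

    ``parameter`` is a target BMI (kg/m^2) for ``physique``, a volumetric scale
    fraction for ``heart_scale`` or a rotation angle in degrees (about the
    vertical axis through the heart centroid) for ``heart_rotate``.
    """

    kind: str
    parameter: float

    def __post_init__(self) -> None:
        if self.kind not in ("physique", "heart_scale", "heart_rotate"):
            raise ValueError(f"unknown morph kind {self.kind!r}")
        if self.kind == "heart_scale" and not 0.90 <= self.parameter <= 1.10:
            raise ValueError("heart_scale must lie in [0.90, 1.10]")
        if self.kind == "heart_rotate" and not -8.0 <= self.parameter <= 8.0:
            raise ValueError("heart_rotate must lie in [-8, +8] degrees")
        if self.kind == "physique" and not 15.0 <= self.parameter <= 40.0:
            raise ValueError("physique BMI target must lie in [15, 40]")


@dataclass(frozen=True)
class TorsoGeometry:
    """Parametric description of the synthetic torso (all lengths mm)."""

    a_mm: float = 210.0           # torso half-width (x)
    b_mm: float = 147.0           # torso half-depth (y)
    height_mm: float = 400.0      # torso section height (z)
    power: float = 2.5            # superellipse exponent of the cross-section
    skin_mm: float = 4.0
    fat_mm: float = 12.0
    muscle_mm: float = 16.0       # explicit muscle shell; interior is muscle too
    lung_offset_x_mm: float = 85.0
    lung_axes_mm: tuple[float, float, float] = (55.0, 65.0, 130.0)
    heart_center_mm: tuple[float, float, float] = (30.0, 35.0, 200.0)
    heart_axes_mm: tuple[float, float, float] = (55.0, 50.0, 60.0)
    myocardium_mm: float = 12.0
    ribcage: bool = False
    rib_thickness_mm: float = 8.0
    rib_period_mm: float = 36.0
    resolution_mm: float = 4.0
    seed: int = 0


def coarse_geometry(resolution_mm: float = 8.0, **overrides) -> TorsoGeometry:
    """Demo-scale geometry: layer thicknesses inflated to stay >= 1 voxel."""
    h = float(resolution_mm)
    base = TorsoGeometry()
    params = dict(
        resolution_mm=h,
        skin_mm=max(base.skin_mm, h),
        fat_mm=max(base.fat_mm, 1.5 * h),
        muscle_mm=max(base.muscle_mm, 1.5 * h),
        myocardium_mm=max(base.myocardium_mm, 1.5 * h),
    )
    params.update(overrides)
    return replace(base, **params)


def _superellipse_inside(x, y, a: float, b: float, p: float):
    return (np.abs(x) / a) ** p + (np.abs(y) / b) ** p <= 1.0


def _ellipsoid_inside(x, y, z, center, axes):
    cx, cy, cz = center
    ax, ay, az = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def build_phantom(params: TorsoGeometry | None = None, **overrides) -> LabeledVolume:
    """Voxelize the synthetic torso. Deterministic given the parameter set.

    Raises :class:`GeometryError` if the shell thicknesses exceed the torso
    radius, the grid would be coarser than 20 voxels per axis, or an organ
    would poke through the fat layer.
    """
    p = params or TorsoGeometry()
    if overrides:
        p = replace(p, **overrides)
    h = float(p.resolution_mm)
    if h <= 0:
        raise GeometryError("resolution must be positive")
    t_shell = p.skin_mm + p.fat_mm + p.muscle_mm
    if t_shell >= min(p.a_mm, p.b_mm):
        raise GeometryError("layer thicknesses exceed torso radius")
    if min(p.skin_mm, p.fat_mm, p.muscle_mm) < h:
        raise GeometryError("every layer must be at least one voxel thick")

    pad = 2.0 * h  # >= 1-voxel air shell on all faces
    # Snap the origin to the voxel lattice so every phantom (all morphs of a
    # study) shares one world-space node grid: conduction-path points then
    # snap to identical nodes across members instead of drifting by a
    # sub-voxel origin offset.
    half_x = np.ceil((p.a_mm + pad) / h) * h
    half_y = np.ceil((p.b_mm + pad) / h) * h
    origin = np.array([-half_x, -half_y, -pad])
    extent = np.array([2 * half_x, 2 * half_y, p.height_mm + 2 * pad])
    dims = np.rint(extent / h).astype(int)
    if np.any(dims < 20):
        raise GeometryError("resolution too coarse: need >= 20 voxels per axis")

    ix = np.arange(dims[0])
    iy = np.arange(dims[1])
    iz = np.arange(dims[2])
    x = origin[0] + (ix + 0.5) * h
    y = origin[1] + (iy + 0.5) * h
    z = origin[2] + (iz + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij", sparse=True)

    in_z = (Z >= 0.0) & (Z <= p.height_mm)
    body = _superellipse_inside(X, Y, p.a_mm, p.b_mm, p.power) & in_z
    after_skin = _superellipse_inside(X, Y, p.a_mm - p.skin_mm, p.b_mm - p.skin_mm, p.power) & in_z
    after_fat = _superellipse_inside(
        X, Y, p.a_mm - p.skin_mm - p.fat_mm, p.b_mm - p.skin_mm - p.fat_mm, p.power
    ) & in_z

    labels = np.zeros(tuple(dims), dtype=np.uint8)
    labels[body] = SKIN
    labels[after_skin] = FAT
    labels[after_fat] = MUSCLE  # muscle shell and generic interior soft tissue

    if p.ribcage:
        rib_outer = after_fat
        rib_inner = _superellipse_inside(
            X, Y,
            p.a_mm - p.skin_mm - p.fat_mm - p.rib_thickness_mm,
            p.b_mm - p.skin_mm - p.fat_mm - p.rib_thickness_mm,
            p.power,
        ) & in_z
        bands = (np.floor(Z / (p.rib_period_mm / 2.0)).astype(int) % 2) == 0
        labels[rib_outer & ~rib_inner & bands & (Z > 40) & (Z < p.height_mm - 40)] = BONE

    zc = p.height_mm / 2.0
    lung_r = _ellipsoid_inside(X, Y, Z, (-p.lung_offset_x_mm, 0.0, zc), p.lung_axes_mm)
    lung_l = _ellipsoid_inside(X, Y, Z, (p.lung_offset_x_mm, 0.0, zc), p.lung_axes_mm)
    lungs = lung_r | lung_l
    if np.any(lungs & ~after_fat):
        raise GeometryError("lungs do not fit inside the muscle interior")
    labels[lungs] = LUNG

    heart = _ellipsoid_inside(X, Y, Z, p.heart_center_mm, p.heart_axes_mm)
    blood_axes = tuple(max(a - p.myocardium_mm, 1.0) for a in p.heart_axes_mm)
    blood = _ellipsoid_inside(X, Y, Z, p.heart_center_mm, blood_axes)
    if np.any(heart & ~after_fat):
        raise GeometryError("heart does not fit inside the muscle interior")
    labels[heart] = MYOCARDIUM
    labels[blood] = BLOOD

    return LabeledVolume(
        labels=labels,
        spacing=np.array([h, h, h]),
        origin=origin,
        meta={"geometry": asdict(p)},
    )


# ---------------------------------------------------------------------------
# mass / BMI


def body_mass_kg(vol: LabeledVolume) -> float:
    """Whole-body mass implied by the torso: uniform density, fixed torso fraction."""
    torso_cm3 = int(np.count_nonzero(vol.body_mask())) * vol.voxel_volume_mm3 / 1e3
    torso_kg = torso_cm3 * BODY_DENSITY_G_PER_CM3 / 1e3
    return torso_kg / TORSO_MASS_FRACTION


def body_bmi(vol: LabeledVolume, height_m: float = BODY_HEIGHT_M) -> float:
    return body_mass_kg(vol) / height_m**2


# ---------------------------------------------------------------------------
# morphs


def morph_physique(vol: LabeledVolume, target_bmi: float) -> LabeledVolume:
    """Rescale torso cross-section and fat layer to hit a target BMI.

    The organs (lungs, heart, ribs if present) keep their world positions and
    sizes; only the soft-tissue shells move, so the heart volume is conserved
    up to re-voxelization on the resized grid. The torso height is unchanged.
    Requires the generator parameters in ``vol.meta`` (phantoms from
    :func:`build_phantom` carry them).
    """
    if not 15.0 <= target_bmi <= 40.0:
        raise MorphError("target BMI must lie in [15, 40]")
    if "geometry" not in vol.meta:
        raise MorphError("physique morph requires generator geometry metadata")
    current = body_bmi(vol)
    if abs(target_bmi - current) / target_bmi < 1e-3:
        return vol.copy()

    base = TorsoGeometry(**vol.meta["geometry"])

    def rebuild(s: float) -> LabeledVolume:
        return build_phantom(
            replace(
                base,
                a_mm=base.a_mm * s,
                b_mm=base.b_mm * s,
                fat_mm=max(base.fat_mm * s * s, base.resolution_mm),
            )
        )

    def objective(s: float) -> float:
        return body_bmi(rebuild(s)) - target_bmi

    # Bracket the root by walking from the identity scale; the walk stops at
    # the validity boundary (organs no longer fitting) or a hard scale cap.
    s_lo = s_hi = 1.0
    try:
        if current < target_bmi:
            while objective(s_hi) < 0:
                s_hi *= 1.12
                if s_hi > 2.5:
                    raise MorphError(f"BMI {target_bmi} above reachable range")
        else:
            while True:
                s_try = s_lo * 0.97
                try:
                    f = objective(s_try)
                except GeometryError as exc:
                    raise MorphError(
                        f"BMI {target_bmi} unreachable: {exc}"
                    ) from exc
                s_lo = s_try
                if f < 0:
                    break
        s_star = optimize.brentq(objective, s_lo, s_hi, xtol=1e-4, rtol=1e-5)
        out = rebuild(s_star)
    except MorphError:
        raise
    except (ValueError, GeometryError) as exc:
        raise MorphError(f"BMI {target_bmi} unreachable: {exc}") from exc

    achieved = body_bmi(out)
    if abs(achieved - target_bmi) / target_bmi > 0.02:
        raise MorphError(
            f"BMI {target_bmi} not met within 2% (achieved {achieved:.2f})"
        )
    n_heart_in, n_heart_out = (
        int(np.count_nonzero(m.heart_mask())) for m in (vol, out)
    )
    if abs(n_heart_out - n_heart_in) / n_heart_in > 0.10:
        raise MorphError("heart volume drifted by more than 10% during morph")
    out.meta["morph"] = {"kind": "physique", "target_bmi": target_bmi, "scale": s_star}
    return out


def _heart_box(vol: LabeledVolume, linear_scale: float):
    """Bounding-box slice around the heart, grown to hold the transform."""
    heart_old = vol.heart_mask()
    if not heart_old.any():
        raise MorphError("phantom has no heart voxels")
    idx = np.argwhere(heart_old)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    halfspan = (hi - lo + 1) / 2.0
    grow = np.ceil(halfspan * (max(linear_scale, 1.0) * 1.5 - 1.0)).astype(int) + 3
    lo = np.maximum(lo - grow, 0)
    hi = np.minimum(hi + grow, np.array(vol.labels.shape) - 1)
    return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi)), heart_old


def _inverse_map(w: np.ndarray, center: np.ndarray, linear_scale: float, angle_deg: float) -> np.ndarray:
    """Source points of the inverse affine: rotate by -angle about z, unscale."""
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    rel = w - center
    src = np.empty_like(rel)
    src[..., 0] = (ct * rel[..., 0] + st * rel[..., 1]) / linear_scale
    src[..., 1] = (-st * rel[..., 0] + ct * rel[..., 1]) / linear_scale
    src[..., 2] = rel[..., 2] / linear_scale
    return src + center


def _apply_heart_labels(vol: LabeledVolume, sl, heart_old, new_heart_box, sampled) -> LabeledVolume:
    """Write the transformed heart into a copy; vacated voxels become lung."""
    out = vol.copy()
    box = out.labels[sl]
    old_heart_box = heart_old[sl]
    appeared = new_heart_box & ~old_heart_box
    if np.any(np.isin(box[appeared], (AIR, SKIN, FAT))):
        raise MorphError("transformed heart exits the torso interior")
    vacated = old_heart_box & ~new_heart_box
    box[vacated] = LUNG
    box[new_heart_box] = sampled[new_heart_box]
    # Any heart voxels outside the working box would mean the box was too small.
    rest = out.heart_mask()
    rest[sl] = False
    if rest.any():
        raise MorphError("heart transform exceeded its working region")
    return out


def _heart_affine_analytic(vol: LabeledVolume, vol_scale: float, angle_deg: float) -> LabeledVolume:
    """Re-voxelize the analytically known heart under the composed affine.

    The generator's implicit ellipsoids (carried in ``vol.meta``) are
    evaluated at inverse-mapped voxel centers, so sub-voxel boundary motion
    (a few percent volumetric scaling) is tracked exactly — crisp labels,
    no dead zone. Successive heart morphs compose their affines.
    """
    geom = TorsoGeometry(**vol.meta["geometry"])
    prev = vol.meta.get("heart_affine", {"volumetric_scale": 1.0, "rotate_z_deg": 0.0})
    tot_scale = prev["volumetric_scale"] * vol_scale
    tot_rot = prev["rotate_z_deg"] + angle_deg
    lin = tot_scale ** (1.0 / 3.0)
    c0 = np.asarray(geom.heart_center_mm, dtype=float)

    sl, heart_old = _heart_box(vol, lin / prev["volumetric_scale"] ** (1.0 / 3.0))
    gx, gy, gz = np.meshgrid(
        *(np.arange(s.start, s.stop) for s in sl), indexing="ij", sparse=False
    )
    w = vol.origin + (np.stack([gx, gy, gz], axis=-1) + 0.5) * vol.spacing
    src = _inverse_map(w, c0, lin, tot_rot)
    x, y, z = src[..., 0], src[..., 1], src[..., 2]
    new_heart_box = _ellipsoid_inside(x, y, z, geom.heart_center_mm, geom.heart_axes_mm)
    blood_axes = tuple(max(a - geom.myocardium_mm, 1.0) for a in geom.heart_axes_mm)
    blood = _ellipsoid_inside(x, y, z, geom.heart_center_mm, blood_axes)
    sampled = np.where(blood, BLOOD, MYOCARDIUM).astype(vol.labels.dtype)

    out = _apply_heart_labels(vol, sl, heart_old, new_heart_box, sampled)
    out.meta["heart_affine"] = {"volumetric_scale": tot_scale, "rotate_z_deg": tot_rot}
    return out


def _heart_affine_resample(vol: LabeledVolume, linear_scale: float, angle_deg: float) -> LabeledVolume:
    """Fallback for volumes without generator metadata: signed-distance resampling.

    The heart/blood surfaces of the label image are tracked as linearly
    interpolated signed distances and re-thresholded at the inverse-mapped
    voxel centers. Boundary motion below about half a voxel is not resolved
    (the label image itself carries no sub-voxel information).
    """
    sl, heart_old = _heart_box(vol, linear_scale)
    gx, gy, gz = np.meshgrid(
        *(np.arange(s.start, s.stop) for s in sl), indexing="ij", sparse=False
    )
    w = vol.origin + (np.stack([gx, gy, gz], axis=-1) + 0.5) * vol.spacing
    c = vol.heart_centroid_mm()
    src = _inverse_map(w, c, linear_scale, angle_deg)
    src_frac = (src - vol.origin) / vol.spacing - 0.5

    def signed_distance(mask: np.ndarray) -> np.ndarray:
        inside = ndimage.distance_transform_edt(mask, sampling=vol.spacing)
        outside = ndimage.distance_transform_edt(~mask, sampling=vol.spacing)
        return inside - outside

    coords = np.moveaxis(src_frac, -1, 0)
    sdf_heart = ndimage.map_coordinates(
        signed_distance(heart_old), coords, order=1, mode="constant", cval=-1e6
    )
    sdf_blood = ndimage.map_coordinates(
        signed_distance(vol.labels == BLOOD), coords, order=1, mode="constant", cval=-1e6
    )
    new_heart_box = sdf_heart > 0
    sampled = np.where(sdf_blood > 0, BLOOD, MYOCARDIUM).astype(vol.labels.dtype)
    return _apply_heart_labels(vol, sl, heart_old, new_heart_box, sampled)


def morph_heart(vol: LabeledVolume, spec: MorphSpec) -> LabeledVolume:
    """Scale (volumetric fraction) or rotate (degrees about z) the heart in place.

    Voxels the heart vacates are refilled with lung tissue, all other tissue
    is untouched, so the total body voxel count is conserved exactly. For
    generator phantoms the implicit heart surface is re-voxelized under the
    composed affine (exact sub-voxel scaling); other volumes fall back to
    signed-distance label resampling.
    """
    if spec.kind == "heart_scale":
        vol_scale, angle = float(spec.parameter), 0.0
    elif spec.kind == "heart_rotate":
        vol_scale, angle = 1.0, float(spec.parameter)
    else:
        raise MorphError("morph_heart handles heart_scale / heart_rotate only")
    if vol_scale == 1.0 and angle == 0.0:
        return vol.copy()
    if "geometry" in vol.meta:
        out = _heart_affine_analytic(vol, vol_scale, angle)
    else:
        out = _heart_affine_resample(vol, vol_scale ** (1.0 / 3.0), angle)
    out.meta["morph"] = {"kind": spec.kind, "parameter": spec.parameter}
    return out


def apply_morph(vol: LabeledVolume, spec: MorphSpec) -> LabeledVolume:
    if spec.kind == "physique":
        return morph_physique(vol, spec.parameter)
    return morph_heart(vol, spec)


# ---------------------------------------------------------------------------
# invariant checks (used by tests and the study pipeline)


def validate_phantom(vol: LabeledVolume) -> None:
    """Raise ``GeometryError`` if structural invariants are violated."""
    labels = vol.labels
    body = vol.body_mask()
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]]
    if any(np.any(f != AIR) for f in faces):
        raise GeometryError("body touches the volume boundary (no air shell)")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    _, n_body = ndimage.label(body, structure=structure)
    if n_body != 1:
        raise GeometryError(f"body has {n_body} connected components")
    heart = vol.heart_mask()
    _, n_heart = ndimage.label(heart, structure=structure)
    if n_heart != 1:
        raise GeometryError(f"heart has {n_heart} connected components")
    shell = ndimage.binary_dilation(heart, structure=structure) & ~heart
    if np.any(labels[shell] == AIR) or np.any(labels[shell] == SKIN):
        raise GeometryError("heart is not strictly inside the torso")


def anterior_heart_skin_distance_mm(vol: LabeledVolume) -> float:
    """Distance from the heart's anterior face to the skin along +y at the heart (x, z)."""
    heart_idx = np.argwhere(vol.heart_mask())
    cx, _, cz = np.round(heart_idx.mean(axis=0)).astype(int)
    column = vol.labels[cx, :, cz]
    heart_y = np.flatnonzero(np.isin(column, HEART_LABELS))
    skin_y = np.flatnonzero(column == SKIN)
    if heart_y.size == 0 or skin_y.size == 0:
        raise ValueError("heart/skin not found on the mid-heart column")
    front = skin_y[skin_y > heart_y.max()]
    if front.size == 0:
        raise ValueError("no anterior skin above the heart")
    return float((front.min() - heart_y.max()) * vol.spacing[1])
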