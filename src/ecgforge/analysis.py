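"""Robustness evaluation: scenario sets, pairwise DTW means, regression, quality map.

The evaluation design examines five uncertainty factors:

* ``physique`` — four body-mass-index morphs (17.2, 23.2, 28.5, 34.2 kg/m^2),
  compared over all 6 unordered model pairs;
* ``heart_size`` — seven volumetric heart scalings (90..110%), 21 pairs;
* ``heart_orientation`` — seven rotations (-8..+8 deg), 21 pairs;
* ``misalign_1cm`` / ``misalign_2cm`` — per lead pair, the reference waveform
  against 16 variants (upper/lower electrode x 8 directions).

That is 6 + 21 + 21 = 48 individual-difference comparison patterns; with the
35 diagonal bipolar pairs the pooled evaluation spans 35 x 48 = 1680
DTW/normalized-DTW waveform comparisons.

For each comparison the differences in heart-electrode distance (delta d)
and subtended angle (delta theta) act as geometric predictors. Multivariate
ordinary least squares on standardized predictors, with variance inflation
factors as a collinearity screen, decomposes DTW and normalized DTW
variation into per-predictor contribution rates. The electrode quality map
normalizes mean amplitude and mean normalized DTW per factor by their maxima
and ranks lead pairs by the difference (amplitude high, shape variability
low); the top-20% region is the recommended placement area.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .leads import (
    GridSpec,
    LeadPair,
    LeadWaveform,
    assemble_waveform,
    lead_pairs,
    misalignment_variants,
    place_grid,
    solve_sequence,
)
from .metrics import GeometryMetrics, dtw, normalized_dtw, pair_geometry, signal_amplitude
from .phantom import (
    HEART_ROTATION_DEG,
    HEART_SCALE_FACTORS,
    PHYSIQUE_BMI_TARGETS,
    LabeledVolume,
    MorphSpec,
    apply_morph,
)
from .sources import build_path, default_path_spec, transform_path_spec
from .spfd import SolverConfig, assemble
from .tissues import TissueTable, default_tissue_table

INDIVIDUAL_FACTORS = ("physique", "heart_size", "heart_orientation")
MISALIGN_FACTORS = ("misalign_1cm", "misalign_2cm")
ALL_FACTORS = INDIVIDUAL_FACTORS + MISALIGN_FACTORS

FACTOR_MEMBERS: dict[str, tuple] = {
    "physique": PHYSIQUE_BMI_TARGETS,
    "heart_size": HEART_SCALE_FACTORS,
    "heart_orientation": HEART_ROTATION_DEG,
}


class IncompleteSetError(ValueError):
    """A scenario member is missing waveforms for some lead pair."""


class DegenerateFactorError(ValueError):
    """A factor's amplitude or dissimilarity maximum is zero; cannot normalize."""


@dataclass
class ScenarioMember:
    name: str
    parameter: float
    waveforms: dict[str, LeadWaveform]
    geometry: dict[str, GeometryMetrics]
    pairs: dict[str, LeadPair]
    solver_stats: dict = dc_field(default_factory=dict)


@dataclass
class ScenarioSet:
    """All waveforms needed to evaluate one uncertainty factor."""

    factor: str
    members: list[ScenarioMember]
    # For misalignment factors: pair_id -> list of (variant waveform, variant geometry).
    variants: dict[str, list[tuple[LeadWaveform, GeometryMetrics]]] = dc_field(
        default_factory=dict
    )

    @property
    def pair_ids(self) -> list[str]:
        return list(self.members[0].waveforms)

    def n_comparisons(self) -> int:
        if self.factor in MISALIGN_FACTORS:
            return 16
        n = len(self.members)
        return n * (n - 1) // 2


def _member_evaluation(
    name: str,
    parameter: float,
    vol: LabeledVolume,
    path_spec: dict[str, np.ndarray],
    grid_spec: GridSpec,
    tissues: TissueTable,
    solver_cfg: SolverConfig,
    step_mm: float,
):
    """Solve one phantom and build all 35 lead waveforms + pair geometry."""
    seq = build_path(vol, path_spec, step_mm=step_mm)
    sys = assemble(vol, tissues)
    fields = solve_sequence(sys, seq, solver_cfg)
    grid = place_grid(vol, grid_spec)
    pairs = lead_pairs(grid)
    waveforms = {p.pair_id: assemble_waveform(fields, p) for p in pairs}
    geom = {p.pair_id: pair_geometry(vol, seq, p) for p in pairs}
    member = ScenarioMember(
        name=name, parameter=parameter, waveforms=waveforms, geometry=geom,
        pairs={p.pair_id: p for p in pairs},
        solver_stats={
            "n_dipole_solves": len(fields.residuals),
            "max_relative_residual": float(fields.residuals.max()),
            "max_iterations": int(fields.iterations.max()),
        },
    )
    return member, fields, vol, seq


def run_scenarios(
    base_vol: LabeledVolume,
    factor: str,
    tissues: TissueTable | None = None,
    path_spec: dict[str, np.ndarray] | None = None,
    grid_spec: GridSpec | None = None,
    solver_cfg: SolverConfig | None = None,
    step_mm: float = 2.0,
) -> ScenarioSet:
    """Generate all member phantoms (or misaligned lead variants) for a factor
    and build their 35 bipolar waveforms. Deterministic."""
    if factor not in ALL_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    tissues = tissues or default_tissue_table()
    solver_cfg = solver_cfg or SolverConfig(method="direct")
    grid_spec = grid_spec or GridSpec()
    heart_c = base_vol.heart_centroid_mm()
    base_spec = path_spec or default_path_spec(heart_c)

    if factor in MISALIGN_FACTORS:
        displacement = 10.0 if factor == "misalign_1cm" else 20.0
        member, fields, vol, seq = _member_evaluation(
            "reference", 0.0, base_vol, base_spec, grid_spec, tissues, solver_cfg, step_mm
        )
        variants: dict[str, list[tuple[LeadWaveform, GeometryMetrics]]] = {}
        for pid, pair in member.pairs.items():
            entries = []
            for _, moved in misalignment_variants(pair, displacement, vol):
                w = assemble_waveform(fields, moved)
                entries.append((w, pair_geometry(vol, seq, moved)))
            variants[pid] = entries
        return ScenarioSet(factor=factor, members=[member], variants=variants)

    members = []
    for param in FACTOR_MEMBERS[factor]:
        if factor == "physique":
            vol_m = apply_morph(base_vol, MorphSpec("physique", param))
            spec_m = base_spec
        elif factor == "heart_size":
            vol_m = apply_morph(base_vol, MorphSpec("heart_scale", param))
            spec_m = transform_path_spec(base_spec, heart_c, volumetric_scale=param)
        else:
            vol_m = apply_morph(base_vol, MorphSpec("heart_rotate", param))
            spec_m = transform_path_spec(base_spec, heart_c, rotate_z_deg=param)
        member, _, _, _ = _member_evaluation(
            f"{factor}={param}", float(param), vol_m, spec_m, grid_spec, tissues,
            solver_cfg, step_mm,
        )
        members.append(member)
    return ScenarioSet(factor=factor, members=members)


def summarize(sset: ScenarioSet) -> pd.DataFrame:
    """Per-lead-pair means over the factor's comparisons.

    Columns: mean SA (V), mean DTW, mean normalized DTW, mean |delta d| (mm),
    mean |delta theta| (deg), comparison count; one row per lead pair.
    """
    rows = []
    if sset.factor in MISALIGN_FACTORS:
        ref = sset.members[0]
        for pid in sset.pair_ids:
            entries = sset.variants.get(pid)
            if not entries:
                raise IncompleteSetError(f"missing misalignment variants for {pid}")
            w0, g0 = ref.waveforms[pid], ref.geometry[pid]
            dtws = [dtw(w0.v_volts, w.v_volts).value for w, _ in entries]
            ndtws = [normalized_dtw(w0, w) for w, _ in entries]
            dds = [abs(g0.d_mm - g.d_mm) for _, g in entries]
            dths = [abs(g0.theta_deg - g.theta_deg) for _, g in entries]
            sas = [signal_amplitude(w) for w, _ in entries]
            rows.append((pid, np.mean(sas), np.mean(dtws), np.mean(ndtws),
                         np.mean(dds), np.mean(dths), len(entries)))
    else:
        combos = list(itertools.combinations(sset.members, 2))
        for pid in sset.pair_ids:
            for m in sset.members:
                if pid not in m.waveforms:
                    raise IncompleteSetError(f"member {m.name} lacks pair {pid}")
            dtws, ndtws, dds, dths = [], [], [], []
            for a, b in combos:
                dtws.append(dtw(a.waveforms[pid].v_volts, b.waveforms[pid].v_volts).value)
                ndtws.append(normalized_dtw(a.waveforms[pid], b.waveforms[pid]))
                dds.append(abs(a.geometry[pid].d_mm - b.geometry[pid].d_mm))
                dths.append(abs(a.geometry[pid].theta_deg - b.geometry[pid].theta_deg))
            sas = [signal_amplitude(m.waveforms[pid]) for m in sset.members]
            rows.append((pid, np.mean(sas), np.mean(dtws), np.mean(ndtws),
                         np.mean(dds), np.mean(dths), len(combos)))
    df = pd.DataFrame(
        rows,
        columns=["pair_id", "mean_sa_V", "mean_dtw", "mean_ndtw",
                 "mean_dd_mm", "mean_dtheta_deg", "n_comparisons"],
    )
    df.insert(0, "factor", sset.factor)
    return df


def comparison_records(sset: ScenarioSet) -> pd.DataFrame:
    """One row per comparison pattern: DTW / nDTW / delta d / delta theta averaged
    over the 35 lead pairs (the per-comparison pooling used for regression)."""
    rows = []
    if sset.factor in MISALIGN_FACTORS:
        ref = sset.members[0]
        for k in range(16):
            vals = np.array([
                [
                    dtw(ref.waveforms[pid].v_volts, sset.variants[pid][k][0].v_volts).value,
                    normalized_dtw(ref.waveforms[pid], sset.variants[pid][k][0]),
                    abs(ref.geometry[pid].d_mm - sset.variants[pid][k][1].d_mm),
                    abs(ref.geometry[pid].theta_deg - sset.variants[pid][k][1].theta_deg),
                ]
                for pid in sset.pair_ids
            ])
            rows.append((sset.factor, "reference", f"variant{k}", *vals.mean(axis=0)))
    else:
        for a, b in itertools.combinations(sset.members, 2):
            vals = np.array([
                [
                    dtw(a.waveforms[pid].v_volts, b.waveforms[pid].v_volts).value,
                    normalized_dtw(a.waveforms[pid], b.waveforms[pid]),
                    abs(a.geometry[pid].d_mm - b.geometry[pid].d_mm),
                    abs(a.geometry[pid].theta_deg - b.geometry[pid].theta_deg),
                ]
                for pid in sset.pair_ids
            ])
            rows.append((sset.factor, a.name, b.name, *vals.mean(axis=0)))
    return pd.DataFrame(
        rows, columns=["factor", "member_a", "member_b", "dtw", "ndtw", "dd", "dtheta"]
    )


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    response: str
    coef: dict[str, float]            # standardized OLS coefficients
    pvalues: dict[str, float]
    vif: dict[str, float]
    contributions_pct: dict[str, float]
    r_squared: float
    method: str
    warnings: list[str] = dc_field(default_factory=list)


def _vif(Z: np.ndarray, names: list[str]) -> dict[str, float]:
    out = {}
    for j, name in enumerate(names):
        others = np.delete(Z, j, axis=1)
        X = sm.add_constant(others)
        r2 = sm.OLS(Z[:, j], X).fit().rsquared
        out[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def _contributions(coef: np.ndarray, Z: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "squared_std_coef":
        sq = coef**2
        return 100.0 * sq / sq.sum() if sq.sum() > 0 else np.full_like(sq, np.nan)
    if method == "lmg":
        # Average R^2 increment of each predictor over all entry orderings.
        k = Z.shape[1]
        idx = list(range(k))

        def r2_of(subset):
            if not subset:
                return 0.0
            X = sm.add_constant(Z[:, list(subset)])
            return sm.OLS(y, X).fit().rsquared

        shares = np.zeros(k)
        for order in itertools.permutations(idx):
            prev: list[int] = []
            for j in order:
                shares[j] += r2_of(prev + [j]) - r2_of(prev)
                prev.append(j)
        shares /= float(np.prod(np.arange(1, k + 1)))
        return 100.0 * shares / shares.sum()
    raise ValueError(f"unknown contribution method {method!r}")


def regress(
    comparisons: pd.DataFrame,
    predictors: tuple[str, str] = ("dd", "dtheta"),
    responses: tuple[str, str] = ("dtw", "ndtw"),
    contribution_method: str = "squared_std_coef",
) -> dict[str, RegressionResult]:
    """Multivariate OLS of each response on standardized geometric predictors.

    Returns one result per response with p-values, VIF (1/(1-R_j^2)) and
    contribution rates summing to 100%. A VIF >= 10 attaches a
    multicollinearity warning but the fit is still returned.
    """
    if len(comparisons) < 3:
        raise ValueError("need at least 3 pooled observations")
    Z = comparisons[list(predictors)].to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("a predictor is constant; cannot standardize")
    Z = (Z - Z.mean(axis=0)) / sd
    vif = _vif(Z, list(predictors))
    out: dict[str, RegressionResult] = {}
    for resp in responses:
        y = comparisons[resp].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(Z)).fit()
        coef = fit.params[1:]
        contrib = _contributions(coef, Z, y, contribution_method)
        warnings = [
            f"VIF {name} = {v:.2f} >= 10: multicollinearity suspected"
            for name, v in vif.items()
            if v >= 10
        ]
        out[resp] = RegressionResult(
            response=resp,
            coef=dict(zip(predictors, map(float, coef))),
            pvalues=dict(zip(predictors, map(float, fit.pvalues[1:]))),
            vif=vif,
            contributions_pct=dict(zip(predictors, map(float, contrib))),
            r_squared=float(fit.rsquared),
            method=contribution_method,
            warnings=warnings,
        )
    return out


# ---------------------------------------------------------------------------
# electrode quality map


def quality_map(summaries: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Waveform-quality factor per lead pair and the top-20% placement region.

    Per factor, mean SA and mean normalized DTW are divided by their maxima
    over the 35 pairs; the quality factor is the mean over factors of
    (SA_norm - nDTW_norm). The region mask marks pairs at or above the 80th
    percentile (ties included).
    """
    if not summaries:
        raise ValueError("no factor summaries given")
    pair_ids = list(next(iter(summaries.values()))["pair_id"])
    sa_norm = pd.DataFrame(index=pair_ids)
    nd_norm = pd.DataFrame(index=pair_ids)
    for factor, df in summaries.items():
        d = df.set_index("pair_id")
        if set(d.index) != set(pair_ids):
            raise IncompleteSetError(f"factor {factor} does not cover all pairs")
        sa_max = d["mean_sa_V"].max()
        nd_max = d["mean_ndtw"].max()
        if sa_max <= 0 or nd_max <= 0:
            raise DegenerateFactorError(f"factor {factor} has a zero maximum")
        sa_norm[factor] = d["mean_sa_V"] / sa_max
        nd_norm[factor] = d["mean_ndtw"] / nd_max
    quality = (sa_norm - nd_norm).mean(axis=1)
    threshold = np.percentile(quality.to_numpy(), 80.0)
    out = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "sa_norm_mean": sa_norm.mean(axis=1).to_numpy(),
            "ndtw_norm_mean": nd_norm.mean(axis=1).to_numpy(),
            "quality": quality.to_numpy(),
            "top20": (quality.to_numpy() >= threshold),
        }
    )
    out.attrs["threshold"] = float(threshold)
    return out
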