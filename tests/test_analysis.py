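import numpy as np
import pandas as pd
import pytest

import ecgforge as ef
from ecgforge.analysis import (
    DegenerateFactorError,
    IncompleteSetError,
    RegressionResult,
    ScenarioMember,
    ScenarioSet,
    comparison_records,
    quality_map,
    regress,
    summarize,
)
from ecgforge.leads import LeadWaveform
from ecgforge.metrics import GeometryMetrics, dtw


def _wave(values):
    v = np.asarray(values, dtype=float)
    return LeadWaveform(t_s=np.arange(len(v)) * 1e-3, v_volts=v)


def _member(name, waves, geos):
    return ScenarioMember(
        name=name,
        parameter=0.0,
        waveforms={k: _wave(v) for k, v in waves.items()},
        geometry={k: GeometryMetrics(*g) for k, g in geos.items()},
        pairs={},
    )


class TestSummarize:
    def test_identical_members_give_zero_dissimilarity(self):
        waves = {"p1": [0.0, 1.0, 0.2], "p2": [0.5, -0.5, 0.0]}
        geos = {"p1": (100.0, 40.0), "p2": (120.0, 30.0)}
        sset = ScenarioSet(
            factor="heart_size",
            members=[_member(f"m{i}", waves, geos) for i in range(3)],
        )
        df = summarize(sset).set_index("pair_id")
        assert (df["mean_dtw"] == 0).all()
        assert (df["mean_ndtw"] == 0).all()
        assert (df["mean_dd_mm"] == 0).all()
        assert (df["n_comparisons"] == 3).all()

    def test_two_members_mean_is_single_comparison(self):
        a = {"p1": [0.0, 1.0, 0.0]}
        b = {"p1": [0.0, 2.0, 1.0]}
        g = {"p1": (100.0, 40.0)}
        g2 = {"p1": (110.0, 35.0)}
        sset = ScenarioSet(
            factor="physique", members=[_member("a", a, g), _member("b", b, g2)]
        )
        row = summarize(sset).iloc[0]
        assert row["mean_dtw"] == pytest.approx(dtw(a["p1"], b["p1"]).value)
        assert row["mean_dd_mm"] == pytest.approx(10.0)
        assert row["mean_dtheta_deg"] == pytest.approx(5.0)
        assert row["n_comparisons"] == 1

    def test_three_member_toy_matches_hand_average(self):
        # hand-computed: DTW(a,b)=1 (diagonal up-shift x3 minus...), worked out below
        wa, wb, wc = [0.0, 1.0], [0.0, 2.0], [1.0, 3.0]
        # |0-0|+|1-2| = 1 ; dtw(a,c): |0-1|+|1-3|=3 alt path |0-1|+|1-1|+... = min(3, |0-1|+|1-1|+|3-1|) = 3 via enumeration: paths over 2x2
        # dtw(b,c): |0-1|+|2-3| = 2
        g = {"p1": (100.0, 40.0)}
        sset = ScenarioSet(
            factor="physique",
            members=[
                _member("a", {"p1": wa}, g),
                _member("b", {"p1": wb}, g),
                _member("c", {"p1": wc}, g),
            ],
        )
        row = summarize(sset).iloc[0]
        d_ab = dtw(wa, wb).value
        d_ac = dtw(wa, wc).value
        d_bc = dtw(wb, wc).value
        assert row["mean_dtw"] == pytest.approx((d_ab + d_ac + d_bc) / 3)
        assert d_ab == pytest.approx(1.0)
        assert d_bc == pytest.approx(2.0)

    def test_missing_pair_raises(self):
        sset = ScenarioSet(
            factor="physique",
            members=[
                _member("a", {"p1": [0, 1.0]}, {"p1": (1, 1)}),
                _member("b", {}, {}),
            ],
        )
        with pytest.raises(IncompleteSetError):
            summarize(sset)

    def test_misalignment_sixteen_pattern_mean(self):
        ref = _member("ref", {"p1": [0.0, 1.0, 0.0]}, {"p1": (100.0, 40.0)})
        variants = {
            "p1": [
                (_wave([0.0, 1.0 + 0.1 * k, 0.0]), GeometryMetrics(100.0 + k, 40.0 - k))
                for k in range(16)
            ]
        }
        sset = ScenarioSet(factor="misalign_2cm", members=[ref], variants=variants)
        row = summarize(sset).iloc[0]
        assert row["n_comparisons"] == 16
        assert row["mean_dd_mm"] == pytest.approx(np.mean(range(16)))
        assert row["mean_dtw"] == pytest.approx(np.mean([0.1 * k for k in range(16)]))


class TestRegress:
    @staticmethod
    def _orthogonal_predictors(n=48, seed=0):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(n, 2))
        q, _ = np.linalg.qr(Z - Z.mean(axis=0))
        return q[:, 0], q[:, 1]

    def test_orthogonal_predictors_have_unit_vif(self):
        z1, z2 = self._orthogonal_predictors()
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"dd": z1, "dtheta": z2, "dtw": 3 * z1 + 0.01 * rng.normal(size=len(z1)),
             "ndtw": 3 * z2 + 0.01 * rng.normal(size=len(z1))}
        )
        res = regress(df)
        for r in res.values():
            assert r.vif["dd"] == pytest.approx(1.0, abs=0.05)
            assert r.vif["dtheta"] == pytest.approx(1.0, abs=0.05)
            assert not r.warnings

    def test_single_driver_takes_full_contribution(self):
        z1, z2 = self._orthogonal_predictors(seed=2)
        rng = np.random.default_rng(3)
        noise = 0.03 * rng.normal(size=len(z1))
        df = pd.DataFrame(
            {"dd": z1, "dtheta": z2, "dtw": 3 * z1 + noise, "ndtw": 3 * z1 + noise}
        )
        res = regress(df)
        assert res["dtw"].contributions_pct["dd"] > 95.0
        assert res["dtw"].pvalues["dd"] < 1e-6

    def test_equal_drivers_split_evenly(self):
        z1, z2 = self._orthogonal_predictors(seed=4)
        rng = np.random.default_rng(5)
        y = z1 + z2 + 0.02 * rng.normal(size=len(z1))
        df = pd.DataFrame({"dd": z1, "dtheta": z2, "dtw": y, "ndtw": y})
        res = regress(df)
        assert res["dtw"].contributions_pct["dd"] == pytest.approx(50.0, abs=5.0)
        assert res["dtw"].contributions_pct["dtheta"] == pytest.approx(50.0, abs=5.0)

    def test_collinear_predictors_warn_but_fit(self):
        rng = np.random.default_rng(6)
        z1 = rng.normal(size=40)
        z2 = z1 + 0.01 * rng.normal(size=40)
        df = pd.DataFrame({"dd": z1, "dtheta": z2, "dtw": z1, "ndtw": z2})
        res = regress(df)
        assert all(r.warnings for r in res.values())
        assert all(v >= 10 for r in res.values() for v in r.vif.values())

    def test_lmg_contributions_sum_to_hundred(self):
        z1, z2 = self._orthogonal_predictors(seed=7)
        rng = np.random.default_rng(8)
        y = 2 * z1 + z2 + 0.05 * rng.normal(size=len(z1))
        df = pd.DataFrame({"dd": z1, "dtheta": z2, "dtw": y, "ndtw": y})
        res = regress(df, contribution_method="lmg")
        assert sum(res["dtw"].contributions_pct.values()) == pytest.approx(100.0)
        assert res["dtw"].contributions_pct["dd"] > res["dtw"].contributions_pct["dtheta"]

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"dd": [1, 2], "dtheta": [2, 1], "dtw": [1, 2], "ndtw": [1, 2]})
        with pytest.raises(ValueError):
            regress(df)


class TestQualityMap:
    @staticmethod
    def _summary(pair_ids, sa, ndtw, factor="physique"):
        return pd.DataFrame(
            {
                "factor": factor,
                "pair_id": pair_ids,
                "mean_sa_V": sa,
                "mean_dtw": ndtw,
                "mean_ndtw": ndtw,
                "mean_dd_mm": 0.0,
                "mean_dtheta_deg": 0.0,
                "n_comparisons": 1,
            }
        )

    def test_uniform_tables_rank_everything_top(self):
        pids = [f"p{i}" for i in range(35)]
        qm = quality_map({"f": self._summary(pids, [2.0] * 35, [1.0] * 35)})
        assert qm["quality"].nunique() == 1
        assert qm["top20"].sum() >= int(np.ceil(0.2 * 35))

    def test_dominant_pair_is_top_ranked(self):
        pids = ["a", "b", "c", "d", "e"]
        sa = [5.0, 1.0, 1.0, 1.0, 1.0]
        nd = [0.1, 1.0, 2.0, 2.0, 2.0]
        qm = quality_map(
            {
                "f1": self._summary(pids, sa, nd),
                "f2": self._summary(pids, sa, nd, factor="heart_size"),
            }
        ).set_index("pair_id")
        assert qm["quality"].idxmax() == "a"
        assert bool(qm.loc["a", "top20"])

    def test_two_factor_toy_matches_hand_computation(self):
        pids = ["a", "b"]
        qm = quality_map(
            {
                "f1": self._summary(pids, [2.0, 1.0], [0.5, 1.0]),
                "f2": self._summary(pids, [1.0, 4.0], [2.0, 1.0]),
            }
        ).set_index("pair_id")
        # f1: sa_norm (1, .5), nd_norm (.5, 1)  -> q (.5, -.5)
        # f2: sa_norm (.25, 1), nd_norm (1, .5) -> q (-.75, .5)
        assert qm.loc["a", "quality"] == pytest.approx((0.5 - 0.75) / 2)
        assert qm.loc["b", "quality"] == pytest.approx((-0.5 + 0.5) / 2)

    def test_zero_maximum_rejected(self):
        pids = ["a", "b"]
        with pytest.raises(DegenerateFactorError):
            quality_map({"f1": self._summary(pids, [0.0, 0.0], [1.0, 1.0])})

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(IncompleteSetError):
            quality_map(
                {
                    "f1": self._summary(["a", "b"], [1, 2], [1, 2]),
                    "f2": self._summary(["a", "c"], [1, 2], [1, 2]),
                }
            )


def test_comparison_records_shape():
    waves = {"p1": [0.0, 1.0], "p2": [1.0, 0.0]}
    geos = {"p1": (100.0, 40.0), "p2": (110.0, 42.0)}
    members = [
        _member("a", waves, geos),
        _member("b", {"p1": [0.0, 2.0], "p2": [2.0, 0.0]}, {"p1": (105.0, 41.0), "p2": (112.0, 41.0)}),
        _member("c", {"p1": [0.0, 3.0], "p2": [3.0, 0.0]}, {"p1": (90.0, 39.0), "p2": (100.0, 44.0)}),
    ]
    sset = ScenarioSet(factor="heart_orientation", members=members)
    rec = comparison_records(sset)
    assert len(rec) == 3  # 3C2
    assert {"dtw", "ndtw", "dd", "dtheta"} <= set(rec.columns)
    # first row: mean over the two pairs of |delta d|
    assert rec.iloc[0]["dd"] == pytest.approx((5.0 + 2.0) / 2)
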