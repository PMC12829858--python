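import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffaconcord.concordance import (SScoreTable, aerc, compare_model_sscores,
                                    polygon_area, radar_vertices, rank_models,
                                    sscore, zscore_reference)
from ffaconcord.io import SampleTable


# ---------------------------------------------------------------- helpers
def _table(groups, values_by_analyte, species="human"):
    n = len(groups)
    df = pd.DataFrame({"sample_id": [f"{species}{i}" for i in range(n)],
                       "species": species, "group": groups})
    for a, vals in values_by_analyte.items():
        df[a] = vals
    return SampleTable(df, list(values_by_analyte))


def shoelace_area(radii):
    """Cartesian shoelace oracle on the polar vertices."""
    r = np.asarray(radii, dtype=float)
    k = len(r)
    ang = 2 * np.pi * np.arange(k) / k
    x, y = r * np.cos(ang), r * np.sin(ang)
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _stable(analytes, s_rows, groups):
    """Build an SScoreTable directly from an array of s-values."""
    df = pd.DataFrame({"sample_id": [f"m{i}" for i in range(len(s_rows))],
                       "group": groups})
    for j, a in enumerate(analytes):
        df[a] = [row[j] for row in s_rows]
    stats = pd.DataFrame({"mean_z": 0.0, "sd_z": 1.0, "n": 3},
                         index=pd.Index(analytes, name="analyte_id"))
    return SScoreTable(df, list(analytes), "alMDD", stats)


# ---------------------------------------------------------------- z-score
class TestZScore:
    def test_hand_computed_value(self):
        # reference [2,4,6]: mean 4, sample SD 2 -> case value 6 has z = 1
        t = _table(["HC", "HC", "HC", "alMDD"], {"C6:0": [2.0, 4.0, 6.0, 6.0]})
        z = zscore_reference(t, "HC")
        assert z.values("alMDD")["C6:0"].iloc[0] == pytest.approx(1.0)

    def test_value_at_reference_mean_is_zero(self):
        t = _table(["HC", "HC", "HC", "alMDD"], {"C6:0": [2.0, 4.0, 6.0, 4.0]})
        z = zscore_reference(t, "HC")
        assert z.values("alMDD")["C6:0"].iloc[0] == pytest.approx(0.0)

    def test_reference_cohort_standardized_identity(self, human_table):
        z = zscore_reference(human_table, "HC")
        ref = z.values("HC")
        assert np.allclose(ref.mean(), 0.0, atol=1e-12)
        assert np.allclose(ref.std(ddof=1), 1.0, atol=1e-12)

    def test_missing_reference_group(self, human_table):
        with pytest.raises(ValueError, match="absent"):
            zscore_reference(human_table, "nope")

    def test_zero_sd_analyte_dropped(self):
        t = _table(["HC", "HC", "alMDD", "alMDD"],
                   {"C6:0": [3.0, 3.0, 1.0, 2.0], "C9:0": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="zero/undefined"):
            z = zscore_reference(t, "HC")
        assert z.analytes == ["C9:0"]
        assert z.dropped == ["C6:0"]


# ---------------------------------------------------------------- s-score
class TestSScore:
    def _patient_z(self):
        # HC [2,4,6]: mean 4, SD 2; patient raws [2,4,0] -> z [-1,0,-2],
        # so the patient z distribution has mean -1 and sample SD 1
        t = _table(["HC"] * 3 + ["alMDD"] * 3,
                   {"C6:0": [2.0, 4.0, 6.0, 2.0, 4.0, 0.0]})
        z = zscore_reference(t, "HC")
        zp = z.values("alMDD")["C6:0"]
        assert np.allclose(zp, [-1.0, 0.0, -2.0])
        return z

    def _mouse_z(self, raw_value):
        t = _table(["ctrl", "ctrl", "ctrl", "LPS"],
                   {"C6:0": [2.0, 4.0, 6.0, raw_value]}, species="mouse")
        return zscore_reference(t, "ctrl")

    def test_animal_at_patient_mean_scores_zero(self):
        patient = self._patient_z()
        mouse = self._mouse_z(2.0)  # z = (2-4)/2 = -1 = patient mean z
        s = sscore(mouse, patient, "alMDD")
        assert s.values("LPS")["C6:0"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_values(self):
        # patient stats here: mean z -1, sd z 1; animal z 0 -> s = 1
        patient = self._patient_z()
        s = sscore(self._mouse_z(4.0), patient, "alMDD")
        assert s.values("LPS")["C6:0"].iloc[0] == pytest.approx(1.0)
        s = sscore(self._mouse_z(0.0), patient, "alMDD")  # z = -2 -> s = -1
        assert s.values("LPS")["C6:0"].iloc[0] == pytest.approx(-1.0)

    def test_worked_example_on_prebuilt_z_tables(self):
        """Patient z [-1,-0.5,-1.5] (mean -1, SD 0.5): animal z 0 -> s=2,
        animal z -1.5 -> s=-1, by direct construction of the z tables."""
        pz = _table(["alMDD"] * 3, {"C6:0": [1.0, 2.0, 3.0]})
        from ffaconcord.concordance import ZScoreTable
        zdf = pz.data[["sample_id", "species", "group"]].copy()
        zdf["C6:0"] = [-1.0, -0.5, -1.5]
        patient = ZScoreTable(zdf, ["C6:0"], "HC",
                              pd.DataFrame({"mean": [0.0], "sd": [1.0],
                                            "n": [3]}, index=["C6:0"]))
        mdf = pd.DataFrame({"sample_id": ["m0", "m1"], "species": "mouse",
                            "group": ["LPS", "LPS"], "C6:0": [0.0, -1.5]})
        mouse = ZScoreTable(mdf, ["C6:0"], "ctrl",
                            patient.reference_stats)
        s = sscore(mouse, patient, "alMDD")
        assert np.allclose(s.values()["C6:0"], [2.0, -1.0])

    def test_affine_invariance_of_units(self, human_table, mouse_table):
        """Rescaling raw units within each species leaves s unchanged."""
        hz = zscore_reference(human_table, "HC")
        mz = zscore_reference(mouse_table, "saline")
        s0 = sscore(mz, hz, "alMDD")

        h2 = SampleTable(human_table.data.copy(), list(human_table.analytes))
        h2.data[h2.analytes] = h2.data[h2.analytes] * 1000.0  # ng/mL
        m2 = SampleTable(mouse_table.data.copy(), list(mouse_table.analytes))
        m2.data[m2.analytes] = m2.data[m2.analytes] * 0.001
        s1 = sscore(zscore_reference(m2, "saline"),
                    zscore_reference(h2, "HC"), "alMDD")
        pd.testing.assert_frame_equal(s0.values(), s1.values())

    def test_disjoint_panels_rejected(self, human_table):
        hz = zscore_reference(human_table, "HC")
        t = _table(["ctrl"] * 2 + ["LPS"] * 2, {"C99:0": [1.0, 2, 3, 4]},
                   species="mouse")
        mz = zscore_reference(t, "ctrl")
        with pytest.raises(ValueError, match="shared"):
            sscore(mz, hz, "alMDD")


# ------------------------------------------------------------------- AERC
class TestAERC:
    @pytest.mark.parametrize("k", [3, 4, 7, 26])
    def test_unit_radii_closed_form(self, k):
        assert polygon_area([1.0] * k) == pytest.approx(
            (k / 2) * np.sin(2 * np.pi / k))

    def test_square_area(self):
        assert polygon_area([1, 1, 1, 1]) == pytest.approx(2.0)

    def test_zero_radii_zero_area(self):
        assert polygon_area([0.0, 0.0, 0.0, 0.0]) == 0.0

    def test_single_spike_zero_area(self):
        assert polygon_area([5.0, 0.0, 0.0, 0.0]) == 0.0

    def test_rejects_short_and_negative(self):
        with pytest.raises(ValueError, match="at least 3"):
            polygon_area([1.0, 2.0])
        with pytest.raises(ValueError, match="non-negative"):
            polygon_area([1.0, -0.1, 1.0])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0.0, 10.0), min_size=3, max_size=8))
    def test_matches_cartesian_shoelace(self, radii):
        assert polygon_area(radii) == pytest.approx(shoelace_area(radii),
                                                    abs=1e-10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 5.0), min_size=3, max_size=8),
           st.floats(1.0, 10.0))
    def test_quadratic_scaling(self, radii, c):
        assert polygon_area(np.array(radii) * c) == pytest.approx(
            c ** 2 * polygon_area(radii), rel=1e-9)

    def test_aerc_table_and_sem(self):
        analytes = ["C6:0", "C9:0", "C14:0", "C16:1"]
        s = _stable(analytes, [[1, 1, 1, 1], [2, 2, 2, 2],
                               [1, -1, 1, -1]], ["LPS"] * 3)
        res = aerc(s)
        # |s| transform: rows give areas 2, 8, 2
        assert np.allclose(res.per_animal["area"], [2.0, 8.0, 2.0])
        summary = res.group_summary.loc["LPS"]
        vals = np.array([2.0, 8.0, 2.0])
        assert summary["mean"] == pytest.approx(4.0)
        assert summary["sem"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(3))
        assert res.panel_order == analytes
        assert res.radius_transform == "abs"

    def test_order_dependence_is_exposed(self):
        analytes = ["C6:0", "C9:0", "C14:0", "C16:1"]
        s = _stable(analytes, [[3, 0.1, 3, 0.1]], ["LPS"])
        a1 = aerc(s).per_animal["area"].iloc[0]
        a2 = aerc(s, panel_order=["C6:0", "C14:0", "C9:0", "C16:1"]
                  ).per_animal["area"].iloc[0]
        assert a1 != a2

    @pytest.mark.parametrize("transform, expected", [
        ("abs", [1.0, 1.0, 1.0]),
        ("shift_min", [0.0, 2.0, 0.0]),
        ("clip_zero", [0.0, 1.0, 0.0]),
    ])
    def test_radius_transforms(self, transform, expected):
        from ffaconcord.concordance import _transform_radii
        out = _transform_radii(np.array([[-1.0, 1.0, -1.0]]), transform)
        assert np.allclose(out, [expected])

    def test_too_few_analytes_rejected(self):
        s = _stable(["C6:0", "C9:0"], [[1, 1]], ["LPS"])
        with pytest.raises(ValueError, match="at least 3"):
            aerc(s)

    def test_radar_vertices_shape(self):
        v = radar_vertices([1.0, 2.0, 3.0], ["a", "b", "c"])
        assert list(v.columns) == ["analyte_id", "angle", "radius", "x", "y"]
        assert v["angle"].iloc[0] == 0.0


# ---------------------------------------------------- model comparison
class TestModelComparison:
    def test_identical_tables_no_winner(self):
        analytes = ["C6:0", "C9:0", "C14:0"]
        rows = [[1, 2, 3], [2, 3, 4], [0, 1, 2]]
        a = _stable(analytes, rows, ["LPS"] * 3)
        b = _stable(analytes, rows, ["CSDS"] * 3)
        table, overall = compare_model_sscores(a, b, "LPS", "CSDS")
        assert np.allclose(table["p_value"], 1.0)
        assert (table["closer_model"] == "tie").all()
        assert overall["LPS"] == overall["CSDS"]

    def test_zero_s_model_flagged_closer(self):
        analytes = ["C6:0", "C9:0", "C14:0"]
        a = _stable(analytes, [[0, 0, 0], [0, 0, 0]], ["LPS"] * 2)
        b = _stable(analytes, [[3, 3, 3], [3, 3, 3]], ["CSDS"] * 2)
        table, overall = compare_model_sscores(a, b, "LPS", "CSDS")
        assert (table["closer_model"] == "LPS").all()
        assert overall["LPS"] < overall["CSDS"]


class TestRanking:
    def test_orders_by_mean_aerc(self):
        df = rank_models({"A": 1.0, "B": 2.0}, {"A": 0.5, "B": 0.7})
        assert list(df["model"]) == ["A", "B"]
        assert list(df["rank"]) == [1, 2]

    def test_tie_broken_by_secondary_then_name(self):
        df = rank_models({"A": 1.0, "B": 1.0}, {"A": 0.7, "B": 0.5})
        assert list(df["model"]) == ["B", "A"]
        df = rank_models({"A": 1.0, "B": 1.0}, {"A": 0.5, "B": 0.5})
        assert list(df["model"]) == ["A", "B"]

    def test_single_model(self):
        df = rank_models({"only": 1.5}, {"only": 0.9})
        assert len(df) == 1 and df["model"].iloc[0] == "only"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models({}, {})
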