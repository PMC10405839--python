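"""Group statistics: summaries, unpaired t-tests, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tropus.containers import ReconImage
from tropus.phantoms import STUDY_GROUPS
from tropus.stats import (
    build_report,
    group_summary,
    liver_mean_sos,
    percent_difference,
    significance_stars,
    unpaired_ttest,
    validate_cohort_table,
)


def _table(n_per_group=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in [("control", 1538.0), ("nafld_24w", 1475.0), ("nafld_36w", 1473.0)]:
        for k in range(n_per_group):
            rows.append(
                {
                    "section_id": f"{g}_{k}",
                    "group": g,
                    "mouse_id": f"{g}_m{k // 5}",
                    "liver_mean_sos": rng.normal(mu, 20),
                    "lipid_metric": rng.uniform(0.5, 1.5),
                    "area": rng.normal(400, 30),
                    "weight": rng.normal(35, 3),
                    "qc_excluded": False,
                }
            )
    return pd.DataFrame(rows)


class TestLiverMeanSos:
    def test_constant_map(self):
        img = ReconImage(pixels=np.full((8, 8), 1500.0), pixel_size=0.5, mode="sos", units="m/s")
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        assert liver_mean_sos(img, mask) == 1500.0

    def test_half_half_average(self):
        px = np.full((4, 4), 1450.0)
        px[:2] = 1550.0
        img = ReconImage(pixels=px, pixel_size=0.5, mode="sos", units="m/s")
        assert liver_mean_sos(img, np.ones((4, 4), dtype=bool)) == pytest.approx(1500.0)

    def test_empty_mask_rejected(self):
        img = ReconImage(pixels=np.full((4, 4), 1500.0), pixel_size=0.5, mode="sos", units="m/s")
        with pytest.raises(ValueError, match="empty"):
            liver_mean_sos(img, np.zeros((4, 4), dtype=bool))


class TestGroupSummary:
    def test_two_value_hand_arithmetic(self):
        t = _table(2)
        t.loc[t["group"] == "control", "area"] = [10.0, 20.0]
        s = group_summary(t, "area")
        row = s[s["group"] == "control"].iloc[0]
        assert row["mean"] == 15.0
        assert row["std"] == pytest.approx(np.sqrt(50.0))
        assert row["n"] == 2

    def test_std_uses_n_minus_1_two_pass_oracle(self, rng):
        t = _table(8, seed=3)
        vals = t.loc[t["group"] == "control", "liver_mean_sos"].to_numpy()
        mean = vals.sum() / len(vals)
        two_pass = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
        s = group_summary(t, "liver_mean_sos")
        assert s[s["group"] == "control"]["std"].iloc[0] == pytest.approx(two_pass, rel=1e-12)

    def test_sampling_consistency_with_generator(self):
        spec = STUDY_GROUPS["control"]
        rng = np.random.default_rng(7)
        t = _table(20, seed=7)
        t.loc[t["group"] == "control", "liver_mean_sos"] = rng.normal(
            spec.liver_sos_mean, spec.liver_sos_std, 20
        )
        s = group_summary(t, "liver_mean_sos")
        row = s[s["group"] == "control"].iloc[0]
        assert abs(row["mean"] - spec.liver_sos_mean) <= 2 * spec.liver_sos_std / np.sqrt(20)

    def test_single_row_group_rejected(self):
        t = _table(2)
        t = t.drop(t[t["group"] == "control"].index[1:])
        with pytest.raises(ValueError, match="control"):
            group_summary(t, "area")


class TestUnpairedTtest:
    def test_identical_groups(self):
        assert unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (
            pytest.approx(0.0),
            pytest.approx(1.0),
        )

    def test_hand_computed_pooled_t(self):
        t, p = unpaired_ttest([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_matches_textbook_closed_form(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.3, 9)
        t, p = unpaired_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_ref = 2 * sps.t.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_equal_means_convention(self):
        assert unpaired_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_welch_flag(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 5, 10)
        t, p = unpaired_ttest(a, b, welch=True)
        res = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(float(res.statistic))
        assert p == pytest.approx(float(res.pvalue))

    def test_significance_stars(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.01) == "**"
        assert significance_stars(0.001) == "***"
        assert significance_stars(0.0001) == "****"


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a,b,expected", [(1.47, 1.00, 47.0), (5.0, 5.0, 0.0), (1538.0, 1475.0, 4.271)]
    )
    def test_examples(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected, abs=1e-3)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            percent_difference(1.0, 0.0)


class TestBuildReport:
    def test_three_group_pairwise_structure(self, tmp_path):
        t = _table(5)
        paths = build_report(t, tmp_path / "report")
        pw = pd.read_csv(paths["pairwise"])
        sos = pw[pw["metric"] == "liver_mean_sos"]
        assert len(sos) == 3
        assert set(zip(sos["group_a"], sos["group_b"])) == {
            ("control", "nafld_24w"),
            ("control", "nafld_36w"),
            ("nafld_24w", "nafld_36w"),
        }
        summary = pd.read_csv(paths["summary"])
        assert set(summary["metric"]) == {"liver_mean_sos", "lipid_metric", "area", "weight"}

    def test_exclusions_dropped_and_listed(self, tmp_path):
        import json

        t = _table(5)
        t.loc[0, "qc_excluded"] = True
        paths = build_report(t, tmp_path / "r")
        with open(paths["manifest"]) as fh:
            man = json.load(fh)
        assert man["qc_excluded"] == ["control_0"]
        assert man["n_sections"] == 14

    def test_byte_identical_regeneration(self, tmp_path):
        t = _table(4)
        p1 = build_report(t, tmp_path / "a")
        p2 = build_report(t, tmp_path / "b")
        for key in ("summary", "pairwise", "long"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_duplicate_sections_rejected(self):
        t = _table(3)
        t.loc[1, "section_id"] = t.loc[0, "section_id"]
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort_table(t)


def test_power_control_vs_nafld24_sos():
    """At the published group parameters and n=20/group, the control vs
    NAFLD-24w speed-of-sound comparison is essentially always significant."""
    ctrl, dis = STUDY_GROUPS["control"], STUDY_GROUPS["nafld_24w"]
    rng = np.random.default_rng(42)
    hits = 0
    for _ in range(100):
        a = rng.normal(ctrl.liver_sos_mean, ctrl.liver_sos_std, 20)
        b = rng.normal(dis.liver_sos_mean, dis.liver_sos_std, 20)
        _, p = unpaired_ttest(a, b)
        hits += p < 0.001
    assert hits >= 95
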