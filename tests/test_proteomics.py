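"""Unit tests for CSF proteomic scoring: HD scaling, the composite severity,
protein selection, the activation score, and the paired change analysis."""

import numpy as np
import pandas as pd
import pytest

from pyroscore import (
    PathwaySpec,
    ScoreWeights,
    change_analysis,
    global_severity,
    group_compare,
    hd_scale,
    pyroptosis_score,
    score_samples,
    select_score_proteins,
    yearly_score_change,
)
from pyroscore.proteomics import extreme_gene_list


def weights_of(d: dict) -> ScoreWeights:
    table = pd.DataFrame(
        {"gene": list(d), "rho": list(d.values()), "pvalue": 0.01},
        index=pd.Index(list(d), name="protein"),
    )
    return ScoreWeights(table)


class TestHdScale:
    def test_hand_computed_z(self):
        m = pd.DataFrame({"P": [1.0, 2.0, 3.0, 4.0]}, index=["h1", "h2", "h3", "q"])
        scaled = hd_scale(m, hd_ids=["h1", "h2", "h3"])
        # sample SD of {1,2,3} is 1 -> (4-2)/1 = 2; the HD mean itself maps to 0
        assert scaled.loc["q", "P"] == pytest.approx(2.0)
        assert scaled.loc["h2", "P"] == pytest.approx(0.0)
        assert scaled.loc[["h1", "h2", "h3"], "P"].mean() == pytest.approx(0.0)
        assert scaled.loc[["h1", "h2", "h3"], "P"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent_on_already_scaled_matrix(self, toy_matrix):
        hd = list(toy_matrix.index[:4])
        once = hd_scale(toy_matrix, hd)
        twice = hd_scale(once.abs(), hd)  # keep positivity contract out of play
        again = hd_scale(hd_scale(toy_matrix, hd).abs(), hd)
        pd.testing.assert_frame_equal(twice, again)

    def test_zero_variance_protein_excluded_with_warning(self, toy_matrix, caplog):
        m = toy_matrix.copy()
        m["FLAT"] = 1.0
        with caplog.at_level("WARNING", logger="pyroscore.proteomics"):
            scaled = hd_scale(m, list(m.index[:4]))
        assert "FLAT" not in scaled.columns
        assert "zero HD variance" in caplog.text

    def test_requires_two_hd_samples(self, toy_matrix):
        with pytest.raises(ValueError, match=">=2"):
            hd_scale(toy_matrix, [toy_matrix.index[0]])


class TestGlobalSeverity:
    def test_two_patient_hand_computation(self):
        out = pd.DataFrame(
            {
                "brain_damage_severity": [0.0, 1.0],
                "combiwise_severity": [0.0, 1.0],
                "msdss": [0.0, 1.0],
            },
            index=["a", "b"],
        )
        sev = global_severity(out)
        # each z = +/- 1/sqrt(2) with ddof=1; summed over three outcomes
        assert sev["a"] == pytest.approx(-3 / np.sqrt(2), abs=1e-9)
        assert sev["b"] == pytest.approx(+3 / np.sqrt(2), abs=1e-9)

    def test_cohort_mean_zero_and_order_invariance(self):
        rng = np.random.default_rng(1)
        out = pd.DataFrame(
            rng.normal(size=(12, 3)),
            columns=["brain_damage_severity", "combiwise_severity", "msdss"],
            index=[f"p{i}" for i in range(12)],
        )
        sev = global_severity(out)
        assert sev.mean() == pytest.approx(0.0, abs=1e-12)
        shuffled = global_severity(out.sample(frac=1, random_state=0))
        pd.testing.assert_series_equal(sev.sort_index(), shuffled.sort_index())

    def test_constant_outcome_rejected(self):
        out = pd.DataFrame(
            {
                "brain_damage_severity": [1.0, 1.0, 1.0],
                "combiwise_severity": [0.0, 1.0, 2.0],
                "msdss": [0.0, 1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="constant"):
            global_severity(out)


class TestSelection:
    def test_disjoint_pathway_rejected(self, toy_matrix):
        scaled = hd_scale(toy_matrix, list(toy_matrix.index[:4]))
        pathway = PathwaySpec.from_directions({"NOPE1": 1, "NOPE2": -1})
        sev = pd.Series(np.arange(8, dtype=float), index=toy_matrix.index)
        with pytest.raises(ValueError, match="not represented"):
            select_score_proteins(scaled, sev, pathway)

    def test_needs_ten_ms_samples(self, toy_matrix):
        scaled = hd_scale(toy_matrix, list(toy_matrix.index[:4]))
        pathway = PathwaySpec.from_directions({"P1": 1})
        sev = pd.Series([1.0, 2.0], index=toy_matrix.index[:2])
        with pytest.raises(ValueError, match=">=10"):
            select_score_proteins(scaled, sev, pathway)

    def test_recovers_monotone_association_with_sign(self):
        rng = np.random.default_rng(3)
        n = 40
        sev = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        up = sev + rng.normal(0, 0.1, n)
        down = -sev + rng.normal(0, 0.1, n)
        noise = pd.Series(rng.normal(size=n), index=sev.index)
        scaled = pd.DataFrame({"UP": up, "DOWN": down, "NOISE": noise})
        pathway = PathwaySpec.from_directions({"UP": 1, "DOWN": -1, "NOISE": 1})
        w = select_score_proteins(scaled, sev, pathway, alpha=1e-4)
        assert set(w.proteins) == {"UP", "DOWN"}
        assert w.rho["UP"] > 0 > w.rho["DOWN"]


class TestScore:
    def test_hand_dot_product(self):
        sample = pd.Series({"A": 1.0, "B": -1.0, "C": 2.0}, name="s1")
        w = weights_of({"A": 0.5, "B": 0.4, "C": -0.25})
        res = pyroptosis_score(sample, w)
        assert res.score == pytest.approx(0.5 - 0.4 - 0.5)
        assert res.score == pytest.approx(res.contributions.sum())

    def test_zero_levels_zero_score_and_linearity(self):
        w = weights_of({"A": 0.3, "B": -0.6})
        zero = pd.Series({"A": 0.0, "B": 0.0}, name="z")
        assert pyroptosis_score(zero, w).score == 0.0
        s = pd.Series({"A": 1.5, "B": 2.0}, name="s")
        assert pyroptosis_score(2 * s, w).score == pytest.approx(
            2 * pyroptosis_score(s, w).score
        )

    def test_missing_protein_is_an_error(self):
        w = weights_of({"A": 0.3, "B": -0.6})
        with pytest.raises(ValueError, match="missing"):
            pyroptosis_score(pd.Series({"A": 1.0}, name="s"), w)

    def test_score_samples_matches_per_sample_scores(self, toy_matrix):
        scaled = hd_scale(toy_matrix, list(toy_matrix.index[:4]))
        w = weights_of({"P1": 0.5, "P3": -0.2})
        table = score_samples(scaled, w)
        for sid in scaled.index:
            assert table.loc[sid, "score"] == pytest.approx(
                pyroptosis_score(scaled.loc[sid], w).score
            )


class TestYearlyChange:
    def test_arithmetic(self):
        assert yearly_score_change(1.0, "2020-01-01", 1.0, "2021-01-01") == 0.0
        half_year = yearly_score_change(0.0, "2020-01-01", 1.0, "2020-07-01")
        assert half_year == pytest.approx(1.0 / (182 / 365.25))
        one_year = yearly_score_change(1.0, "2020-03-01", 1.41, "2021-03-01")
        assert one_year == pytest.approx(0.41 / (365 / 365.25))

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError, match="postdate"):
            yearly_score_change(0.0, "2020-06-01", 1.0, "2020-06-01")


class TestChangeAnalysis:
    @staticmethod
    def _paired(rng, n_pairs, n_proteins, shift=0.0):
        idx = [f"p{i}" for i in range(n_pairs)]
        cols = [f"P{i}" for i in range(n_proteins)]
        base = pd.DataFrame(rng.normal(size=(n_pairs, n_proteins)), index=idx, columns=cols)
        ther = base + shift + rng.normal(size=(n_pairs, n_proteins))
        return base, ther

    def test_identical_shift_yields_min_exact_p(self):
        base = pd.DataFrame(np.zeros((9, 3)), columns=["A", "B", "C"])
        ther = base.copy()
        ther["A"] += 1.0  # identical +1 change in all 9 pairs
        table = change_analysis(base, ther)
        assert table.loc["A", "wilcoxon_p"] == pytest.approx(2 / 512, abs=1e-12)
        assert not table.loc["B", "wilcoxon_defined"]
        assert table.loc["B", "wilcoxon_p"] == 1.0

    def test_extreme_flag_rate_near_normal_tail(self):
        rng = np.random.default_rng(8)
        base, ther = self._paired(rng, 9, 4000)
        table = change_analysis(base, ther)
        rate = table["extreme"].mean()
        assert 0.03 < rate < 0.065  # ~4.6% for a normal tail beyond 2 SD

    def test_mean_change_recovers_planted_shift(self):
        rng = np.random.default_rng(9)
        base, ther = self._paired(rng, 20, 50, shift=0.8)
        table = change_analysis(base, ther)
        assert table["mean_change"].mean() == pytest.approx(0.8, abs=0.1)

    def test_requires_three_pairs(self):
        base = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match=">=3"):
            change_analysis(base, base)

    def test_extreme_gene_list_maps_ids(self):
        base = pd.DataFrame(np.zeros((9, 3)), columns=["p1", "p2", "p3"])
        ther = base.copy()
        ther["p2"] += 5.0
        table = change_analysis(base, ther)
        table.loc["p2", "extreme"] = True  # 3 proteins cannot flag by z alone
        gene_map = pd.Series({"p1": "G1", "p2": "G2", "p3": "G3"})
        assert extreme_gene_list(table, gene_map) == ["G2"]


class TestGroupCompare:
    def test_identical_groups_p_near_one(self):
        scores = pd.Series(
            np.tile([1.0, 2.0, 3.0, 4.0], 3), index=[f"s{i}" for i in range(12)]
        )
        diag = pd.Series(
            ["HD"] * 4 + ["RRMS"] * 4 + ["progMS"] * 4, index=scores.index
        )
        res = group_compare(scores, diag)
        assert res["prog_vs_rrms"]["pvalue"] > 0.9

    def test_monotone_shift_detected(self):
        rng = np.random.default_rng(10)
        scores = pd.Series(
            np.concatenate(
                [rng.normal(0, 1, 30), rng.normal(2, 1, 30), rng.normal(4, 1, 30)]
            ),
            index=[f"s{i}" for i in range(90)],
        )
        diag = pd.Series(
            ["HD"] * 30 + ["RRMS"] * 30 + ["progMS"] * 30, index=scores.index
        )
        res = group_compare(scores, diag)
        assert res["ms_vs_hd"]["pvalue"] < 1e-6
        assert res["prog_vs_rrms"]["pvalue"] < 1e-4

    def test_perfect_monotone_severity_correlation(self):
        n = 20
        scores = pd.Series(
            np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)]
        )
        diag = pd.Series(["RRMS"] * (n // 2) + ["progMS"] * (n // 2), index=scores.index)
        diag = pd.concat([diag, pd.Series(["HD", "HD"], index=["h0", "h1"])])
        scores = pd.concat([scores, pd.Series([0.0, 1.0], index=["h0", "h1"])])
        patients = pd.Series(scores.index, index=scores.index)
        outcomes = pd.DataFrame(
            {
                "brain_damage_severity": scores,
                "combiwise_severity": scores,
                "msdss": scores,
            },
            index=scores.index,
        )
        res = group_compare(
            scores, diag, severity_outcomes=outcomes, patient_of_sample=patients
        )
        assert res["score_vs_brain_damage"]["rho"] == pytest.approx(1.0)
        assert res["score_vs_msdss"]["rho"] == pytest.approx(1.0)
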