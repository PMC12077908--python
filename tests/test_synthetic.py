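"""Tests of the synthetic-data generators: determinism, planted structure,
and null calibration."""

import numpy as np
import pandas as pd
import pytest

from pyroscore import (
    SimulationConfig,
    evaluate_patient,
    fit_visit_slope,
    generate_cell_matrix,
    generate_expression_summaries,
    generate_proteomics,
    generate_trajectories,
    global_severity,
    hd_scale,
    score_cell_types,
    select_score_proteins,
)


def ms_severity_by_sample(sim):
    meta = sim.dataset.samples
    ms = meta[(meta["visit_role"] == "baseline") & (meta["diagnosis"] != "HD")]
    sev = global_severity(sim.outcomes)
    return pd.Series(sev.loc[ms["patient_id"]].to_numpy(), index=ms.index)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="n_informative"):
            SimulationConfig(n_informative=20, n_pathway=10)
        with pytest.raises(ValueError, match=">= 0"):
            SimulationConfig(visit_noise_sd=-1)

    def test_zero_hd_rejected_by_proteomics_generator(self):
        cfg = SimulationConfig(n_hd=0, n_proteins=50, n_pathway=5, n_informative=2)
        with pytest.raises(ValueError, match="healthy-donor"):
            generate_proteomics(cfg)


class TestDeterminism:
    def test_proteomics_bitwise_identical(self, small_cfg):
        a = generate_proteomics(small_cfg)
        b = generate_proteomics(small_cfg)
        pd.testing.assert_frame_equal(a.dataset.abundance, b.dataset.abundance)
        assert a.truth["informative_proteins"] == b.truth["informative_proteins"]

    def test_trajectories_and_expression_identical(self, small_cfg):
        ta, tb = generate_trajectories(small_cfg), generate_trajectories(small_cfg)
        for x, y in zip(ta.trajectories, tb.trajectories):
            pd.testing.assert_frame_equal(x.visits, y.visits)
        ea, eb = generate_expression_summaries(small_cfg), generate_expression_summaries(small_cfg)
        pd.testing.assert_frame_equal(ea.summary, eb.summary)

    def test_different_seeds_differ(self, small_cfg):
        import dataclasses

        other = dataclasses.replace(small_cfg, seed=small_cfg.seed + 1)
        a = generate_proteomics(small_cfg).dataset.abundance
        b = generate_proteomics(other).dataset.abundance
        assert not np.allclose(a.to_numpy(), b.to_numpy())


class TestProteomicsStructure:
    def test_planted_proteins_recovered(self, small_cfg):
        sim = generate_proteomics(small_cfg)
        scaled = hd_scale(sim.dataset)
        sev = ms_severity_by_sample(sim)
        w = select_score_proteins(
            scaled, sev, sim.pathway, gene_map=sim.dataset.proteins["gene"]
        )
        truth = set(sim.truth["informative_proteins"])
        assert len(truth & set(w.proteins)) >= 9
        for pid, d in sim.truth["informative_directions"].items():
            if pid in w.proteins:
                assert np.sign(w.rho[pid]) == d

    def test_null_config_selection_near_alpha(self):
        # no informative proteins: ~alpha of 50 pathway proteins selected
        hits, total = 0, 0
        for seed in range(15):
            cfg = SimulationConfig(
                seed=seed, n_proteins=100, n_pathway=50, n_informative=0,
                n_hd=15, n_rrms=30, n_prog=30, n_treated=0, effect_size=0.0,
            )
            sim = generate_proteomics(cfg)
            scaled = hd_scale(sim.dataset)
            sev = ms_severity_by_sample(sim)
            try:
                w = select_score_proteins(
                    scaled, sev, sim.pathway, gene_map=sim.dataset.proteins["gene"]
                )
                hits += len(w.proteins)
            except ValueError:
                pass  # no selection at all is a valid null outcome
            total += 50
        rate = hits / total
        assert 0.01 < rate < 0.12  # ~5% under the null, binomial slack

    def test_group_shift_visible_in_latent_severity(self, small_cfg):
        sim = generate_proteomics(small_cfg)
        sev = sim.truth["latent_severity"]
        meta = sim.dataset.samples.drop_duplicates("patient_id").set_index("patient_id")
        rr = sev[meta["diagnosis"] == "RRMS"].mean()
        pr = sev[meta["diagnosis"] == "progMS"].mean()
        assert pr > rr


class TestTrajectories:
    def test_noiseless_slopes_exact(self):
        cfg = SimulationConfig(
            seed=3, n_patients=4, visit_noise_sd=0.0,
            baseline_slope_mean=1.0, baseline_slope_sd=0.0,
            therapy_slope_multiplier=6.0,
        )
        sim = generate_trajectories(cfg)
        for traj in sim.trajectories:
            base = fit_visit_slope(traj.pre_therapy)
            ther = fit_visit_slope(traj.on_therapy)
            assert base.slope == pytest.approx(1.0, abs=1e-9)
            assert ther.slope == pytest.approx(6.0, abs=1e-9)

    def test_minimum_visits_enforced(self):
        with pytest.raises(ValueError, match="n_visits"):
            generate_trajectories(SimulationConfig(n_visits=1))

    def test_null_false_trigger_rate_small(self):
        cfg = SimulationConfig(seed=4, n_patients=400, therapy_slope_multiplier=1.0)
        sim = generate_trajectories(cfg)
        triggered = total = 0
        for traj in sim.trajectories:
            from pyroscore import check_eligibility

            if not check_eligibility(traj).eligible:
                continue
            d = evaluate_patient(traj)
            if d is None:
                continue
            total += 1
            triggered += d.triggered
        assert total > 100
        assert triggered / total < 0.1  # far below the 33% arm-stop fraction

    def test_arm_stop_fires_with_three_planted_toxic_patients(self):
        from pyroscore import evaluate_arm

        mult = [6.0, 6.0, 6.0] + [1.0] * 6
        cfg = SimulationConfig(
            seed=5, n_patients=9, visit_noise_sd=0.0,
            baseline_slope_mean=1.0, baseline_slope_sd=0.1,
            therapy_slope_multiplier=mult,
        )
        sim = generate_trajectories(cfg)
        decisions = [evaluate_patient(t) for t in sim.trajectories]
        arm = evaluate_arm(decisions)
        assert arm.stopped and arm.n_triggered == 3
        assert arm.fraction_triggered == pytest.approx(1 / 3)

    def test_lesion_counts_follow_configured_rate(self):
        cfg = SimulationConfig(
            seed=6, n_patients=300, lesion_rate_per_year=2.0, visit_noise_sd=0.0
        )
        sim = generate_trajectories(cfg)
        rates = [
            float(t.visits["lesions"].iloc[1:].sum())
            / ((t.visits["date"].iloc[-1] - t.visits["date"].iloc[0]).days / 365.25)
            for t in sim.trajectories
        ]
        assert np.mean(rates) == pytest.approx(2.0, rel=0.1)


class TestExpression:
    def test_planted_outliers_exactly_excluded_at_large_displacement(self):
        # low noise and a large displacement: every block should exclude the
        # planted genes and nothing else
        cfg = SimulationConfig(
            seed=7, n_outlier_genes=2, activation_offsets={},
            expression_noise_sd=0.02, outlier_sd_multiplier=30.0,
        )
        sim = generate_expression_summaries(cfg)
        _, exclusions = score_cell_types(sim.summary, sim.pathway)
        planted = set(sim.truth["outlier_genes"])
        assert len(exclusions) > 0
        for (_, _), block in exclusions.groupby(["group", "cell_type"]):
            assert set(block["gene"]) == planted

    def test_null_offsets_centered_at_zero(self):
        diffs = []
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, activation_offsets={}, n_outlier_genes=0
            )
            sim = generate_expression_summaries(cfg)
            scores, _ = score_cell_types(sim.summary, sim.pathway)
            pivot = scores.pivot(index="cell_type", columns="group", values="tppas")
            diffs.append((pivot["MS"] - pivot["control"]).mean())
        mean = np.mean(diffs)
        sd = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean) < 4 * sd + 1e-9

    def test_planted_activation_raises_ms_score(self):
        wins = 0
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, n_outlier_genes=0)
            sim = generate_expression_summaries(cfg)
            scores, _ = score_cell_types(sim.summary, sim.pathway)
            pivot = scores.pivot(index="cell_type", columns="group", values="tppas")
            if pivot.loc["microglia_macrophage", "MS"] > pivot.loc["microglia_macrophage", "control"]:
                wins += 1
        assert wins >= 38  # >= 95% of seeds

    def test_empty_cell_type_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_expression_summaries(SimulationConfig(cell_types=()))


class TestCellMatrix:
    def test_shapes_and_qc_frame(self, small_cfg):
        counts, genes, cell_types, lesion_types, qc = generate_cell_matrix(
            small_cfg, n_cells=120
        )
        assert counts.shape == (120, small_cfg.n_pathway_genes)
        assert len(genes) == small_cfg.n_pathway_genes
        assert len(cell_types) == len(lesion_types) == 120
        assert {"mito_fraction", "umi"} <= set(qc.columns)
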