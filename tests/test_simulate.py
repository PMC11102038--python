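"""Synthetic-data generators: determinism, thinning, ground truth."""
from __future__ import annotations

import io
import math

import numpy as np
import pytest
from pydantic import ValidationError

from adrquant.disproportionality import ror
from adrquant.errors import ConfigError
from adrquant.records import write_prescriptions_csv, write_reports_jsonl
from adrquant.simulate import (
    PlantedTarget,
    SimConfig,
    generate_ade_reports,
    generate_expert_grades,
    generate_prescriptions,
    generate_target_map,
    ground_truth,
)
from adrquant.vocab import SERIOUS_OUTCOMES, Grade


def one_pair_config(**kw) -> SimConfig:
    defaults = dict(
        n_drugs=1,
        n_adrs=1,
        n_patients_per_drug_year=10_000,
        years=[2012],
        incidence_matrix=[[0.01]],
        outcome_profile=[0.2, 0.2, 0.2, 0.2, 0.2],
        nonprofessional_fraction=0.0,
        excluded_soc_fraction=0.0,
        multi_ingredient_fraction=0.0,
        missing_outcome_fraction=0.0,
        seed=7,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestReportGeneration:
    def test_zero_incidence_means_zero_reports(self):
        cfg = one_pair_config(incidence_matrix=[[0.0]])
        reports, _ = generate_ade_reports(cfg)
        assert reports == []

    def test_empty_config_gives_explicit_empty_output(self):
        cfg = SimConfig(n_drugs=0, n_adrs=0, years=[])
        reports, truth = generate_ade_reports(cfg)
        assert reports == [] and truth.true_incidence == {}

    def test_report_count_matches_binomial_expectation_full_reporting(self):
        cfg = one_pair_config(reporting_rate_serious=1.0, reporting_rate_other=1.0)
        reports, _ = generate_ade_reports(cfg)
        sd = math.sqrt(10_000 * 0.01 * 0.99)
        assert abs(len(reports) - 100) <= 3 * sd

    def test_report_count_thinned_at_six_percent(self):
        cfg = one_pair_config(
            reporting_rate_serious=0.06, reporting_rate_other=0.06
        )
        reports, _ = generate_ade_reports(cfg)
        p = 0.01 * 0.06
        sd = math.sqrt(10_000 * p * (1 - p))
        assert abs(len(reports) - 6) <= 3 * sd

    def test_thinning_rates_per_severity_stratum(self):
        cfg = one_pair_config(
            n_patients_per_drug_year=100_000,
            incidence_matrix=[[0.02]],
            years=[2012, 2013],
            seed=3,
        )
        reports, truth = generate_ade_reports(cfg)
        serious = sum(
            1 for r in reports if r.adrs[0].outcome in SERIOUS_OUTCOMES
        )
        other = len(reports) - serious
        for observed, n_events, rate in [
            (serious, truth.n_events_serious, cfg.reporting_rate_serious),
            (other, truth.n_events_other, cfg.reporting_rate_other),
        ]:
            sd = math.sqrt(n_events * rate * (1 - rate))
            assert abs(observed - n_events * rate) <= 3 * sd

    def test_identical_seed_identical_bytes(self):
        cfg = SimConfig(n_drugs=3, n_adrs=4, n_patients_per_drug_year=2000,
                        years=[2012, 2013], seed=11)
        outs = []
        for _ in range(2):
            reports, _ = generate_ade_reports(cfg)
            buf = io.StringIO()
            for r in reports:
                buf.write(r.model_dump_json())
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_ground_truth_covers_every_drug_and_pair(self):
        cfg = SimConfig(n_drugs=3, n_adrs=4, seed=1)
        truth = ground_truth(cfg)
        assert set(truth.true_incidence) == {"D000", "D001", "D002"}
        for d in truth.true_incidence:
            assert len(truth.true_incidence[d]) == 4
            assert len(truth.true_outcome_profile[d]) == 4
        assert set(truth.true_annual_prescriptions) == set(truth.true_incidence)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(reporting_rate_other=1.5)
        with pytest.raises(ValidationError):
            SimConfig(n_drugs=1, n_adrs=1, incidence_matrix=[[1.2]])
        with pytest.raises(ValidationError):
            SimConfig(n_drugs=1, n_adrs=1, outcome_profile=[0.5, 0.5, 0.5, 0, 0])


class TestPrescriptionGeneration:
    def test_weight_sum_per_drug_year_equals_true_volume(self):
        cfg = SimConfig(n_drugs=2, n_adrs=1, n_patients_per_drug_year=12_000,
                        years=[2012, 2013], seed=5)
        df = generate_prescriptions(cfg)
        sums = df.groupby("year")["person_weight"].sum()
        for year in cfg.years:
            # both drugs' shares: 2 x 12,000 per year
            assert sums[year] == pytest.approx(24_000, rel=1e-9)

    def test_byte_identical_csv_on_rerun(self, tmp_path):
        cfg = SimConfig(n_drugs=2, n_adrs=1, years=[2012], seed=9)
        blobs = []
        for i in range(2):
            path = tmp_path / f"p{i}.csv"
            write_prescriptions_csv(generate_prescriptions(cfg), path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_name_noise_toggle(self):
        noisy = generate_prescriptions(
            SimConfig(n_drugs=5, n_adrs=1, years=[2012, 2013], seed=2, name_noise=True)
        )
        clean = generate_prescriptions(
            SimConfig(n_drugs=5, n_adrs=1, years=[2012, 2013], seed=2, name_noise=False)
        )
        assert noisy["raw_name"].str.contains("mg|solution|capsules|tablets").any()
        assert not clean["raw_name"].str.contains("mg|solution").any()


class TestExpertGrades:
    MODEL = {f"PT{i:03d}": {Grade.MILD, Grade.MODERATE} for i in range(100)}

    def test_pure_subset_fraction_gives_subsets(self):
        cfg = SimConfig(expert_fractions=(1.0, 0.0, 0.0), seed=1)
        table = generate_expert_grades(cfg, self.MODEL)
        assert len(table) == 100
        assert all(table[pt] <= self.MODEL[pt] for pt in table)

    def test_pure_disjoint_fraction_gives_disjoint(self):
        cfg = SimConfig(expert_fractions=(0.0, 0.0, 1.0), seed=1)
        table = generate_expert_grades(cfg, self.MODEL)
        assert all(not (table[pt] & self.MODEL[pt]) for pt in table)

    def test_largest_remainder_allocation_is_exact(self):
        cfg = SimConfig(expert_fractions=(0.5, 0.3, 0.2), seed=1)
        table = generate_expert_grades(cfg, self.MODEL)
        states = {"subset": 0, "overlap": 0, "disjoint": 0}
        for pt, expert in table.items():
            model = self.MODEL[pt]
            if expert <= model:
                states["subset"] += 1
            elif expert & model:
                states["overlap"] += 1
            else:
                states["disjoint"] += 1
        assert states == {"subset": 50, "overlap": 30, "disjoint": 20}

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(expert_fractions=(0.8, 0.3, 0.2))

    def test_full_grade_sets_claim_subset_quota(self):
        model = {"PTX": set(Grade)}
        cfg = SimConfig(expert_fractions=(0.0, 1.0, 0.0), seed=1)
        with pytest.raises(ConfigError):
            generate_expert_grades(cfg, model)


class TestTargetMap:
    def test_zero_targets_per_drug_gives_empty_map(self):
        assert generate_target_map(SimConfig(max_targets_per_drug=0)) == {}

    def test_every_drug_gets_one_to_k_targets(self):
        cfg = SimConfig(n_drugs=30, n_targets=20, max_targets_per_drug=4, seed=2)
        tm = generate_target_map(cfg)
        assert set(tm) == set(f"D{i:03d}" for i in range(30))
        assert all(1 <= len(ts) <= 4 for ts in tm.values())

    def test_planted_or_must_be_positive(self):
        with pytest.raises(ValidationError):
            PlantedTarget(carrier_drugs=set(), odds_ratio=0.0)

    @staticmethod
    def _drug_level_or(tm, carriers, target_id):
        a = sum(1 for d, ts in tm.items() if d in carriers and target_id in ts)
        b = sum(1 for d, ts in tm.items() if d not in carriers and target_id in ts)
        c = sum(1 for d, ts in tm.items() if d in carriers and target_id not in ts)
        d_ = sum(1 for d, ts in tm.items() if d not in carriers and target_id not in ts)
        return ror((a, b, c, d_))

    def test_null_plant_estimates_near_one(self):
        drugs = [f"D{i:03d}" for i in range(200)]
        carriers = set(drugs[:100])
        covered = 0
        for seed in range(10):
            cfg = SimConfig(n_drugs=200, seed=seed)
            tm = generate_target_map(
                cfg,
                planted=PlantedTarget(carrier_drugs=carriers, odds_ratio=1.0),
            )
            res = self._drug_level_or(tm, carriers, "T_PLANT")
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 8

    def test_planted_or_five_recovered_within_ci(self):
        drugs = [f"D{i:03d}" for i in range(200)]
        carriers = set(drugs[:100])
        covered = 0
        for seed in range(20):
            cfg = SimConfig(n_drugs=200, seed=seed)
            tm = generate_target_map(
                cfg,
                planted=PlantedTarget(carrier_drugs=carriers, odds_ratio=5.0),
            )
            res = self._drug_level_or(tm, carriers, "T_PLANT")
            covered += res.ci_low <= 5.0 <= res.ci_high
        assert covered >= 16
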