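import numpy as np
import pandas as pd
import pytest

from specstarch.errors import DataError, SchemeError
from specstarch.evaluation import (
    build_cv_scheme,
    compute_metrics,
    grouped_split,
    run_cv_schemes,
    verify_plan,
    within_trial_evaluate,
)
from specstarch.spectra_io import average_scans
from specstarch.synthetic import SimulationConfig, simulate_reference, simulate_spectra


class TestGroupedSplit:
    def test_seven_three_split(self):
        ids = [f"s{i}" for i in range(10)]
        groups = [f"g{i}" for i in range(10)]
        plan = grouped_split(ids, groups, 0.7, seed=0)
        assert len(plan.train_ids) == 7 and len(plan.test_ids) == 3

    def test_replicates_stay_together(self):
        ids = [f"s{i}" for i in range(30)]
        groups = np.repeat([f"g{i}" for i in range(10)], 3)
        for seed in range(20):
            plan = grouped_split(ids, groups, 0.7, seed=seed)
            train_groups = {groups[int(s[1:])] for s in plan.train_ids}
            test_groups = {groups[int(s[1:])] for s in plan.test_ids}
            assert not train_groups & test_groups

    def test_many_seeds_give_distinct_plans_near_fraction(self):
        ids = [f"s{i}" for i in range(40)]
        groups = ids
        plans = [grouped_split(ids, groups, 0.7, seed=s) for s in range(50)]
        test_sets = {frozenset(p.test_ids) for p in plans}
        assert len(test_sets) > 45
        fractions = [len(p.test_ids) / 40 for p in plans]
        assert np.mean(fractions) == pytest.approx(0.3, abs=0.01)

    def test_single_group_rejected(self):
        with pytest.raises(SchemeError):
            grouped_split(["a", "b"], ["g", "g"], 0.7, seed=0)


class TestMetrics:
    def test_perfect_agreement(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(obs, obs)
        assert m["r2p"] == pytest.approx(1.0)
        assert m["rmsep"] == 0.0 and m["bias"] == 0.0
        assert m["ccc"] == pytest.approx(1.0)
        assert np.isnan(m["rpd"]) and np.isnan(m["rpiq"])

    def test_location_shift_penalizes_ccc_not_r2(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(obs, obs + 2.0)
        assert m["r2p"] == pytest.approx(1.0)
        assert m["ccc"] < 1.0
        assert m["bias"] == pytest.approx(2.0)

    def test_four_point_hand_oracle(self):
        # frozen values computed by exact rational arithmetic
        m = compute_metrics([1.0, 2.0, 3.0, 4.0], [1.1, 1.9, 3.2, 3.8])
        assert m["bias"] == pytest.approx(0.0, abs=1e-10)
        assert m["rmsep"] == pytest.approx(np.sqrt(0.025), abs=1e-10)
        assert m["sep"] == pytest.approx(np.sqrt(1.0 / 30.0), abs=1e-10)
        assert m["rpd"] == pytest.approx(np.sqrt(5.0 / 3.0) / np.sqrt(0.025), abs=1e-10)
        assert m["rpiq"] == pytest.approx(1.5 / np.sqrt(0.025), abs=1e-10)
        assert m["ccc"] == pytest.approx(94.0 / 95.0, abs=1e-10)
        assert m["r2p"] == pytest.approx(2209.0 / 2250.0, abs=1e-10)

    def test_rpiq_over_rpd_is_iqr_over_sd(self, rng):
        obs = rng.normal(size=50)
        pred = obs + rng.normal(size=50) * 0.3
        m = compute_metrics(obs, pred)
        q1, q3 = np.percentile(obs, [25, 75])
        assert m["rpiq"] / m["rpd"] == pytest.approx((q3 - q1) / np.std(obs, ddof=1),
                                                     abs=1e-12)

    def test_ccc_bounded_by_abs_r(self, rng):
        for _ in range(200):
            obs = rng.normal(size=10)
            pred = rng.normal(size=10)
            if np.std(pred) == 0:
                continue
            m = compute_metrics(obs, pred)
            r = abs(np.corrcoef(obs, pred)[0, 1])
            assert m["ccc"] <= r + 1e-12

    def test_error_conditions(self):
        with pytest.raises(DataError):
            compute_metrics([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataError):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(DataError):
            compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def four_trial_data():
    config = SimulationConfig(n_trials=4, genotypes_per_trial=20,
                              shared_genotype_fraction=0.3, seed=11)
    reference = simulate_reference(config)
    spectra = average_scans(simulate_spectra(reference, config))
    return spectra, reference


class TestSchemes:
    def test_cv0_definition(self, four_trial_data):
        _, reference = four_trial_data
        (plan,) = build_cv_scheme("CV0", reference, "T01", seed=0)
        focal = reference.data[reference.data["trial_id"] == "T01"]
        rest = reference.data[reference.data["trial_id"] != "T01"]
        assert set(plan.test_ids) == set(focal["sample_id"])
        assert set(plan.train_ids) == set(rest["sample_id"])

    def test_cv00_excludes_shared_genotypes(self, four_trial_data):
        _, reference = four_trial_data
        (plan,) = build_cv_scheme("CV00", reference, "T01", seed=0)
        ref = reference.data.set_index("sample_id")
        g_train = set(ref.loc[plan.train_ids, "genotype_id"])
        g_test = set(ref.loc[plan.test_ids, "genotype_id"])
        assert not g_train & g_test
        # the design shares genotypes, so CV00 must be a strict subset of CV0
        (cv0,) = build_cv_scheme("CV0", reference, "T01", seed=0)
        assert set(plan.train_ids) < set(cv0.train_ids)

    def test_cv1_cv2_share_test_sets(self, four_trial_data):
        _, reference = four_trial_data
        cv2 = build_cv_scheme("CV2", reference, "T02", seed=3, niter=5)
        cv1 = build_cv_scheme("CV1", reference, "T02", seed=3, niter=5)
        for a, b in zip(cv2, cv1):
            assert set(a.test_ids) == set(b.test_ids)
            assert set(b.train_ids) <= set(a.train_ids)

    def test_all_plans_verify(self, four_trial_data):
        _, reference = four_trial_data
        for scheme in ("CV2", "CV1", "CV0", "CV00"):
            niter = 1 if scheme in ("CV0", "CV00") else 3
            for trial in reference.trials:
                for plan in build_cv_scheme(scheme, reference, trial, seed=1, niter=niter):
                    verify_plan(plan, reference)

    def test_missing_focal_trial(self, four_trial_data):
        _, reference = four_trial_data
        with pytest.raises(SchemeError):
            build_cv_scheme("CV2", reference, "T99", seed=0)

    def test_single_trial_rejected(self, tiny_reference):
        with pytest.raises(SchemeError):
            build_cv_scheme("CV0", tiny_reference, "T", seed=0)


class TestWithinTrial:
    def test_deterministic(self, four_trial_data):
        spectra, reference = four_trial_data
        a = within_trial_evaluate(spectra, reference, "RAW", "PLSR", niter=3, seed=5)
        b = within_trial_evaluate(spectra, reference, "RAW", "PLSR", niter=3, seed=5)
        assert a.per_iteration.equals(b.per_iteration)

    def test_aggregate_shape(self, four_trial_data):
        spectra, reference = four_trial_data
        result = within_trial_evaluate(spectra, reference, "SNV", "PLSR", niter=3, seed=2)
        assert len(result.per_iteration) == 3
        assert {"mean", "std"} == set(result.aggregate.index)
        assert result.aggregate.loc["mean", "r2p"] > 0.5


class TestRunCvSchemes:
    def test_information_ordering_and_determinism(self, four_trial_data):
        spectra, reference = four_trial_data
        table = run_cv_schemes(spectra, reference, ("SNV",), ("PLSR",),
                               schemes=("CV2", "CV00"), niter=3, seed=5)
        means = table.groupby("scheme")["r2p"].mean()
        assert means["CV2"] >= means["CV00"]
        again = run_cv_schemes(spectra, reference, ("SNV",), ("PLSR",),
                               schemes=("CV2", "CV00"), niter=3, seed=5)
        pd.testing.assert_frame_equal(table, again)

    def test_single_trial_rejected(self, tiny_reference, four_trial_data):
        spectra, _ = four_trial_data
        with pytest.raises(SchemeError):
            run_cv_schemes(spectra, tiny_reference)
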