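"""Greedy Monte-Carlo refinement, cross-validation and evaluation statistics."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

import ppaffinity as ppa
from ppaffinity.errors import DegenerateDataError, PPAffinityError
from ppaffinity.refine import adjust_predictions


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert ppa.pearson(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert ppa.pearson(x, -x + 7.0) == pytest.approx(-1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert ppa.pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            ppa.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_raises(self):
        with pytest.raises(DegenerateDataError):
            ppa.pearson([1.0], [2.0])


class TestMCRefine:
    def test_planted_weights_are_a_fixed_point(self, tiny_synth):
        # starting at the optimum, every greedy proposal is rejected
        config = ppa.MCConfig(seed=1, max_steps=2000, stall_window=500)
        result = ppa.mc_refine(tiny_synth.dataset, config, init=tiny_synth.planted)
        assert result.trace[0] == pytest.approx(1.0, abs=1e-9)
        assert result.n_accepted == 0
        assert len(result.trace) == 1

    def test_trace_is_nondecreasing_and_final_rho_improves(self, tiny_synth):
        config = ppa.MCConfig(seed=2, max_steps=5000, stall_window=5000)
        result = ppa.mc_refine(tiny_synth.dataset, config)
        assert np.all(np.diff(result.trace) >= 0.0)
        assert result.rho >= result.trace[0]

    def test_bit_reproducible_for_same_seed(self, tiny_synth):
        config = ppa.MCConfig(seed=3, max_steps=3000, stall_window=3000)
        a = ppa.mc_refine(tiny_synth.dataset, config)
        b = ppa.mc_refine(tiny_synth.dataset, config)
        np.testing.assert_array_equal(a.weights.as_flat(), b.weights.as_flat())
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_incremental_rho_matches_full_recomputation(self, tiny_synth):
        config = ppa.MCConfig(seed=4, max_steps=3000, stall_window=3000,
                              validate_incremental=True)
        result = ppa.mc_refine(tiny_synth.dataset, config)
        assert result.n_accepted > 0
        assert result.max_incremental_error < 1e-10

    def test_degenerate_affinities_raise(self, tiny_synth):
        import copy

        ds = copy.deepcopy(tiny_synth.dataset)
        for rec in ds.records:
            rec.dg_exp = -10.0
        with pytest.raises(DegenerateDataError):
            ppa.mc_refine(ds, ppa.MCConfig(seed=0, max_steps=10, stall_window=10))


class TestAdjustPredictions:
    def test_moment_matching(self):
        rng = np.random.default_rng(1)
        calc = rng.normal(5.0, 2.0, 50)
        exp = rng.normal(-10.0, 3.0, 50)
        adjusted = adjust_predictions(calc, calc, exp)
        assert adjusted.mean() == pytest.approx(exp.mean())
        assert adjusted.std() == pytest.approx(exp.std())

    def test_identity_when_moments_match(self):
        exp = np.array([-12.0, -10.0, -8.0, -9.0])
        out = adjust_predictions(exp, exp, exp)
        np.testing.assert_allclose(out, exp, atol=1e-12)

    def test_matches_affine_oracle(self):
        rng = np.random.default_rng(2)
        test = rng.normal(size=7)
        calc = rng.normal(size=30)
        exp = rng.normal(size=30)
        expected = exp.mean() + (test - calc.mean()) * exp.std() / calc.std()
        np.testing.assert_allclose(adjust_predictions(test, calc, exp), expected, atol=1e-12)

    def test_zero_sd_raises(self):
        with pytest.raises(DegenerateDataError):
            adjust_predictions([1.0], [2.0, 2.0], [1.0, 3.0])


class TestLOOCV:
    def test_bookkeeping_partition(self, tiny_synth):
        config = ppa.MCConfig(seed=5, max_steps=2000, stall_window=2000)
        cv = ppa.run_loocv(tiny_synth.dataset, config)
        assert len(cv.runs) == len(tiny_synth.dataset.families)
        all_test = list(itertools.chain.from_iterable(r.test_indices for r in cv.runs))
        assert sorted(all_test) == list(range(len(tiny_synth.dataset)))
        # a family never contributes to its own refinement
        for run in cv.runs:
            fams = {tiny_synth.dataset.records[i].family_id for i in run.test_indices}
            assert fams == {run.family_id}
        assert np.all(np.isfinite(cv.predictions_adjusted))

    def test_family_test_set_size_is_wildtype_plus_mutants(self, tiny_synth):
        config = ppa.MCConfig(seed=6, max_steps=500, stall_window=500)
        cv = ppa.run_loocv(tiny_synth.dataset, config)
        for run in cv.runs:
            assert len(run.test_indices) == tiny_synth.spec.mutants_per_family + 1

    def test_single_family_raises(self, tiny_synth):
        one_family = tiny_synth.dataset.subset(
            tiny_synth.dataset.families[tiny_synth.dataset.family_ids[0]]
        )
        with pytest.raises(DegenerateDataError):
            ppa.run_loocv(one_family, ppa.MCConfig(seed=0, max_steps=10, stall_window=10))

    def test_repeats_produce_one_rho_each(self, tiny_synth):
        config = ppa.MCConfig(seed=7, max_steps=500, stall_window=500)
        cv = ppa.run_loocv(tiny_synth.dataset, config, repeats=2)
        assert len(cv.repeat_rhos) == 2
        assert cv.repeat_rhos[0] == pytest.approx(cv.pooled_rho)


class TestMutationEffectMetrics:
    def _dataset_from_values(self, exp_by_family):
        """Tiny synthetic dataset whose dg values are overwritten."""
        from ppaffinity.dataset import AffinityDataset, AffinityRecord
        from ppaffinity.model import FeatureVector, Mutation

        records = []
        for fam, values in exp_by_family.items():
            for i, dg in enumerate(values):
                muts = () if i == 0 else (Mutation("A", i, "A", "G"),)
                records.append(AffinityRecord(
                    f"{fam}:{i}", fam, muts, FeatureVector(f"{fam}:{i}"), dg
                ))
        return AffinityDataset(records)

    def test_perfect_predictions_score_one(self):
        ds = self._dataset_from_values({"f1": [-10.0, -12.0, -8.0], "f2": [-9.0, -11.0]})
        preds = [r.dg_exp for r in ds.records]
        m = ppa.mutation_effect_metrics(ds, preds)
        assert (m["sensitivity"], m["specificity"], m["precision"], m["accuracy"]) == (1, 1, 1, 1)

    def test_constructed_confusion_counts(self):
        # wild type at -10; experimental: 4 increase (more negative), 6 decrease
        exp = [-10.0, -12, -11, -13, -11.5, -9, -8, -9.5, -7, -8.5, -9.2]
        # predictions: TP=3, FN=1, TN=5, FP=1
        pred = [-10.0, -12, -11, -13, -9.0, -9, -8, -9.5, -7, -8.5, -11.0]
        ds = self._dataset_from_values({"f": exp})
        m = ppa.mutation_effect_metrics(ds, pred)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (3, 1, 5, 1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_ties_count_as_decrease(self):
        ds = self._dataset_from_values({"f": [-10.0, -12.0, -9.0]})
        preds = [-10.0, -10.0, -10.0]  # zero predicted change for both mutants
        m = ppa.mutation_effect_metrics(ds, preds)
        assert m["tp"] == 0 and m["fn"] == 1 and m["tn"] == 1 and m["fp"] == 0

    def test_random_predictions_on_balanced_labels_are_chance(self):
        rng = np.random.default_rng(8)
        n = 10_000
        exp = [-10.0] + list(-10.0 + np.repeat([-1.0, 1.0], n // 2))
        pred = [-10.0] + list(-10.0 + rng.choice([-1.0, 1.0], n))
        ds = self._dataset_from_values({"f": exp})
        m = ppa.mutation_effect_metrics(ds, pred)
        # within 3 binomial standard deviations of 0.5
        assert abs(m["accuracy"] - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_missing_wildtype_prediction_raises(self):
        ds = self._dataset_from_values({"f": [-10.0, -12.0]})
        with pytest.raises(PPAffinityError):
            ppa.mutation_effect_metrics(ds, [np.nan, -12.0])


class TestPermutationTest:
    def test_perfect_correlation_is_maximally_significant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        p = ppa.permutation_test(x, x, n_perm=1000, seed=0)
        assert p <= 1 / 1000

    def test_length_two_enumeration(self):
        # only two permutations exist; rho is +1 or -1
        p = ppa.permutation_test([0.0, 1.0], [5.0, 9.0], n_perm=2000, seed=1)
        assert p == pytest.approx(0.5, abs=0.05)
        p_anti = ppa.permutation_test([1.0, 0.0], [5.0, 9.0], n_perm=2000, seed=2)
        assert p_anti == pytest.approx(1.0, abs=0.05)

    def test_resolution_floor(self):
        x = np.arange(50.0)
        assert ppa.permutation_test(x, x, n_perm=100, seed=3) >= 1 / 100


class TestWnScan:
    def test_single_value_scan_equals_direct_loocv(self, tiny_synth):
        config = ppa.MCConfig(seed=10, max_steps=500, stall_window=500, w_n=0.7)
        rows = ppa.wn_scan(tiny_synth.dataset, [0.7], config)
        direct = ppa.run_loocv(tiny_synth.dataset, config)
        assert rows[0]["testing_rho"] == pytest.approx(direct.pooled_rho)

    def test_wn_zero_ignores_noninterfacial_features(self, tiny_synth):
        import copy

        config = ppa.MCConfig(seed=11, max_steps=800, stall_window=800, w_n=0.0)
        ds = tiny_synth.dataset
        scrambled = copy.deepcopy(ds)
        for rec in scrambled.records:
            rec.features.noninterfacial = {
                (k + 7) % 120: v for k, v in rec.features.noninterfacial.items()
            }
        a = ppa.run_loocv(ds, config)
        b = ppa.run_loocv(scrambled, config)
        assert a.pooled_rho == pytest.approx(b.pooled_rho, abs=1e-12)

    def test_rejects_out_of_range_values(self, tiny_synth):
        with pytest.raises(ValueError):
            ppa.wn_scan(tiny_synth.dataset, [1.5],
                        ppa.MCConfig(seed=0, max_steps=10, stall_window=10))


class TestRegionStratifiedPCC:
    def test_single_stratum_equals_pooled(self, tiny_synth):
        ds = tiny_synth.dataset
        rng = np.random.default_rng(12)
        preds = ds.dg_exp + rng.normal(0, 0.5, len(ds))
        import copy

        mono = copy.deepcopy(ds)
        for rec in mono.records:
            if len(rec.mutations) == 1:
                rec.mutation_region = "surface"
        singles = [i for i, r in enumerate(mono.records) if len(r.mutations) == 1]
        out = ppa.region_stratified_pcc(mono, preds)
        assert set(out) == {"surface"}
        assert out["surface"] == pytest.approx(
            ppa.pearson(preds[singles], ds.dg_exp[singles])
        )

    def test_small_strata_are_undefined(self, tiny_synth):
        import copy

        ds = copy.deepcopy(tiny_synth.dataset)
        singles = [r for r in ds.records if len(r.mutations) == 1]
        for rec in singles:
            rec.mutation_region = "surface"
        for rec in singles[:2]:
            rec.mutation_region = "core"
        preds = np.arange(float(len(ds)))
        out = ppa.region_stratified_pcc(ds, preds)
        assert out["core"] is None
        assert out["surface"] is not None
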