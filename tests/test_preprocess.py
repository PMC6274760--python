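"""Tests for probe collapsing, matching, normalization and batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from crosscohort_mtl import preprocess
from crosscohort_mtl.data import CohortDataset
from crosscohort_mtl.preprocess import (
    adjust_covariates,
    collapse_probes,
    concatenate,
    intersect_genes,
    propensity_match,
    quantile_normalize,
    standardized_mean_difference,
    zscore_per_dataset,
)
from crosscohort_mtl.synthetic import ImbalanceSpec, SyntheticConfig, generate, make_imbalanced

from conftest import make_cohort


class TestCollapseProbes:
    def test_duplicate_rows_averaged(self):
        expr = pd.DataFrame([[1.0, 3.0], [3.0, 5.0], [7.0, 9.0]],
                            index=["A", "A", "B"], columns=["s1", "s2"])
        out = collapse_probes(expr)
        assert list(out.index) == ["A", "B"]
        assert np.allclose(out.loc["A"], [2.0, 4.0])
        assert np.allclose(out.loc["B"], [7.0, 9.0])

    def test_no_duplicates_identity(self):
        expr = pd.DataFrame(np.arange(6.0).reshape(3, 2),
                            index=["A", "B", "C"], columns=["s1", "s2"])
        pd.testing.assert_frame_equal(collapse_probes(expr), expr)

    def test_matches_bruteforce_aggregation(self):
        rng = np.random.default_rng(4)
        symbols = ["G1", "G2", "G1", "G3", "G1", "G4", "G5", "G6", "G7", "G8"]
        expr = pd.DataFrame(rng.normal(size=(10, 4)), index=symbols)
        out = collapse_probes(expr)
        for sym in set(symbols):
            rows = [i for i, s in enumerate(symbols) if s == sym]
            brute = np.mean([expr.iloc[i].to_numpy() for i in rows], axis=0)
            assert np.allclose(out.loc[sym].to_numpy(), brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(pd.DataFrame())


class TestIntersectGenes:
    def _cohort_with_genes(self, cid, genes, seed=0):
        c = make_cohort(cid, p=len(genes), n=6, seed=seed)
        expr = c.expr.copy()
        expr.index = genes
        return CohortDataset(cid, expr, c.meta)

    def test_two_cohorts(self):
        a = self._cohort_with_genes("a", ["A", "B", "C"])
        b = self._cohort_with_genes("b", ["B", "C", "D"], seed=1)
        out = intersect_genes([a, b])
        assert out[0].genes == out[1].genes == ["B", "C"]

    def test_identical_sets_sorted_identity(self):
        a = self._cohort_with_genes("a", ["C", "A", "B"])
        b = self._cohort_with_genes("b", ["C", "A", "B"], seed=1)
        out = intersect_genes([a, b])
        assert out[0].genes == ["A", "B", "C"]

    def test_random_subsets_match_set_oracle(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(150)]
        gene_sets = [sorted(rng.choice(universe, 100, replace=False))
                     for _ in range(3)]
        cohorts = [self._cohort_with_genes(f"c{i}", gs, seed=i)
                   for i, gs in enumerate(gene_sets)]
        out = intersect_genes(cohorts)
        expected = sorted(set(gene_sets[0]) & set(gene_sets[1]) & set(gene_sets[2]))
        assert out[0].genes == expected

    def test_empty_intersection_rejected(self):
        a = self._cohort_with_genes("a", ["A", "B", "C"])
        b = self._cohort_with_genes("b", ["D", "E", "F"], seed=1)
        with pytest.raises(ValueError, match="empty"):
            intersect_genes([a, b])


class TestPropensityMatch:
    def test_balanced_cohort_keeps_everyone(self):
        cfg = SyntheticConfig(t=1, p=10, s=4, n_per_cohort=40, seed=1)
        (cohort,), _ = generate(cfg)
        design = propensity_match(cohort)
        assert design.n_pairs == 20
        ids = design.matched_ids()
        assert len(set(ids)) == len(ids) == 40

    def test_pigeonhole_bound(self):
        cfg = SyntheticConfig(t=1, p=10, s=4, n_per_cohort=30, seed=2)
        (cohort,), _ = make_imbalanced(cfg, ImbalanceSpec(case_fraction=25 / 30))
        design = propensity_match(cohort)
        assert design.n_pairs <= 5

    def test_matching_reduces_age_imbalance(self):
        cfg = SyntheticConfig(t=1, p=10, s=4, n_per_cohort=200, seed=31)
        (cohort,), _ = make_imbalanced(
            cfg, ImbalanceSpec(age_shift=10.0, case_fraction=0.6))
        before = abs(standardized_mean_difference(cohort.meta, "age"))
        design = propensity_match(cohort)
        matched = preprocess.apply_matching(cohort, design)
        after = abs(standardized_mean_difference(matched.meta, "age"))
        assert after < before

    def test_matching_never_worsens_balance_on_average(self):
        """Mean absolute SMD of age over seeds decreases after matching."""
        befores, afters = [], []
        for seed in range(20):
            cfg = SyntheticConfig(t=1, p=5, s=2, n_per_cohort=120, seed=100 + seed)
            (cohort,), _ = make_imbalanced(
                cfg, ImbalanceSpec(age_shift=8.0, case_fraction=0.55))
            befores.append(abs(standardized_mean_difference(cohort.meta, "age")))
            matched = preprocess.apply_matching(cohort, propensity_match(cohort))
            afters.append(abs(standardized_mean_difference(matched.meta, "age")))
        assert np.mean(afters) < np.mean(befores)

    def test_single_class_rejected(self):
        cohort = make_cohort("c1", p=4, n=6)
        cohort.meta["diagnosis"] = "case"
        with pytest.raises(ValueError, match="class absent"):
            propensity_match(cohort)

    def test_propensity_in_unit_interval(self):
        cfg = SyntheticConfig(t=1, p=10, s=4, n_per_cohort=50, seed=3)
        (cohort,), _ = generate(cfg)
        design = propensity_match(cohort)
        assert ((design.propensity > 0) & (design.propensity < 1)).all()


class TestQuantileNormalize:
    def test_two_sample_closed_form(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(expr)
        assert np.allclose(out["s1"], [2.5, 3.5, 4.5])
        assert np.allclose(out["s2"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        expr = pd.DataFrame({"s1": col, "s2": col})
        assert np.allclose(quantile_normalize(expr).to_numpy(),
                           expr.to_numpy())

    def test_all_columns_share_sorted_vector(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(50, 20)))
        out = quantile_normalize(expr).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(20):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(30, 5)))
        once = quantile_normalize(expr)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_ties_receive_average_reference(self):
        expr = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]})
        out = quantile_normalize(expr)
        # tied entries stay tied and equal the mean of their rank references
        assert out["s1"][0] == out["s1"][1]

    def test_na_rejected(self):
        expr = pd.DataFrame({"s1": [1.0, np.nan]})
        with pytest.raises(ValueError, match="NA"):
            quantile_normalize(expr)


class TestAdjustCovariates:
    def _concat_synthetic(self, **kw):
        cfg = SyntheticConfig(**kw)
        cohorts, truth = generate(cfg)
        expr, meta = concatenate(cohorts)
        return expr, meta, cohorts, truth

    def test_removes_known_batch_offsets(self):
        """Post-adjustment per-cohort gene means agree across cohorts within
        0.05 SD when the only difference is an additive batch offset."""
        expr, meta, cohorts, _ = self._concat_synthetic(
            t=3, p=150, n_per_cohort=80, s=0, beta=0.0, sigma_batch=2.0, seed=41)
        out = adjust_covariates(expr, meta)
        means = np.column_stack([
            out.loc[:, meta.loc[meta["dataset"] == c.cohort_id, "sample_id"]]
            .to_numpy().mean(axis=1)
            for c in cohorts
        ])
        spread = means.max(axis=1) - means.min(axis=1)
        assert np.quantile(spread, 0.95) < 0.05
        assert spread.mean() < 0.05

    def test_no_batch_no_covariates_near_identity(self):
        expr, meta, _, _ = self._concat_synthetic(
            t=2, p=80, n_per_cohort=500, s=0, beta=0.0, sigma_batch=0.0, seed=42)
        out = adjust_covariates(expr, meta)
        for g in range(0, 80, 13):
            r = np.corrcoef(expr.iloc[g], out.iloc[g])[0, 1]
            assert r > 0.99

    def test_removes_injected_age_effect(self):
        expr, meta, _, truth = self._concat_synthetic(
            t=2, p=100, n_per_cohort=150, s=0, beta=0.0, sigma_batch=0.5,
            covariate_effects={"age": 0.1}, n_cov_genes=10, seed=43)
        out = adjust_covariates(expr, meta)
        age = meta["age"].to_numpy(dtype=float)
        affected = np.flatnonzero(truth.cov_loadings["age"])
        for g in affected:
            r_after = np.corrcoef(out.to_numpy()[g], age)[0, 1]
            assert abs(r_after) < 0.1

    def test_diagnosis_signal_preserved(self):
        """Adjustment must not remove the case-control difference."""
        expr, meta, _, truth = self._concat_synthetic(
            t=2, p=100, n_per_cohort=150, s=10, beta=1.0, sigma_task=0.0,
            sigma_batch=2.0, seed=44)
        out = adjust_covariates(expr, meta)
        y = (meta["diagnosis"] == "case").to_numpy()
        diffs = out.to_numpy()[:, y].mean(axis=1) - out.to_numpy()[:, ~y].mean(axis=1)
        support_effect = np.abs(diffs[truth.support]).mean()
        null_effect = np.abs(np.delete(diffs, truth.support)).mean()
        assert support_effect > 5 * null_effect

    def test_misaligned_meta_rejected(self):
        expr, meta, _, _ = self._concat_synthetic(
            t=2, p=10, s=4, n_per_cohort=10, seed=45)
        with pytest.raises(ValueError, match="align"):
            adjust_covariates(expr, meta.iloc[::-1].reset_index(drop=True))


class TestZscore:
    def test_closed_form_three_values(self):
        c = make_cohort("c1", p=1, n=3)
        c.expr.iloc[0] = [1.0, 2.0, 3.0]
        (out,) = zscore_per_dataset([c])
        assert np.allclose(out.expr.iloc[0],
                           [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_constant_gene_zeroed_with_warning(self):
        c = make_cohort("c1", p=2, n=4)
        c.expr.iloc[0] = 7.0
        with pytest.warns(UserWarning, match="constant gene"):
            (out,) = zscore_per_dataset([c])
        assert np.all(out.expr.iloc[0] == 0.0)

    def test_population_moments_exact(self):
        c = make_cohort("c1", p=30, n=25, seed=8)
        (out,) = zscore_per_dataset([c])
        vals = out.expr.to_numpy()
        assert np.abs(vals.mean(axis=1)).max() < 1e-12
        assert np.abs(vals.std(axis=1, ddof=0) - 1).max() < 1e-12

    def test_single_sample_rejected(self):
        c = make_cohort("c1", p=3, n=2)
        single = CohortDataset("c1", c.expr.iloc[:, :1],
                               c.meta.iloc[:1].reset_index(drop=True))
        with pytest.raises(ValueError, match="single sample"):
            zscore_per_dataset([single])


def test_full_pipeline_order_and_output():
    cfg = SyntheticConfig(t=3, p=60, n_per_cohort=30, seed=19)
    cohorts, _ = generate(cfg)
    processed, info = preprocess.run_pipeline(cohorts)
    assert info["n_common_genes"] == 60
    for c in processed:
        vals = c.expr.to_numpy()
        assert np.abs(vals.mean(axis=1)).max() < 1e-10
        assert c.n_samples % 2 == 0   # 1:1 matched
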