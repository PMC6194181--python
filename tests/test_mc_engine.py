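"""Monte Carlo engine: perturbation, cells, the factorial design."""

import numpy as np
import pytest

from sgrcorr import (CellLevels, FakingModel, SimulationDesign,
                     default_marginals, honest_joint_pmf, perturb_sample,
                     population_q, replacement_kernel, run_cell, run_design,
                     sample_honest, significance_crosstab, table_summary,
                     thresholds_from_marginals)
from sgrcorr.mc_engine import expected_row_change_probability


@pytest.fixture
def kernels_v5():
    return (replacement_kernel(5, FakingModel.from_preset("average", "good")),
            replacement_kernel(5, FakingModel.from_preset("average", "good")))


class TestPerturbSample:
    def test_no_fakers_leaves_sample_untouched(self, thresholds_v5, kernels_v5):
        D = sample_honest(200, thresholds_v5, 0.2, seed=1)
        X = perturb_sample(D, 0.0, *kernels_v5, seed=2)
        assert np.array_equal(D.data, X.data)

    def test_all_fakers_dichotomous_good_saturates(self):
        ts = thresholds_from_marginals((0.5, 0.5))
        k = replacement_kernel(2, FakingModel.from_preset("slight", "good"))
        D = sample_honest(100, ts, 0.0, seed=3)
        X = perturb_sample(D, 1.0, k, k, seed=4)
        assert np.all(X.data == 2)

    def test_same_seed_reproduces_perturbation(self, thresholds_v5, kernels_v5):
        D = sample_honest(300, thresholds_v5, 0.5, seed=5)
        X1 = perturb_sample(D, 0.4, *kernels_v5, seed=6)
        X2 = perturb_sample(D, 0.4, *kernels_v5, seed=6)
        assert np.array_equal(X1.data, X2.data)

    def test_fraction_of_changed_rows_matches_theory(self, thresholds_v5,
                                                     kernels_v5):
        """The observed share of modified rows agrees with the replacement
        probability enumerated from the honest pmf and the kernels."""
        n = 100_000
        alpha = 0.5
        D = sample_honest(n, thresholds_v5, 0.3, seed=7)
        X = perturb_sample(D, alpha, *kernels_v5, seed=8)
        changed = np.mean(np.any(D.data != X.data, axis=1))
        P = honest_joint_pmf(thresholds_v5, 0.3)
        expect = expected_row_change_probability(P, *kernels_v5, alpha)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(changed - expect) < 3 * se


class TestRunCell:
    def test_no_fakers_gives_exactly_zero_q(self):
        levels = CellLevels(n=50, alpha=0.0, model="slight", direction="same",
                            v=5, rho_latent=0.3)
        s = run_cell(levels, replications=50, seed=10)
        assert s.median_q_pearson == 0.0
        assert s.median_q_spearman == 0.0

    def test_same_seed_is_deterministic(self):
        levels = CellLevels(n=40, alpha=0.5, model="extreme",
                            direction="opposite", v=5, rho_latent=-0.3)
        a = run_cell(levels, replications=30, seed=11)
        b = run_cell(levels, replications=30, seed=11)
        assert a == b

    def test_large_samples_converge_to_population_value(self):
        """At n = 1000 the cell median q sits within +-0.03 of the exact
        population Q for the same configuration."""
        levels = CellLevels(n=1000, alpha=0.3, model="extreme",
                            direction="same", v=5, rho_latent=0.0)
        s = run_cell(levels, replications=150, seed=12)
        mx = FakingModel.from_preset("extreme", "good")
        pop = population_q(5, None, 0.0, mx, mx, 0.3, index="spearman").q
        assert s.median_q_spearman == pytest.approx(pop, abs=0.03)

    def test_degenerates_counted_and_excluded(self):
        # v=2, tiny n, 90% fakers good: perturbed column often constant
        levels = CellLevels(n=10, alpha=0.9, model="slight", direction="same",
                            v=2, rho_latent=0.0)
        s, reps = run_cell(levels, replications=60, seed=13,
                           return_replicates=True)
        assert s.n_degenerate > 0
        assert len(reps) == 60 - s.n_degenerate

    def test_fully_degenerate_cell_is_flagged(self):
        from sgrcorr import DegenerateSampleError
        levels = CellLevels(n=10, alpha=1.0, model="slight", direction="same",
                            v=2, rho_latent=0.0)
        with pytest.raises(DegenerateSampleError):
            run_cell(levels, replications=10, seed=13)

    def test_replicate_table_contains_paired_estimates(self):
        levels = CellLevels(n=60, alpha=0.2, model="slight", direction="same",
                            v=5, rho_latent=0.6)
        s, reps = run_cell(levels, replications=25, seed=14,
                           return_replicates=True)
        assert len(reps) == 25 - s.n_degenerate
        assert {"rd_spearman", "rm_spearman", "q_spearman", "n"} <= set(reps)


class TestRunDesign:
    def _tiny_design(self, **kw):
        base = dict(n_levels=(30,), alphas=(0.0, 0.4), models=("slight",),
                    directions=("same",), v_levels=(5,), rho_levels=(0.0, 0.6),
                    replications=20, seed=123)
        base.update(kw)
        return SimulationDesign(**base)

    def test_one_row_per_cell(self):
        design = self._tiny_design()
        results = run_design(design)
        assert len(results) == design.n_cells == 4

    def test_master_seed_determinism(self):
        r1 = run_design(self._tiny_design())
        r2 = run_design(self._tiny_design())
        assert r1.equals(r2)

    def test_cell_subset_reproduces_full_run_values(self):
        """Restricting the factor grid reproduces the same numbers for the
        shared cells (per-cell seed streams are independent)."""
        full = run_design(self._tiny_design())
        sub = run_design(self._tiny_design(alphas=(0.4,)))
        merged = sub.merge(full, on=["n", "alpha", "model", "direction", "v",
                                     "rho_latent"], suffixes=("_sub", "_full"))
        assert len(merged) == 2
        assert np.allclose(merged["median_q_spearman_sub"],
                           merged["median_q_spearman_full"])

    def test_default_design_has_full_crossing(self):
        assert SimulationDesign().n_cells == 3360

    def test_variance_trends_with_n_and_alpha(self):
        """q varies more at small n and at high faker proportions."""
        rows = run_design(self._tiny_design(
            n_levels=(20, 1000), alphas=(0.1, 0.6), rho_levels=(0.0,),
            replications=60))
        var = rows.set_index(["n", "alpha"])["var_q_spearman"]
        assert var[(20, 0.1)] > var[(1000, 0.1)]
        assert var[(20, 0.6)] > var[(1000, 0.6)]
        assert var[(1000, 0.6)] > var[(1000, 0.1)]


class TestSummaries:
    def test_table_summary_averages_per_n_medians(self):
        design = SimulationDesign(
            n_levels=(20, 50), alphas=(0.2,), models=("slight",),
            directions=("same",), v_levels=(5,), rho_levels=(0.0,),
            replications=30, seed=77)
        results = run_design(design)
        grid = table_summary(results, 5, "slight", "same")
        expected = results["median_q_spearman"].mean()
        assert grid.loc[0.0, 0.2] == pytest.approx(expected, abs=1e-12)
        assert grid.shape == (1, 1)

    def test_missing_cells_appear_as_gaps(self):
        design = SimulationDesign(
            n_levels=(20,), alphas=(0.2,), models=("slight",),
            directions=("same",), v_levels=(5,), rho_levels=(0.0,),
            replications=10, seed=5)
        results = run_design(design)
        grid = table_summary(results, 5, "extreme", "same")
        assert grid.size == 0 or grid.isna().all().all()


class TestSignificanceCrosstab:
    def test_no_fakers_no_disagreement(self):
        levels = CellLevels(n=80, alpha=0.0, model="slight", direction="same",
                            v=5, rho_latent=0.3)
        _, reps = run_cell(levels, replications=60, seed=21,
                           return_replicates=True)
        table = significance_crosstab(reps)
        assert table.loc["honest_sig", "perturbed_ns"] == 0
        assert table.loc["honest_ns", "perturbed_sig"] == 0

    def test_counts_partition_replicates(self):
        levels = CellLevels(n=40, alpha=0.5, model="extreme",
                            direction="opposite", v=5, rho_latent=0.6)
        _, reps = run_cell(levels, replications=80, seed=22,
                           return_replicates=True)
        table = significance_crosstab(reps)
        assert table.to_numpy().sum() == len(reps)

    def test_destructive_faking_turns_significance_off(self):
        """Strong opposite faking of a clearly significant correlation
        mostly produces honest-significant / perturbed-nonsignificant
        replicates among the disagreements."""
        # 15% opposite extreme fakers push the mixture correlation of a
        # latent-0.6 pair close to zero, killing significance at n=50
        levels = CellLevels(n=50, alpha=0.15, model="extreme",
                            direction="opposite", v=5, rho_latent=0.6)
        _, reps = run_cell(levels, replications=60, seed=23,
                           return_replicates=True)
        table = significance_crosstab(reps)
        assert table.loc["honest_sig", "perturbed_ns"] >= \
            table.loc["honest_ns", "perturbed_sig"]
        assert table.loc["honest_sig", "perturbed_ns"] > 0
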