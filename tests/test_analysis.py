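"""Trajectory summaries and ensemble sweep machinery."""

import numpy as np
import pytest
from scipy import stats

import flowmigrate as fm


@pytest.fixture(scope="module")
def stable_br5_run(a_branch):
    """A BR5 run at the stability optimum that keeps its bifurcation."""
    for seed in fm.generate_seeds(30):
        traj, loss = fm.run_simulation(a_branch, fm.RuleSpec("BR5", alpha=0.45),
                                       seed=int(seed))
        if not loss.occurred:
            return traj
    raise RuntimeError("no stable run among 30 seeds")  # pragma: no cover


class TestMeanBranchDiameter:
    def test_initial_diameter_is_n0_cells_wrapped(self, a_branch, params):
        traj, _ = fm.run_simulation(a_branch, fm.RuleSpec("BR1"))
        for branch in ("proximal", "distal"):
            d0 = fm.mean_branch_diameter(traj, branch)["mean_diameter_m"].iloc[0]
            assert d0 == pytest.approx(params.n0 * params.w / np.pi)

    def test_regressed_branch_diameter_reaches_zero(self, a_branch):
        traj, loss = fm.run_simulation(a_branch, fm.RuleSpec("BR1"))
        d = fm.mean_branch_diameter(traj, "distal")["mean_diameter_m"]
        assert loss.occurred and d.iloc[-1] == 0.0

    def test_equal_subset_sizes_for_both_branches(self, a_branch):
        from flowmigrate.analysis import _diameter_subset

        traj, _ = fm.run_simulation(a_branch, fm.RuleSpec("BR1"))
        prox = _diameter_subset(traj, "proximal")
        dist = _diameter_subset(traj, "distal")
        assert len(prox) == len(dist) == 10
        # distal subset hugs the flow-convergent node
        assert dist == a_branch.branch_order["distal"][-10:]


class TestFixedProbabilityRules:
    def test_br3_preserves_both_branches_with_similar_diameters(self, a_branch):
        """Equal fixed probabilities keep both branches open (10 seeds)."""
        finals = {"proximal": [], "distal": []}
        for seed in fm.generate_seeds(10):
            traj, loss = fm.run_simulation(a_branch, fm.RuleSpec("BR3"), seed=int(seed))
            assert not loss.occurred
            for br in finals:
                d = fm.mean_branch_diameter(traj, br)["mean_diameter_m"]
                finals[br].append(d.iloc[-10:].mean())
        p, d = np.mean(finals["proximal"]), np.mean(finals["distal"])
        assert abs(p - d) / max(p, d) < 0.10

    def test_br4_stabilises_proximal_at_larger_diameter(self, a_branch):
        """A 0.7/0.3 bias renders diameter control favouring the high-flow branch."""
        p_mean, d_mean = [], []
        for seed in fm.generate_seeds(10):
            traj, loss = fm.run_simulation(a_branch, fm.RuleSpec("BR4"), seed=int(seed))
            assert not loss.occurred
            p_mean.append(
                fm.mean_branch_diameter(traj, "proximal")["mean_diameter_m"].iloc[-10:].mean()
            )
            d_mean.append(
                fm.mean_branch_diameter(traj, "distal")["mean_diameter_m"].iloc[-10:].mean()
            )
        assert np.mean(p_mean) > np.mean(d_mean)


class TestProbabilityTraces:
    def test_components_sum_to_one_each_step(self, stable_br5_run):
        df = fm.probability_traces(stable_br5_run)
        np.testing.assert_allclose(df["P1"] + df["P2"], 1.0, atol=1e-12)

    def test_stable_run_favours_high_flow_branch(self, stable_br5_run):
        df = fm.probability_traces(stable_br5_run)
        late = df.iloc[15:]
        assert late["P1"].mean() > late["P2"].mean()
        assert 0.55 < late["P1"].mean() < 0.8

    def test_rejects_non_br5_trajectory(self, a_branch):
        traj, _ = fm.run_simulation(a_branch, fm.RuleSpec("BR1"))
        with pytest.raises(ValueError):
            fm.probability_traces(traj)


class TestPressureCellNumberTraces:
    def test_step_changes_anticorrelated(self, stable_br5_run):
        df = fm.pressure_cellnumber_traces(stable_br5_run, "proximal")
        dn, ddp = np.diff(df["n"]), np.diff(df["dp_Pa"])
        keep = dn != 0
        rho = stats.spearmanr(dn[keep], ddp[keep]).statistic
        assert rho < 0

    def test_constant_cell_interval_gives_constant_dp(self, a_branch):
        traj, _ = fm.run_simulation(a_branch, fm.RuleSpec("BR1"))
        df = fm.pressure_cellnumber_traces(traj, "proximal")
        # after regression completes, the surviving loop reaches a steady state
        tail = df.iloc[-5:]
        if tail["n"].nunique() == 1:
            assert tail["dp_Pa"].nunique() == 1

    def test_unknown_branch_rejected(self, stable_br5_run):
        with pytest.raises(KeyError):
            fm.pressure_cellnumber_traces(stable_br5_run, "feeding")


@pytest.fixture(scope="module")
def small_sweep(a_branch):
    return fm.alpha_sweep(a_branch, [0.2, 0.8], fm.generate_seeds(20))


class TestSweep:
    def test_table_shape_and_columns(self, small_sweep):
        assert len(small_sweep.table) == 2 * 20
        assert {"alpha", "seed", "occurred", "loss_step", "lost_branch"} <= set(
            small_sweep.table.columns
        )

    def test_loss_curves_monotone_and_bounded(self, small_sweep):
        for a in small_sweep.alphas:
            frac = small_sweep.loss_fraction_by_time(a)["fraction_lost"].to_numpy()
            assert np.all(np.diff(frac) >= 0)
            assert frac.min() >= 0.0 and frac.max() <= 1.0

    def test_attribution_sums_to_one_over_lost_runs(self, small_sweep):
        for a in small_sweep.alphas:
            attr = small_sweep.attribution(a)
            if attr:
                assert sum(attr.values()) == pytest.approx(1.0)

    def test_surface_and_write(self, small_sweep, tmp_path):
        surface = small_sweep.loss_surface()
        assert {"alpha", "time_hr", "fraction_lost"} == set(surface.columns)
        small_sweep.write(tmp_path)
        assert (tmp_path / "sweep_summary.csv").exists()
        assert (tmp_path / "sweep_surface.csv").exists()

    def test_empty_grid_rejected(self, a_branch):
        with pytest.raises(ValueError):
            fm.alpha_sweep(a_branch, [], [1, 2])


class TestOscillationPeriod:
    def test_pure_sine_period_recovered(self):
        x = np.sin(2 * np.pi * np.arange(200) / 25.0)
        assert fm.oscillation_period(x) == pytest.approx(25.0, abs=0.5)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            fm.oscillation_period(np.ones(50))
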