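"""Structured-coalescent simulator against analytic oracles."""

import numpy as np
import pytest

from stepstone.coalescent_sim import (
    MetapopModel,
    MutationModel,
    PriorSpec,
    build_model,
    draw_truncated_exponential,
    evolve_sequences,
    expected_coalescence_times,
    sample_priors,
    simulate_dataset,
    simulate_genealogy,
    simulate_infinite_sites_population,
    truncated_exponential_mean,
)
from stepstone.errors import (
    ConfigurationError,
    ModelInvariantError,
    NonCoalescingError,
)
from stepstone.popgen_stats import phi_st
from stepstone.alignment_io import pairwise_differences


class TestBuildModel:
    def test_panmixia_single_deme(self):
        m = build_model("panmixia", ["D"], theta=0.02)
        assert m.n_demes == 1
        assert m.M.shape == (1, 1)

    def test_panmixia_rejects_migration(self):
        with pytest.raises(ModelInvariantError):
            build_model("panmixia", ["D"], theta=0.02, m=1.0)

    def test_panmixia_rejects_multiple_demes(self):
        with pytest.raises(ModelInvariantError):
            build_model("panmixia", ["A", "B"], theta=0.02)

    def test_island_five_demes_twenty_rates(self):
        m = build_model("island", [f"D{i}" for i in range(5)], theta=0.01, m=0.5)
        off = m.M[~np.eye(5, dtype=bool)]
        assert len(off) == 20
        assert np.all(off == 0.5)

    def test_island_unequal_theta_rejected(self):
        with pytest.raises(ModelInvariantError):
            build_model("island", ["A", "B"], theta=[0.01, 0.02], m=1.0)

    def test_stepping_stone_line_topology(self):
        demes = [f"D{i}" for i in range(5)]
        m = build_model("stepping_stone", demes, theta=0.01, m=2.0)
        assert len(m.neighbor_pairs) == 4
        assert int((m.M > 0).sum()) == 8  # directed rates
        # only adjacent pairs connected
        assert m.M[0, 1] == 2.0 and m.M[0, 2] == 0.0

    def test_stepping_stone_disconnected_rejected(self):
        demes = ["A", "B", "C", "D"]
        pairs = [("A", "B"), ("C", "D")]
        with pytest.raises(NonCoalescingError):
            build_model("stepping_stone", demes, neighbor_pairs=pairs,
                        theta=0.01, m=1.0)


class TestPriors:
    def test_draws_within_window(self):
        ps = PriorSpec()
        rng = np.random.default_rng(0)
        draws = draw_truncated_exponential(
            ps.theta_lower, ps.theta_upper, ps.theta_mean, rng, size=20_000
        )
        assert draws.min() >= ps.theta_lower
        assert draws.max() <= ps.theta_upper

    def test_empirical_mean_matches_truncated_analytic(self):
        ps = PriorSpec()
        rng = np.random.default_rng(1)
        draws = draw_truncated_exponential(
            ps.m_lower, ps.m_upper, ps.m_mean, rng, size=100_000
        )
        analytic = truncated_exponential_mean(ps.m_lower, ps.m_upper, ps.m_mean)
        assert abs(draws.mean() - analytic) / analytic < 0.02

    def test_sample_priors_pair(self):
        theta, m = sample_priors(PriorSpec(), seed=5)
        assert 1e-5 <= theta <= 1e-1
        assert 1e-4 <= m <= 1e6


class TestExpectedCoalescenceTimes:
    def test_single_deme_pair_is_half_theta(self):
        model = build_model("panmixia", ["D"], theta=0.02)
        assert expected_coalescence_times(model, {"D": 2}) == pytest.approx(0.01)

    def test_disconnected_demes_infinite(self):
        model = MetapopModel(
            label="island", demes=["A", "B"],
            theta=np.array([0.01, 0.01]), M=np.zeros((2, 2)),
        )
        assert expected_coalescence_times(model, {"A": 1, "B": 1}) == np.inf

    def test_two_deme_symmetric_hand_algebra(self):
        # classic strong-migration algebra: E[T | together] = theta,
        # E[T | apart] = theta + 1/(2M)
        theta, m = 0.02, 50.0
        model = build_model("island", ["A", "B"], theta=theta, m=m)
        apart = expected_coalescence_times(model, {"A": 1, "B": 1})
        together = expected_coalescence_times(model, {"A": 2})
        assert together == pytest.approx(theta, rel=1e-12)
        assert apart == pytest.approx(theta + 1 / (2 * m), rel=1e-12)

    def test_state_space_cap(self):
        model = build_model("panmixia", ["D"], theta=0.02)
        with pytest.raises(ConfigurationError):
            expected_coalescence_times(model, {"D": 5})


class TestSimulateGenealogy:
    def test_coalescence_event_count(self):
        model = build_model("island", ["A", "B"], theta=0.01, m=5.0)
        g = simulate_genealogy(model, {"A": 4, "B": 3}, seed=3)
        assert g.n_coalescences == 6
        assert g.n_tips == 7
        assert g.total_branch_length > 0

    def test_pairwise_time_matches_closed_form(self):
        theta = 0.02
        model = build_model("panmixia", ["D"], theta=theta)
        times = [simulate_genealogy(model, 2, seed=i).tmrca for i in range(1500)]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - theta / 2) < 3 * se

    def test_two_deme_time_matches_linear_system_oracle(self):
        model = build_model("island", ["A", "B"], theta=0.02, m=20.0)
        expected = expected_coalescence_times(model, {"A": 1, "B": 1})
        times = [
            simulate_genealogy(model, {"A": 1, "B": 1}, seed=i).tmrca
            for i in range(1500)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - expected) < 3 * se

    def test_high_migration_approaches_pooled_panmixia(self):
        theta = 0.02
        model = build_model("island", ["A", "B"], theta=theta, m=2000.0)
        pooled = build_model("panmixia", ["D"], theta=2 * theta)
        expected = expected_coalescence_times(pooled, {"D": 2})
        times = [
            simulate_genealogy(model, {"A": 1, "B": 1}, seed=i).tmrca
            for i in range(1200)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - expected) < 3 * se + 0.02 * expected

    def test_zero_migration_across_demes_rejected(self):
        model = MetapopModel(
            label="island", demes=["A", "B"],
            theta=np.array([0.01, 0.01]), M=np.zeros((2, 2)),
        )
        with pytest.raises(NonCoalescingError):
            simulate_genealogy(model, {"A": 2, "B": 2}, seed=0)

    def test_migration_events_recorded(self):
        model = build_model("island", ["A", "B"], theta=0.01, m=50.0)
        g = simulate_genealogy(model, {"A": 2, "B": 2}, seed=11,
                               record_migrations=True)
        newick = g.to_newick()
        assert newick.startswith("(")
        if g.migrations:
            assert "# migration" in newick


class TestMutationModel:
    def test_category_rates_mean_one(self):
        for alpha in (0.1, 0.5, 2.0):
            rates = MutationModel(alpha=alpha).category_rates()
            assert len(rates) == 4
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(rates) > 0)

    def test_base_freqs_must_sum_to_one(self):
        with pytest.raises(ModelInvariantError):
            MutationModel(base_freqs=(0.5, 0.5, 0.5, 0.5))


class TestEvolveSequences:
    def test_tiny_tree_gives_identical_tips(self):
        model = build_model("panmixia", ["D"], theta=1e-8)
        g = simulate_genealogy(model, 5, seed=1)
        aln = evolve_sequences(g, 100, MutationModel(), seed=2)
        assert len(set(aln.sequences)) == 1

    def test_variable_fraction_monotone_in_theta(self):
        fractions = []
        for theta in (0.001, 0.02, 0.5):
            model = build_model("panmixia", ["D"], theta=theta)
            varfrac = []
            for rep in range(10):
                g = simulate_genealogy(model, 6, seed=100 + rep)
                aln = evolve_sequences(g, 300, MutationModel(), seed=rep)
                enc = aln.encoded()
                varfrac.append(np.mean(enc.min(axis=0) != enc.max(axis=0)))
            fractions.append(np.mean(varfrac))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_transition_transversion_event_ratio(self):
        """Counted substitution events approach the kappa:2 rate ratio."""
        kappa = 4.0
        model = build_model("panmixia", ["D"], theta=1.0)
        transitions = transversions = 0
        pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for rep in range(10):
            g = simulate_genealogy(model, 2, seed=400 + rep)
            mm = MutationModel(kappa=kappa)
            # count events directly off the mutation table
            from stepstone.coalescent_sim import _rescale_ts
            import msprime

            ts = _rescale_ts(g.ts, 3000)
            mts = msprime.sim_mutations(
                ts, rate=1.0,
                model=msprime.HKY(kappa=kappa,
                                  equilibrium_frequencies=[0.25] * 4),
                random_seed=500 + rep,
            )
            for site in mts.sites():
                muts = {m.id: m for m in site.mutations}
                for mut in site.mutations:
                    prev = (
                        site.ancestral_state
                        if mut.parent == -1
                        else muts[mut.parent].derived_state
                    )
                    pair = (prev, mut.derived_state)
                    if pair in pairs:
                        transitions += 1
                    elif pair[0] != pair[1]:
                        transversions += 1
        # instantaneous ratio is kappa:2 with equal base frequencies
        ratio = transitions / transversions
        assert ratio == pytest.approx(kappa / 2, rel=0.15)


class TestSimulateDataset:
    def test_determinism_under_seed(self):
        model = build_model("island", ["A", "B"], theta=0.02, m=5.0)
        mm = MutationModel()
        a1, p1 = simulate_dataset(model, {"A": 4, "B": 4}, 200, mm, seed=9)
        a2, p2 = simulate_dataset(model, {"A": 4, "B": 4}, 200, mm, seed=9)
        assert a1.sequences == a2.sequences
        assert p1.assignment == p2.assignment

    def test_different_topologies_differ_under_same_seed(self):
        demes = ["A", "B", "C"]
        mm = MutationModel()
        isl = build_model("island", demes, theta=0.01, m=1.0)
        ss = build_model("stepping_stone", demes, theta=0.01, m=1.0)
        a1, _ = simulate_dataset(isl, {d: 4 for d in demes}, 200, mm, seed=33)
        a2, _ = simulate_dataset(ss, {d: 4 for d in demes}, 200, mm, seed=33)
        assert a1.sequences != a2.sequences

    def test_panmixia_phi_st_centers_on_zero(self):
        model = build_model("panmixia", ["D"], theta=0.02)
        mm = MutationModel()
        vals = []
        for rep in range(25):
            aln, _ = simulate_dataset(model, 12, 300, mm, seed=700 + rep)
            dm = pairwise_differences(aln)
            val = phi_st(dm, ["A"] * 6 + ["B"] * 6)
            if val == val:  # skip undefined (monomorphic) draws
                vals.append(val)
        assert abs(np.mean(vals)) < 0.06

    def test_isolation_by_distance_in_line(self):
        """End demes differentiate more than adjacent demes."""
        demes = ["A", "B", "C"]
        model = build_model("stepping_stone", demes, theta=0.01, m=2.0)
        mm = MutationModel()
        adjacent, ends = [], []
        for rep in range(20):
            aln, pm = simulate_dataset(model, {d: 8 for d in demes}, 400, mm,
                                       seed=900 + rep)
            dm = pairwise_differences(aln)
            labels = np.array([pm.assignment[i] for i in aln.ids])
            sel_ab = np.isin(labels, ["A", "B"])
            sel_ac = np.isin(labels, ["A", "C"])
            from stepstone.alignment_io import DifferenceMatrix

            def sub(sel):
                return DifferenceMatrix(
                    d=dm.d[np.ix_(sel, sel)],
                    sites_compared=dm.sites_compared[np.ix_(sel, sel)],
                )

            va = phi_st(sub(sel_ab), labels[sel_ab])
            vc = phi_st(sub(sel_ac), labels[sel_ac])
            if va == va and vc == vc:
                adjacent.append(va)
                ends.append(vc)
        assert np.mean(ends) >= np.mean(adjacent)


class TestInfiniteSites:
    def test_theta_estimator_unbiased(self):
        theta = 2.0
        vals = [
            simulate_infinite_sites_population(10, theta, seed=i)[1]
            for i in range(400)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - theta) < 3 * se

    def test_matrix_consistent_with_theta_pi(self):
        k, theta_pi, d = simulate_infinite_sites_population(8, 1.5, seed=4)
        iu = np.triu_indices(8, 1)
        assert theta_pi == pytest.approx(d[iu].mean())
        assert k >= 1
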