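"""Counterfactual engine: selection, invasion, Hamilton values, equilibria."""
import numpy as np
import pytest

import hamrule as hr
from conftest import random_fitness


def analysis_for(example):
    st = hr.endpoint_profiles(example.fitness.n, example.u, example.ubar)
    return hr.SelectionAnalysis(st, example.fitness)


def constant_r_S_closed_form(fit, r, p):
    """Independent affine closed form of S(p) for n = 2 constant-r mixing."""
    a = (1 - r) * fit.piC(1) + r * fit.piC(2) - fit.piD(0)
    b = (1 - r) * (fit.piC(2) - fit.piC(1) + fit.piD(0) - fit.piD(1))
    return a + b * p


class TestMeanFitnesses:
    def test_weak_assortment_selects_against_cooperation(self, examples):
        an = analysis_for(examples["linear_weak_assortment"])
        assert an.selection_differential(0.0) == pytest.approx(-0.128, abs=1e-12)
        assert an.selection_differential(1.0) == pytest.approx(-0.128, abs=1e-12)

    def test_quadratic_boundary_differentials(self, examples):
        an = analysis_for(examples["quadratic_synergy"])
        assert an.selection_differential(0.0) == pytest.approx(-0.33, abs=1e-12)
        assert an.selection_differential(1.0) == pytest.approx(0.45, abs=1e-12)

    def test_clonal_mutant_group(self, rng):
        # under full assortment a rare cooperator experiences pi_C(n)
        fit = random_fitness(rng, 6)
        st = hr.clonal_or_binomial(6, 1.0)
        s = hr.SelectionAnalysis(st, fit).selection_differential(0.0)
        assert s == pytest.approx(fit.piC(6) - fit.piD(0))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            hr.SelectionAnalysis(hr.constant_r_2player(0.1), hr.linear_game(10))

    def test_boundary_identities(self, examples):
        an = analysis_for(examples["quadratic_synergy"])
        assert an.mean_fitnesses(0.0).mean_fitness_D == an.fitness.piD(0)
        assert an.mean_fitnesses(1.0).mean_fitness_C == an.fitness.piC(10)


class TestInvasion:
    def test_synergy_game_invasion_threshold(self, synergy_fitness):
        # closed form: (1-r) 0.1 + 3 r > 2  <=>  r > 1.9/2.9
        st = hr.constant_r_2player(0.7)
        rep = hr.SelectionAnalysis(st, synergy_fitness).can_invade("zero")
        assert rep.invades and rep.lhs == pytest.approx(2.13)
        st = hr.constant_r_2player(0.5)
        rep = hr.SelectionAnalysis(st, synergy_fitness).can_invade("zero")
        assert not rep.invades and rep.lhs == pytest.approx(1.55)

    def test_lone_mutant_without_assortment(self, rng):
        fit = hr.FitnessFunction(2, {1: 0.5, 2: 3.0}, {0: 1.0, 1: 1.5})
        rep = hr.SelectionAnalysis(hr.constant_r_2player(0.0),
                                   fit).can_invade("zero")
        assert not rep.invades  # pi_C(1) < pi_D(0)

    def test_tie_is_neutral_non_invasion(self):
        fit = hr.FitnessFunction(2, {1: 1.0, 2: 1.0}, {0: 1.0, 1: 1.0})
        rep = hr.SelectionAnalysis(hr.constant_r_2player(0.2),
                                   fit).can_invade("zero")
        assert rep.neutral and not rep.invades


class TestRelatedness:
    @pytest.mark.parametrize("r", [0.0, 0.25, 0.6, 1.0])
    @pytest.mark.parametrize("p", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_constant_r_family_returns_r(self, r, p):
        an = hr.SelectionAnalysis(hr.constant_r_2player(r),
                                  hr.linear_game(2))
        assert an.relatedness(p) == pytest.approx(r, abs=1e-12)

    def test_strong_assortment_profile(self, examples):
        an = analysis_for(examples["linear_strong_assortment"])
        # (E[i] - 1)/(n - 1) with E[i] = 2.8
        assert an.relatedness(0.0) == pytest.approx(0.2)

    def test_well_mixed_is_zero(self):
        an = hr.SelectionAnalysis(hr.clonal_or_binomial(10, 0.0),
                                  hr.linear_game(10))
        for p in (0.0, 0.3, 0.7, 1.0):
            assert an.relatedness(p) == pytest.approx(0.0, abs=1e-12)


class TestPopulationCB:
    def test_weak_assortment_inclusive_fitness(self, examples):
        cbr = analysis_for(examples["linear_weak_assortment"]).population_cb(0.0)
        assert (cbr.r, cbr.b, cbr.c) == pytest.approx((0.04, 1.8, 0.2))
        assert cbr.hr == pytest.approx(-0.128)

    def test_strong_assortment_inclusive_fitness(self, examples):
        cbr = analysis_for(examples["linear_strong_assortment"]).population_cb(0.0)
        assert cbr.hr == pytest.approx(0.2 * 1.8 - 0.2)

    def test_equal_gains_hr_equals_selection_everywhere(self, rng):
        # under equal gains rb - c = S(p) exactly, any structure, any rule
        fit = hr.linear_game(8)
        st = hr.generate_random_structure(3, 8, 3)
        an = hr.SelectionAnalysis(st, fit)
        for p in (0.0, 0.15, 0.5, 0.85, 1.0):
            s = an.selection_differential(p)
            if 0 < p < 1:
                for avg in ("cooperators", "defectors", "population"):
                    assert an.population_cb(p, averaging=avg).hr == \
                        pytest.approx(s, abs=1e-12)
            else:
                assert an.population_cb(p).hr == pytest.approx(s, abs=1e-12)

    def test_unknown_averaging_rule(self):
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.3), hr.linear_game(2))
        with pytest.raises(ValueError):
            an.population_cb(0.5, averaging="median")


class TestEndpointHamilton:
    def test_matches_population_cb(self, examples):
        an = analysis_for(examples["linear_weak_assortment"])
        rep = an.hamilton_at_endpoint("zero")
        assert rep.lhs - rep.rhs == pytest.approx(-0.128, abs=1e-12)
        assert rep.rb_minus_c == pytest.approx(an.population_cb(0.0).hr,
                                               abs=1e-12)

    def test_antisynergy_boundary_violation_window(self, antisynergy_fitness):
        # rb > c for r > 1/29 while invasion needs r > 1/11: a violation
        # at p = 0 for r in between (here r = 0.06)
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.06),
                                  antisynergy_fitness)
        rep = an.hamilton_at_endpoint("zero")
        assert rep.rb_minus_c == pytest.approx(0.06 * 2.9 - 0.1)
        assert rep.holds
        assert not an.can_invade("zero").invades
        # outside the window the two verdicts agree again
        an2 = hr.SelectionAnalysis(hr.constant_r_2player(0.03),
                                   antisynergy_fitness)
        assert not an2.hamilton_at_endpoint("zero").holds
        assert not an2.can_invade("zero").invades

    def test_upper_boundary_orientation(self, rng):
        # at p = 1 the inequality is reversed: lhs > rhs iff rb < c
        fit = random_fitness(rng, 5)
        st = hr.generate_random_structure(9, 5, 2)
        an = hr.SelectionAnalysis(st, fit)
        rep = an.hamilton_at_endpoint("one")
        assert ((rep.lhs > rep.rhs) == (rep.rb_minus_c < 0)) or \
            rep.lhs == rep.rhs


class TestClassification:
    def test_equal_gains_verdict(self):
        an = hr.SelectionAnalysis(hr.clonal_or_binomial(10, 0.3),
                                  hr.linear_game(10))
        cls = an.synergy_conditions()
        assert cls.equal_gains
        assert cls.verdict == "no_violation_possible"

    def test_quadratic_synergy_conditions_hold(self):
        an = hr.SelectionAnalysis(hr.clonal_or_binomial(10, 0.3),
                                  hr.quadratic_game(10))
        cls = an.synergy_conditions()
        assert cls.synergy_cond1 and cls.synergy_cond2
        assert not cls.equal_gains
        assert cls.verdict == "violations_only_out_of_equilibrium"

    def test_antisynergy_verdict(self, antisynergy_fitness):
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.3),
                                  antisynergy_fitness)
        cls = an.synergy_conditions()
        assert not cls.synergy_cond1
        assert cls.verdict == "in_equilibrium_violations_possible"

    def test_grid_too_small(self):
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.3), hr.linear_game(2))
        with pytest.raises(ValueError):
            an.synergy_conditions(grid_size=5)


class TestEquilibria:
    def test_antisynergy_mixed_equilibrium(self, antisynergy_fitness):
        # closed form: S(p) = 0.23 - 1.26 p, root 23/126, stable;
        # there c = 0.87, b = 2.13 so rb - c = -0.231
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.3),
                                  antisynergy_fitness)
        rep = an.find_equilibria()
        stable = [e for e in rep.equilibria if e.stability == "stable"]
        assert len(stable) == 1
        assert stable[0].p == pytest.approx(23 / 126, abs=1e-9)
        assert stable[0].hr == pytest.approx(-0.231, abs=1e-9)
        assert not rep.endpoint_states["zero"].stable
        assert not rep.endpoint_states["one"].stable

    @pytest.mark.parametrize("r", np.round(np.arange(0.0, 1.0, 0.1), 10))
    def test_synergy_game_has_no_stable_interior(self, r, synergy_fitness):
        # S'(p) = 1.8 (1 - r) > 0: any interior root is unstable
        an = hr.SelectionAnalysis(hr.constant_r_2player(r), synergy_fitness)
        rep = an.find_equilibria()
        assert all(e.stability == "unstable" for e in rep.equilibria)

    def test_uniform_selection_against_cooperation(self):
        # equal gains with rb - c < 0 for all p: only p = 0 is stable
        an = hr.SelectionAnalysis(hr.clonal_or_binomial(10, 0.0),
                                  hr.linear_game(10))
        rep = an.find_equilibria()
        assert rep.equilibria == []
        assert rep.endpoint_states["zero"].stable
        assert not rep.endpoint_states["one"].stable

    def test_flat_differential_warns_degenerate(self):
        fit = hr.FitnessFunction(2, {1: 1.0, 2: 1.0}, {0: 1.0, 1: 1.0})
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.4), fit)
        with pytest.warns(hr.DegenerateSystemWarning):
            rep = an.find_equilibria()
        assert rep.degenerate and rep.equilibria == []

    def test_closed_form_oracle_for_selection(self, rng):
        # engine S(p) vs independently derived affine closed form
        for _ in range(10):
            fit = random_fitness(rng, 2)
            r = rng.uniform(0, 1)
            an = hr.SelectionAnalysis(hr.constant_r_2player(r), fit)
            for p in (0.0, 0.31, 0.5, 0.77, 1.0):
                assert an.selection_differential(p) == pytest.approx(
                    constant_r_S_closed_form(fit, r, p), abs=1e-12)


class TestViolationMap:
    def test_antisynergy_in_equilibrium_violation(self, antisynergy_fitness):
        an = hr.SelectionAnalysis(hr.constant_r_2player(0.3),
                                  antisynergy_fitness)
        df, summary = an.violation_map(201)
        assert summary.in_equilibrium_violation
        assert summary.stable_states_in_disagreement == \
            pytest.approx([23 / 126], abs=1e-9)
        assert list(df.columns) == ["p", "S", "hr", "r", "c", "b", "agree"]

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.2, 0.5, 0.9])
    def test_synergy_game_disagreements_are_transient(self, r, synergy_fitness):
        # disagreement regions exist, but selection leads away from them
        an = hr.SelectionAnalysis(hr.constant_r_2player(r), synergy_fitness)
        _, summary = an.violation_map(201)
        assert not summary.in_equilibrium_violation

    def test_equal_gains_no_disagreement_anywhere(self):
        an = hr.SelectionAnalysis(hr.clonal_or_binomial(10, 0.4),
                                  hr.linear_game(10))
        df, summary = an.violation_map(101)
        assert df["agree"].all()
        assert summary.disagreement_intervals == []


class TestScan:
    def test_antisynergy_invasion_boundary(self, antisynergy_fitness):
        # S(0) = 1.1 r - 0.1 flips sign at r = 1/11 on the p = 0 edge
        df = hr.scan_constant_r(hr.antisynergy_game(),
                                r_grid=[1 / 11 - 1e-3, 1 / 11 + 1e-3],
                                p_grid=[0.0])
        s = df["S"].to_numpy()
        assert s[0] < 0 < s[1]

    def test_synergy_defector_invasion_boundary(self, synergy_fitness):
        # S(1) = 1.1 r - 0.1 flips at r = 1/11 on the p = 1 edge
        df = hr.scan_constant_r(hr.synergy_game(),
                                r_grid=[1 / 11 - 1e-3, 1 / 11 + 1e-3],
                                p_grid=[1.0])
        s = df["S"].to_numpy()
        assert s[0] < 0 < s[1]

    def test_clonal_row_sign(self, rng):
        # at r = 1 the dynamics compare pi_C(2) with pi_D(0) at every p
        fit = random_fitness(rng, 2)
        game = hr.GameMatrix.from_fitness(fit)
        df = hr.scan_constant_r(game, r_grid=[1.0],
                                p_grid=np.linspace(0, 1, 11))
        expected = np.sign(fit.piC(2) - fit.piD(0))
        assert all(np.sign(df["S"]) == expected)

    def test_tsv_round_trip(self, tmp_path, antisynergy_fitness):
        import pandas as pd
        df = hr.scan_constant_r(hr.antisynergy_game(), [0.3],
                                np.linspace(0, 1, 5))
        path = tmp_path / "scan.tsv"
        hr.write_tsv(df, path)
        assert path.read_text().splitlines()[0] == "p\tS\thr\tr\tc\tb\tagree"
        back = pd.read_csv(path, sep="\t")
        assert np.allclose(back["hr"], df["hr"])
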