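import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warped import (
    ALLELE_FREQ_GRID,
    DE_NOVO_GRID,
    PENETRANCE_GRID,
    Individual,
    ModelParams,
    ParameterError,
    Pedigree,
    build_network,
    exact_posterior_enumeration,
    run_belief_propagation,
    run_warp,
    single_sibship_posterior,
    sweep_parameters,
)

from conftest import random_tree_pedigree

# closed-form Bayes values for the default model (prior 0.01, penetrance 0.9):
# 0.01*0.9^4 / (0.01*0.9^4 + 0.99*0.5^4) and the 2-son/2-daughter analogue
POST_4_SONS = 0.01 * 0.9**4 / (0.01 * 0.9**4 + 0.99 * 0.5**4)
POST_2_2 = 0.01 * 0.9**2 * 0.1**2 / (0.01 * 0.9**2 * 0.1**2 + 0.99 * 0.5**4)


class TestModelParams:
    def test_defaults_follow_chosen_combination(self, default_params):
        assert default_params.penetrance == 0.90
        assert default_params.allele_freq == 0.01
        assert default_params.de_novo_rate == 1e-6
        assert default_params.mode == "male_bias_Y"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"penetrance": 1.2},
            {"allele_freq": -0.1},
            {"de_novo_rate": 2.0},
            {"penetrance": 0.3},  # below the null sex probability
            {"mode": "autosomal"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParams(**kwargs)

    def test_grid_constants_match_published_sweep(self):
        assert len(PENETRANCE_GRID) == 14
        assert len(ALLELE_FREQ_GRID) == 4
        assert len(DE_NOVO_GRID) == 5


class TestBuildNetwork:
    def test_isolated_founder_gets_prior(self, default_params):
        ped = Pedigree([Individual("x", "male")])
        net = build_network(ped, default_params)
        assert net.priors[0] == (0.99, 0.01)
        post = run_belief_propagation(net)
        assert post.values["x"] == pytest.approx(0.01, abs=1e-12)

    def test_female_cannot_carry_y(self, default_params):
        ped = Pedigree([Individual("x", "female")])
        net = build_network(ped, default_params)
        assert net.priors[0] == (1.0, 0.0)

    def test_x_mode_female_founder_can_carry(self):
        ped = Pedigree([Individual("x", "female")])
        params = ModelParams(mode="female_bias_X")
        post = run_warp(ped, params)
        assert post.values["x"] == pytest.approx(0.01, abs=1e-12)

    def test_cpt_rows_normalize(self, default_params):
        rng = np.random.default_rng(3)
        ped = random_tree_pedigree(rng, 40)
        for mode in ("male_bias_Y", "female_bias_X"):
            net = build_network(ped, ModelParams(mode=mode))
            for fam in net.families:
                for tab in fam.tables:
                    for (t0, t1) in tab:
                        # psi = P(sex|parents) * P(carrier|...); summing the
                        # carrier dimension leaves the sex evidence, a
                        # probability (or 1 when sex is uninformative)
                        assert 0.0 <= t0 + t1 <= 1.0 + 1e-12


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["male_bias_Y", "female_bias_X"])
    def test_bp_matches_enumeration(self, mode):
        rng = np.random.default_rng(17)
        for _ in range(25):
            ped = random_tree_pedigree(rng, int(rng.integers(2, 13)))
            params = ModelParams(
                mode=mode,
                penetrance=float(rng.choice([0.5, 0.7, 0.9, 0.99])),
                de_novo_rate=float(rng.choice([1e-6, 1e-3])),
            )
            bp = run_warp(ped, params)
            exact = exact_posterior_enumeration(ped, params)
            assert bp.converged
            for iid, v in exact.values.items():
                assert bp.values[iid] == pytest.approx(v, abs=1e-9)

    def test_enumeration_refuses_large_pedigrees(self, default_params):
        ped = Pedigree([Individual(f"m{k}", "male") for k in range(21)])
        with pytest.raises(ValueError, match="enumeration"):
            exact_posterior_enumeration(ped, default_params)

    def test_loopy_pedigree_flagged_but_bounded(self):
        # inbreeding loop: sibling mating; loopy BP stays in [0,1] and
        # reports its convergence status honestly
        ped = Pedigree(
            [
                Individual("gf", "male"),
                Individual("gm", "female"),
                Individual("a", "male", "gf", "gm"),
                Individual("b", "female", "gf", "gm"),
                Individual("c", "female", "a", "b"),
            ],
            mode="permissive",
        )
        post = run_warp(ped, ModelParams(mode="female_bias_X"), damping=0.2)
        assert all(0.0 <= v <= 1.0 for v in post.values.values())
        assert isinstance(post.converged, bool)


class TestSibshipPosteriors:
    def test_no_evidence_returns_prior(self, default_params):
        assert single_sibship_posterior(0, 0, default_params) == pytest.approx(0.01)

    def test_four_sons_closed_form(self, default_params):
        assert single_sibship_posterior(4, 0, default_params) == pytest.approx(
            POST_4_SONS, abs=1e-12
        )
        assert POST_4_SONS == pytest.approx(0.0959, abs=5e-5)

    def test_two_two_closed_form(self, default_params):
        assert single_sibship_posterior(2, 2, default_params) == pytest.approx(
            POST_2_2, abs=1e-12
        )
        assert POST_2_2 == pytest.approx(0.00131, abs=5e-6)

    def test_matches_enumeration_on_the_pedigree(
        self, founder_sons_pedigree, default_params
    ):
        exact = exact_posterior_enumeration(founder_sons_pedigree, default_params)
        assert exact.values["f"] == pytest.approx(
            single_sibship_posterior(4, 0, default_params), abs=1e-12
        )

    def test_four_sons_beats_two_and_two(self, default_params):
        # a father of four sons has a higher carrier likelihood than a
        # father of two sons and two daughters
        inds = [Individual("f", "male")] + [
            Individual(f"s{i}", "male", father_id="f") for i in range(2)
        ] + [Individual(f"d{i}", "female", father_id="f") for i in range(2)]
        mixed = Pedigree(inds)
        p22 = run_warp(mixed, default_params).values["f"]
        inds4 = [Individual("f", "male")] + [
            Individual(f"s{i}", "male", father_id="f") for i in range(4)
        ]
        p40 = run_warp(Pedigree(inds4), default_params).values["f"]
        assert p40 > p22

    @given(extra=st.integers(0, 6))
    @settings(max_examples=7, deadline=None)
    def test_monotone_in_favored_count(self, extra):
        params = ModelParams()
        total = 8
        a = single_sibship_posterior(extra, total - extra, params)
        b = single_sibship_posterior(extra + 1, total - extra - 1, params)
        assert b >= a


class TestNullDegeneracy:
    def test_penetrance_half_recovers_prior_chain(self):
        # null model: sex evidence carries no information, so posteriors
        # follow priors + inheritance alone down a male chain
        params = ModelParams(penetrance=0.5, de_novo_rate=1e-3)
        ped = Pedigree(
            [
                Individual("a", "male"),
                Individual("b", "male", father_id="a"),
                Individual("c", "male", father_id="b"),
                Individual("d", "female", father_id="b"),
            ]
        )
        post = run_warp(ped, params)
        af, dn = params.allele_freq, params.de_novo_rate
        expect_a = af
        expect_b = expect_a * (1 - dn) + (1 - expect_a) * dn
        expect_c = expect_b * (1 - dn) + (1 - expect_b) * dn
        assert post.values["a"] == pytest.approx(expect_a, abs=1e-9)
        assert post.values["b"] == pytest.approx(expect_b, abs=1e-9)
        assert post.values["c"] == pytest.approx(expect_c, abs=1e-9)
        assert post.values["d"] == 0.0

    def test_all_female_pedigree_posteriors_below_prior(self, default_params):
        ped = Pedigree(
            [
                Individual("f", "male"),
                *[Individual(f"d{i}", "female", father_id="f") for i in range(4)],
            ]
        )
        post = run_warp(ped, default_params)
        assert post.values["f"] <= default_params.allele_freq


class TestHeritabilityCoupling:
    def test_son_posterior_increases_with_father_evidence(self, default_params):
        # same son sibship; father's own sibship made more male-biased
        def build(father_sons, father_daughters):
            inds = [Individual("gf", "male")]
            inds += [
                Individual(f"u{i}", "male", father_id="gf")
                for i in range(father_sons)
            ]
            inds += [
                Individual(f"a{i}", "female", father_id="gf")
                for i in range(father_daughters)
            ]
            # u0 is the father under study; his son s
            inds.append(Individual("s", "male", father_id="u0"))
            return Pedigree(inds)

        weak = run_warp(build(1, 3), default_params)
        strong = run_warp(build(4, 0), default_params)
        assert strong.values["u0"] > weak.values["u0"]
        assert strong.values["s"] > weak.values["s"]

    def test_posteriors_bounded_on_fuzzed_pedigrees(self, default_params):
        rng = np.random.default_rng(23)
        for _ in range(10):
            ped = random_tree_pedigree(rng, 60)
            post = run_warp(ped, default_params)
            assert all(0.0 <= v <= 1.0 for v in post.values.values())


class TestSweepParameters:
    def test_single_cell_grid_matches_direct_run(self, founder_sons_pedigree):
        table = sweep_parameters(
            founder_sons_pedigree, [0.9], [0.01], [1e-6]
        )
        assert len(table) == 1
        row = table.iloc[0]
        direct = run_warp(founder_sons_pedigree, ModelParams())
        assert row["max_posterior"] == pytest.approx(direct.max_value())
        assert row["argmax_id"] == direct.max_id()

    def test_null_penetrance_never_wins_on_biased_data(self, founder_sons_pedigree):
        table = sweep_parameters(
            founder_sons_pedigree, [0.5, 0.7, 0.9], [0.01], [1e-6]
        )
        by_pen = table.set_index("penetrance")["max_posterior"]
        assert by_pen[0.5] <= by_pen[0.7]
        assert by_pen[0.5] <= by_pen[0.9]

    def test_full_grid_unique_rows(self):
        rng = np.random.default_rng(9)
        ped = random_tree_pedigree(rng, 200)
        table = sweep_parameters(ped)
        assert len(table) == 14 * 4 * 5
        combos = table[["penetrance", "allele_freq", "de_novo_rate"]]
        assert not combos.duplicated().any()

    def test_empty_grid_rejected(self, founder_sons_pedigree):
        with pytest.raises(ValueError):
            sweep_parameters(founder_sons_pedigree, [], [0.01], [1e-6])
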