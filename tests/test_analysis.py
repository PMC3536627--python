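import numpy as np
import pytest

from cisevo import analysis, dynamics, evolution, genome, landscape as ls
from cisevo.analysis import CATEGORIES, EventTable
from cisevo.errors import (
    BaselineError,
    DecompositionError,
    GenerationError,
    InvalidParameterError,
)
from cisevo.genome import PointMutation

from conftest import table_from_binders


def make_individual(urrs, tables, tf_signs=None, initial_state=None):
    n = len(urrs)
    g = genome.Genotype(
        urrs=tuple(urrs),
        tf_signs=tf_signs if tf_signs is not None else [1.0] * n,
        initial_state=initial_state if initial_state is not None else [0.0] * n,
    )
    net = genome.build_network(g, tables)
    res = dynamics.develop(g, net)
    assert res.stable
    return evolution.Individual(genotype=g, network=net, result=res, fitness=1.0)


@pytest.fixture()
def toy_tables():
    t0 = table_from_binders({"AAAAAAAA": 1.0, "AAAAAAAC": 0.4}, tf_id="tf0")
    t1 = table_from_binders({"GGGGGGGG": 1.0}, tf_id="tf1")
    return [t0, t1]


class TestClassifyMutation:
    def test_silent_in_binder_free_region(self, toy_tables):
        g = genome.Genotype(
            urrs=("C" * 50, "T" * 50), tf_signs=[1, 1], initial_state=[0, 0]
        )
        mut = PointMutation(gene=0, position=25, old_base="C", new_base="T")
        assert analysis.classify_mutation(g, mut, toy_tables) == "silent"

    def test_preserved_site(self, toy_tables):
        # sole TF0 site AAAAAAAA; last A -> C keeps it a (weaker) binder
        urr = "T" * 20 + "AAAAAAAA" + "T" * 22
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=27, old_base="A", new_base="C")
        assert analysis.classify_mutation(g, mut, toy_tables) == "preserved"

    def test_deleted_unique(self, toy_tables):
        urr = "T" * 20 + "AAAAAAAA" + "T" * 22
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=27, old_base="A", new_base="G")
        assert analysis.classify_mutation(g, mut, toy_tables) == "deleted_unique"

    def test_deleted_redundant(self, toy_tables):
        # two disjoint TF0 sites; destroying one leaves the input intact
        urr = "AAAAAAAA" + "T" * 10 + "AAAAAAAA" + "T" * 24
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=0, old_base="A", new_base="G")
        assert analysis.classify_mutation(g, mut, toy_tables) == "deleted_redundant"

    def test_created_unique(self, toy_tables):
        urr = "T" * 20 + "GGGGGGGC" + "T" * 22
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=27, old_base="C", new_base="G")
        assert analysis.classify_mutation(g, mut, toy_tables) == "created_unique"

    def test_created_redundant(self, toy_tables):
        urr = "GGGGGGGG" + "T" * 10 + "GGGGGGGC" + "T" * 24
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=25, old_base="C", new_base="G")
        assert analysis.classify_mutation(g, mut, toy_tables) == "created_redundant"

    def test_combined(self, toy_tables):
        # A->G at the junction destroys the TF0 site and creates a TF1 site
        urr = "T" * 13 + "AAAAAAAA" + "GGGGGGG" + "T" * 22
        g = genome.Genotype(urrs=(urr, "C" * 50), tf_signs=[1, 1],
                            initial_state=[0, 0])
        mut = PointMutation(gene=0, position=20, old_base="A", new_base="G")
        assert analysis.classify_mutation(g, mut, toy_tables) == "combined"

    def test_every_probe_has_one_category(self, default_tables):
        rng = np.random.default_rng(0)
        g = genome.random_genotype(10, 50, rng)
        for _ in range(300):
            mut = analysis.random_point_mutation(g, rng)
            cat = analysis.classify_mutation(g, mut, default_tables)
            assert cat in CATEGORIES


class TestProbeAndRobustness:
    def test_silent_effect_is_zero(self, toy_tables):
        ind = make_individual(["C" * 50, "T" * 50], toy_tables)
        mut = PointMutation(gene=0, position=10, old_base="C", new_base="A")
        # single C->A cannot complete an 8-mer binder inside poly-C
        ev = analysis.probe_mutation(ind, toy_tables, mut)
        assert ev.category == "silent"
        assert ev.stable
        assert ev.effect == 0.0

    def test_binder_free_robustness(self, toy_tables):
        ind = make_individual(["C" * 50, "T" * 50], toy_tables)
        rng = np.random.default_rng(1)
        mean_d, frac = analysis.measure_robustness(ind, toy_tables, 200, rng)
        # single point mutations in poly-C/poly-T cannot create any toy binder
        assert mean_d == 0.0
        assert frac == 1.0

    def test_fraction_stable_bounds(self, default_tables):
        rng = np.random.default_rng(2)
        cfg = evolution.SimulationConfig(M=1, generations=0, seed=4)
        ind = evolution.make_founder(cfg, default_tables, rng)
        _, frac = analysis.measure_robustness(ind, default_tables, 50, rng)
        assert 0.0 <= frac <= 1.0

    def test_n_mut_validation(self, toy_tables):
        ind = make_individual(["C" * 50, "T" * 50], toy_tables)
        with pytest.raises(InvalidParameterError):
            analysis.measure_robustness(ind, toy_tables, 0, np.random.default_rng(0))


class TestEventTable:
    def test_frequencies_sum_to_one(self, default_tables):
        rng = np.random.default_rng(3)
        cfg = evolution.SimulationConfig(M=1, generations=0, seed=5)
        ind = evolution.make_founder(cfg, default_tables, rng)
        table = analysis.event_table([ind] * 5, default_tables, 100, rng)
        assert sum(table.f.values()) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= table.f_s <= 1.0

    def test_binder_free_population_all_silent(self, toy_tables):
        ind = make_individual(["C" * 50, "T" * 50], toy_tables)
        rng = np.random.default_rng(4)
        table = analysis.event_table([ind], toy_tables, 100, rng)
        assert table.f["silent"] == pytest.approx(1.0)
        assert table.e["silent"] == 0.0

    def test_silent_mean_effect_zero(self, default_tables):
        rng = np.random.default_rng(5)
        cfg = evolution.SimulationConfig(M=1, generations=0, seed=6)
        ind = evolution.make_founder(cfg, default_tables, rng)
        table = analysis.event_table([ind] * 3, default_tables, 200, rng)
        assert table.e["silent"] == 0.0


def _table(f, e, f_s):
    full_f = {c: f.get(c, 0.0) for c in CATEGORIES}
    full_e = {c: e.get(c, 0.0) for c in CATEGORIES}
    return EventTable(f=full_f, e=full_e, f_s=f_s)


class TestDecomposition:
    def test_identical_tables_error(self):
        t = _table({"silent": 0.5, "preserved": 0.5}, {"preserved": 0.1}, 1.0)
        with pytest.raises(DecompositionError):
            analysis.decompose_robustness(t, t)

    def test_constant_frequencies_give_cs_zero(self):
        t0 = _table({"silent": 0.5, "preserved": 0.5}, {"preserved": 0.2}, 1.0)
        t1 = _table({"silent": 0.5, "preserved": 0.5}, {"preserved": 0.1}, 1.0)
        dec = analysis.decompose_robustness(t0, t1)
        assert dec.cs == pytest.approx(0.0)
        for c in CATEGORIES:
            assert dec.rho[c] == pytest.approx(dec.rho_prime[c])

    def test_two_category_hand_computed(self):
        # spreadsheet oracle, worked by hand:
        #   g0 = (silent .6, deleted_unique .4), e0 = (0, .05)
        #   g1 = (silent .8, deleted_unique .2), e1 = (0, .04)
        #   rho(silent) = 0; rho(du) = .05*.4 - .04*.2 = .012
        #   rho'(du) = (.05-.04)*.4 = .004
        #   delta_g(du) = -.2 < 0  ->  CS = (.012-.004)/.012 = 2/3
        t0 = _table({"silent": 0.6, "deleted_unique": 0.4},
                    {"deleted_unique": 0.05}, 1.0)
        t1 = _table({"silent": 0.8, "deleted_unique": 0.2},
                    {"deleted_unique": 0.04}, 1.0)
        dec = analysis.decompose_robustness(t0, t1)
        assert dec.cs == pytest.approx(2 / 3)

    def test_delta_g_sums_to_zero(self):
        t0 = _table({"silent": 0.6, "deleted_unique": 0.3, "preserved": 0.1},
                    {"deleted_unique": 0.05, "preserved": 0.01}, 0.99)
        t1 = _table({"silent": 0.7, "deleted_unique": 0.2, "preserved": 0.1},
                    {"deleted_unique": 0.03, "preserved": 0.02}, 0.97)
        dec = analysis.decompose_robustness(t0, t1)
        assert sum(dec.delta_g.values()) == pytest.approx(0.0, abs=1e-9)


class TestAvoidanceAndDeNovo:
    def test_avoidance_arithmetic(self):
        t = _table({"silent": 0.5}, {}, 1.0)
        assert analysis.tfbs_avoidance(t, 0.5) == pytest.approx(1.0)
        t = _table({"silent": 0.9}, {}, 1.0)
        assert analysis.tfbs_avoidance(t, 0.6) == pytest.approx(1.5)
        with pytest.raises(InvalidParameterError):
            analysis.tfbs_avoidance(t, 0.0)

    def test_de_novo_zero_with_empty_tables(self):
        tables = [table_from_binders({}, tf_id="tf0")]
        g = genome.Genotype(urrs=("C" * 50,), tf_signs=[1], initial_state=[0])
        net = genome.build_network(g, tables)
        assert analysis.de_novo_propensity(g, net, tables) == 0.0

    def test_de_novo_single_window(self):
        # URR of exactly one window; count binder-creating mutants by hand
        site = "CCCCCCCC"
        muts = sorted(ls.single_point_mutants(site))
        tables = [table_from_binders({m: 0.5 for m in muts[:6]}, tf_id="tf0")]
        g = genome.Genotype(urrs=(site,), tf_signs=[1], initial_state=[0])
        net = genome.build_network(g, tables)
        assert analysis.de_novo_propensity(g, net, tables) == pytest.approx(6 / 24)

    def test_de_novo_requires_free_window(self):
        tables = [table_from_binders({"AAAAAAAA": 1.0}, tf_id="tf0")]
        g = genome.Genotype(urrs=("A" * 8,), tf_signs=[1], initial_state=[0])
        net = genome.build_network(g, tables)
        with pytest.raises(GenerationError):
            analysis.de_novo_propensity(g, net, tables)

    def test_de_novo_in_unit_interval(self, default_tables):
        rng = np.random.default_rng(6)
        g = genome.random_genotype(10, 50, rng)
        net = genome.build_network(g, default_tables)
        val = analysis.de_novo_propensity(g, net, default_tables)
        assert 0.0 <= val <= 1.0


class TestConservationMeasures:
    def test_mean_conservation_range(self, default_tables):
        rng = np.random.default_rng(7)
        cfg = evolution.SimulationConfig(M=1, generations=0, seed=8)
        ind = evolution.make_founder(cfg, default_tables, rng)
        val = analysis.mean_tfbs_conservation(ind, default_tables)
        assert 0.0 <= val <= 1.0

    def test_single_site_half_conserved(self):
        site = "ACGTACGT"
        muts = sorted(ls.single_point_mutants(site))
        binders = {site: 1.0}
        binders.update({m: 0.5 for m in muts[:12]})
        tables = [table_from_binders(binders, tf_id="tf0")]
        urr = "T" * 20 + site + "T" * 22
        # poly-T windows must not bind: ensure TTTTTTTT not in binders
        ind = make_individual([urr], tables)
        assert analysis.mean_tfbs_conservation(ind, tables) == pytest.approx(0.5)


class TestRewiring:
    def test_phi_identical(self):
        w = np.eye(5)
        assert analysis.rewiring_phi(w, w) == 0.0

    def test_phi_disjoint(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[0, 0] = 1.0
        b[1, 1] = 1.0
        assert analysis.rewiring_phi(a, b) == 1.0

    def test_phi_partial(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 0] = a[0, 1] = 1.0
        b[0, 0] = b[1, 1] = 1.0
        # intersection 1, union 3 -> phi = 2/3
        assert analysis.rewiring_phi(a, b) == pytest.approx(2 / 3)

    def test_phi_empty_networks(self):
        z = np.zeros((3, 3))
        assert analysis.rewiring_phi(z, z) == 0.0

    def test_phi_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            a = (rng.random((5, 5)) < 0.3).astype(float)
            b = (rng.random((5, 5)) < 0.3).astype(float)
            sa = {(i, j) for i, j in zip(*np.nonzero(a))}
            sb = {(i, j) for i, j in zip(*np.nonzero(b))}
            union = sa | sb
            expected = 1 - len(sa & sb) / len(union) if union else 0.0
            assert analysis.rewiring_phi(a, b) == pytest.approx(expected)
            assert 0.0 <= analysis.rewiring_phi(a, b) <= 1.0

    def test_phi_corrected(self):
        base = analysis.BaselineFit(a=0.6, b=0.0, r2=1.0)
        assert analysis.phi_corrected(0.6, 0.5, base) == pytest.approx(0.0)
        assert analysis.phi_corrected(1.0, 0.5, base) == pytest.approx(1.0)
        assert analysis.phi_corrected(0.8, 0.5, base) == pytest.approx(0.5)

    def test_estimate_rewiring_bundle(self):
        base = analysis.BaselineFit(a=0.5, b=0.0, r2=1.0)
        a = np.zeros((2, 2))
        b = np.zeros((2, 2))
        a[0, 0] = 1.0
        b[1, 1] = 1.0
        est = analysis.estimate_rewiring(a, b, base)
        assert est.phi_raw == 1.0
        assert est.phi_random == 0.5
        assert est.phi_corrected == 1.0

    def test_phi_corrected_invalid_baseline(self):
        base = analysis.BaselineFit(a=1.2, b=0.0, r2=1.0)
        with pytest.raises(BaselineError):
            analysis.phi_corrected(0.5, 0.5, base)

    def test_baseline_grid_validation(self, default_tables):
        cfg = evolution.SimulationConfig()
        with pytest.raises(InvalidParameterError):
            analysis.phi_random_baseline(
                [0.2], default_tables, cfg, np.random.default_rng(0)
            )

    def test_baseline_fit(self, default_tables):
        cfg = evolution.SimulationConfig()
        rng = np.random.default_rng(9)
        fit = analysis.phi_random_baseline(
            [0.15, 0.35], default_tables, cfg, rng, n_pairs=15
        )
        assert 0.0 <= fit.r2 <= 1.0
        # spurious overlap grows with connectivity, so random phi decreases
        assert fit.b < 0
        assert 0.0 < fit.predict(0.25) < 1.0


class TestNetRedundancy:
    def test_random_individual_near_zero(self, default_tables):
        rng = np.random.default_rng(10)
        cfg = evolution.SimulationConfig(M=1, generations=0, seed=11)
        ind = evolution.make_founder(cfg, default_tables, rng)
        raw, corrected = analysis.net_redundancy(
            ind, default_tables, cfg, rng, n_random=60
        )
        assert raw >= 0
        # the individual is itself a random draw, so the correction should
        # bring it near zero (loose bound: within a few sites)
        assert abs(corrected) < 6.0


class TestCombinedComposition:
    def test_components_mirror_single_event_frequencies(self, default_tables):
        # long URRs produce frequent combined events; their internal make-up
        # should rank-correlate with the single-event frequencies
        from scipy import stats as sps

        rng = np.random.default_rng(12)
        cfg = evolution.SimulationConfig(L=200, M=1, generations=0, seed=13)
        ind = evolution.make_founder(cfg, default_tables, rng)
        table = analysis.event_table([ind] * 10, default_tables, 300, rng)
        singles = ["deleted_unique", "deleted_redundant",
                   "created_unique", "created_redundant"]
        f_single = [table.f[c] for c in singles]
        f_comb = [table.combined_components.get(c, 0) for c in singles]
        rho, _ = sps.spearmanr(f_single, f_comb)
        assert rho > 0
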