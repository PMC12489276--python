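import numpy as np
import pytest
from scipy import stats

from algaegem import (
    MetabolicModel,
    parse_gpr,
    Metabolite,
    Reaction,
    call_active_reactions,
    compare_homolog_fluxes,
    condition_partition,
    essentiality,
    fba,
    fva,
    growth_correlated_targets,
    pfba,
)
from algaegem.sampling import FluxSample
from algaegem.synthetic import ToySpec, make_random_model


def parallel_paths_model():
    """Substrate to product via a 1-step and a 2-step route."""
    m = MetabolicModel(id="parallel", compartments=["c", "e"])
    for mid, comp in [("s_e", "e"), ("s", "c"), ("i", "c"), ("p", "c")]:
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_s", {"s_e": -1.0}, lb=-10, ub=1000, kind="exchange"))
    m.add_reaction(Reaction("UPT", {"s_e": -1.0, "s": 1.0}))
    m.add_reaction(Reaction("short", {"s": -1.0, "p": 1.0}))
    m.add_reaction(Reaction("long1", {"s": -1.0, "i": 1.0}))
    m.add_reaction(Reaction("long2", {"i": -1.0, "p": 1.0}))
    m.add_reaction(Reaction("biomass", {"p": -1.0}, kind="biomass"))
    m.objective = "biomass"
    return m


class TestFBA:
    def test_chain_closed_form(self, chain_model):
        model, records = chain_model
        res = fba(model)
        assert res.ok
        assert res.objective == pytest.approx(records["expected_growth"])  # 5.0

    def test_blocked_biomass_gives_zero(self, chain_model):
        model, _ = chain_model
        broken = model.copy()
        broken.remove_reactions(["R2"])
        res = fba(broken)
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_respected(self, chain_model):
        model, _ = chain_model
        res = fba(model)
        for r in model.reactions:
            assert r.lb - 1e-6 <= res.fluxes[r.id] <= r.ub + 1e-6
        balance = {}
        for r in model.reactions:
            for met, c in r.stoich.items():
                balance[met] = balance.get(met, 0.0) + c * res.fluxes[r.id]
        assert max(abs(v) for v in balance.values()) < 1e-6


class TestPFBA:
    def test_growth_matches_fba_at_fraction_one(self, chain_model):
        model, _ = chain_model
        assert pfba(model).objective == pytest.approx(fba(model).objective, rel=1e-9)

    def test_parsimony_zeroes_longer_route(self):
        model = parallel_paths_model()
        sol = pfba(model)
        assert sol.fluxes["short"] == pytest.approx(10.0)
        assert sol.fluxes["long1"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["long2"] == pytest.approx(0.0, abs=1e-9)

    def test_total_flux_not_above_fba_solution(self, chain_model):
        model, _ = chain_model
        fba_total = sum(abs(v) for v in fba(model).fluxes.values())
        pfba_total = sum(abs(v) for v in pfba(model).fluxes.values())
        assert pfba_total <= fba_total + 1e-6


class TestFVA:
    def test_essential_chain_has_point_ranges(self, chain_model):
        model, _ = chain_model
        ranges = fva(model)
        for rid, (lo, hi) in ranges.items():
            if rid == "EX_S":
                assert (lo, hi) == pytest.approx((-10.0, -10.0))
            else:
                assert lo == pytest.approx(hi)

    def test_parallel_branches_share_total(self):
        model = parallel_paths_model()
        ranges = fva(model)
        assert ranges["short"] == pytest.approx((0.0, 10.0))
        assert ranges["long1"] == pytest.approx((0.0, 10.0))

    def test_fraction_zero_relaxes_to_bounds(self, chain_model):
        model, _ = chain_model
        ranges = fva(model, fraction_of_optimum=0.0)
        assert ranges["biomass"] == pytest.approx((0.0, 5.0))

    def test_brackets_fba_fluxes(self, chain_model):
        model, _ = chain_model
        sol = fba(model)
        for rid, (lo, hi) in fva(model).items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


class TestActiveReactions:
    def test_used_irreversible_reactions_are_active(self, chain_model):
        model, _ = chain_model
        active = call_active_reactions(model)
        assert {"R1", "R2", "R3", "R4", "UPT", "biomass"} <= active

    def test_cycle_pair_with_equal_maxima_excluded(self):
        m = parallel_paths_model()
        # add a reversible shuttle that forms a 2-cycle with itself: its split
        # halves have identical maxima and must be excluded
        m.add_metabolite(Metabolite("q", compartment="c"))
        m.add_reaction(Reaction("shuttle", {"i": -1.0, "q": 1.0}, lb=-1000, ub=1000))
        m.add_reaction(Reaction("shuttle2", {"q": -1.0, "i": 1.0}, lb=-1000, ub=1000))
        active = call_active_reactions(m, fraction_of_optimum=0.0)
        assert "shuttle" not in active
        assert "shuttle2" not in active

    def test_unequal_maxima_keep_parent_active(self):
        m = parallel_paths_model()
        # reversible reaction whose backward capacity differs from forward
        m.reactions[2].lb = -3.0  # "short" now reversible with asymmetric caps
        active = call_active_reactions(m, fraction_of_optimum=0.0)
        assert "short" in active


class TestPartition:
    def test_seven_class_table(self):
        auto = frozenset({"a", "b"})
        mixo = frozenset({"b", "c"})
        hetero = frozenset({"c"})
        part = condition_partition(auto, mixo, hetero)
        assert part["auto_only"] == {"a"}
        assert part["auto_mixo"] == {"b"}
        assert part["mixo_hetero"] == {"c"}
        assert part["hetero_only"] == set()
        assert part["all"] == set()

    def test_identical_sets_collapse_to_triple_intersection(self):
        s = frozenset({"x", "y"})
        part = condition_partition(s, s, s)
        assert part["all"] == s
        assert all(not part[k] for k in part if k != "all")

    def test_classes_partition_the_union(self):
        rng = np.random.default_rng(7)
        universe = [f"r{i}" for i in range(30)]
        sets = [frozenset(rng.choice(universe, size=rng.integers(5, 20),
                                     replace=False)) for _ in range(3)]
        part = condition_partition(*sets)
        union = frozenset().union(*sets)
        assert frozenset().union(*part.values()) == union
        assert sum(len(v) for v in part.values()) == len(union)


class TestEssentiality:
    def test_single_path_everything_essential(self, chain_model):
        model, _ = chain_model
        ess = essentiality(model, target="reaction")
        assert {"UPT", "R1", "R2", "R3", "R4", "biomass", "EX_S"} <= ess

    def test_isozyme_pair_protects_genes_not_reaction(self):
        m = parallel_paths_model()
        m.remove_reactions(["long1", "long2"])
        m.reaction("short").gpr = parse_gpr("g1 or g2")
        assert essentiality(m, target="gene") == frozenset()
        assert "short" in essentiality(m, target="reaction")

    def test_complex_makes_both_genes_essential(self):
        m = parallel_paths_model()
        m.remove_reactions(["long1", "long2"])
        m.reaction("short").gpr = parse_gpr("g1 and g2")
        assert essentiality(m, target="gene") == frozenset({"g1", "g2"})

    def test_gene_and_reaction_views_consistent(self, chain_model):
        """A single-gene reaction is essential iff its gene is."""
        model, _ = chain_model
        ess_g = essentiality(model, target="gene")
        ess_r = essentiality(model, target="reaction")
        for r in model.reactions:
            genes = r.genes
            if len(genes) == 1:
                assert (r.id in ess_r) == (next(iter(genes)) in ess_g)


class TestGrowthCorrelation:
    def test_chain_reactions_all_perfectly_correlated(self, chain_model):
        model, _ = chain_model
        res = growth_correlated_targets(model, n_increments=25)
        assert res.genes == model.genes
        assert (res.table.loc[res.table["selected"], "r"] > 0.999).all()

    def test_constant_flux_reaction_skipped(self, chain_model):
        model, _ = chain_model
        fixed = model.copy()
        # maintenance-style reaction pinned at constant flux
        fixed.add_metabolite(Metabolite("atp_like", compartment="c"))
        fixed.add_reaction(Reaction("gen", {"atp_like": 1.0}, lb=1.0, ub=1.0))
        fixed.add_reaction(Reaction("use", {"atp_like": -1.0}, lb=0.0, ub=10.0))
        res = growth_correlated_targets(fixed, n_increments=15)
        assert "gen" in res.skipped

    def test_matches_independent_pearson_recomputation(self, chain_model):
        """Flux series r and p agree with a direct scipy recomputation."""
        model, _ = chain_model
        n = 20
        res = growth_correlated_targets(model, n_increments=n, mtc="bonferroni")
        mu_max = fba(model).objective
        grid = np.array([(k / n) * mu_max for k in range(1, n + 1)])
        for rid in ("R1", "biomass"):
            series = []
            for mu in grid:
                fixed = model.copy()
                bio = fixed.reaction("biomass")
                bio.lb = bio.ub = mu
                series.append(pfba(fixed).fluxes[rid])
            r_ref, p_ref = stats.pearsonr(np.array(series), grid)
            row = res.table[res.table["reaction_id"] == rid].iloc[0]
            assert row["r"] == pytest.approx(r_ref, abs=1e-9)
            assert row["p"] == pytest.approx(p_ref, rel=1e-6)

    def test_degenerate_screen_returns_every_varying_reaction(self, chain_model):
        model, _ = chain_model
        res = growth_correlated_targets(model, n_increments=15, r_min=0.0, alpha=1.0)
        varying = {r.id for r in model.reactions} - res.skipped
        positively = set(res.table.loc[res.table["r"] > 0, "reaction_id"])
        # every varying, positively-correlated reaction passes the degenerate
        # screen (uptake exchanges anticorrelate by sign convention)
        assert set(res.table.loc[res.table["selected"], "reaction_id"]) == varying & positively
        assert varying - positively <= {"EX_S"}


class TestHomologComparison:
    @staticmethod
    def _sample(mat, ids):
        return FluxSample(samples=np.asarray(mat, dtype=float), reaction_ids=ids,
                          seed=0, thinning=1)

    def test_identical_samples_yield_no_hits(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(200, 2))
        a = self._sample(mat, ["r1", "r2"])
        b = self._sample(mat.copy(), ["r1", "r2"])
        table = compare_homolog_fluxes(a, b, [("r1", "r1"), ("r2", "r2")])
        assert int(table["significant"].sum()) == 0

    def test_planted_five_sigma_shift_detected(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(500, 3))
        shifted = base.copy()
        shifted[:, 1] += 5.0  # 5 SD shift in one reaction only
        a = self._sample(shifted, ["x", "y", "z"])
        b = self._sample(rng.normal(size=(500, 3)), ["x", "y", "z"])
        table = compare_homolog_fluxes(a, b, [("x", "x"), ("y", "y"), ("z", "z")])
        assert table.loc[table["reaction_a"] == "y", "significant"].item()
        assert table.loc[table["reaction_a"] == "y", "higher_in"].item() == "a"
        assert int(table["significant"].sum()) == 1

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(5)
        mats = rng.normal(size=(2, 100, 4))
        a, b = (self._sample(m, list("abcd")) for m in mats)
        pairs = [(c, c) for c in "abcd"]
        table = compare_homolog_fluxes(a, b, pairs)
        raw_scaled = np.minimum(table["p"].to_numpy() * len(pairs), 1.0)
        assert table["p_bonf"].to_numpy() == pytest.approx(raw_scaled)

    def test_zero_variance_pair_flagged_undefined(self):
        a = self._sample(np.ones((50, 1)), ["r"])
        b = self._sample(np.ones((50, 1)) * 2, ["r"])
        table = compare_homolog_fluxes(a, b, [("r", "r")])
        assert table["higher_in"].item() == "undefined"
        assert not table["significant"].item()


def test_high_vs_low_light_comparison_via_identity_pairing(chain_model):
    """Comparing one model under two bound settings reduces to sampling both
    and testing identity pairs; the loosened uptake shows higher flux."""
    from algaegem.sampling import sample_fluxes

    model, _ = chain_model
    tight = model.copy()
    tight.reaction("EX_S").lb = -2.0
    loose = model.copy()
    a = sample_fluxes(loose, n=150, thinning=20, seed=10)
    b = sample_fluxes(tight, n=150, thinning=20, seed=11)
    table = compare_homolog_fluxes(a, b, [("biomass", "biomass")])
    assert table["significant"].item()
    assert table["higher_in"].item() == "a"
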