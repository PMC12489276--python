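import pytest

from algaegem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    aggregate_tool_predictions,
    assign_reaction_compartments,
    vote_reactions,
)
from algaegem.localization import LocalizationProfile, read_predictions_tsv
from algaegem.model import ConfigurationError
from algaegem.synthetic import make_tca_like_block, simulate_localization_profiles


def single_gene_model(n, compartments):
    m = MetabolicModel(compartments=list(compartments))
    m.add_metabolite(Metabolite("a", compartment=compartments[0]))
    m.add_metabolite(Metabolite("b", compartment=compartments[0]))
    for i in range(n):
        m.add_reaction(Reaction(f"r{i}", {"a": -1.0, "b": 1.0}, gpr=f"g{i}"))
    return m


class TestAggregation:
    def test_two_tool_symmetry(self):
        prof = LocalizationProfile()
        prof.set("p", "t1", {"c": 1.0})
        prof.set("p", "t2", {"h": 1.0})
        consensus = aggregate_tool_predictions(prof)
        assert consensus.get("p") == pytest.approx({"c": 0.5, "h": 0.5})

    def test_single_tool_identity(self):
        prof = LocalizationProfile()
        prof.set("p", "t1", {"m": 0.7, "c": 0.3})
        assert aggregate_tool_predictions(prof).get("p") == pytest.approx(
            {"m": 0.7, "c": 0.3}
        )

    def test_three_tool_hand_arithmetic(self):
        # {c:0.6,m:0.4}, {c:1.0}, {m:1.0} -> {c:8/15, m:7/15}
        prof = LocalizationProfile()
        prof.set("p", "t1", {"c": 0.6, "m": 0.4})
        prof.set("p", "t2", {"c": 1.0})
        prof.set("p", "t3", {"m": 1.0})
        consensus = aggregate_tool_predictions(prof)
        assert consensus.get("p") == pytest.approx({"c": 8 / 15, "m": 7 / 15})

    def test_per_tool_renormalization(self):
        prof = LocalizationProfile()
        prof.set("p", "t1", {"c": 0.5, "m": 0.25})  # sums to 0.75
        assert aggregate_tool_predictions(prof).get("p") == pytest.approx(
            {"c": 2 / 3, "m": 1 / 3}
        )

    def test_all_zero_protein_flagged_unlocalized(self):
        prof = LocalizationProfile()
        prof.set("p", "t1", {"c": 0.0})
        consensus = aggregate_tool_predictions(prof)
        assert "p" in consensus.unlocalized
        assert consensus.get("p") == {}

    def test_consensus_sums_to_one(self):
        prof = simulate_localization_profiles(
            {f"g{i}": ["c", "h", "m"][i % 3] for i in range(6)},
            n_tools=3, noise=0.3, seed=4, compartments=["c", "h", "m"], jitter=0.1,
        )
        consensus = aggregate_tool_predictions(prof)
        for protein in consensus.probabilities:
            assert sum(consensus.get(protein).values()) == pytest.approx(1.0, abs=1e-9)


class TestVoting:
    def test_two_gene_or_rule_splits_votes(self):
        m = MetabolicModel(compartments=["c", "m"])
        m.add_metabolite(Metabolite("a", compartment="c"))
        m.add_metabolite(Metabolite("b", compartment="c"))
        m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0}, gpr="g1 or g2"))
        prof = LocalizationProfile()
        prof.set("g1", "t", {"c": 1.0})
        prof.set("g2", "t", {"m": 1.0})
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        assert votes["r"] == pytest.approx({"c": 0.5, "m": 0.5})

    def test_four_gene_complex_three_to_one(self):
        m = MetabolicModel(compartments=["c", "m"])
        m.add_metabolite(Metabolite("a", compartment="c"))
        m.add_metabolite(Metabolite("b", compartment="c"))
        m.add_reaction(Reaction("r", {"a": -1.0, "b": 1.0},
                                gpr="g1 and g2 and g3 and g4"))
        prof = LocalizationProfile()
        for g in ("g1", "g2", "g3"):
            prof.set(g, "t", {"c": 1.0})
        prof.set("g4", "t", {"m": 1.0})
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        assert votes["r"] == pytest.approx({"c": 0.75, "m": 0.25})

    def test_votes_sum_to_one_with_gpr(self):
        truth = {f"g{i}": ["c", "h", "m"][i % 3] for i in range(9)}
        prof = simulate_localization_profiles(truth, n_tools=4, noise=0.3, seed=2,
                                              compartments=["c", "h", "m"])
        m = single_gene_model(9, ["c", "h", "m"])
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        for rid, vote in votes.items():
            assert sum(vote.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_gpr_reactions_get_no_vote_record(self):
        m = single_gene_model(1, ["c"])
        m.add_reaction(Reaction("orphan", {"a": -1.0, "b": 1.0}))
        prof = LocalizationProfile()
        prof.set("g0", "t", {"c": 1.0})
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        assert "orphan" not in votes


class TestAssignment:
    def test_threshold_keeps_all_above_25_percent(self):
        votes = {"r": {"h": 0.5, "c": 0.3, "m": 0.2}}
        assert assign_reaction_compartments(votes)["r"] == frozenset({"h", "c"})

    def test_strict_inequality_at_boundary(self):
        votes = {"r": {"c": 0.25, "m": 0.25, "h": 0.5}}
        assert assign_reaction_compartments(votes)["r"] == frozenset({"h"})

    def test_argmax_fallback_with_lexicographic_tie_break(self):
        votes = {"r": {c: 0.2 for c in ("e", "c", "m", "h", "x")}}
        assert assign_reaction_compartments(votes, threshold=0.25)["r"] == frozenset({"c"})

    def test_fixed_assignments_override_votes(self):
        votes = {"r": {"c": 1.0}}
        out = assign_reaction_compartments(votes, fixed={"r": frozenset({"m"})})
        assert out["r"] == frozenset({"m"})

    def test_fixed_compartment_must_exist_in_model(self):
        m = single_gene_model(1, ["c"])
        with pytest.raises(ConfigurationError):
            assign_reaction_compartments(
                {"r0": {"c": 1.0}}, fixed={"r0": frozenset({"zz"})}, model=m
            )

    def test_no_gpr_reactions_default_to_cytoplasm(self):
        m = single_gene_model(1, ["c", "m"])
        m.add_reaction(Reaction("orphan", {"a": -1.0, "b": 1.0}))
        out = assign_reaction_compartments({"r0": {"m": 1.0}}, model=m)
        assert out["orphan"] == frozenset({"c"})

    def test_raising_threshold_is_monotone(self):
        truth = {f"g{i}": ["c", "h", "m"][i % 3] for i in range(12)}
        prof = simulate_localization_profiles(truth, n_tools=5, noise=0.4, seed=3,
                                              compartments=["c", "h", "m"], jitter=0.2)
        m = single_gene_model(12, ["c", "h", "m"])
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        for low, high in [(0.1, 0.2), (0.2, 0.3), (0.3, 0.45)]:
            a_low = assign_reaction_compartments(votes, threshold=low)
            a_high = assign_reaction_compartments(votes, threshold=high)
            for rid in votes:
                extra = a_high[rid] - a_low[rid]
                # fallback can swap to argmax but never adds above-threshold comps
                assert not any(votes[rid].get(c, 0) > high for c in extra)


class TestRecovery:
    def test_full_recovery_at_noise_point_two(self):
        """eta=0.2, 5 tools, 25% threshold: all planted single-gene
        compartments recovered."""
        comps = ["c", "h", "m", "x", "l"]
        truth = {f"g{i}": comps[i % 5] for i in range(50)}
        prof = simulate_localization_profiles(truth, n_tools=5, noise=0.2, seed=11,
                                              compartments=comps)
        m = single_gene_model(50, comps)
        votes = vote_reactions(m, aggregate_tool_predictions(prof))
        assignment = assign_reaction_compartments(votes)
        recovered = sum(
            assignment[f"r{i}"] == frozenset({truth[f"g{i}"]}) for i in range(50)
        )
        assert recovered == 50

    def test_tca_like_block_assigned_to_mitochondrion(self):
        """All reactions of a 9-reaction mitochondrial cycle (22+ associated
        genes) land in the mitochondrion."""
        model, truth = make_tca_like_block(n_reactions=9, genes_per_reaction=3)
        prof = simulate_localization_profiles(truth, n_tools=5, noise=0.2, seed=5,
                                              compartments=["c", "m"])
        votes = vote_reactions(model, aggregate_tool_predictions(prof))
        assignment = assign_reaction_compartments(votes)
        assert all(
            assignment[r.id] == frozenset({"m"}) for r in model.reactions
        )


def test_tsv_reader_applies_aliases(tmp_path):
    path = tmp_path / "preds.tsv"
    path.write_text(
        "protein_id\ttool\tcompartment\tprobability\n"
        "p1\tdeeploc\tChloroplast\t0.8\n"
        "p1\tdeeploc\tCytosol\t0.2\n"
        "p1\ttargetp\tmitochondrion\t1.0\n"
    )
    prof = read_predictions_tsv(path)
    assert prof.data["p1"]["deeploc"] == pytest.approx({"h": 0.8, "c": 0.2})
    assert prof.data["p1"]["targetp"] == {"m": 1.0}
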