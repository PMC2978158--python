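"""Orthology projection (approaches A/B), collapse, dead-end detection."""

import pytest

from orthoflux import (
    HomologyTable,
    MetabolicModel,
    Reaction,
    count_dead_ends,
    decompartmentalize,
    generate_homology_table,
    project_model_A,
    project_model_B,
    solve_fba,
)
from orthoflux.gpr import parse_gpr


def identity_table(model):
    return HomologyTable(
        mapping={g: {f"t_{g}"} for g in model.genes}, species="target"
    )


class TestApproachA:
    def test_identity_table_keeps_everything(self, synth):
        _, model, _ = synth
        projected, report = project_model_A(model, identity_table(model))
        assert set(projected.reactions) == set(model.reactions)
        assert report.gene_ratio == 1.0 and report.reaction_ratio == 1.0

    def test_empty_table_keeps_exactly_non_gene_associated(self, synth):
        _, model, _ = synth
        projected, _ = project_model_A(model, HomologyTable())
        expected = {rid for rid, r in model.reactions.items() if r.gpr.is_empty}
        assert set(projected.reactions) == expected

    def test_isozyme_rescue_and_sole_gene_removal(self):
        m = MetabolicModel(compartments=("c", "e"))
        m.add_reaction(Reaction("r_iso", {"a[c]": -1.0, "b[c]": 1.0}, 0, 10,
                                gpr=parse_gpr("gA or gB")))
        m.add_reaction(Reaction("r_sole", {"a[c]": -1.0, "c[c]": 1.0}, 0, 10,
                                gpr=parse_gpr("gA")))
        table = HomologyTable(mapping={"gB": {"tB"}})  # gA unmapped
        projected, _ = project_model_A(m, table)
        assert "r_iso" in projected.reactions
        assert "r_sole" not in projected.reactions
        # the survivor's rule now lives in the target namespace
        assert projected.reactions["r_iso"].gpr.genes() == {"tB"}

    def test_report_ratios_equal_recounts(self, synth):
        spec, model, _ = synth
        table = generate_homology_table(spec, model, retention=0.8, seed=11)
        projected, report = project_model_A(model, table)
        mapped = {g for g, t in table.mapping.items() if t}
        assert report.gene_ratio == pytest.approx(
            len(mapped & set(model.genes)) / len(model.genes)
        )
        assert report.reaction_ratio == pytest.approx(
            len(projected.reactions) / len(model.reactions)
        )
        assert set(report.retained) | set(report.removed) == set(model.reactions)


class TestApproachB:
    def test_drops_non_gene_associated_metabolic(self, synth):
        _, model, truth = synth
        table = identity_table(model)
        mB, _ = project_model_B(model, table)
        mA, _ = project_model_A(model, table)
        for rid, r in model.reactions.items():
            if r.gpr.is_empty and truth.kind_tags[rid] == "metabolic":
                assert rid not in mB.reactions
                assert rid in mA.reactions

    def test_matches_prediction_from_ground_truth_tags(self, synth):
        spec, model, truth = synth
        table = generate_homology_table(spec, model, retention=0.85, seed=3)
        mapped = {g for g, t in table.mapping.items() if t}
        mB, _ = project_model_B(model, table)
        keep_kinds = {"transport", "demand", "sink", "exchange", "biomass"}
        expected = {
            rid
            for rid, r in model.reactions.items()
            if (r.gpr.evaluate(mapped) if not r.gpr.is_empty
                else truth.kind_tags[rid] in keep_kinds)
        }
        assert set(mB.reactions) == expected

    @pytest.mark.parametrize("retention,seed", [(1.0, 1), (0.9, 2), (0.5, 3), (0.0, 4)])
    def test_B_subset_of_A(self, synth, retention, seed):
        spec, model, _ = synth
        table = generate_homology_table(spec, model, retention=retention, seed=seed)
        mA, _ = project_model_A(model, table)
        mB, _ = project_model_B(model, table)
        assert set(mB.reactions) <= set(mA.reactions)

    def test_monotone_in_homology(self, synth):
        spec, model, _ = synth
        sparse_table = generate_homology_table(spec, model, retention=0.7, seed=9)
        richer = HomologyTable(
            mapping={g: {f"t_{g}"} for g in model.genes}, species="target"
        )
        for g, t in sparse_table.mapping.items():
            richer.mapping[g] = richer.mapping.get(g, set()) | t
        for fn in (project_model_A, project_model_B):
            small, _ = fn(model, sparse_table)
            big, _ = fn(model, richer)
            assert set(small.reactions) <= set(big.reactions)


class TestDecompartmentalize:
    def test_pure_intracellular_transport_removed(self, synth):
        _, model, truth = synth
        coll = decompartmentalize(model)
        for rid, r in model.reactions.items():
            comps = {m.split("[")[1][:-1] for m in r.stoichiometry}
            if truth.kind_tags[rid] == "transport" and "e" not in comps:
                assert rid not in coll.reactions

    def test_exchange_and_uptake_survive(self, synth):
        _, model, truth = synth
        coll = decompartmentalize(model)
        for rid, kind in truth.kind_tags.items():
            if kind == "exchange":
                assert rid in coll.reactions
        assert solve_fba(coll).objective > 0

    def test_no_more_dead_ends_than_original(self, synth):
        _, model, _ = synth
        assert len(count_dead_ends(decompartmentalize(model))) <= len(
            count_dead_ends(model)
        )

    def test_duplicate_merge_keeps_or_of_gprs(self):
        m = MetabolicModel(compartments=("c", "m", "e"))
        m.add_reaction(Reaction("r_c", {"a[c]": -1.0, "b[c]": 1.0}, 0, 10,
                                gpr=parse_gpr("g1")))
        m.add_reaction(Reaction("r_m", {"a[m]": -1.0, "b[m]": 1.0}, 0, 10,
                                gpr=parse_gpr("g2")))
        coll = decompartmentalize(m)
        assert len(coll.reactions) == 1
        merged = next(iter(coll.reactions.values()))
        assert merged.gpr.evaluate({"g1"}) and merged.gpr.evaluate({"g2"})
        assert not merged.gpr.evaluate(set())


class TestDeadEnds:
    def test_chain_without_exit_flags_terminal(self):
        m = MetabolicModel(compartments=("c", "e"))
        m.add_reaction(Reaction("EX_a", {"a[e]": -1.0}, -10, 10))
        m.add_reaction(Reaction("T", {"a[e]": -1.0, "a[c]": 1.0}, 0, 10))
        m.add_reaction(Reaction("AtoB", {"a[c]": -1.0, "b[c]": 1.0}, 0, 10))
        assert count_dead_ends(m) == {"b[c]"}

    def test_connected_cycle_with_exchange_has_none(self):
        m = MetabolicModel(compartments=("c", "e"))
        m.add_reaction(Reaction("EX_a", {"a[e]": -1.0}, -10, 10))
        m.add_reaction(Reaction("T", {"a[e]": -1.0, "a[c]": 1.0}, -10, 10))
        m.add_reaction(Reaction("AtoB", {"a[c]": -1.0, "b[c]": 1.0}, 0, 10))
        m.add_reaction(Reaction("BtoA", {"b[c]": -1.0, "a[c]": 1.0}, 0, 10))
        assert count_dead_ends(m) == set()

    def test_planted_orphans_recovered_exactly(self, synth):
        _, model, truth = synth
        assert count_dead_ends(model) == truth.dead_end_metabolites
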