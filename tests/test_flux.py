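"""FBA, FVA, gene deletion and the essentiality screen."""

import numpy as np
import pytest

from helpers import eval_gpr_text, fba_vertex_oracle, random_small_network, to_cobra
from orthoflux import (
    ModelError,
    apply_medium,
    count_active,
    delete_gene,
    essential_genes,
    essentiality_screen,
    run_fva,
    solve_fba,
)
from orthoflux.flux import disabled_by
from orthoflux.model import MetabolicModel, Reaction
from conftest import make_chain_model


class TestFBA:
    def test_chain_limited_by_uptake(self):
        m = make_chain_model(uptake=10.0)
        assert solve_fba(m).objective == pytest.approx(10.0)

    def test_chain_limited_by_internal_bottleneck(self):
        m = make_chain_model(uptake=10.0, internal_cap=5.0)
        assert solve_fba(m).objective == pytest.approx(5.0)

    def test_infeasible_reported_not_raised(self):
        m = MetabolicModel()
        # demands force consumption of a metabolite nothing produces
        m.add_reaction(Reaction("d", {"a[c]": -1.0}, 2.0, 10.0))
        m.objective_id = "d"
        assert solve_fba(m).status == "infeasible"

    def test_unknown_objective_rejected(self, chain_model):
        with pytest.raises(ModelError):
            solve_fba(chain_model, "nope")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_vertex_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_small_network(rng, n_rxns=5, n_mets=3)
        sol = solve_fba(m, "r0")
        assert sol.optimal
        assert sol.objective == pytest.approx(fba_vertex_oracle(m, "r0"), abs=1e-6)

    def test_relaxing_bound_never_decreases_optimum(self, synth):
        _, model, truth = synth
        m = apply_medium(model, truth.minimal_medium)
        base = solve_fba(m).objective
        relaxed = m.copy()
        ex = next(iter(truth.minimal_medium.bounds))
        relaxed.reactions[ex].lower = -1000.0
        assert solve_fba(relaxed).objective >= base - 1e-9

    def test_agrees_with_cobra_on_synthetic_model(self, synth):
        _, model, truth = synth
        m = apply_medium(model, truth.minimal_medium)
        assert to_cobra(m).slim_optimize() == pytest.approx(
            solve_fba(m).objective, rel=1e-6
        )


class TestFVA:
    def test_linear_chain_pins_every_reaction(self):
        m = make_chain_model(uptake=10.0)
        fva = run_fva(m, fraction=1.0)
        for rid, (lo, hi) in fva.ranges.items():
            expect = -10.0 if rid == "EX_a" else 10.0
            assert lo == pytest.approx(expect, abs=1e-6)
            assert hi == pytest.approx(expect, abs=1e-6)

    def test_parallel_equivalent_paths_range_zero_to_optimum(self):
        m = MetabolicModel(compartments=("c", "e"))
        m.add_reaction(Reaction("EX_a", {"a[e]": -1.0}, -10.0, 1000.0))
        m.add_reaction(Reaction("T1", {"a[e]": -1.0, "a[c]": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("T2", {"a[e]": -1.0, "a[c]": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("BIO", {"a[c]": -1.0}, 0.0, 1000.0))
        m.objective_id = "BIO"
        fva = run_fva(m, fraction=1.0)
        for rid in ("T1", "T2"):
            assert fva.ranges[rid][0] == pytest.approx(0.0, abs=1e-6)
            assert fva.ranges[rid][1] == pytest.approx(10.0, abs=1e-6)

    def test_fba_flux_within_fva_range(self, synth):
        _, model, truth = synth
        m = apply_medium(model, truth.minimal_medium)
        sol = solve_fba(m)
        fva = run_fva(m, fraction=1.0)
        for rid, (lo, hi) in fva.ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_infeasible_model_raises_before_loop(self):
        m = MetabolicModel()
        m.add_reaction(Reaction("d", {"a[c]": -1.0}, 2.0, 10.0))
        m.objective_id = "d"
        with pytest.raises(ModelError):
            run_fva(m)

    def test_count_active_excludes_planted_blocked(self, synth):
        _, model, truth = synth
        fva = run_fva(apply_medium(model, truth.rich_medium), fraction=0.0)
        for rid in truth.blocked_reactions:
            assert fva.ranges[rid] == (pytest.approx(0.0, abs=1e-9),) * 2
        assert count_active(fva) == len(model.reactions) - len(truth.blocked_reactions)


class TestDeletion:
    def test_isozyme_partner_rescues(self, chain_model):
        m = chain_model.copy()
        from orthoflux.gpr import parse_gpr
        from orthoflux.model import Gene

        m.reactions["AtoB"].gpr = parse_gpr("g1 or g2")
        m.genes["g2"] = Gene("g2")
        ko = delete_gene(m, "g1")
        assert ko.reactions["AtoB"].upper > 0
        assert solve_fba(ko).objective == pytest.approx(10.0)

    def test_sole_gene_zeroes_bounds(self, chain_model):
        ko = delete_gene(chain_model, "g1")
        assert (ko.reactions["AtoB"].lower, ko.reactions["AtoB"].upper) == (0.0, 0.0)
        assert solve_fba(ko).objective == pytest.approx(0.0, abs=1e-9)
        # original untouched
        assert chain_model.reactions["AtoB"].upper > 0

    def test_unknown_gene_rejected(self, chain_model):
        with pytest.raises(ModelError):
            delete_gene(chain_model, "absent")

    def test_disabled_set_matches_truth_table_oracle(self, small_synth):
        _, model, _ = small_synth
        for gene in model.genes:
            present = set(model.genes) - {gene}
            expected = [
                rid
                for rid, r in model.reactions.items()
                if not r.gpr.is_empty
                and not eval_gpr_text(r.gpr.to_string(), present)
            ]
            assert disabled_by(model, gene) == expected

    def test_knockout_never_beats_wild_type(self, small_synth):
        _, model, truth = small_synth
        m = apply_medium(model, truth.minimal_medium)
        wt = solve_fba(m).objective
        for gene in m.genes:
            sol = solve_fba(delete_gene(m, gene))
            opt = sol.objective if sol.optimal else 0.0
            assert opt <= wt + 1e-6


class TestEssentiality:
    def test_matches_ground_truth(self, synth):
        _, model, truth = synth
        res = essentiality_screen(model, truth.minimal_medium)
        assert essential_genes(res) == truth.essential_genes

    def test_gene_disabling_nothing_never_essential(self, synth):
        _, model, truth = synth
        res = essentiality_screen(model, truth.minimal_medium)
        for r in res:
            if not r.disabled_reactions:
                assert not r.essential

    def test_matches_independent_cobra_rebuild(self, small_synth):
        """Brute-force oracle: rebuild each knockout from scratch in cobra
        and re-solve with cobra's own solver."""
        _, model, truth = small_synth
        m = apply_medium(model, truth.minimal_medium)
        res = {r.gene: r.essential for r in essentiality_screen(m)}
        for gene in m.genes:
            present = set(m.genes) - {gene}
            ko = m.copy()
            for rid, r in ko.reactions.items():
                if not r.gpr.is_empty and not eval_gpr_text(
                    r.gpr.to_string(), present
                ):
                    r.lower = r.upper = 0.0
            growth = to_cobra(ko).slim_optimize()
            if growth is None or np.isnan(growth):
                growth = 0.0
            assert res[gene] == (growth < 1e-6), gene

    def test_requires_growing_wild_type(self, chain_model):
        from orthoflux.model import MediumCondition

        with pytest.raises(ModelError):
            essentiality_screen(chain_model, MediumCondition())
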