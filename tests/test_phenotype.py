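"""Capacity-change classification, the even-split chi-square statistic,
subsystem shift tests and activity-profile trees."""

import pytest

from orthoflux import (
    ActivityProfile,
    ModelError,
    chi_square_even,
    compare_fva,
    count_significant_metabolism,
    fva_distance_tree,
    knockout_phenotype,
    subsystem_shift_test,
)
from orthoflux.datasets import (
    load_knockout_subsystem_counts,
    load_lpl_knockout_counts,
)
from orthoflux.flux import FVAResult
from orthoflux.phenotype import FluxCapacityChange


class TestChiSquareEven:
    @pytest.mark.parametrize(
        "down,up,printed",
        [
            (85, 133, 0.00115),
            (35, 55, 0.03501),
            (60, 37, 0.01953),
            (13, 32, 0.00462),
            (12, 34, 0.00118),
            (64, 103, 0.00255),
            (6, 19, 0.00932),
            (48, 48, 1.00000),
            (0, 0, 1.00000),
            (368, 437, 0.01502),
            (7, 18, 0.02781),
        ],
    )
    def test_reproduces_published_p_values(self, down, up, printed):
        """p-values agree with the published knockout tables to their
        printed precision."""
        _, p = chi_square_even(down, up)
        assert round(p, 5) == pytest.approx(printed, abs=1e-5)

    @pytest.mark.parametrize(
        "down,up,printed",
        [(53, 45, 0.41900), (19, 27, 0.23820), (122, 98, 0.10560)],
    )
    def test_reproduces_published_truncated_p_values(self, down, up, printed):
        """Cells the source table truncated at four decimals (padded with a
        trailing zero) agree to that precision."""
        _, p = chi_square_even(down, up)
        assert abs(p - printed) <= 1e-4

    def test_even_split_gives_p_one(self):
        for k in (0, 1, 7, 48, 500):
            stat, p = chi_square_even(k, k)
            assert stat == 0.0 and p == 1.0

    def test_symmetry(self):
        assert chi_square_even(10, 30) == chi_square_even(30, 10)

    def test_p_decreases_with_imbalance_at_fixed_total(self):
        ps = [chi_square_even(d, 100 - d)[1] for d in range(50, 101, 5)]
        assert ps == sorted(ps, reverse=True)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_even(-1, 3)


class TestPublishedSignificanceCounts:
    """The per-knockout counts of significantly shifted metabolism
    subsections, recomputed from the published raw down/up counts at
    alpha = 0.05/10, must match the published tallies."""

    EXPECTED = {"PGM1": 6, "FUT9": 2, "SORD": 0, "DHCR7": 7}

    @pytest.mark.parametrize("knockout", sorted(EXPECTED))
    def test_counts(self, knockout):
        df = load_knockout_subsystem_counts()
        sub = df[df["knockout"] == knockout]
        changes = []
        submap = {}
        for _, row in sub.iterrows():
            for i in range(int(row["n_down"])):
                rid = f"{row['subsystem']}_d{i}"
                changes.append(FluxCapacityChange(rid, "decreased", -1.0))
                submap[rid] = row["subsystem"]
            for i in range(int(row["n_up"])):
                rid = f"{row['subsystem']}_u{i}"
                changes.append(FluxCapacityChange(rid, "increased", 1.0))
                submap[rid] = row["subsystem"]
        tests = subsystem_shift_test(changes, submap, alpha=0.05, k=10)
        assert count_significant_metabolism(tests) == self.EXPECTED[knockout]

    def test_lpl_headline_p_values(self):
        df = load_lpl_knockout_counts().set_index("subsystem")
        _, p_glycan = chi_square_even(
            int(df.loc["Glycan Metabolism", "n_down"]),
            int(df.loc["Glycan Metabolism", "n_up"]),
        )
        _, p_lipid = chi_square_even(
            int(df.loc["Lipid Metabolism", "n_down"]),
            int(df.loc["Lipid Metabolism", "n_up"]),
        )
        assert p_glycan <= 1e-16
        assert p_lipid <= 1e-15


class TestCompareFVA:
    def _fva(self, ranges):
        return FVAResult(ranges, 1.0, 1.0)

    def test_identical_all_unchanged(self):
        r = {"a": (0.0, 5.0), "b": (-2.0, 3.0)}
        changes = compare_fva(self._fva(r), self._fva(dict(r)))
        assert all(c.status == "unchanged" for c in changes)

    def test_disabled_reaction_decreased(self):
        wt = self._fva({"a": (0.0, 10.0)})
        ko = self._fva({"a": (0.0, 0.0)})
        (c,) = compare_fva(wt, ko)
        assert c.status == "decreased" and c.delta_v_max == pytest.approx(-10.0)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ModelError):
            compare_fva(self._fva({"a": (0, 1)}), self._fva({"b": (0, 1)}))

    def test_noise_below_tolerance_is_unchanged(self):
        wt = self._fva({"a": (0.0, 10.0)})
        ko = self._fva({"a": (0.0, 10.0 + 1e-8)})
        (c,) = compare_fva(wt, ko)
        assert c.status == "unchanged"

    def test_statuses_recomputable_from_raw_ranges(self, synth):
        from orthoflux import apply_medium, delete_gene, run_fva

        _, model, truth = synth
        m = apply_medium(model, truth.minimal_medium)
        wt = run_fva(m)
        ko = run_fva(delete_gene(m, "ess01"))
        for c in compare_fva(wt, ko):
            delta = ko.ranges[c.reaction_id][1] - wt.ranges[c.reaction_id][1]
            if c.status == "decreased":
                assert delta < 0
            elif c.status == "increased":
                assert delta > 0


class TestKnockoutPhenotype:
    def test_essential_path_gene_shifts_its_subsystem(self, synth):
        _, model, truth = synth
        changes, tests = knockout_phenotype(model, truth.minimal_medium, "ess00")
        own = model.reactions["C_00_2"].subsystem
        by_sub = {t.subsystem: t for t in tests}
        assert by_sub[own].significant
        assert by_sub[own].n_down > by_sub[own].n_up

    def test_non_disabling_gene_is_fixed_point(self, synth):
        from orthoflux.flux import disabled_by

        _, model, truth = synth
        gene = next(g for g in model.genes if not disabled_by(model, g))
        changes, tests = knockout_phenotype(model, truth.minimal_medium, gene)
        assert all(c.status == "unchanged" for c in changes)
        assert not any(t.significant for t in tests)

    def test_all_unchanged_input_gives_p_one_everywhere(self):
        changes = [FluxCapacityChange(f"r{i}", "unchanged", 0.0) for i in range(20)]
        submap = {f"r{i}": "Lipid Metabolism" for i in range(20)}
        tests = subsystem_shift_test(changes, submap)
        assert all(t.p_value == 1.0 and not t.significant for t in tests)


class TestDistanceTree:
    def test_similar_pair_is_sister(self):
        universe = [f"r{i}" for i in range(20)]
        a = ActivityProfile("a", frozenset(universe[:18]))
        b = ActivityProfile("b", frozenset(universe[:17] + [universe[19]]))
        c = ActivityProfile("c", frozenset(universe[18:]))
        newick = fva_distance_tree([a, b, c])
        inner = newick[newick.index("(", 1): newick.rindex(")")]
        assert "a" in inner and "b" in inner and "c" not in inner

    def test_identical_profiles_zero_branch_lengths(self):
        p = frozenset({"r1", "r2"})
        newick = fva_distance_tree(
            [ActivityProfile(x, p) for x in ("a", "b", "c")]
        )
        assert ":0.0" in newick.replace(":0.0,", ":0.0,")
        assert newick.count(":") >= 3

    def test_fewer_than_three_profiles_rejected(self):
        with pytest.raises(ValueError):
            fva_distance_tree(
                [ActivityProfile("a", frozenset()), ActivityProfile("b", frozenset())]
            )

    def test_nested_activity_sets_reproduce_jaccard_distances(self):
        """Closed-form check: profiles a superset chain, so pairwise Jaccard
        distances are 1 - |small|/|large|; average linkage reproduces the
        ultrametric merge heights."""
        import re

        u = [f"r{i}" for i in range(10)]
        a = ActivityProfile("a", frozenset(u))       # 10 active
        b = ActivityProfile("b", frozenset(u[:9]))   # d(a,b) = 0.1
        c = ActivityProfile("c", frozenset(u[:5]))   # d(a,c)=0.5, d(b,c)=4/9
        newick = fva_distance_tree([a, b, c])
        lengths = sorted(float(x) for x in re.findall(r":([\d.]+)", newick))
        # a,b merge at height 0.1/2 = 0.05 from the tips
        assert min(lengths) == pytest.approx(0.05, abs=1e-9)
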