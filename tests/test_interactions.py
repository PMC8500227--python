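"""Pathway cover enumeration, constraints, observation comparison and
network export."""

import json
from itertools import chain, combinations
from random import Random

import numpy as np
import pytest

from crossfeed.gpr import SpeciesReactionTable
from crossfeed.interactions import (
    Combination,
    ConstraintSet,
    InteractionError,
    PathwayDef,
    compare_to_observations,
    complete_species,
    covers,
    enumerate_combinations,
    export_network,
    read_constraints_tsv,
    read_pathways_tsv,
    satisfies_constraints,
    write_interactions,
)


def table_from(caps: dict[str, set[str]], reactions: list[str]) -> SpeciesReactionTable:
    species = sorted(caps)
    matrix = np.array(
        [[1 if r in caps[sp] else 0 for r in reactions] for sp in species]
    )
    return SpeciesReactionTable(species=species, reactions=reactions, matrix=matrix)


ABC = table_from(
    {"A": {"r1"}, "B": {"r2"}, "C": {"r1", "r2"}}, ["r1", "r2"]
)
PW = PathwayDef("bta", ("r1", "r2"))


def powerset(items):
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


def oracle_combinations(table, pathway, constraints):
    """Independent exhaustive subset enumeration."""
    complete = [
        sp
        for sp in table.species
        if all(r in table.reactions_of(sp) for r in pathway.reactions)
    ]
    pool = sorted(table.species)
    if not constraints.include_complete_in_combinations:
        pool = [sp for sp in pool if sp not in set(complete)]
    out = []
    for members in powerset(pool):
        if len(members) < 2:
            continue
        if (
            constraints.max_combination_size is not None
            and len(members) > constraints.max_combination_size
        ):
            continue
        if not covers(members, table, pathway, constraints.completeness_fraction):
            continue
        if not satisfies_constraints(members, table, constraints):
            continue
        out.append(tuple(sorted(members)))
    return sorted(complete), sorted(out, key=lambda m: (len(m), m))


class TestCompleteSpecies:
    def test_all_one_row_listed(self):
        assert complete_species(ABC, PW) == ["C"]

    def test_empty_capabilities(self):
        empty = table_from({"A": set(), "B": set()}, ["r1"])
        assert complete_species(empty, PathwayDef("p", ("r1",))) == []

    def test_unknown_reaction_errors(self):
        with pytest.raises(InteractionError, match="r9"):
            complete_species(ABC, PathwayDef("p", ("r9",)))

    def test_matches_row_scan_oracle(self):
        rng = Random(23)
        reactions = [f"r{j}" for j in range(6)]
        caps = {
            f"S{i}": {r for r in reactions if rng.random() < 0.6}
            for i in range(8)
        }
        table = table_from(caps, reactions)
        pathway = PathwayDef("p", tuple(reactions[:4]))
        expected = sorted(
            sp for sp in caps if all(r in caps[sp] for r in pathway.reactions)
        )
        assert complete_species(table, pathway) == expected


class TestConstraints:
    def test_subset_split_across_species_fails(self):
        cs = ConstraintSet(single_species_subsets=(frozenset({"r1", "r2"}),))
        assert not satisfies_constraints({"A", "B"}, ABC, cs)

    def test_subset_carried_by_one_member_passes(self):
        cs = ConstraintSet(single_species_subsets=(frozenset({"r1", "r2"}),))
        assert satisfies_constraints({"A", "B", "C"}, ABC, cs)

    def test_transporter_modes(self):
        cs_any = ConstraintSet(
            transporter_reactions=frozenset({"r1"}), transporter_mode="any_member"
        )
        cs_all = ConstraintSet(
            transporter_reactions=frozenset({"r1"}), transporter_mode="every_member"
        )
        assert satisfies_constraints({"A", "B"}, ABC, cs_any)
        assert not satisfies_constraints({"A", "B"}, ABC, cs_all)
        assert satisfies_constraints({"A", "C"}, ABC, cs_all)

    def test_matches_independent_predicate_on_random_instances(self):
        rng = Random(31)
        reactions = [f"r{j}" for j in range(5)]
        for _ in range(200):
            caps = {
                f"S{i}": {r for r in reactions if rng.random() < 0.5}
                for i in range(6)
            }
            table = table_from(caps, reactions)
            combo = {f"S{i}" for i in rng.sample(range(6), rng.randint(1, 4))}
            subsets = tuple(
                frozenset(rng.sample(reactions, rng.randint(1, 2)))
                for _ in range(rng.randint(0, 2))
            )
            transporters = frozenset(
                r for r in reactions if rng.random() < 0.3
            )
            mode = rng.choice(["off", "any_member", "every_member"])
            max_size = rng.choice([None, 2, 3, 4])
            cs = ConstraintSet(
                single_species_subsets=subsets,
                transporter_reactions=transporters,
                transporter_mode=mode,
                max_combination_size=max_size,
            )
            # independent re-statement of the predicate
            expected = all(
                any(sub <= caps[sp] for sp in combo) for sub in subsets
            )
            if mode == "any_member":
                expected &= any(caps[sp] & transporters for sp in combo)
            elif mode == "every_member":
                expected &= all(caps[sp] & transporters for sp in combo)
            if max_size is not None:
                expected &= len(combo) <= max_size
            assert satisfies_constraints(combo, table, cs) == expected


class TestEnumerate:
    def test_three_species_example(self):
        cs = ConstraintSet(include_complete_in_combinations=False)
        result = enumerate_combinations(ABC, PW, cs)
        assert result.complete_species == ["C"]
        assert [c.members for c in result.combinations] == [("A", "B")]
        attribution = result.combinations[0].contributor_map()
        assert attribution == {"r1": ("A",), "r2": ("B",)}

    def test_complete_included_by_default(self):
        result = enumerate_combinations(ABC, PW)
        assert ("A", "B") in [c.members for c in result.combinations]
        assert ("A", "C") in [c.members for c in result.combinations]

    def test_uncoverable_reaction_yields_empty(self):
        table = table_from({"A": {"r1"}, "B": {"r1"}}, ["r1", "r2"])
        result = enumerate_combinations(table, PW)
        assert result.combinations == []

    def test_soundness_and_oracle_on_random_instances(self):
        rng = Random(41)
        for _ in range(20):
            reactions = [f"r{j}" for j in range(6)]
            caps = {
                f"S{i:02d}": {r for r in reactions if rng.random() < 0.45}
                for i in range(10)
            }
            table = table_from(caps, reactions)
            pathway = PathwayDef("p", tuple(sorted(rng.sample(reactions, 4))))
            cs = ConstraintSet(
                single_species_subsets=tuple(
                    frozenset(rng.sample(list(pathway.reactions), 2))
                    for _ in range(rng.randint(0, 1))
                ),
                max_combination_size=rng.choice([None, 3]),
                completeness_fraction=rng.choice([1.0, 0.75]),
                include_complete_in_combinations=rng.random() < 0.5,
            )
            result = enumerate_combinations(table, pathway, cs)
            for combo in result.combinations:
                assert covers(combo.members, table, pathway, cs.completeness_fraction)
                assert satisfies_constraints(combo.members, table, cs)
            expected_complete, expected_combos = oracle_combinations(table, pathway, cs)
            assert result.complete_species == expected_complete
            assert [c.members for c in result.combinations] == expected_combos

    def test_removing_reaction_never_shrinks_combinations(self):
        rng = Random(43)
        reactions = [f"r{j}" for j in range(4)]
        caps = {
            f"S{i}": {r for r in reactions if rng.random() < 0.5} for i in range(6)
        }
        table = table_from(caps, reactions)
        full = enumerate_combinations(table, PathwayDef("p", tuple(reactions)))
        reduced = enumerate_combinations(table, PathwayDef("p", tuple(reactions[:3])))
        full_set = {c.members for c in full.combinations}
        reduced_set = {c.members for c in reduced.combinations}
        assert full_set <= reduced_set

    def test_enumeration_bound(self):
        reactions = ["r1"]
        caps = {f"S{i:02d}": {"r1"} for i in range(31)}
        table = table_from(caps, reactions)
        with pytest.raises(InteractionError, match="31"):
            enumerate_combinations(table, PathwayDef("p", ("r1",)))

    def test_deterministic_ordering(self):
        result = enumerate_combinations(ABC, PW)
        sizes = [len(c.members) for c in result.combinations]
        assert sizes == sorted(sizes)
        members = [c.members for c in result.combinations]
        assert members == sorted(members, key=lambda m: (len(m), m))


class TestObservations:
    def test_complete_singleton_explained(self):
        result = enumerate_combinations(ABC, PW)
        explained, grown = compare_to_observations(
            result, ABC, PW, observed=[({"C"}, True)]
        )
        assert (explained, grown) == (1, 1)

    def test_covering_pair_explained(self):
        result = enumerate_combinations(ABC, PW)
        explained, grown = compare_to_observations(
            result, ABC, PW, observed=[({"A", "B"}, True)]
        )
        assert (explained, grown) == (1, 1)

    def test_incomplete_singleton_not_explained(self):
        result = enumerate_combinations(ABC, PW)
        explained, grown = compare_to_observations(
            result, ABC, PW, observed=[({"A"}, True), ({"B"}, False)]
        )
        assert (explained, grown) == (0, 1)

    def test_unknown_species_errors(self):
        result = enumerate_combinations(ABC, PW)
        with pytest.raises(InteractionError, match="Z"):
            compare_to_observations(result, ABC, PW, observed=[({"Z"}, True)])


class TestNetworkExport:
    def test_counts_one_species_two_reactions(self, tmp_path):
        table = table_from({"A": {"R00001", "R00002"}}, ["R00001", "R00002"])
        graph = export_network(table, None, tmp_path / "net")
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2
        data = json.loads((tmp_path / "net.json").read_text())
        assert len(data["links"]) == 2
        assert (tmp_path / "net.html").exists()

    def test_empty_matrix_no_edges(self, tmp_path):
        table = table_from({"A": set(), "B": set()}, ["r1"])
        graph = export_network(table, None, tmp_path / "net")
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 3

    def test_edges_equal_one_cells(self, tmp_path):
        rng = Random(51)
        reactions = [f"R0000{j}" for j in range(1, 5)]
        caps = {
            f"S{i}": {r for r in reactions if rng.random() < 0.5} for i in range(5)
        }
        table = table_from(caps, reactions)
        graph = export_network(table, None, tmp_path / "net")
        expected = {(sp, r) for sp in caps for r in caps[sp]}
        assert {tuple(sorted(e, key=lambda x: x.startswith("R0")) ) for e in graph.edges} == {
            (sp, r) for sp, r in expected
        }

    def test_kegg_url_on_standard_reaction_ids(self, tmp_path):
        table = table_from({"A": {"R02451", "custom_rxn"}}, ["R02451", "custom_rxn"])
        graph = export_network(table, None, tmp_path / "net")
        assert "R02451" in graph.nodes["R02451"]["url"]
        assert graph.nodes["custom_rxn"]["url"] is None


class TestConfigFiles:
    def test_pathways_roundtrip(self, tmp_path):
        f = tmp_path / "pathways.tsv"
        f.write_text("pathway_name\treactions\nbta\tr1,r2\nshort\tr1\n")
        pathways = read_pathways_tsv(f)
        assert pathways[0] == PathwayDef("bta", ("r1", "r2"))
        assert pathways[1].reactions == ("r1",)

    def test_constraints_parsing(self, tmp_path):
        f = tmp_path / "constraints.tsv"
        f.write_text(
            "pathway_name\tsingle_species_subsets\ttransporters\tmax_size\tcompleteness\n"
            "bta\tr1,r2;r2\tr1\t3\t0.8\n"
        )
        cs = read_constraints_tsv(f)["bta"]
        assert cs.single_species_subsets == (
            frozenset({"r1", "r2"}),
            frozenset({"r2"}),
        )
        assert cs.transporter_reactions == frozenset({"r1"})
        assert cs.transporter_mode == "any_member"
        assert cs.max_combination_size == 3
        assert cs.completeness_fraction == 0.8

    def test_write_interactions_files(self, tmp_path):
        result = enumerate_combinations(ABC, PW)
        write_interactions(result, tmp_path / "interactions")
        complete = (tmp_path / "interactions" / "bta_complete_species.txt").read_text()
        assert complete.strip() == "C"
        combos = (tmp_path / "interactions" / "bta_combinations.tsv").read_text()
        assert "A,B\t2\tr1:A;r2:B" in combos
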