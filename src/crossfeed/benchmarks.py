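"""Reference benchmark fixtures.

These builders define the standard synthetic scenarios used to
validate the pipeline end to end: a small annotation fixture, a
planted-community recovery scenario, random interaction-prediction
instances, and the point-mutation robustness fixture.  They are part
of the library (rather than test-local helpers) so that validation
scripts and the test suite exercise exactly the same conditions.
"""

from __future__ import annotations

from random import Random

from .clusters import ClusterSet, OrthologCluster
from .gpr import ORAdb, SpeciesReactionTable, reaction_capabilities
from .interactions import ConstraintSet, PathwayDef
from .simulate import (
    MutationSpec,
    generate_community,
    generate_family,
    generate_oradb_fixture,
    mutate_cds,
    translate_longest,
)

__all__ = [
    "annotation_fixture",
    "recovery_fixture",
    "random_interaction_instance",
    "mutation_fixture",
    "MUTATION_RATES",
]

#: The substitution-rate grid of the mutation benchmark.
MUTATION_RATES = (0.01, 0.03, 0.05, 0.1, 0.15, 0.25)


def annotation_fixture(seed: int = 100):
    """3 clusters x 4 KOs: two clusters carry true family members
    (one of them members of two families), the third holds decoys.

    Returns ``(db, clusters, seqs)`` where ``seqs`` maps sequence ids
    to proteins.
    """
    db_kos = {}
    members = {}
    for i, ko in enumerate(["K50001", "K50002", "K50003", "K50004"], start=1):
        fam = generate_family(
            seed=seed + i, length=80, n_members=5, divergence=0.08, family_id=ko
        )
        db_kos[ko] = fam.members[:3]
        members[ko] = fam.members[3:]
    db = ORAdb(
        ko_sequences=db_kos,
        reaction_kos={
            "R50001": {"K50001", "K50002"},
            "R50002": {"K50003", "K50004"},
        },
    )
    decoy = generate_family(
        seed=seed + 899, length=80, n_members=2, divergence=0.0, family_id="DEC"
    )
    seqs: dict[str, str] = {}
    clusters = []
    layout = [("OG0", ["K50001"]), ("OG1", ["K50002", "K50003"]), ("OG2", [])]
    for cid, kos in layout:
        ids = []
        pool = (
            [p for ko in kos for p in members[ko]] if kos else decoy.members
        )
        for sid, s in pool:
            seqs[sid] = s
            ids.append(sid)
        clusters.append(OrthologCluster(cid, {"spA": sorted(ids)}))
    return db, ClusterSet(clusters=clusters), seqs


def recovery_fixture(seed: int = 1):
    """Planted community for end-to-end parameter recovery.

    6 species, 8 reactions and at most 15 KOs (``complex_fraction``
    0.4; the database is redrawn from successive sub-seeds until the
    KO budget holds), community members diverged 8% from the family
    ancestors, 5 decoys per species.  Returns
    ``(db, proteomes, truth)``.
    """
    sub = seed
    while True:
        db = generate_oradb_fixture(8, complex_fraction=0.4, seed=sub)
        if len(db.kos) <= 15:
            break
        sub += 100003  # deterministic redraw on KO-budget overflow
    proteomes, truth = generate_community(
        6, db, seed=seed + 1, divergence=0.08, n_decoys=5
    )
    return db, proteomes, truth


def random_interaction_instance(rng: Random):
    """One random interaction-prediction problem.

    Up to 12 species x up to 8 reactions with random GPR rules,
    planted KO sets, and random constraints.  Returns
    ``(table, pathway, constraints)``.
    """
    n_species = rng.randint(4, 12)
    n_reactions = rng.randint(3, 8)
    db = generate_oradb_fixture(
        n_reactions, complex_fraction=rng.uniform(0.0, 0.7), seed=rng.randrange(2**31)
    )
    from .simulate import random_species_kos

    kos = random_species_kos(
        db, n_species, seed=rng.randrange(2**31), p_reaction=rng.uniform(0.3, 0.7)
    )
    table = reaction_capabilities(kos, db)
    k = rng.randint(2, len(table.reactions))
    pathway = PathwayDef("p", tuple(sorted(rng.sample(table.reactions, k))))
    subsets = tuple(
        frozenset(rng.sample(list(pathway.reactions), min(2, len(pathway.reactions))))
        for _ in range(rng.randint(0, 1))
    )
    transporters = frozenset(r for r in table.reactions if rng.random() < 0.25)
    constraints = ConstraintSet(
        single_species_subsets=subsets,
        transporter_reactions=transporters,
        transporter_mode=rng.choice(["off", "any_member", "every_member"])
        if transporters
        else "off",
        max_combination_size=rng.choice([None, 3, 4]),
        completeness_fraction=rng.choice([1.0, 0.75]),
        include_complete_in_combinations=rng.random() < 0.5,
    )
    return table, pathway, constraints


_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

#: Gene lengths (codons) of the three mutation-benchmark genes, at
#: the scale of real bacterial catabolic genes (1.5-2.5 kb).
MUTATION_GENE_CODONS = (800, 550, 550)


def mutation_fixture(master_seed: int = 0):
    """Point-mutation robustness benchmark.

    Three stop-free random genes; each is mutated at every rate of
    :data:`MUTATION_RATES` (one in-silico strain per rate, seed
    ``1000*gene + 100*rate``).  Returns ``(seqs, truth, rate_of)``
    where ``seqs`` maps a per-strain species id to its single
    ``(sequence_id, protein)``, ``truth`` labels every sequence with
    its gene family, and ``rate_of`` maps variant sequence ids to
    their mutation rate (originals excluded).
    """
    rng = Random(master_seed)
    seqs: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}
    rate_of: dict[str, float] = {}
    for g, n_codons in enumerate(MUTATION_GENE_CODONS):
        cds = (
            "ATG"
            + "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
            + "TAA"
        )
        sid = f"gene{g}|orig"
        seqs[f"strain_orig{g}"] = [(sid, translate_longest(cds))]
        truth[sid] = f"gene{g}"
        for rate in MUTATION_RATES:
            spec = MutationSpec(rate=rate, seed=1000 * g + int(rate * 100))
            _, protein = mutate_cds(cds, spec)
            vid = f"gene{g}|r{int(rate * 100)}"
            seqs[f"strain_{vid}"] = [(vid, protein)]
            truth[vid] = f"gene{g}"
            rate_of[vid] = rate
    return seqs, truth, rate_of
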