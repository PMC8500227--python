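"""Synthetic fixtures: reference databases, protein families, species
proteomes with planted truth, and a point-mutation simulator.

The generators emulate the study design the pipeline is meant for:
KO reference sets are families of proteins diverged from a common
ancestor; each synthetic species carries one diverged member of every
KO it needs to satisfy its planted reactions, plus unrelated decoy
proteins.  The mutation simulator introduces DNA substitutions into a
coding sequence — never in the first or last codon — and translates
the longest open reading frame of the result, modelling how point
mutations (including newly created stop/start codons) perturb the
protein actually observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

import edlib
from Bio.Seq import Seq

from .gpr import And, GprRule, KoLeaf, ORAdb, Or, SpeciesReactionTable, reaction_capabilities

__all__ = [
    "AMINO_ACIDS",
    "SimulationError",
    "MutationSpec",
    "Family",
    "FixtureTruth",
    "generate_family",
    "generate_oradb_fixture",
    "generate_community",
    "random_species_kos",
    "mutate_cds",
    "translate_longest",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_DNA = "ACGT"


class SimulationError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


@dataclass(frozen=True)
class MutationSpec:
    """Substitution rate (fraction of bases) and RNG seed."""

    rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise SimulationError("mutation rate must be in [0, 1]")


@dataclass
class Family:
    """A protein family: one ancestor and diverged members."""

    family_id: str
    ancestor: str
    members: list[tuple[str, str]]  # (sequence_id, sequence)


@dataclass
class FixtureTruth:
    """Planted ground truth accompanying a generated community."""

    table: SpeciesReactionTable
    sequence_labels: dict[str, str]  # sequence_id -> KO (or decoy tag)
    families: dict[str, list[str]]  # KO -> community member sequence ids
    species_kos: dict[str, set[str]] = field(default_factory=dict)


def _random_protein(rng: Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _diverge(rng: Random, seq: str, n_subs: int) -> str:
    positions = rng.sample(range(len(seq)), n_subs)
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([a for a in AMINO_ACIDS if a != chars[pos]])
    return "".join(chars)


def generate_family(
    seed: int,
    length: int = 120,
    n_members: int = 3,
    divergence: float = 0.05,
    family_id: str = "FAM",
) -> Family:
    """Protein family from one random ancestor.

    Each member differs from the ancestor at exactly
    ``round(divergence * length)`` positions (chosen without
    replacement).  Deterministic for a fixed seed.
    """
    if length < 30:
        raise SimulationError("family length must be >= 30")
    if not 0.0 <= divergence <= 0.5:
        raise SimulationError("divergence must be within [0, 0.5]")
    rng = Random(seed)
    ancestor = _random_protein(rng, length)
    n_subs = _round_half_up(divergence * length)
    members = [
        (f"{family_id}_m{i}", _diverge(rng, ancestor, n_subs) if n_subs else ancestor)
        for i in range(1, n_members + 1)
    ]
    return Family(family_id=family_id, ancestor=ancestor, members=members)


def generate_oradb_fixture(
    n_reactions: int,
    complex_fraction: float = 0.3,
    kos_per_reaction: int | None = None,
    seed: int = 0,
    refs_per_ko: int = 3,
    length: int = 120,
    ref_divergence: float = 0.05,
) -> ORAdb:
    """Synthetic ORAdb with a mixture of rule shapes.

    With probability ``complex_fraction`` a reaction gets a multi-KO
    rule: an AND complex over ``kos_per_reaction`` subunits when that
    is given, otherwise an AND over 2–4 subunits or an OR of two
    alternative branches (isoenzymes / alternative complexes).  Other
    reactions get a single-KO rule.  Reference sets come from
    :func:`generate_family`; everything is deterministic per seed.
    """
    if n_reactions < 1:
        raise SimulationError("need at least one reaction")
    rng = Random(seed)
    ko_counter = 0
    ko_sequences: dict[str, list[tuple[str, str]]] = {}
    reaction_kos: dict[str, set[str]] = {}
    gpr: dict[str, GprRule] = {}

    def new_ko() -> str:
        nonlocal ko_counter
        ko_counter += 1
        ko = f"K9{ko_counter:04d}"
        fam = generate_family(
            seed=rng.randrange(2**31),
            length=length,
            n_members=refs_per_ko,
            divergence=ref_divergence,
            family_id=f"{ko}_ref",
        )
        ko_sequences[ko] = fam.members
        return ko

    for i in range(1, n_reactions + 1):
        reaction = f"R9{i:04d}"
        if rng.random() < complex_fraction:
            if kos_per_reaction is not None:
                expr = And(tuple(KoLeaf(new_ko()) for _ in range(kos_per_reaction)))
            elif rng.random() < 0.3:
                # isoenzymes: OR over two alternative branches
                left = And(tuple(KoLeaf(new_ko()) for _ in range(rng.randint(2, 3))))
                right: And | KoLeaf
                if rng.random() < 0.5:
                    right = And(tuple(KoLeaf(new_ko()) for _ in range(2)))
                else:
                    right = KoLeaf(new_ko())
                expr = Or((left, right))
            else:
                expr = And(tuple(KoLeaf(new_ko()) for _ in range(rng.randint(2, 4))))
        else:
            expr = KoLeaf(new_ko())
        gpr[reaction] = GprRule(reaction_id=reaction, expression=expr)
        reaction_kos[reaction] = expr.kos()

    return ORAdb(ko_sequences=ko_sequences, reaction_kos=reaction_kos, gpr=gpr)


def _satisfying_kos(expr, rng: Random) -> set[str]:
    """One satisfying KO set for a rule (a random OR branch, all AND
    children)."""
    if isinstance(expr, KoLeaf):
        return {expr.ko}
    if isinstance(expr, And):
        out: set[str] = set()
        for child in expr.children:
            out |= _satisfying_kos(child, rng)
        return out
    if isinstance(expr, Or):
        return _satisfying_kos(rng.choice(expr.children), rng)
    raise SimulationError(f"unknown expression node {expr!r}")


def random_species_kos(
    db: ORAdb,
    n_species: int,
    seed: int,
    p_reaction: float = 0.5,
    min_carriers: int = 2,
) -> dict[str, set[str]]:
    """Plant KO sets: each species carries each reaction with
    probability ``p_reaction``, receiving the KOs of one satisfying
    branch of the reaction's rule.  A reaction carried at all is
    carried by at least ``min_carriers`` species (orthologs occur in
    several genomes in real study sets; single-copy families would be
    invisible to cluster-level annotation).  The implied capability
    table (via :func:`reaction_capabilities`) is consistent by
    construction."""
    rng = Random(seed)
    species = [f"SP{i:02d}" for i in range(1, n_species + 1)]
    min_carriers = min(min_carriers, n_species)
    carriers: dict[str, list[str]] = {}
    for reaction in db.reactions:
        chosen = [sp for sp in species if rng.random() < p_reaction]
        if chosen and len(chosen) < min_carriers:
            extra = [sp for sp in species if sp not in chosen]
            chosen += rng.sample(extra, min_carriers - len(chosen))
        carriers[reaction] = sorted(chosen)
    out: dict[str, set[str]] = {sp: set() for sp in species}
    for reaction in db.reactions:
        # carriers share one branch: orthologs of the same family are
        # what co-occurs across genomes in a real community
        branch = _satisfying_kos(db.rule_for(reaction).expression, rng)
        for sp in carriers[reaction]:
            out[sp] |= branch
    return out


def _decoy(
    rng: Random,
    length: int,
    family_seqs: list[str],
    max_identity: float = 0.30,
    max_tries: int = 50,
) -> str:
    """A random protein globally < max_identity identical to every
    family sequence (edit-distance identity; re-sampled otherwise)."""
    for _ in range(max_tries):
        cand = _random_protein(rng, length)
        ok = True
        for fam in family_seqs:
            dist = edlib.align(cand, fam)["editDistance"]
            identity = 1.0 - dist / max(len(cand), len(fam))
            if identity >= max_identity:
                ok = False
                break
        if ok:
            return cand
    raise SimulationError("could not sample a sufficiently dissimilar decoy")


def generate_community(
    n_species: int,
    db: ORAdb,
    planted: SpeciesReactionTable | None = None,
    seed: int = 0,
    divergence: float = 0.08,
    n_decoys: int = 5,
    decoy_length: int = 120,
    p_reaction: float = 0.5,
    max_branch_retries: int = 20,
) -> tuple[dict[str, list[tuple[str, str]]], FixtureTruth]:
    """Per-species proteomes with planted truth.

    When ``planted`` is given, each species receives the KOs of one
    satisfying branch per planted reaction; branch choices are redrawn
    (up to ``max_branch_retries``) if overlapping OR branches would
    switch on a reaction planted as absent, and a
    :class:`SimulationError` names the species and reaction when no
    consistent choice exists.  Without ``planted``, KO sets are drawn
    by :func:`random_species_kos` and the table derived from them.

    Each needed KO contributes one member diverged from the KO's
    ancestral reference by ``round(divergence * length)``
    substitutions; ``n_decoys`` unrelated random proteins are added
    per species.
    """
    rng = Random(seed)
    ancestors = {
        ko: refs[0][1] for ko, refs in db.ko_sequences.items() if refs
    }
    if planted is not None:
        species_kos: dict[str, set[str]] = {}
        for sp in planted.species:
            wanted = planted.reactions_of(sp)
            ok = False
            for _ in range(max_branch_retries):
                kos: set[str] = set()
                for reaction in sorted(wanted):
                    rule = db.rule_for(reaction)
                    branch = _satisfying_kos(rule.expression, rng)
                    if not branch <= set(ancestors):
                        raise SimulationError(
                            f"species {sp}, reaction {reaction}: required KOs "
                            "have no reference sequences"
                        )
                    kos |= branch
                derived = {
                    r for r in db.reactions if db.rule_for(r).evaluate(kos)
                }
                if derived == wanted:
                    ok = True
                    break
            if not ok:
                bad = sorted(derived.symmetric_difference(wanted))[0]
                raise SimulationError(
                    f"species {sp}, reaction {bad}: planted row is not "
                    "satisfiable consistently under the GPR rules"
                )
            species_kos[sp] = kos
        table = planted
    else:
        species_kos = random_species_kos(db, n_species, rng.randrange(2**31), p_reaction)
        table = reaction_capabilities(species_kos, db)

    all_family_seqs = [seq for refs in db.ko_sequences.values() for _, seq in refs]
    proteomes: dict[str, list[tuple[str, str]]] = {}
    labels: dict[str, str] = {}
    families: dict[str, list[str]] = {ko: [] for ko in db.kos}
    for sp in table.species:
        seqs: list[tuple[str, str]] = []
        for ko in sorted(species_kos[sp]):
            ancestor = ancestors[ko]
            n_subs = _round_half_up(divergence * len(ancestor))
            sid = f"{sp}|{ko}"
            seqs.append((sid, _diverge(rng, ancestor, n_subs) if n_subs else ancestor))
            labels[sid] = ko
            families[ko].append(sid)
        for i in range(1, n_decoys + 1):
            sid = f"{sp}|decoy{i}"
            seqs.append((sid, _decoy(rng, decoy_length, all_family_seqs)))
            labels[sid] = f"decoy|{sid}"
        proteomes[sp] = seqs

    truth = FixtureTruth(
        table=table,
        sequence_labels=labels,
        families=families,
        species_kos=species_kos,
    )
    return proteomes, truth


# --------------------------------------------------------------------------
# Point-mutation simulator
# --------------------------------------------------------------------------

def mutate_cds(dna: str, spec: MutationSpec) -> tuple[str, str]:
    """Introduce point substitutions into a coding sequence.

    ``max(1, round(rate * length))`` bases are substituted (0 for rate
    0), at positions drawn uniformly without replacement from the
    bases of codons 2..(n-1) — the first and last codon are never
    touched.  Each substituted base becomes one of the three other
    bases, uniformly.  Returns the mutated DNA and the protein
    translated from its longest open reading frame.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise SimulationError("CDS length must be divisible by 3")
    if len(dna) < 9:
        raise SimulationError("CDS must have at least 3 codons")
    bad = next((c for c in dna if c not in _DNA), None)
    if bad is not None:
        raise SimulationError(f"illegal DNA character {bad!r}")
    n_subs = 0 if spec.rate == 0 else max(1, _round_half_up(spec.rate * len(dna)))
    eligible = range(3, len(dna) - 3)
    if n_subs > len(eligible):
        raise SimulationError(
            f"{n_subs} substitutions requested but only {len(eligible)} "
            "eligible positions (first and last codon are protected)"
        )
    rng = Random(spec.seed)
    chars = list(dna)
    for pos in rng.sample(eligible, n_subs):
        chars[pos] = rng.choice([b for b in _DNA if b != chars[pos]])
    mutated = "".join(chars)
    return mutated, translate_longest(mutated)


def translate_longest(dna: str) -> str:
    """Largest protein among the in-frame ORF candidates.

    Candidates are the translation from position 0 to the first
    in-frame stop (or the end), plus from every in-frame ATG to the
    next in-frame stop (or the end).  Frame shifts cannot occur under
    substitution-only mutation, so only the original reading frame is
    scanned.  Ties go to the earliest start; an empty candidate set is
    an error.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise SimulationError("sequence length must be divisible by 3")
    starts = [0] + [
        i for i in range(3, len(dna), 3) if dna[i : i + 3] == "ATG"
    ]
    best = ""
    best_start = -1
    for start in starts:
        prot = str(Seq(dna[start:]).translate(to_stop=True))
        if len(prot) > len(best):
            best = prot
            best_start = start
    if not best:
        raise SimulationError("no open reading frame translates to a protein")
    return best
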