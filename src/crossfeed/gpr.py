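"""Ortholog–reaction association database (ORAdb) and GPR rules.

The ORAdb groups reference protein sequences by KEGG Orthology group
(KO, ``K#####``) and maps each reaction to the KOs that can enable it.
Gene–protein–reaction (GPR) rules are boolean expressions over KOs:
``AND`` joins the subunits of a protein complex, ``OR`` joins
isoenzymes or alternative complexes.  A species can perform a reaction
when its annotated KO set satisfies the reaction's rule.

On disk an ORAdb is a directory holding one multi-FASTA per KO
(``<ko>.fasta``), a ``reaction_kos.tsv`` mapping (reaction_id, ko_id)
and a ``gpr_rules.tsv`` with the rule strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import PROTEIN_ALPHABET

__all__ = [
    "KO_PATTERN",
    "REACTION_PATTERN",
    "EC_PATTERN",
    "GprParseError",
    "OradbError",
    "KoLeaf",
    "And",
    "Or",
    "GprRule",
    "ORAdb",
    "BuildReport",
    "SpeciesReactionTable",
    "Fetcher",
    "DictFetcher",
    "OfflineFetcher",
    "validate_ko",
    "validate_reaction",
    "classify_identifier",
    "parse_gpr",
    "evaluate_gpr",
    "reaction_capabilities",
    "build_oradb",
    "read_oradb",
    "write_oradb",
    "read_identifier_list",
]

KO_PATTERN = re.compile(r"^K\d{5}$")
REACTION_PATTERN = re.compile(r"^R\d{5}$")
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class GprParseError(ValueError):
    """Malformed GPR rule string."""


class OradbError(ValueError):
    """Invalid ORAdb content or directory layout."""


def validate_ko(token: str) -> str:
    """Return the KO id uppercased; raise if it is not ``K#####``."""
    up = token.strip().upper()
    if not KO_PATTERN.match(up):
        raise ValueError(f"invalid KO identifier: {token!r}")
    return up


def validate_reaction(token: str) -> str:
    tok = token.strip()
    if not tok or any(c.isspace() for c in tok):
        raise ValueError(f"invalid reaction identifier: {token!r}")
    return tok


def classify_identifier(token: str) -> str:
    """Classify a user identifier as 'ko', 'reaction', 'ec' or 'unknown'."""
    tok = token.strip().upper()
    if KO_PATTERN.match(tok):
        return "ko"
    if REACTION_PATTERN.match(tok):
        return "reaction"
    if EC_PATTERN.match(token.strip()):
        return "ec"
    return "unknown"


# --------------------------------------------------------------------------
# GPR boolean expressions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KoLeaf:
    ko: str

    def evaluate(self, kos: frozenset[str] | set[str]) -> bool:
        return self.ko in kos

    def kos(self) -> set[str]:
        return {self.ko}

    def unparse(self, parent: str | None = None) -> str:
        return self.ko


@dataclass(frozen=True)
class And:
    children: tuple

    def evaluate(self, kos) -> bool:
        return all(c.evaluate(kos) for c in self.children)

    def kos(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.kos()
        return out

    def unparse(self, parent: str | None = None) -> str:
        inner = " AND ".join(c.unparse("AND") for c in self.children)
        return inner


@dataclass(frozen=True)
class Or:
    children: tuple

    def evaluate(self, kos) -> bool:
        return any(c.evaluate(kos) for c in self.children)

    def kos(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.kos()
        return out

    def unparse(self, parent: str | None = None) -> str:
        inner = " OR ".join(c.unparse("OR") for c in self.children)
        # OR binds loosest: parenthesise when nested under an AND.
        return f"({inner})" if parent == "AND" else inner


Expression = KoLeaf | And | Or


@dataclass(frozen=True)
class GprRule:
    """A reaction's boolean requirement over KO groups."""

    reaction_id: str
    expression: Expression

    def evaluate(self, kos: Iterable[str]) -> bool:
        return self.expression.evaluate(set(kos))

    def kos(self) -> set[str]:
        return self.expression.kos()

    def unparse(self) -> str:
        return self.expression.unparse()


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str, reaction_id: str = "") -> GprRule:
    """Parse a boolean rule string into a :class:`GprRule`.

    Grammar (case-insensitive keywords, AND binds tighter than OR)::

        expr   := term (OR term)*
        term   := factor (AND factor)*
        factor := KO | '(' expr ')'

    Same-operator nodes are flattened (``a AND b AND c`` is one AND
    node with three children), which preserves the truth table.
    """
    if not text or not text.strip():
        raise GprParseError("empty rule string")
    tokens = _tokenize(text)
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def err(msg: str, pos: int) -> GprParseError:
        return GprParseError(f"{msg} at position {pos + 1} in rule {text!r}")

    def parse_factor() -> Expression:
        nonlocal idx
        tok = peek()
        if tok is None:
            raise err("unexpected end of rule", len(text) - 1)
        word, pos = tok
        if word == "(":
            idx += 1
            node = parse_expr()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise err("unbalanced parentheses", pos)
            idx += 1
            return node
        if word == ")":
            raise err("unexpected ')'", pos)
        if word.upper() in ("AND", "OR"):
            raise err(f"dangling operator {word!r}", pos)
        try:
            ko = validate_ko(word)
        except ValueError:
            raise err(f"malformed KO token {word!r}", pos) from None
        idx += 1
        return KoLeaf(ko)

    def parse_term() -> Expression:
        nonlocal idx
        children = [parse_factor()]
        while True:
            tok = peek()
            if tok is None or tok[0].upper() != "AND":
                break
            idx += 1
            children.append(parse_factor())
        if len(children) == 1:
            return children[0]
        flat: list[Expression] = []
        for c in children:
            flat.extend(c.children if isinstance(c, And) else (c,))
        return And(tuple(flat))

    def parse_expr() -> Expression:
        nonlocal idx
        children = [parse_term()]
        while True:
            tok = peek()
            if tok is None or tok[0].upper() != "OR":
                break
            idx += 1
            children.append(parse_term())
        if len(children) == 1:
            return children[0]
        flat: list[Expression] = []
        for c in children:
            flat.extend(c.children if isinstance(c, Or) else (c,))
        return Or(tuple(flat))

    expression = parse_expr()
    trailing = peek()
    if trailing is not None:
        raise err(f"unexpected token {trailing[0]!r}", trailing[1])
    return GprRule(reaction_id=reaction_id, expression=expression)


def evaluate_gpr(rule: GprRule, kos: Iterable[str]) -> bool:
    """True iff the KO set satisfies the rule (standard boolean semantics)."""
    return rule.evaluate(kos)


# --------------------------------------------------------------------------
# ORAdb
# --------------------------------------------------------------------------

@dataclass
class ORAdb:
    """KO reference sequences + reaction→KO map + GPR rules.

    ``ko_sequences`` maps each KO to ``(sequence_id, protein)`` pairs;
    ``reaction_kos`` maps each reaction to the KOs associated with it;
    ``gpr`` maps a reaction to its rule (reactions without an explicit
    rule default to OR over their KO set — one protein suffices).
    """

    ko_sequences: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    reaction_kos: dict[str, set[str]] = field(default_factory=dict)
    gpr: dict[str, GprRule] = field(default_factory=dict)
    load_report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for reaction, kos in self.reaction_kos.items():
            for ko in kos:
                if ko not in self.ko_sequences:
                    self.ko_sequences[ko] = []
                    self.load_report.append(
                        f"KO {ko} (reaction {reaction}) has no reference sequences"
                    )
        for reaction, rule in self.gpr.items():
            for ko in rule.kos():
                if ko not in self.ko_sequences:
                    self.ko_sequences[ko] = []
                    self.load_report.append(
                        f"KO {ko} (rule for {reaction}) has no reference sequences"
                    )

    @property
    def reactions(self) -> list[str]:
        return sorted(self.reaction_kos)

    @property
    def kos(self) -> list[str]:
        return sorted(self.ko_sequences)

    def rule_for(self, reaction: str) -> GprRule:
        """The reaction's GPR rule, defaulting to OR over its KO set."""
        if reaction in self.gpr:
            return self.gpr[reaction]
        kos = sorted(self.reaction_kos.get(reaction, set()))
        if not kos:
            raise OradbError(f"reaction {reaction} has no KOs and no rule")
        expr: Expression
        if len(kos) == 1:
            expr = KoLeaf(kos[0])
        else:
            expr = Or(tuple(KoLeaf(k) for k in kos))
        return GprRule(reaction_id=reaction, expression=expr)

    def total_residues(self) -> int:
        return sum(
            len(seq) for refs in self.ko_sequences.values() for _, seq in refs
        )

    def reference_pairs(self) -> list[tuple[str, str]]:
        """All (sequence_id, sequence) pairs across KOs, sorted by id."""
        out = [
            (sid, seq)
            for refs in self.ko_sequences.values()
            for sid, seq in refs
        ]
        return sorted(out)


@dataclass
class SpeciesReactionTable:
    """Binary species × reaction capability matrix."""

    species: list[str]
    reactions: list[str]
    matrix: np.ndarray  # shape (n_species, n_reactions), dtype int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.species), len(self.reactions)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("duplicate reaction labels")

    def has(self, species: str, reaction: str) -> bool:
        i = self.species.index(species)
        j = self.reactions.index(reaction)
        return bool(self.matrix[i, j])

    def reactions_of(self, species: str) -> set[str]:
        i = self.species.index(species)
        return {r for j, r in enumerate(self.reactions) if self.matrix[i, j]}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.species, columns=self.reactions
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpeciesReactionTable":
        return cls(
            species=list(df.index),
            reactions=list(df.columns),
            matrix=df.to_numpy(dtype=int),
        )


def reaction_capabilities(
    species_kos: Mapping[str, set[str]], db: ORAdb
) -> SpeciesReactionTable:
    """Evaluate every reaction's GPR rule against every species' KO set.

    Rows (species) and columns (reactions) are ordered
    lexicographically, so the output is deterministic.
    """
    if not species_kos:
        raise OradbError("empty species table")
    species = sorted(species_kos)
    reactions = db.reactions
    matrix = np.zeros((len(species), len(reactions)), dtype=int)
    for j, reaction in enumerate(reactions):
        rule = db.rule_for(reaction)
        for i, sp in enumerate(species):
            if rule.evaluate(species_kos[sp]):
                matrix[i, j] = 1
    return SpeciesReactionTable(species=species, reactions=reactions, matrix=matrix)


# --------------------------------------------------------------------------
# Database construction via a pluggable fetcher
# --------------------------------------------------------------------------

class Fetcher(Protocol):
    """Resolver used by :func:`build_oradb`.

    A live KEGG REST implementation can sit behind this interface;
    the bundled implementations are offline (dictionary- and
    directory-backed) so that database construction is reproducible
    and testable without network access.
    """

    def map_to_kos(self, identifier: str) -> set[str]:
        """KOs associated with a reaction or EC identifier."""
        ...

    def ko_fasta(self, ko: str) -> list[tuple[str, str]]:
        """Reference (sequence_id, protein) pairs for one KO."""
        ...

    def gpr_for(self, reactions: Sequence[str]) -> dict[str, str]:
        """Rule strings (AND/OR over KOs) for the given reactions."""
        ...

    def reactions_of_ko(self, ko: str) -> set[str]:
        """Reactions associated with a bare KO identifier (may be empty)."""
        ...


class DictFetcher:
    """In-memory fetcher for fixtures and tests."""

    def __init__(
        self,
        ko_seqs: Mapping[str, Sequence[tuple[str, str]]],
        reaction_map: Mapping[str, Iterable[str]] | None = None,
        gpr_rules: Mapping[str, str] | None = None,
        ec_map: Mapping[str, Iterable[str]] | None = None,
        ko_reactions: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self._ko_seqs = {k: list(v) for k, v in ko_seqs.items()}
        self._reaction_map = {
            k: set(v) for k, v in (reaction_map or {}).items()
        }
        self._gpr = dict(gpr_rules or {})
        self._ec_map = {k: set(v) for k, v in (ec_map or {}).items()}
        self._ko_reactions = {
            k: set(v) for k, v in (ko_reactions or {}).items()
        }

    def map_to_kos(self, identifier: str) -> set[str]:
        kind = classify_identifier(identifier)
        if kind == "reaction":
            return set(self._reaction_map.get(identifier.upper(), set()))
        if kind == "ec":
            return set(self._ec_map.get(identifier, set()))
        raise KeyError(identifier)

    def ko_fasta(self, ko: str) -> list[tuple[str, str]]:
        return list(self._ko_seqs.get(ko, []))

    def gpr_for(self, reactions: Sequence[str]) -> dict[str, str]:
        return {r: self._gpr[r] for r in reactions if r in self._gpr}

    def reactions_of_ko(self, ko: str) -> set[str]:
        return set(self._ko_reactions.get(ko, set()))


class OfflineFetcher(DictFetcher):
    """Fetcher backed by a directory in the ORAdb on-disk layout.

    The directory holds ``<ko>.fasta`` files, ``reaction_kos.tsv`` and
    optionally ``gpr_rules.tsv`` and ``ec_kos.tsv`` (columns: ec, ko).
    """

    def __init__(self, directory: str | Path) -> None:
        directory = Path(directory)
        if not directory.is_dir():
            raise OradbError(f"fetcher directory not found: {directory}")
        ko_seqs: dict[str, list[tuple[str, str]]] = {}
        for fasta in sorted(directory.glob("*.fasta")):
            ko = validate_ko(fasta.stem)
            ko_seqs[ko] = _read_protein_fasta(fasta)
        reaction_map: dict[str, set[str]] = {}
        ko_reactions: dict[str, set[str]] = {}
        mapping = directory / "reaction_kos.tsv"
        if mapping.exists():
            df = pd.read_csv(mapping, sep="\t", dtype=str)
            for _, row in df.iterrows():
                reaction = validate_reaction(row["reaction_id"])
                ko = validate_ko(row["ko_id"])
                reaction_map.setdefault(reaction, set()).add(ko)
                ko_reactions.setdefault(ko, set()).add(reaction)
        gpr: dict[str, str] = {}
        rules = directory / "gpr_rules.tsv"
        if rules.exists():
            df = pd.read_csv(rules, sep="\t", dtype=str)
            gpr = dict(zip(df["reaction_id"], df["rule"]))
        ec_map: dict[str, set[str]] = {}
        ec_file = directory / "ec_kos.tsv"
        if ec_file.exists():
            df = pd.read_csv(ec_file, sep="\t", dtype=str)
            for _, row in df.iterrows():
                ec_map.setdefault(row["ec"], set()).add(validate_ko(row["ko"]))
        super().__init__(ko_seqs, reaction_map, gpr, ec_map, ko_reactions)


@dataclass
class BuildReport:
    """What :func:`build_oradb` could and could not resolve."""

    resolved: dict[str, set[str]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)
    empty_kos: list[str] = field(default_factory=list)

    def ok(self) -> bool:
        return not self.unresolved


def build_oradb(
    ids: Sequence[str], fetcher: Fetcher
) -> tuple[ORAdb, BuildReport]:
    """Assemble an ORAdb from user identifiers via a fetcher.

    Identifiers are classified by pattern (``K#####`` → KO,
    ``R#####`` → reaction, dotted quad → EC number); anything else is
    reported unresolved.  Bare KOs are attached to the reactions the
    fetcher knows for them, or to a synthetic per-KO reaction when it
    knows none.
    """
    report = BuildReport()
    reaction_kos: dict[str, set[str]] = {}
    wanted_kos: set[str] = set()

    for raw_id in ids:
        token = raw_id.strip()
        if not token:
            continue
        kind = classify_identifier(token)
        if kind == "ko":
            ko = validate_ko(token)
            wanted_kos.add(ko)
            reactions = fetcher.reactions_of_ko(ko)
            if not reactions:
                reactions = {f"RX_{ko}"}
            for r in reactions:
                reaction_kos.setdefault(r, set()).add(ko)
            report.resolved[token] = {ko}
        elif kind in ("reaction", "ec"):
            try:
                kos = fetcher.map_to_kos(token)
            except KeyError:
                kos = set()
            if not kos:
                report.unresolved.append(token)
                continue
            kos = {validate_ko(k) for k in kos}
            wanted_kos |= kos
            key = token.upper() if kind == "reaction" else token
            reaction_kos.setdefault(key, set()).update(kos)
            report.resolved[token] = kos
        else:
            report.unresolved.append(token)

    ko_sequences: dict[str, list[tuple[str, str]]] = {}
    for ko in sorted(wanted_kos):
        seqs = fetcher.ko_fasta(ko)
        ko_sequences[ko] = [(sid, validate_protein_or_raise(seq, sid)) for sid, seq in seqs]
        if not seqs:
            report.empty_kos.append(ko)

    rule_strings = fetcher.gpr_for(sorted(reaction_kos))
    gpr = {
        reaction: parse_gpr(rule, reaction_id=reaction)
        for reaction, rule in rule_strings.items()
    }
    db = ORAdb(ko_sequences=ko_sequences, reaction_kos=reaction_kos, gpr=gpr)
    return db, report


def validate_protein_or_raise(seq: str, record_id: str) -> str:
    up = seq.upper()
    for ch in up:
        if ch not in PROTEIN_ALPHABET:
            raise OradbError(
                f"record {record_id}: illegal character {ch!r} in protein sequence"
            )
    return up


# --------------------------------------------------------------------------
# On-disk layout
# --------------------------------------------------------------------------

def _read_protein_fasta(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise OradbError(f"{path}: duplicate sequence id {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, validate_protein_or_raise(str(rec.seq), rec.id)))
    return records


def write_oradb(db: ORAdb, directory: str | Path) -> None:
    """Write the database to a directory (FASTA per KO + two TSVs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ko in db.kos:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in db.ko_sequences[ko]
        ]
        SeqIO.write(records, str(directory / f"{ko}.fasta"), "fasta")
    rows = [
        {"reaction_id": r, "ko_id": k}
        for r in db.reactions
        for k in sorted(db.reaction_kos[r])
    ]
    pd.DataFrame(rows, columns=["reaction_id", "ko_id"]).to_csv(
        directory / "reaction_kos.tsv", sep="\t", index=False
    )
    rule_rows = [
        {"reaction_id": r, "rule": db.gpr[r].unparse()} for r in sorted(db.gpr)
    ]
    pd.DataFrame(rule_rows, columns=["reaction_id", "rule"]).to_csv(
        directory / "gpr_rules.tsv", sep="\t", index=False
    )


def read_oradb(directory: str | Path) -> ORAdb:
    """Read a database directory written by :func:`write_oradb`."""
    directory = Path(directory)
    if not directory.is_dir():
        raise OradbError(f"ORAdb directory not found: {directory}")
    mapping = directory / "reaction_kos.tsv"
    if not mapping.exists():
        raise OradbError(f"missing mapping file: {mapping}")
    rules_path = directory / "gpr_rules.tsv"
    if not rules_path.exists():
        raise OradbError(f"missing rules file: {rules_path}")

    ko_sequences: dict[str, list[tuple[str, str]]] = {}
    for fasta in sorted(directory.glob("*.fasta")):
        ko = validate_ko(fasta.stem)
        if ko in ko_sequences:
            raise OradbError(f"duplicate KO file for {ko}")
        ko_sequences[ko] = _read_protein_fasta(fasta)

    reaction_kos: dict[str, set[str]] = {}
    df = pd.read_csv(mapping, sep="\t", dtype=str)
    if list(df.columns) != ["reaction_id", "ko_id"]:
        raise OradbError(
            f"{mapping}: expected columns reaction_id, ko_id; found {list(df.columns)}"
        )
    for _, row in df.iterrows():
        reaction_kos.setdefault(validate_reaction(row["reaction_id"]), set()).add(
            validate_ko(row["ko_id"])
        )

    gpr: dict[str, GprRule] = {}
    rules_df = pd.read_csv(rules_path, sep="\t", dtype=str)
    for _, row in rules_df.iterrows():
        reaction = validate_reaction(row["reaction_id"])
        gpr[reaction] = parse_gpr(row["rule"], reaction_id=reaction)

    return ORAdb(ko_sequences=ko_sequences, reaction_kos=reaction_kos, gpr=gpr)


def read_identifier_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line text file; ``#`` starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            out.append(token)
    return out
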