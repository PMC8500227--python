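"""Local protein alignment with Karlin–Altschul statistics.

This module wraps Smith–Waterman local alignment with affine gap
penalties (via :class:`Bio.Align.PairwiseAligner`) and adds the raw
score → bit score → E-value normalisation used to filter homology
hits throughout the annotation pipeline.  It also reads externally
computed hits in 12-column BLAST tabular format so users can plug in
DIAMOND/BLAST/MMseqs2 output instead of the internal aligner.

The E-value search space is plain ``m * n`` (query length times
database residue count) with no effective-length correction; the
pipeline is threshold-driven, so agreement with BLAST's exact
E-values is not required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "PROTEIN_ALPHABET",
    "ScoringScheme",
    "AlignmentHit",
    "AlignmentError",
    "local_align",
    "bit_score",
    "e_value",
    "search",
    "read_tabular_hits",
    "validate_protein",
]

#: The 20 standard amino acids plus the ambiguity code ``X``.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class AlignmentError(ValueError):
    """Raised for invalid sequences or malformed hit files."""


def validate_protein(seq: str, name: str = "sequence") -> str:
    """Validate an amino-acid sequence, returning it uppercased.

    Raises :class:`AlignmentError` naming the first offending position.
    """
    if not seq:
        raise AlignmentError(f"{name}: empty sequence")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in PROTEIN_ALPHABET:
            raise AlignmentError(
                f"{name}: illegal character {ch!r} at position {i + 1}"
            )
    return up


def _default_matrix():
    mat = substitution_matrices.load("BLOSUM62").copy()
    # X is treated as fully ambiguous: neutral (0) against everything.
    for c in mat.alphabet:
        mat["X", c] = 0.0
        mat[c, "X"] = 0.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and KA statistics.

    gap_open/gap_extend follow the BLAST convention: a gap of length g
    costs ``gap_open + g * gap_extend``.  ``lam`` and ``k_param`` are
    the Karlin–Altschul parameters used to convert raw scores to bits;
    the defaults (0.267, 0.041) are the standard gapped BLOSUM62/11/1
    values.
    """

    matrix: object = field(default_factory=_default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k_param: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.k_param <= 0:
            raise ValueError("lambda and k must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.matrix
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -float(self.gap_extend)
        return a

    @classmethod
    def blosum62(cls) -> "ScoringScheme":
        return cls()


@dataclass(frozen=True)
class AlignmentHit:
    """One best local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    pct_identity: float
    aln_len: int
    raw_score: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be within [0, 100]")


def bit_score(raw: float, scheme: ScoringScheme) -> float:
    """Karlin–Altschul normalised score: (lambda*S - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be non-negative for local alignment")
    return (scheme.lam * raw - math.log(scheme.k_param)) / math.log(2.0)


def e_value(bit: float, m: int, n: int) -> float:
    """Expected chance hits of >= bit bits in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("query length and database size must be >= 1")
    # 2**(-bit) underflows for bit > ~1074; the exact value is 0 at
    # double precision, which is the correct limit.
    try:
        return m * n * math.pow(2.0, -bit)
    except OverflowError:
        return math.inf if bit < 0 else 0.0


def raw_local_score(query: str, subject: str, scheme: ScoringScheme) -> int:
    """Maximum Smith–Waterman score only (no traceback); fast path."""
    q = validate_protein(query, "query")
    s = validate_protein(subject, "subject")
    return int(round(max(0.0, scheme.aligner().score(q, s))))


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: int | None = None,
) -> AlignmentHit:
    """Best local alignment of ``query`` against ``subject``.

    ``db_residues`` sets the ``n`` of the E-value search space; it
    defaults to ``len(subject)`` (a one-sequence database) and is
    overridden by :func:`search` with the full reference residue count.
    A raw score of 0 (no positive-scoring alignment) is reported as an
    empty hit with identity 0 over length 0.
    """
    scheme = scheme or ScoringScheme.blosum62()
    q = validate_protein(query, "query")
    s = validate_protein(subject, "subject")
    aligner = scheme.aligner()
    raw = int(round(max(0.0, aligner.score(q, s))))
    if raw > 0:
        aln = aligner.align(q, s)[0]  # deterministic first optimal traceback
        identities = aln.counts().identities
        aln_len = int(aln.length)
        pct = 100.0 * identities / aln_len
    else:
        aln_len = 0
        pct = 0.0
    bit = bit_score(raw, scheme)
    n = db_residues if db_residues is not None else len(s)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=bit,
        evalue=e_value(bit, len(q), n),
        pct_identity=pct,
        aln_len=aln_len,
    )


def search(
    queries: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 10.0,
) -> list[AlignmentHit]:
    """All-vs-all search: one best hit per (query, subject) pair.

    ``queries`` and ``reference`` are ``(sequence_id, sequence)``
    pairs.  The E-value search space ``n`` is the total residue count
    of the reference set.  Hits with ``evalue > max_evalue`` are
    dropped; results are ordered by query, then subject id.
    """
    if not queries:
        raise AlignmentError("empty query set")
    if not reference:
        raise AlignmentError("empty reference set")
    scheme = scheme or ScoringScheme.blosum62()
    n = sum(len(s) for _, s in reference)
    hits: list[AlignmentHit] = []
    for qid, q in sorted(queries):
        for sid, s in sorted(reference):
            hit = local_align(
                q, s, scheme, query_id=qid, subject_id=sid, db_residues=n
            )
            if hit.evalue <= max_evalue:
                hits.append(hit)
    return hits


_TABULAR_COLS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular (outfmt 6 style) hits.

    Only the fields the pipeline uses (ids, identity, length, E-value,
    bit score) are retained; the raw score is unavailable in this
    format and left unset.
    """
    hits: list[AlignmentHit] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLS:
                raise AlignmentError(
                    f"{path}: line {lineno}: expected {_TABULAR_COLS} "
                    f"tab-separated columns, found {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise AlignmentError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    bit_score=bits,
                    evalue=evalue,
                    pct_identity=pident,
                    aln_len=length,
                )
            )
    return hits
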