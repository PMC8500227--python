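"""Two-stage (relaxed/restrictive) functional annotation of ortholog
clusters against the ORAdb.

Stage 1 (relaxed): half of each cluster's sequences (sampled
uniformly, deterministically per cluster) are aligned against every
KO reference set; a KO whose best E-value reaches the permissive
threshold (default 0.001) becomes a *candidate* for that cluster.
Clusters without candidates are dropped.

Stage 2 (restrictive): every sequence of a surviving cluster is
aligned against the full reference set of each candidate KO; a
sequence is annotated with a KO when its best hit satisfies
``evalue <= restrictive_evalue`` (default 1e-9) and
``bit_score > min_bit_score`` (default 50, strictly greater).

The E-value search space ``n`` is the total residue count of the
ORAdb in both stages, so a given (sequence, reference) pair has the
same E-value whichever stage computes it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from random import Random
from typing import Mapping, Sequence

from .align import AlignmentHit, ScoringScheme, bit_score, e_value, local_align, raw_local_score
from .clusters import ClusterSet, OrthologCluster
from .gpr import ORAdb

__all__ = [
    "AnnotationConfig",
    "AnnotationResult",
    "AnnotationEvaluation",
    "AnnotationError",
    "sample_cluster",
    "relaxed_search",
    "restrictive_search",
    "annotate",
    "annotate_with_hits",
    "species_ko_table",
    "annotation_performance",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds and sampling parameters of the two-stage search."""

    relaxed_evalue: float = 0.001
    restrictive_evalue: float = 1e-9
    min_bit_score: float = 50.0  # strict inequality: bit must EXCEED this
    sample_fraction: float = 0.5
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.relaxed_evalue < self.restrictive_evalue:
            raise ValueError(
                "relaxed_evalue must be at least restrictive_evalue"
            )
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class AnnotationResult:
    """Candidates per cluster, per-sequence KO assignments with the
    best supporting hit, and (once aggregated) the species→KO map."""

    candidate_kos: dict[str, set[str]] = field(default_factory=dict)
    assignments: dict[str, dict[str, AlignmentHit]] = field(default_factory=dict)
    species_kos: dict[str, set[str]] = field(default_factory=dict)
    dropped_clusters: dict[str, str] = field(default_factory=dict)

    def annotated_pairs(self) -> set[tuple[str, str]]:
        """All (sequence_id, KO) assignment pairs."""
        return {
            (sid, ko)
            for sid, kos in self.assignments.items()
            for ko in kos
        }


def sample_cluster(
    cluster: OrthologCluster, fraction: float, seed: int
) -> list[str]:
    """Deterministic uniform sample (without replacement) of a
    cluster's sequence ids.

    Sample size is ``ceil(fraction * size)`` with a floor of one, so a
    singleton cluster always contributes its sequence.  The RNG stream
    is derived from the seed and the cluster id (CRC32), making the
    sample independent of cluster order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    ids = cluster.sequence_ids
    k = max(1, math.ceil(fraction * len(ids)))
    if k >= len(ids):
        return ids
    rng = Random(seed ^ zlib.crc32(cluster.cluster_id.encode()))
    return sorted(rng.sample(ids, k))


def _ko_references(db: ORAdb) -> dict[str, list[tuple[str, str]]]:
    return {ko: sorted(db.ko_sequences[ko]) for ko in db.kos}


def relaxed_search(
    clusters: ClusterSet,
    seqs: Mapping[str, str],
    db: ORAdb,
    scheme: ScoringScheme | None = None,
    config: AnnotationConfig | None = None,
) -> dict[str, set[str]]:
    """Stage 1: candidate KOs per cluster from the sampled sequences.

    ``seqs`` maps sequence ids to protein sequences.  Returns only
    clusters with at least one candidate KO.
    """
    scheme = scheme or ScoringScheme.blosum62()
    config = config or AnnotationConfig()
    if not db.ko_sequences:
        raise AnnotationError("empty ORAdb")
    refs = _ko_references(db)
    n_db = db.total_residues()
    if n_db == 0:
        raise AnnotationError("ORAdb has no reference residues")
    candidates: dict[str, set[str]] = {}
    for cluster in clusters.clusters:
        sampled = sample_cluster(cluster, config.sample_fraction, config.rng_seed)
        found: set[str] = set()
        for ko, ko_refs in refs.items():
            if _any_hit_at_most(
                sampled, seqs, ko_refs, scheme, n_db, config.relaxed_evalue
            ):
                found.add(ko)
        if found:
            candidates[cluster.cluster_id] = found
    return candidates


def _any_hit_at_most(
    sampled: Sequence[str],
    seqs: Mapping[str, str],
    ko_refs: Sequence[tuple[str, str]],
    scheme: ScoringScheme,
    n_db: int,
    threshold: float,
) -> bool:
    for sid in sampled:
        if sid not in seqs:
            raise AnnotationError(f"no sequence for cluster member {sid}")
        q = seqs[sid]
        for _, ref_seq in ko_refs:
            raw = raw_local_score(q, ref_seq, scheme)
            ev = e_value(bit_score(raw, scheme), len(q), n_db)
            if ev <= threshold:
                return True
    return False


def restrictive_search(
    candidates: Mapping[str, set[str]],
    clusters: ClusterSet,
    seqs: Mapping[str, str],
    db: ORAdb,
    scheme: ScoringScheme | None = None,
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Stage 2: confirm candidate KOs sequence-by-sequence.

    For each cluster and candidate KO, every cluster sequence is
    aligned against the KO's full reference set; the best reference
    (highest bit score, ties to the lexicographically first id) is
    kept, and the sequence is annotated when the best hit passes both
    thresholds.  A sequence may carry several KO annotations.
    """
    scheme = scheme or ScoringScheme.blosum62()
    config = config or AnnotationConfig()
    refs = _ko_references(db)
    n_db = db.total_residues()
    result = AnnotationResult(candidate_kos={k: set(v) for k, v in candidates.items()})
    by_id = {c.cluster_id: c for c in clusters.clusters}
    for cluster_id in sorted(candidates):
        if cluster_id not in by_id:
            raise AnnotationError(f"unknown cluster id {cluster_id}")
        cluster = by_id[cluster_id]
        confirmed_any = False
        for ko in sorted(candidates[cluster_id]):
            if ko not in refs:
                raise AnnotationError(f"candidate KO {ko} absent from ORAdb")
            ko_refs = refs[ko]
            if not ko_refs:
                continue
            for sid in cluster.sequence_ids:
                q = seqs[sid]
                best_ref, best_raw = None, -1
                for ref_id, ref_seq in ko_refs:
                    raw = raw_local_score(q, ref_seq, scheme)
                    if raw > best_raw:
                        best_ref, best_raw = (ref_id, ref_seq), raw
                bit = bit_score(best_raw, scheme)
                ev = e_value(bit, len(q), n_db)
                if ev <= config.restrictive_evalue and bit > config.min_bit_score:
                    hit = local_align(
                        q,
                        best_ref[1],
                        scheme,
                        query_id=sid,
                        subject_id=best_ref[0],
                        db_residues=n_db,
                    )
                    result.assignments.setdefault(sid, {})[ko] = hit
                    confirmed_any = True
        if not confirmed_any:
            result.dropped_clusters[cluster_id] = "no sequence passed the restrictive thresholds"
    for cluster in clusters.clusters:
        if cluster.cluster_id not in candidates:
            result.dropped_clusters[cluster.cluster_id] = "no candidate KO in the relaxed search"
    return result


def annotate(
    clusters: ClusterSet,
    seqs: Mapping[str, str],
    db: ORAdb,
    scheme: ScoringScheme | None = None,
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Run both stages with the internal aligner."""
    candidates = relaxed_search(clusters, seqs, db, scheme, config)
    return restrictive_search(candidates, clusters, seqs, db, scheme, config)


def annotate_with_hits(
    clusters: ClusterSet,
    db: ORAdb,
    hits: Sequence[AlignmentHit],
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Two-stage annotation driven by precomputed tabular hits.

    ``hits`` are (cluster sequence) → (ORAdb reference sequence)
    alignments from an external tool.  The same sampling and the same
    two thresholds apply; E-values and bit scores are taken from the
    hit file as-is.
    """
    config = config or AnnotationConfig()
    ref_ko: dict[str, str] = {}
    for ko, refs in db.ko_sequences.items():
        for sid, _ in refs:
            ref_ko[sid] = ko
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.subject_id in ref_ko:
            by_query.setdefault(h.query_id, []).append(h)

    candidates: dict[str, set[str]] = {}
    for cluster in clusters.clusters:
        sampled = sample_cluster(cluster, config.sample_fraction, config.rng_seed)
        found = {
            ref_ko[h.subject_id]
            for sid in sampled
            for h in by_query.get(sid, [])
            if h.evalue <= config.relaxed_evalue
        }
        if found:
            candidates[cluster.cluster_id] = found

    result = AnnotationResult(candidate_kos=candidates)
    for cluster in clusters.clusters:
        cid = cluster.cluster_id
        if cid not in candidates:
            result.dropped_clusters[cid] = "no candidate KO in the relaxed search"
            continue
        confirmed_any = False
        for sid in cluster.sequence_ids:
            per_ko: dict[str, AlignmentHit] = {}
            for h in by_query.get(sid, []):
                ko = ref_ko[h.subject_id]
                if ko not in candidates[cid]:
                    continue
                best = per_ko.get(ko)
                if best is None or (h.bit_score, best.subject_id) > (
                    best.bit_score,
                    h.subject_id,
                ):
                    per_ko[ko] = h
            for ko, h in per_ko.items():
                if h.evalue <= config.restrictive_evalue and h.bit_score > config.min_bit_score:
                    result.assignments.setdefault(sid, {})[ko] = h
                    confirmed_any = True
        if not confirmed_any:
            result.dropped_clusters[cid] = "no sequence passed the restrictive thresholds"
    return result


def species_ko_table(
    result: AnnotationResult, seq_species: Mapping[str, str]
) -> dict[str, set[str]]:
    """Aggregate per-sequence annotations to a species → KO-set map."""
    table: dict[str, set[str]] = {}
    for sid, kos in result.assignments.items():
        if sid not in seq_species:
            raise AnnotationError(f"annotated sequence {sid} has no species mapping")
        table.setdefault(seq_species[sid], set()).update(kos)
    result.species_kos = table
    return table


@dataclass(frozen=True)
class AnnotationEvaluation:
    """Annotation performance: matched reference annotations over the
    total number of reference annotations."""

    matching_annotated: int
    total_reference_annotations: int

    @property
    def performance(self) -> float:
        return self.matching_annotated / self.total_reference_annotations


def annotation_performance(
    predicted: set[tuple[str, str]], reference: set[tuple[str, str]]
) -> AnnotationEvaluation:
    """Fraction of reference (sequence, KO) annotations recovered."""
    if not reference:
        raise AnnotationError("reference annotation set is empty")
    return AnnotationEvaluation(
        matching_annotated=len(predicted & reference),
        total_reference_annotations=len(reference),
    )
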