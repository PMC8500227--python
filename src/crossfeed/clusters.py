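"""Ortholog clusters: model, Orthogroups.tsv I/O, fallback clusterer,
and pair-wise precision/recall evaluation.

Clustering proper is normally delegated to an external orthogroup
inference tool and imported through its ``Orthogroups.tsv`` output.
For self-contained runs, :func:`internal_cluster` provides a
documented approximation: single-linkage connected components over
reciprocal bit-score edges (no score normalisation, no MCL).

Evaluation uses pair semantics: precision is the fraction of
co-clustered sequence pairs whose function labels agree; recall is
the fraction of all same-label pairs that were co-clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .align import ScoringScheme, bit_score, raw_local_score

__all__ = [
    "ClusterError",
    "UndefinedMetricError",
    "OrthologCluster",
    "ClusterSet",
    "ClusterEvaluation",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
    "internal_cluster",
    "evaluate_clustering",
    "clustering_precision",
    "clustering_recall",
]


class ClusterError(ValueError):
    """Invalid cluster input."""


class UndefinedMetricError(ZeroDivisionError):
    """A precision/recall denominator is zero."""


@dataclass
class OrthologCluster:
    """One orthogroup: sequence ids grouped per species."""

    cluster_id: str
    members: dict[str, list[str]]  # species_id -> sequence ids

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise ClusterError(f"cluster {self.cluster_id} has no members")

    @property
    def sequence_ids(self) -> list[str]:
        return sorted(s for ids in self.members.values() for s in ids)

    @property
    def size(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def species_of(self, seq_id: str) -> str:
        for sp, ids in self.members.items():
            if seq_id in ids:
                return sp
        raise KeyError(seq_id)


@dataclass
class ClusterSet:
    """Clusters plus the singletons left unassigned; together they
    partition the input sequence ids."""

    clusters: list[OrthologCluster]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            for sid in cluster.sequence_ids:
                if sid in seen:
                    raise ClusterError(
                        f"sequence id {sid} appears in more than one cluster"
                    )
                seen.add(sid)
        for sid in self.unassigned:
            if sid in seen:
                raise ClusterError(
                    f"sequence id {sid} is both clustered and unassigned"
                )
            seen.add(sid)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, seq_id: str) -> str | None:
        for cluster in self.clusters:
            if seq_id in cluster.sequence_ids:
                return cluster.cluster_id
        return None

    def all_sequence_ids(self) -> list[str]:
        out = [s for c in self.clusters for s in c.sequence_ids]
        out.extend(self.unassigned)
        return sorted(out)


# --------------------------------------------------------------------------
# Orthogroups.tsv dialect
# --------------------------------------------------------------------------

def read_orthogroups_tsv(
    path: str | Path, species_names: Sequence[str]
) -> ClusterSet:
    """Read an ``Orthogroups.tsv`` file (header: Orthogroup + species
    columns; cells are comma-separated gene ids, possibly empty)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.columns[0] != "Orthogroup":
        raise ClusterError(
            f"{path}: first column must be 'Orthogroup', found {df.columns[0]!r}"
        )
    header_species = list(df.columns[1:])
    unknown = [s for s in header_species if s not in set(species_names)]
    if unknown:
        raise ClusterError(
            f"{path}: species in header not in provided species list: {unknown}"
        )
    clusters: list[OrthologCluster] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        members: dict[str, list[str]] = {}
        for sp in header_species:
            cell = row[sp].strip()
            if not cell:
                continue
            ids = [g.strip() for g in cell.split(",") if g.strip()]
            for g in ids:
                if g in seen:
                    raise ClusterError(f"{path}: gene id {g} appears in two rows")
                seen.add(g)
            members[sp] = ids
        clusters.append(OrthologCluster(cluster_id=row["Orthogroup"], members=members))
    return ClusterSet(clusters=clusters)


def write_orthogroups_tsv(
    clusters: ClusterSet, path: str | Path, species_names: Sequence[str]
) -> None:
    species = sorted(species_names)
    rows = []
    for cluster in clusters.clusters:
        row = {"Orthogroup": cluster.cluster_id}
        for sp in species:
            row[sp] = ", ".join(sorted(cluster.members.get(sp, [])))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Fallback clusterer
# --------------------------------------------------------------------------

def internal_cluster(
    seqs: Mapping[str, Sequence[tuple[str, str]]],
    scheme: ScoringScheme | None = None,
    min_bit: float = 50.0,
) -> ClusterSet:
    """Single-linkage clustering over bit-score edges.

    ``seqs`` maps species ids to ``(sequence_id, sequence)`` pairs.
    Two sequences are joined when the local alignment in both
    directions reaches ``min_bit`` bits; connected components of size
    >= 2 become clusters (ids ``OG0000000``...), singletons go to
    ``unassigned``.  Output is independent of input order: components
    are sorted by their lexicographically smallest member.
    """
    scheme = scheme or ScoringScheme.blosum62()
    flat: list[tuple[str, str, str]] = []  # (seq_id, species, sequence)
    seen: set[str] = set()
    for sp in sorted(seqs):
        for sid, seq in seqs[sp]:
            if sid in seen:
                raise ClusterError(f"duplicate sequence id across species: {sid}")
            seen.add(sid)
            flat.append((sid, sp, seq))
    if not flat:
        raise ClusterError("no sequences to cluster")
    flat.sort()

    graph = nx.Graph()
    graph.add_nodes_from(sid for sid, _, _ in flat)
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            a, b = flat[i], flat[j]
            # the default matrix is symmetric, but reciprocity is
            # checked explicitly so custom asymmetric schemes behave
            fwd = bit_score(raw_local_score(a[2], b[2], scheme), scheme)
            if fwd < min_bit:
                continue
            rev = bit_score(raw_local_score(b[2], a[2], scheme), scheme)
            if rev >= min_bit:
                graph.add_edge(a[0], b[0])

    species_of = {sid: sp for sid, sp, _ in flat}
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    clusters: list[OrthologCluster] = []
    unassigned: list[str] = []
    idx = 0
    for comp in components:
        if len(comp) < 2:
            unassigned.extend(comp)
            continue
        members: dict[str, list[str]] = {}
        for sid in comp:
            members.setdefault(species_of[sid], []).append(sid)
        clusters.append(
            OrthologCluster(cluster_id=f"OG{idx:07d}", members=members)
        )
        idx += 1
    return ClusterSet(clusters=clusters, unassigned=sorted(unassigned))


# --------------------------------------------------------------------------
# Pair-wise evaluation
# --------------------------------------------------------------------------

@dataclass
class ClusterEvaluation:
    correctly_clustered_pairs: int
    total_clustered_pairs: int
    total_true_pairs: int

    @property
    def precision(self) -> float:
        if self.total_clustered_pairs == 0:
            raise UndefinedMetricError(
                "precision undefined: no co-clustered pairs"
            )
        return self.correctly_clustered_pairs / self.total_clustered_pairs

    @property
    def recall(self) -> float:
        if self.total_true_pairs == 0:
            raise UndefinedMetricError(
                "recall undefined: no same-label pairs in the truth"
            )
        return self.correctly_clustered_pairs / self.total_true_pairs


def evaluate_clustering(
    clusters: ClusterSet, truth: Mapping[str, str]
) -> ClusterEvaluation:
    """Count co-clustered pairs, correct pairs, and true pairs.

    Every clustered sequence must carry a truth label.  Unassigned
    sequences contribute no clustered pairs, but their same-label
    pairs still count in the recall denominator.
    """
    correct = 0
    total_clustered = 0
    for cluster in clusters.clusters:
        ids = cluster.sequence_ids
        for sid in ids:
            if sid not in truth:
                raise ClusterError(f"clustered sequence {sid} has no truth label")
        for a, b in combinations(ids, 2):
            total_clustered += 1
            if truth[a] == truth[b]:
                correct += 1
    total_true = sum(
        1 for a, b in combinations(sorted(truth), 2) if truth[a] == truth[b]
    )
    return ClusterEvaluation(
        correctly_clustered_pairs=correct,
        total_clustered_pairs=total_clustered,
        total_true_pairs=total_true,
    )


def clustering_precision(
    clusters: ClusterSet, truth: Mapping[str, str]
) -> ClusterEvaluation:
    """Pair-wise clustering precision; raises if no pairs were clustered."""
    ev = evaluate_clustering(clusters, truth)
    ev.precision  # raises UndefinedMetricError on a zero denominator
    return ev


def clustering_recall(
    clusters: ClusterSet, truth: Mapping[str, str]
) -> ClusterEvaluation:
    """Pair-wise clustering recall; raises if the truth has no pairs."""
    ev = evaluate_clustering(clusters, truth)
    ev.recall
    return ev
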