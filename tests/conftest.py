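"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they
check: the local-alignment oracle enumerates aligned-column index
sets instead of running dynamic programming, and the pair-counting
oracle loops over raw pairs instead of using the evaluation classes.
"""

from __future__ import annotations

from itertools import combinations
from random import Random

import pytest

from crossfeed.align import ScoringScheme
from crossfeed.gpr import And, GprRule, KoLeaf, Or, parse_gpr


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def r02451_rule() -> GprRule:
    # benzoyl-CoA reductase: a four-subunit complex or a two-subunit one
    return parse_gpr(
        "(K04112 AND K04113 AND K04114 AND K04115) OR (K19515 AND K19516)",
        reaction_id="R02451",
    )


def brute_force_local_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Exponential-time local alignment oracle.

    An optimal local alignment starts and ends with an aligned column,
    so its score is determined by the increasing index tuples I (in a)
    and J (in b) of its aligned columns: substitution scores plus one
    affine gap per unaligned run between consecutive columns.  The
    oracle maximises over all such tuples; 0 (the empty alignment) is
    always available.
    """
    mat = scheme.matrix

    def gap(g: int) -> int:
        return 0 if g == 0 else -(scheme.gap_open + g * scheme.gap_extend)

    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for idx_a in combinations(range(len(a)), k):
            for idx_b in combinations(range(len(b)), k):
                score = 0
                for t in range(k):
                    score += int(mat[a[idx_a[t]], b[idx_b[t]]])
                    if t > 0:
                        score += gap(idx_a[t] - idx_a[t - 1] - 1)
                        score += gap(idx_b[t] - idx_b[t - 1] - 1)
                best = max(best, score)
    return best


def random_rule(rng: Random, kos: list[str], depth: int = 2):
    """Random AND/OR expression over the given KO pool."""
    if depth == 0 or rng.random() < 0.4:
        return KoLeaf(rng.choice(kos))
    op = rng.choice([And, Or])
    n_children = rng.randint(2, 3)
    return op(tuple(random_rule(rng, kos, depth - 1) for _ in range(n_children)))


def set_partitions(items: list):
    """All set partitions of ``items`` (each partition a list of blocks)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition
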