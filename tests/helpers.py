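"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: pairwise longest common
substrings come from difflib, transitive closure from scipy's sparse graph
machinery, interval unions from explicit merging, and the hypergeometric
tail from scipy.stats.
"""

from __future__ import annotations

from difflib import SequenceMatcher

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def longest_common_substring(a: str, b: str) -> int:
    m = SequenceMatcher(None, a, b, autojunk=False).find_longest_match(
        0, len(a), 0, len(b)
    )
    return m.size


def brute_force_partition(
    sequences: dict[str, str], min_overlap: int = 50, strand_agnostic: bool = True
) -> set[frozenset[str]]:
    """All-pairs longest-common-substring check + connected components."""
    ids = sorted(sequences)
    n = len(ids)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            hit = longest_common_substring(a, b) >= min_overlap
            if not hit and strand_agnostic:
                hit = longest_common_substring(a, revcomp(b)) >= min_overlap
            if hit:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    groups: dict[int, set[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(ids[idx])
    return {frozenset(g) for g in groups.values()}


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open integer intervals."""
    if not intervals:
        return 0
    ordered = sorted(intervals)
    total = 0
    cur_s, cur_e = ordered[0]
    for s, e in ordered[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
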