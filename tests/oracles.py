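"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own scanning/clustering code paths:
the off-target oracle walks every genome position with plain string
comparison, and the clustering oracle builds an explicit mismatch graph and
takes scipy connected components.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_offtargets(genome: dict[str, str], spacer: str,
                           max_mm: int) -> set[tuple[str, str, int, int]]:
    """Every NGG-adjacent window within max_mm: (contig, strand, start, mm).

    ``start`` is the forward-strand coordinate of the 23-mer window,
    matching the convention of the scanner under test.
    """
    out = set()
    w = len(spacer) + 3
    for contig, seq in genome.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else rc(seq)
            for i in range(L - w + 1):
                if s[i + w - 2:i + w] != "GG":
                    continue
                mm = 0
                for a, b in zip(s[i:i + len(spacer)], spacer):
                    if a != b:
                        mm += 1
                        if mm > max_mm:
                            break
                else:
                    start = i if strand == "+" else L - i - w
                    out.add((contig, strand, start, mm))
    return out


def cluster_oracle(seqs: list[str], max_mm: int) -> list[Counter]:
    """Single-linkage Hamming clusters via an explicit graph."""
    counts = Counter(seqs)
    uniq = list(counts)
    n = len(uniq)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = uniq[i], uniq[j]
            if len(a) != len(b):
                continue
            if sum(x != y for x, y in zip(a, b)) <= max_mm:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    groups: dict[int, Counter] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, Counter())[uniq[i]] = counts[uniq[i]]
    return list(groups.values())
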