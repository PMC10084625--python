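"""Independent dense MCL re-derivation, used only as a test oracle.

Deliberately written from the algorithm definition (explicit loops, repeated
matrix multiplication, transitive merging of attractor groups) rather than
sharing code with the package, so the two paths can disagree.  The
overlapping-attractor resolution rule (largest attractor value, ties to the
smallest representative) is part of the documented contract and is
re-implemented here independently.
"""

from __future__ import annotations

import numpy as np


def reference_mcl_clusters(
    nodes,
    edge_list,
    inflation: float,
    expansion: int = 2,
    self_loop: float = 1.0,
    iterations: int = 300,
    eps: float = 1e-6,
) -> set[frozenset]:
    order = sorted(nodes, key=str)
    index = {node: i for i, node in enumerate(order)}
    n = len(order)
    if n == 0:
        return set()

    a = np.zeros((n, n))
    for u, v, w in edge_list:
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    for i in range(n):
        a[i, i] += self_loop

    m = a / a.sum(axis=0)
    for _ in range(iterations):
        previous = m
        expanded = np.eye(n)
        for _ in range(expansion):
            expanded = expanded.dot(m)
        m = expanded**inflation
        m = m / m.sum(axis=0)
        if np.abs(m - previous).max() < 1e-9:
            break

    attractor_rows = [i for i in range(n) if m[i, i] > eps]
    groups: list[dict] = []
    for row in attractor_rows:
        cols = {int(j) for j in np.flatnonzero(m[row] > eps)} | {row}
        groups.append({"cols": cols, "rows": [row]})
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i]["cols"] & groups[j]["cols"]:
                    groups[i]["cols"] |= groups[j]["cols"]
                    groups[i]["rows"] += groups[j]["rows"]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break

    representatives = [min(str(order[c]) for c in g["cols"]) for g in groups]
    clusters: dict[int, set] = {}
    singletons: list[set] = []
    for col in range(n):
        candidates = [
            (max(m[r, col] for r in g["rows"]), representatives[gi], gi)
            for gi, g in enumerate(groups)
            if col in g["cols"]
        ]
        if not candidates:
            singletons.append({order[col]})
            continue
        best_value = max(v for v, _, _ in candidates)
        _, chosen = min(
            (rep, gi) for v, rep, gi in candidates if v == best_value
        )
        clusters.setdefault(chosen, set()).add(order[col])

    return {frozenset(c) for c in list(clusters.values()) + singletons}
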