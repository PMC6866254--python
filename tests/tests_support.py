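"""Shared independent oracles for the test suite."""

import itertools

import numpy as np

from salmonigh.repertoire import _j_motif_codon, _longest_common_substring


def d_recoverable(t, vmap, dmap, jmap, min_d=5):
    """Whether the planted D allele is identifiable from the read's true
    junction interior, computed from the simulation truth row alone.

    The V 2nd-CYS codon anchors the junction, so V trimming beyond 3 nt
    destroys the anchor; within that, the retained D core (minus any part
    absorbed into the anchor codon slot) must be the strict longest exact
    match among all D regions."""
    if t.v_trim > 3:
        return False
    v, j, d = vmap[t.v_call], jmap[t.j_call], dmap[t.d_call]
    core = d[t.d_trim5 : len(d) - t.d_trim3]
    motif = _j_motif_codon(j)
    junction = (
        v[len(v) - 3 : len(v) - t.v_trim] + t.ins1 + core + t.ins2 + j[t.j_trim : motif + 3]
    )
    interior = junction[3:-3]
    scores = {name: _longest_common_substring(interior, s) for name, s in dmap.items()}
    own = scores.pop(t.d_call)
    return own >= min_d and all(s < own for s in scores.values())


def brute_upgma_heights(dist, labels):
    """Exhaustive average-linkage agglomeration, recomputing every cluster
    distance from the original matrix at each step."""
    clusters = [frozenset([l]) for l in labels]
    idx = {l: i for i, l in enumerate(labels)}

    def cdist(c1, c2):
        return float(np.mean([dist[idx[a], idx[b]] for a in c1 for b in c2]))

    heights = {}
    while len(clusters) > 1:
        best = min(
            (cdist(x, y), tuple(sorted((min(x), min(y)))), x, y)
            for x, y in itertools.combinations(clusters, 2)
        )
        _, _, x, y = best
        clusters = [c for c in clusters if c not in (x, y)] + [x | y]
        heights[x | y] = best[0] / 2
    return heights


def node_heights(tree):
    out = {}

    def rec(node):
        if node.is_leaf:
            return
        out[frozenset(node.leaves())] = node.height
        rec(node.left)
        rec(node.right)

    rec(tree)
    return out
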