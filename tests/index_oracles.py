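"""Independent brute-force oracles for the distance-based indices.

Deliberately naive: a fresh BFS per edge endpoint via networkx, pure-Python
sums, no sharing of distance matrices with the implementation under test.
"""

import math

import networkx as nx


def brute_edge_partition(g, r, s):
    dr = nx.single_source_shortest_path_length(g, r)
    ds = nx.single_source_shortest_path_length(g, s)
    alpha_r = sum(1 for t in g if dr[t] < ds[t])
    alpha_s = sum(1 for t in g if ds[t] < dr[t])
    ties = g.number_of_nodes() - alpha_r - alpha_s
    return alpha_r, alpha_s, ties


def brute_indices(g):
    """Dict of the six indices computed edge by edge from scratch."""
    sz = pi = mo = 0
    abc = ngg = 0.0
    for r, s in g.edges():
        ar, as_, _ = brute_edge_partition(g, r, s)
        sz += ar * as_
        pi += ar + as_
        mo += abs(ar - as_)
        abc += math.sqrt((ar + as_ - 2) / (ar * as_))
        ngg += 1.0 / math.sqrt(ar * as_)
    w = 0
    for r in g:
        w += sum(nx.single_source_shortest_path_length(g, r).values())
    return {"Sz": sz, "ABC": abc, "PI": pi, "MO": mo, "NGG": ngg, "W": w // 2}


def brute_is_distance_balanced(g):
    return all(
        brute_edge_partition(g, r, s)[0] == brute_edge_partition(g, r, s)[1]
        for r, s in g.edges()
    )
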