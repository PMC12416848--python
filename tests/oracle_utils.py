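"""Independent oracles and random-community generators for the test suite.

The scalar right-hand-side here is a deliberate, loop-based transcription
of the growth equation, kept free of any code from the package's
vectorized implementation so the two can be compared as independent
routes to the same quantity.
"""

from __future__ import annotations

import numpy as np

from ecoassembly import Community, InteractionMatrices, SpeciesTraits


def scalar_rhs(x, c, pplus, pminus, m, r, s, delta, h_p, h_m):
    """Loop-based per-species derivative of the community dynamics."""
    S = len(x)
    out = np.zeros(S)
    for i in range(S):
        npos = sum(1 for j in range(S) if m[i][j] > 0) + sum(
            1 for j in range(S) if pplus[i][j] > 0
        )
        denom_i_p = 1.0 + h_p * sum(pplus[i][k] * x[k] for k in range(S))
        denom_i_m = 1.0 + h_m * sum(m[i][k] * x[k] for k in range(S))
        neg = 0.0
        pos = 0.0
        for j in range(S):
            denom_j_p = 1.0 + h_p * sum(pplus[j][k] * x[k] for k in range(S))
            neg += -c[i][j] * x[j] - pminus[i][j] * x[j] / denom_j_p
            pos += pplus[i][j] * x[j] / denom_i_p + m[i][j] * x[j] / denom_i_m
        out[i] = x[i] * (r[i] - delta * npos - s[i] * x[i] + neg) + x[i] * pos
    return out


def random_community(rng: np.random.Generator, S: int, p_link: float = 0.4,
                     sigma: float = 0.2) -> Community:
    """A structurally valid random community for oracle comparisons."""
    net = InteractionMatrices.zeros(S)
    for i in range(S):
        for j in range(i + 1, S):
            if rng.uniform() >= p_link:
                continue
            kind = rng.integers(3)
            w1, w2 = abs(rng.normal(0, sigma)), abs(rng.normal(0, sigma))
            if kind == 0:
                net.c[i, j], net.c[j, i] = w1, w2
            elif kind == 1:
                net.m[i, j], net.m[j, i] = w1, w2
            else:
                if rng.uniform() < 0.5:
                    i_, j_ = i, j
                else:
                    i_, j_ = j, i
                net.pplus[i_, j_] = min(w1, w2)
                net.pminus[j_, i_] = w2
    traits = SpeciesTraits(rng.normal(0.1, 0.01, S), 1.0 / rng.lognormal(0.1, 0.5, S))
    x = rng.uniform(0.01, 0.5, S)
    com = Community(net, traits, x, list(range(S)))
    com.validate()
    return com


def exhaustive_best_modularity(graph, resolution: float = 1.0) -> float:
    """Brute-force maximum of the partition score over ALL node partitions.

    Only feasible for small graphs (Bell(8) = 4140 partitions).
    """
    import networkx as nx

    nodes = list(graph.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [head]] + part[k + 1 :]
            yield part + [[head]]

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(b) for b in part], resolution=resolution)
        best = max(best, q)
    return float(best)
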